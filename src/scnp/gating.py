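"""Hierarchical gating of single-cell events.

Four nested populations are identified per well, mirroring routine
leukemia phospho-flow practice:

1. **intact** cells — a scatter (FSC/SSC) region excluding debris and
   aggregates;
2. **viable** cells — Amine Aqua (amine-reactive viability dye) below a
   threshold; dead/necrotic cells take up the dye strongly;
3. **blast** cells — CD45-dim / SSC-low region of the viable cells
   (leukemic blasts express less CD45 than mature lymphocytes);
4. **healthy blast** cells — blasts negative for cleaved PARP, i.e. not
   executing apoptosis; the split point is the 98th percentile of the
   autofluorescence well's cPARP values (see :mod:`scnp.metrics`).

Gate boundaries for the scatter and CD45 gates are absolute rectangles on
the calibrated intensity scale by default (documented in
:class:`GateParams`); within-well quantile bounds are available as an
alternative mode.  The viability and cPARP thresholds are derived from a
reference (autofluorescence/unstained) well, never hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import cparp_split_point, NonEvaluableError

__all__ = ["GateParams", "PopulationIndex", "gate_hierarchy",
           "cparp_negative_gate", "viability_threshold_from_reference"]

VIABILITY_PERCENTILE = 98.0


@dataclass(frozen=True)
class GateParams:
    """Gate boundaries.

    ``mode="absolute"`` interprets the scatter and CD45 bounds as raw
    intensity values (matching the simulator's documented intensity scale,
    where debris sits near 10**1.8 and blasts near 10**2.6 on FSC);
    ``mode="quantile"`` interprets them as within-well quantiles in [0, 1].
    The viability threshold is not part of the params: it comes from a
    reference well (98th percentile of its Amine Aqua values) passed to
    :func:`gate_hierarchy`.
    """

    mode: str = "absolute"
    fsc_bounds: tuple[float, float] = (10.0 ** 2.2, 10.0 ** 3.2)
    ssc_bounds: tuple[float, float] = (10.0 ** 1.9, 10.0 ** 3.0)
    cd45_bounds: tuple[float, float] = (10.0 ** 2.4, 10.0 ** 3.35)
    ssc_blast_max: float = 10.0 ** 2.7

    @classmethod
    def quantile_defaults(cls) -> "GateParams":
        return cls(mode="quantile", fsc_bounds=(0.02, 0.98),
                   ssc_bounds=(0.02, 0.98), cd45_bounds=(0.0, 0.7),
                   ssc_blast_max=0.9)


@dataclass
class PopulationIndex:
    """Nested boolean masks over one well's events."""

    intact: np.ndarray
    viable: np.ndarray
    blast: np.ndarray
    healthy_blast: np.ndarray | None = None

    @property
    def counts(self) -> dict[str, int]:
        out = {"intact": int(self.intact.sum()),
               "viable": int(self.viable.sum()),
               "blast": int(self.blast.sum())}
        if self.healthy_blast is not None:
            out["healthy_blast"] = int(self.healthy_blast.sum())
        return out

    def check_nested(self) -> None:
        assert not np.any(self.viable & ~self.intact)
        assert not np.any(self.blast & ~self.viable)
        if self.healthy_blast is not None:
            assert not np.any(self.healthy_blast & ~self.blast)


def _bounds(values: np.ndarray, lo, hi, mode: str) -> np.ndarray:
    if mode == "quantile":
        if values.size == 0:
            return np.zeros(0, dtype=bool)
        lo, hi = np.quantile(values, [lo, hi])
    return (values >= lo) & (values <= hi)


def viability_threshold_from_reference(reference_events) -> float:
    """Viability cut: 98th percentile of the reference (autofluorescence /
    unstained) well's Amine Aqua values, mirroring the cPARP split rule."""
    aqua = reference_events.data["AquaAmine"].to_numpy(dtype=float)
    if aqua.size == 0:
        raise NonEvaluableError("empty reference well; no viability threshold")
    return float(np.percentile(aqua, VIABILITY_PERCENTILE))


def gate_hierarchy(events, params: GateParams | None = None, *,
                   viability_threshold: float | None = None,
                   autofluorescence_cparp=None) -> PopulationIndex:
    """Apply the scatter -> viability -> CD45 gating hierarchy to one well.

    Parameters
    ----------
    events : EventTable with FSC, SSC, AquaAmine and CD45 channels.
    params : gate boundaries (defaults: :class:`GateParams`).
    viability_threshold : absolute Amine Aqua cut; if None, falls back to
        the well's own 98th percentile (sensible only for mostly-live wells).
    autofluorescence_cparp : optional cPARP values of the autofluorescence
        well; when given, the cPARP-negative (healthy blast) mask is filled
        in as well.

    An empty intact gate is reported with a warning and all-zero masks, not
    an exception.
    """
    if params is None:
        params = GateParams()
    data = events.data
    for ch in ("FSC", "SSC", "AquaAmine", "CD45"):
        if ch not in data.columns:
            raise KeyError(f"gating requires channel {ch!r}")
    fsc = data["FSC"].to_numpy(dtype=float)
    ssc = data["SSC"].to_numpy(dtype=float)
    aqua = data["AquaAmine"].to_numpy(dtype=float)
    cd45 = data["CD45"].to_numpy(dtype=float)

    intact = (_bounds(fsc, *params.fsc_bounds, params.mode)
              & _bounds(ssc, *params.ssc_bounds, params.mode))
    if intact.size and not intact.any():
        warnings.warn(f"well {events.well_id}: empty intact gate")

    if viability_threshold is None:
        viability_threshold = (float(np.percentile(aqua, VIABILITY_PERCENTILE))
                               if aqua.size else np.inf)
    viable = intact & (aqua <= viability_threshold)

    if params.mode == "quantile":
        vals = cd45[viable]
        if vals.size:
            lo, hi = np.quantile(vals, params.cd45_bounds)
            smax = np.quantile(ssc[viable], params.ssc_blast_max)
        else:
            lo = hi = smax = np.nan
        blast = viable & (cd45 >= lo) & (cd45 <= hi) & (ssc <= smax)
    else:
        blast = (viable
                 & (cd45 >= params.cd45_bounds[0])
                 & (cd45 <= params.cd45_bounds[1])
                 & (ssc <= params.ssc_blast_max))

    healthy = None
    if autofluorescence_cparp is not None:
        mask, _ = cparp_negative_gate(data["cPARP"].to_numpy(dtype=float),
                                      autofluorescence_cparp)
        healthy = blast & mask
    return PopulationIndex(intact=intact, viable=viable, blast=blast,
                           healthy_blast=healthy)


def cparp_negative_gate(blast_cparp, autofluorescence_cparp):
    """cPARP-negative mask over blast events plus the split point used.

    The split point is the 98th percentile of the autofluorescence well's
    cPARP values (linear-interpolation percentile); an empty
    autofluorescence well is an error — there is no fallback threshold.
    """
    split = cparp_split_point(autofluorescence_cparp)
    b = np.asarray(blast_cparp, dtype=float)
    return b <= split, split
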