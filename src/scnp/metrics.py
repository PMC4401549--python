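"""SCNP node metrics.

A "signaling node" is a (modulator, exposure time, proteomic readout)
triple, e.g. AraC+Dauno / 24 h / cPARP.  For each node and gated cell
population, five per-sample metrics summarize the readout distribution
against one of two reference wells — the autofluorescence well ``a``
(cells stained with no antibody against the readout) or the unmodulated
well ``u`` (cells processed identically but without the modulator):

* ``Basal   = log2(ERF_u / ERF_a)`` — baseline signal over autofluorescence
* ``log2Fold = log2(ERF_m / ERF_u)`` — modulated fold change
* ``Uu`` — Mann-Whitney U of modulated vs unmodulated cells scaled to (0,1)
* ``Ua`` — same with the autofluorescence well as reference
* ``PhIntact`` — percent of blast cells negative for cleaved PARP, with the
  positive/negative split at the 98th percentile of the autofluorescence well

ERF denotes bead-calibrated intensities; the location statistic in the
ratio metrics is the per-well median (the mean is available via the
``location`` argument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

__all__ = [
    "NodeDefinition",
    "NodeMetricRecord",
    "NonEvaluableError",
    "metric_basal",
    "metric_log2fold",
    "metric_uu",
    "metric_ua",
    "metric_phintact",
    "cparp_split_point",
    "amine_aqua_death_metric",
    "compute_node_table",
    "node_table_to_frame",
]

CPARP_SPLIT_PERCENTILE = 98.0


class NonEvaluableError(ValueError):
    """A metric is undefined on these inputs (empty well, nonpositive median)."""


@dataclass(frozen=True)
class NodeDefinition:
    """One signaling node: modulator, exposure time, readout channel.

    ``population`` names the gated cell population the metrics are computed
    on: short-term signaling nodes use the cPARP-negative ("healthy")
    blasts, while the 24 h apoptosis/chemosensitivity nodes use all viable
    blasts (the cPARP shift itself is the signal there).  ``u_modulator``
    names the well serving as the unmodulated reference — "unmodulated" for
    short-term nodes, the untreated 24 h well for 24 h drug nodes.
    """

    modulator: str
    time_hours: float
    readout: str
    population: Literal["blast", "healthy_blast", "intact"] = "healthy_blast"
    u_modulator: str = "unmodulated"
    metrics: tuple[str, ...] = ("Basal", "log2Fold", "Uu", "Ua")

    @property
    def node_id(self) -> str:
        t = (f"{self.time_hours:g}h" if self.time_hours >= 1
             else f"{self.time_hours * 60:g}min")
        return f"{self.modulator}|{t}|{self.readout}"


@dataclass
class NodeMetricRecord:
    patient_id: str
    tissue: str
    node_id: str
    metric: str
    value: float
    n_cells: int
    evaluable: bool
    reason: str | None = None


def _location(values, location: str) -> float:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise NonEvaluableError("empty well")
    return float(np.median(v)) if location == "median" else float(np.mean(v))


def _log2_ratio(num_values, den_values, location: str) -> float:
    num = _location(num_values, location)
    den = _location(den_values, location)
    if num <= 0 or den <= 0:
        raise NonEvaluableError(
            f"nonpositive {location} ({num:.4g} / {den:.4g}); "
            "log-ratio metric undefined")
    return math.log2(num / den)


def metric_basal(u_values, a_values, location: str = "median") -> float:
    """Basal = log2(location of unmodulated / location of autofluorescence)."""
    return _log2_ratio(u_values, a_values, location)


def metric_log2fold(m_values, u_values, location: str = "median") -> float:
    """log2Fold = log2(location of modulated / location of unmodulated)."""
    return _log2_ratio(m_values, u_values, location)


def metric_uu(m_values, u_values) -> float:
    """Scaled Mann-Whitney U of modulated vs unmodulated cells, in [0, 1].

    U/(n_m * n_u) with tied pairs given half credit, so identical wells give
    exactly 0.5; values above 0.5 mean the modulated cells are
    stochastically brighter.
    """
    m = np.asarray(m_values, dtype=float)
    u = np.asarray(u_values, dtype=float)
    if m.size == 0 or u.size == 0:
        raise NonEvaluableError("empty well")
    return mann_whitney_u(m, u) / (m.size * u.size)


def metric_ua(m_values, a_values) -> float:
    """Scaled Mann-Whitney U with the autofluorescence well as reference."""
    return metric_uu(m_values, a_values)


def cparp_split_point(autofluorescence_cparp) -> float:
    """cPARP positive/negative split: 98th percentile of the autofluorescence
    well, with linear interpolation between order statistics."""
    a = np.asarray(autofluorescence_cparp, dtype=float)
    if a.size == 0:
        raise NonEvaluableError("empty autofluorescence well; no split point")
    return float(np.percentile(a, CPARP_SPLIT_PERCENTILE))


def metric_phintact(blast_cparp_values, autofluorescence_cparp_values) -> float:
    """Percent of blast cells negative for cleaved PARP (non-apoptotic)."""
    split = cparp_split_point(autofluorescence_cparp_values)
    b = np.asarray(blast_cparp_values, dtype=float)
    if b.size == 0:
        raise NonEvaluableError("zero blast cells")
    return 100.0 * float(np.mean(b <= split))


def amine_aqua_death_metric(treated_24h_aqua, untreated_24h_aqua) -> float:
    """Viability-only chemosensitivity readout: Uu of the Amine Aqua channel,
    drug-treated 24 h well vs untreated 24 h well, on intact cells.

    Amine Aqua uptake marks dead/dying cells, so values above 0.5 indicate a
    drug-induced viability decrease.
    """
    return metric_uu(treated_24h_aqua, untreated_24h_aqua)


# ---------------------------------------------------------------------------
# Per-cohort node-metric table
# ---------------------------------------------------------------------------

class _SampleWells:
    """Per-(patient, tissue) cache: each well calibrated and gated once.

    The viability threshold and the cPARP split both come from the sample's
    autofluorescence well; every node of the panel then reads its gated
    population values out of this cache.
    """

    def __init__(self, bucket, calibrate, gates, gate_params):
        self._bucket = bucket
        self._calibrate = calibrate
        self._gates = gates
        self._gate_params = gate_params
        self._cache: dict = {}
        af_raw = _find_well(bucket, "autofluorescence")
        if af_raw is None:
            raise NonEvaluableError("missing autofluorescence well")
        from .gating import viability_threshold_from_reference
        self._af = calibrate(af_raw)
        self.viability_threshold = viability_threshold_from_reference(self._af)
        af_idx = gates(self._af, gate_params,
                       viability_threshold=self.viability_threshold)
        self.af_blast_cparp = self._af.data.loc[af_idx.blast,
                                                "cPARP"].to_numpy(dtype=float)
        self._cache[("autofluorescence", None)] = (self._af, af_idx)

    def gated(self, modulator, time_hours=None):
        key = (modulator, time_hours)
        if key not in self._cache:
            raw = _find_well(self._bucket, modulator, time_hours)
            if raw is None:
                raise NonEvaluableError(
                    f"missing well (modulator {modulator!r})")
            w = self._calibrate(raw)
            idx = self._gates(w, self._gate_params,
                              viability_threshold=self.viability_threshold)
            self._cache[key] = (w, idx)
        return self._cache[key]

    def population_values(self, modulator, time_hours, population, channel):
        events, idx = self.gated(modulator, time_hours)
        data = events.data
        if channel not in data.columns:
            raise KeyError(
                f"channel {channel!r} absent from well {events.well_id}")
        if population == "intact":
            mask = idx.intact
        elif population == "blast":
            mask = idx.blast
        elif population == "healthy_blast":
            split = cparp_split_point(self.af_blast_cparp)
            mask = idx.blast & (data["cPARP"].to_numpy(dtype=float) <= split)
        else:
            raise ValueError(f"unknown population {population!r}")
        return data.loc[mask, channel].to_numpy(dtype=float)


def compute_node_table(wells: Iterable, gates, calibrations,
                       node_defs: Sequence[NodeDefinition],
                       min_cells: int = 200,
                       gate_params=None) -> list[NodeMetricRecord]:
    """Assemble the tidy per-patient node-metric table for a cohort.

    Parameters
    ----------
    wells : iterable of EventTable
        All wells of the cohort (any order).  Wells are grouped by
        (patient, tissue); each node looks up its modulated well and the
        reference wells by modulator name and exposure time.
    gates : callable ``(EventTable, params) -> PopulationIndex``
        Gating function (``scnp.gating.gate_hierarchy``).
    calibrations : mapping plate_id -> BeadCalibration, or a single
        BeadCalibration, or None for already-ERF-scaled data.
    node_defs : node panel.
    min_cells : evaluability floor — a record whose modulated or reference
        population falls below this count is flagged non-evaluable and its
        value set to nan.

    Records are emitted deterministically sorted by (patient, tissue, node,
    metric), so the output is invariant to well order.
    """
    from .calibration import apply_calibration
    from .gating import gate_hierarchy

    if gates is None:
        gates = gate_hierarchy

    grouped: dict[tuple[str, str], dict[tuple[str, float], object]] = {}
    for w in wells:
        key = (w.patient_id, w.tissue)
        wkey = (w.modulator, float(w.time_hours))
        bucket = grouped.setdefault(key, {})
        if wkey in bucket:
            raise ValueError(f"duplicate well {wkey} for patient {key}")
        bucket[wkey] = w

    def _calibrated(w):
        if calibrations is None:
            return w
        cal = (calibrations.get(w.plate_id)
               if hasattr(calibrations, "get") else calibrations)
        if cal is None:
            raise KeyError(f"no calibration for plate {w.plate_id!r}")
        return apply_calibration(w, cal)

    records: list[NodeMetricRecord] = []
    for (patient, tissue) in sorted(grouped):
        bucket = grouped[(patient, tissue)]
        try:
            sample = _SampleWells(bucket, _calibrated, gates, gate_params)
        except NonEvaluableError as exc:
            for node in node_defs:
                records.extend(
                    NodeMetricRecord(patient, tissue, node.node_id, m,
                                     float("nan"), 0, False, str(exc))
                    for m in node.metrics)
            continue
        for node in node_defs:
            records.extend(_node_records(patient, tissue, node, sample,
                                         min_cells))
    records.sort(key=lambda r: (r.patient_id, r.tissue, r.node_id, r.metric))
    _check_unique(records)
    return records


def _find_well(bucket, modulator, time_hours=None):
    hits = [w for (mod, t), w in bucket.items()
            if mod == modulator and (time_hours is None or t == time_hours)]
    return hits[0] if hits else None


def _check_unique(records):
    seen = set()
    for r in records:
        key = (r.patient_id, r.tissue, r.node_id, r.metric)
        if key in seen:
            raise ValueError(f"duplicate node-metric record {key}")
        seen.add(key)


def _node_records(patient, tissue, node, sample: "_SampleWells", min_cells):
    def _missing(reason):
        return [NodeMetricRecord(patient, tissue, node.node_id, m,
                                 float("nan"), 0, False, reason)
                for m in node.metrics]

    needs_u = any(m in ("Uu", "log2Fold", "Basal") for m in node.metrics)
    pop = node.population
    try:
        m_vals = sample.population_values(node.modulator, node.time_hours,
                                          pop, node.readout)
        u_vals = (sample.population_values(node.u_modulator, None, pop,
                                           node.readout) if needs_u else None)
        a_vals = sample.population_values("autofluorescence", None, pop,
                                          node.readout)
    except NonEvaluableError as exc:
        return _missing(str(exc))

    out = []

    for metric in node.metrics:
        n_used = int(m_vals.size)
        try:
            if metric == "Basal":
                ref = u_vals
                value = metric_basal(u_vals, a_vals)
                n_used = int(u_vals.size)
            elif metric == "log2Fold":
                ref = u_vals
                value = metric_log2fold(m_vals, u_vals)
            elif metric == "Uu":
                ref = u_vals
                value = metric_uu(m_vals, u_vals)
            elif metric == "Ua":
                ref = a_vals
                value = metric_ua(m_vals, a_vals)
            elif metric == "PhIntact":
                ref = a_vals
                value = metric_phintact(m_vals, sample.af_blast_cparp)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            ok = (m_vals.size >= min_cells
                  and (ref is None or np.size(ref) >= min_cells))
            out.append(NodeMetricRecord(
                patient, tissue, node.node_id, metric, float(value),
                n_used, bool(ok),
                None if ok else f"fewer than {min_cells} gated cells"))
        except NonEvaluableError as exc:
            out.append(NodeMetricRecord(patient, tissue, node.node_id, metric,
                                        float("nan"), n_used, False, str(exc)))
    return out


def node_table_to_frame(records: Sequence[NodeMetricRecord]) -> pd.DataFrame:
    """Tidy DataFrame: patient_id, tissue, node_id, metric, value, n_cells,
    evaluable — the on-disk CSV schema."""
    return pd.DataFrame([{
        "patient_id": r.patient_id, "tissue": r.tissue, "node_id": r.node_id,
        "metric": r.metric, "value": r.value, "n_cells": r.n_cells,
        "evaluable": r.evaluable,
    } for r in records])


def node_metric_matrix(records: Sequence[NodeMetricRecord],
                       metric_filter: Sequence[tuple[str, str]] | None = None
                       ) -> pd.DataFrame:
    """Wide (patient, tissue) x "node_id|metric" matrix of evaluable values.

    Non-evaluable records become NaN (they propagate as missing to the
    classifier stage).  ``metric_filter`` optionally restricts to a list of
    (node_id, metric) pairs.
    """
    df = node_table_to_frame(records)
    if metric_filter is not None:
        keep = set(metric_filter)
        df = df[[(n, m) in keep for n, m in zip(df.node_id, df.metric)]]
    df = df.copy()
    df.loc[~df.evaluable, "value"] = np.nan
    df["feature"] = df.node_id + "|" + df.metric
    return df.pivot_table(index=["patient_id", "tissue"], columns="feature",
                          values="value", aggfunc="first")
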