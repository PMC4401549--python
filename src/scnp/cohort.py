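"""Cohort bookkeeping: covariate-adaptive randomization, analysis-set
construction, and clinical-covariate imputation.

Patients are split ~1:1 into Training and Validation sets by the
Pocock-Simon minimization method: each arriving patient is assigned to the
arm that minimizes the total marginal imbalance over a fixed list of
balancing factors (induction response, sample types, cytogenetic risk
group, parent trial arm, FLT3-ITD status, proteomic readout
availability).  Analysis sets then keep only patients with an induction
outcome of CR, CRi or RD — treatment-related mortality is excluded because
the assay measures blast chemosensitivity, not comorbidities — and only
patients with an assessable sample of the set's tissue; each patient
contributes one sample (one tissue) per analysis set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["AllocationState", "AnalysisSet", "minimization_assign",
           "build_analysis_sets", "impute_clinical", "DEFAULT_FACTORS"]

DEFAULT_FACTORS = ("induction_response", "sample_types", "cytogenetic_risk",
                   "parent_trial_arm", "flt3_itd", "readout_availability")

ARMS = ("training", "validation")


@dataclass
class AllocationState:
    """Running per-arm counts per level of each balancing factor."""

    factors: tuple[str, ...] = DEFAULT_FACTORS
    arms: tuple[str, ...] = ARMS
    counts: dict = field(default_factory=dict)  # arm -> factor -> level -> n

    def __post_init__(self):
        for arm in self.arms:
            self.counts.setdefault(arm, {f: {} for f in self.factors})

    def imbalance_if(self, arm: str, levels: Mapping[str, str]) -> float:
        """Total marginal imbalance (range method, unit factor weights) if
        the new patient with these factor levels joined ``arm``."""
        total = 0.0
        for f in self.factors:
            lv = levels[f]
            ns = [self.counts[a][f].get(lv, 0) + (1 if a == arm else 0)
                  for a in self.arms]
            total += max(ns) - min(ns)
        return total

    def add(self, arm: str, levels: Mapping[str, str]) -> None:
        for f in self.factors:
            lv = levels[f]
            self.counts[arm][f][lv] = self.counts[arm][f].get(lv, 0) + 1


def patient_factor_levels(patient, evaluability: Mapping[str, bool] | None = None,
                          parent_trial_arm: str = "A") -> dict[str, str]:
    """Balancing-factor levels for one patient record; missing values become
    the level "missing"."""
    ev = evaluability or {t: True for t in patient.tissue_types}
    avail = "+".join(sorted(t for t, ok in ev.items() if ok)) or "none"
    return {
        "induction_response": patient.outcome,
        "sample_types": "+".join(sorted(patient.tissue_types)),
        "cytogenetic_risk": patient.cytogenetic_risk or "missing",
        "parent_trial_arm": parent_trial_arm,
        "flt3_itd": patient.flt3_itd or "missing",
        "readout_availability": avail,
    }


def minimization_assign(patients_levels: Iterable[Mapping[str, str]],
                        state: AllocationState | None = None,
                        p_deterministic: float = 0.8,
                        rng: np.random.Generator | None = None) -> list[str]:
    """Assign a stream of patients to arms by Pocock-Simon minimization.

    Each patient (given as a factor -> level mapping) goes to the arm with
    the smaller prospective total marginal imbalance with probability
    ``p_deterministic``, and to a uniformly random arm otherwise; exact
    ties are broken uniformly at random.  Unknown factors raise.

    Returns the list of arm labels in arrival order; ``state`` is updated
    in place (a fresh two-arm state is created if None).
    """
    if state is None:
        state = AllocationState()
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= p_deterministic <= 1.0:
        raise ValueError("p_deterministic must lie in [0, 1]")
    out = []
    for levels in patients_levels:
        missing = set(state.factors) - set(levels)
        if missing:
            raise KeyError(f"patient missing balancing factors {sorted(missing)}")
        scores = np.array([state.imbalance_if(a, levels) for a in state.arms])
        best = np.flatnonzero(scores == scores.min())
        if len(best) == len(state.arms):
            arm = state.arms[rng.integers(len(state.arms))]
        elif rng.uniform() < p_deterministic:
            arm = state.arms[best[rng.integers(len(best))]]
        else:
            others = [i for i in range(len(state.arms)) if i not in best]
            arm = state.arms[others[rng.integers(len(others))]]
        state.add(arm, levels)
        out.append(arm)
    return out


@dataclass
class AnalysisSet:
    """One (set label, tissue) analysis set with its exclusion log."""

    label: str                      # training | validation | verification
    tissue: str                     # BM | PB
    patient_ids: list[str] = field(default_factory=list)


def build_analysis_sets(patients, assignments: Mapping[str, str],
                        evaluability: Mapping[str, Mapping[str, bool]] | None = None
                        ) -> tuple[dict[tuple[str, str], AnalysisSet], list[dict]]:
    """Construct per-(arm, tissue) analysis sets and the exclusion log.

    ``assignments`` maps patient_id -> arm; ``evaluability`` maps
    patient_id -> {tissue: bool} (defaults to all assessable).  TRM
    patients and non-assessable samples are excluded with a logged reason.
    A patient with both tissues appears once in the BM set and once in the
    PB set of their arm.  Deterministic and order-invariant: output sets
    are sorted by patient id.
    """
    sets: dict[tuple[str, str], AnalysisSet] = {}
    exclusions: list[dict] = []
    for p in sorted(patients, key=lambda q: q.patient_id):
        arm = assignments.get(p.patient_id)
        if arm is None:
            exclusions.append({"patient_id": p.patient_id,
                               "reason": "not randomized"})
            continue
        if p.outcome == "TRM":
            exclusions.append({"patient_id": p.patient_id,
                               "reason": "TRM outcome"})
            continue
        ev = (evaluability or {}).get(p.patient_id,
                                      {t: True for t in p.tissue_types})
        any_in = False
        for tissue in p.tissue_types:
            if not ev.get(tissue, False):
                exclusions.append({"patient_id": p.patient_id,
                                   "reason": f"{tissue} sample not assessable"})
                continue
            key = (arm, tissue)
            sets.setdefault(key, AnalysisSet(label=arm, tissue=tissue))
            sets[key].patient_ids.append(p.patient_id)
            any_in = True
        if not any_in and p.outcome != "TRM":
            logger.info("patient %s excluded from all analysis sets",
                        p.patient_id)
    return sets, exclusions


def impute_clinical(records: Sequence, training_ids: set[str] | None = None):
    """Fill missing clinical covariates; returns (new records, provenance).

    Rules: unknown cytogenetic risk becomes intermediate (the clinical
    convention); unknown categorical markers (FLT3-ITD, NPM1) become the
    mode, and missing numerics (NaN) the median, of the observed values —
    computed on the training patients only when ``training_ids`` is given,
    to avoid leakage into validation.  Provenance records one entry per
    imputed (patient, field).  An all-missing numeric column raises.
    """
    from dataclasses import replace, fields as dc_fields

    provenance: list[dict] = []
    ref = [r for r in records
           if training_ids is None or r.patient_id in training_ids]
    if not ref:
        raise ValueError("no reference (training) records to impute from")

    def observed(name, predicate):
        return [getattr(r, name) for r in ref if predicate(getattr(r, name))]

    numeric_fields = [f.name for f in dc_fields(records[0])
                      if f.type in ("float", float) and
                      f.name not in ("latent_chemosensitivity",)]
    medians = {}
    for name in numeric_fields:
        obs = observed(name, lambda v: v is not None and np.isfinite(v))
        if any(getattr(r, name) is None or not np.isfinite(getattr(r, name))
               for r in records):
            if not obs:
                raise ValueError(f"cannot impute {name}: all values missing")
            medians[name] = float(np.median(obs))

    def mode(name):
        obs = observed(name, lambda v: v not in (None, "unknown"))
        if not obs:
            raise ValueError(f"cannot impute {name}: all values missing")
        vals, counts = np.unique(obs, return_counts=True)
        return str(vals[np.argmax(counts)])

    out = []
    for r in records:
        changes = {}
        if r.cytogenetic_risk == "unknown":
            changes["cytogenetic_risk"] = "intermediate"
            provenance.append({"patient_id": r.patient_id,
                               "field": "cytogenetic_risk",
                               "rule": "rule:unknown-to-intermediate"})
        for name in ("flt3_itd", "npm1"):
            if getattr(r, name) == "unknown":
                changes[name] = mode(name)
                provenance.append({"patient_id": r.patient_id, "field": name,
                                   "rule": "mode:training"})
        for name, med in medians.items():
            v = getattr(r, name)
            if v is None or not np.isfinite(v):
                changes[name] = med
                provenance.append({"patient_id": r.patient_id, "field": name,
                                   "rule": "median:training"})
        out.append(replace(r, **changes) if changes else r)
    return out, provenance
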