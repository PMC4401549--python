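"""End-to-end convenience layer.

Glue over the stage modules: given a simulated (or loaded) cohort, run
bead calibration, gating and node metrics, score the locked classifier,
and evaluate performance.  Each step is a thin call into the stage module
so scripted analyses can drop to the underlying functions at any point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import fit_erf_calibration
from .classifiers import load_locked_model
from .metrics import compute_node_table, node_metric_matrix, NodeDefinition
from .stats import auroc_trapezoid, exact_mw_test

__all__ = ["cohort_node_matrix", "score_locked_classifier",
           "outcome_series", "locked_classifier_performance"]


def cohort_node_matrix(wells, beads, node_defs: list[NodeDefinition],
                       min_cells: int = 200, gate_params=None) -> pd.DataFrame:
    """Calibrate, gate and compute the wide node-metric matrix for a cohort.

    Returns a (patient_id, tissue)-indexed DataFrame with one column per
    "node_id|metric" feature; non-evaluable values are NaN.
    """
    calibrations = {b.plate_id: fit_erf_calibration(b) for b in beads}
    records = compute_node_table(wells, None, calibrations, node_defs,
                                 min_cells=min_cells, gate_params=gate_params)
    return node_metric_matrix(records)


def classifier_feature_matrix(node_matrix: pd.DataFrame) -> pd.DataFrame:
    """Restrict a node-metric matrix to classifier-input features.

    Classifier development uses the comparative node metrics (Uu, Ua,
    log2Fold, Basal).  PhIntact is a cell-health/evaluability readout, and
    the Amine Aqua viability Uu is a standalone viability-only predictor
    analyzed separately; neither enters combination-model training.
    """
    keep = []
    for c in node_matrix.columns:
        node, metric = c.rsplit("|", 1)
        if metric == "PhIntact" or node.endswith("|AquaAmine"):
            continue
        keep.append(c)
    return node_matrix[keep]


def score_locked_classifier(node_matrix: pd.DataFrame) -> pd.Series:
    """Locked DX_SCNP scores for every (patient, tissue) row with complete
    inputs; rows missing a required node metric get NaN."""
    return load_locked_model().score_table(node_matrix)


def outcome_series(patients, index) -> pd.Series:
    """Binary CR/CRi-vs-RD outcome aligned to a (patient_id, tissue) index;
    TRM patients get NaN (they are excluded from analysis sets)."""
    by_id = {p.patient_id: p for p in patients}
    vals = []
    for pid, _tissue in index:
        p = by_id[pid]
        vals.append(np.nan if p.outcome == "TRM" else float(p.responder))
    return pd.Series(vals, index=index, name="responder")


def locked_classifier_performance(patients, node_matrix: pd.DataFrame,
                                  tissue: str = "BM") -> dict:
    """AUROC and exact one-sided p of the locked model on one tissue's
    scored patients (complete cases, CR/CRi/RD outcomes only)."""
    scores = score_locked_classifier(node_matrix)
    y = outcome_series(patients, node_matrix.index)
    sub = pd.DataFrame({"score": scores, "y": y}).dropna()
    sub = sub[[t == tissue for _, t in sub.index]]
    if sub.empty or sub.y.nunique() < 2:
        raise ValueError(f"no scorable two-class {tissue} cohort")
    auroc = auroc_trapezoid(sub.score.to_numpy(), sub.y.to_numpy())
    p = exact_mw_test(sub.score.to_numpy(), sub.y.to_numpy())
    return {"tissue": tissue, "n": int(len(sub)),
            "n_responders": int(sub.y.sum()), "auroc": auroc, "p_value": p}
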