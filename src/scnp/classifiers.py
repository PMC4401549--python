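"""Response classifiers: the locked DX_SCNP scorer and the training pipeline.

The locked model
----------------
DX_SCNP predicts CR/CRi vs RD after induction chemotherapy from two node
metrics measured after 24 h of in-vitro AraC + daunorubicin exposure:
N1 = Uu of the cPARP readout (apoptosis induction) and N2 = Uu of the CD34
readout (blast depletion).  Each enters through a one-sided
"hinge-squared" transform —

    C1 = (N1 - 0.5)^2  if N1 > 0.5 else 0
    C2 = (0.5 - N2)^2  if N2 < 0.5 else 0

— and the score is the logistic of the locked linear predictor

    score = expit(-1.26004 + 95.60133 * C1 + 34.94358 * C2).

Higher scores mean a higher predicted probability of response.  The
coefficients are immutable and ship as a JSON artifact
(``data/locked_dxscnp.json``); only Uu values above 0.5 (cPARP induced)
and below 0.5 (CD34 depleted) contribute.

The development pipeline
------------------------
The generic trainer mirrors how such a model is found: per-node
prescreening (univariate rank test, random-forest importance, L1-penalized
logistic selection), exhaustive 2-to-4-node logistic combination models,
optimism adjustment of each model's AUROC by Harrell's bootstrap, and
out-of-bag AUROC estimation.  The piecewise transforms of the locked model
came from a later refinement step that is not reconstructed here; the
pipeline fits plain linear logistic models on node metrics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .stats import auroc_trapezoid, exact_mw_test

__all__ = [
    "LockedScnpModel", "CandidateModel", "ClinicalModel", "ScoringError",
    "load_locked_model", "score_dx_scnp", "prescreen_nodes",
    "fit_penalized_logistic", "enumerate_combination_models",
    "adjust_auroc_optimism", "oob_auroc", "build_dx_clinical",
]

logger = logging.getLogger(__name__)

LOCKED_MODEL_RESOURCE = "locked_dxscnp.json"


class ScoringError(ValueError):
    pass


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Locked model
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "hinge_sq_above": lambda n, c: np.where(n > c, (n - c) ** 2, 0.0),
    "hinge_sq_below": lambda n, c: np.where(n < c, (c - n) ** 2, 0.0),
}


@dataclass(frozen=True)
class LockedScnpModel:
    """Immutable scorer built from the locked JSON artifact."""

    name: str
    intercept: float
    coefficients: tuple[float, ...]
    node_bindings: tuple[tuple[str, str], ...]   # (node_id, metric) per input
    transforms: tuple[tuple[str, float], ...]    # (transform name, center)

    def score(self, *node_values) -> np.ndarray | float:
        """Probability of response from the raw node-metric inputs."""
        if len(node_values) != len(self.coefficients):
            raise ScoringError(
                f"expected {len(self.coefficients)} inputs, got {len(node_values)}")
        arrays = [np.asarray(v, dtype=float) for v in node_values]
        for v, (node, metric) in zip(arrays, self.node_bindings):
            if np.any(np.isnan(v)):
                raise ScoringError(f"missing value for {node}|{metric}")
            if np.any((v < 0.0) | (v > 1.0)):
                raise ScoringError(
                    f"{metric} input for {node} outside [0, 1]")
        lp = self.intercept
        for v, coef, (tname, center) in zip(arrays, self.coefficients,
                                            self.transforms):
            lp = lp + coef * _TRANSFORMS[tname](v, center)
        out = _expit(lp)
        return float(out) if np.ndim(out) == 0 else out

    def score_table(self, node_matrix: pd.DataFrame) -> pd.Series:
        """Score a wide (patient, tissue) x "node|metric" matrix.

        Patients missing any required node metric get no score (NaN) —
        they are excluded from downstream performance analyses rather than
        silently imputed."""
        cols = [f"{node}|{metric}" for node, metric in self.node_bindings]
        for c in cols:
            if c not in node_matrix.columns:
                raise ScoringError(f"node-metric column {c!r} absent")
        sub = node_matrix[cols]
        complete = sub.notna().all(axis=1)
        out = pd.Series(np.nan, index=node_matrix.index, name="score")
        if complete.any():
            vals = [sub.loc[complete, c].to_numpy() for c in cols]
            out.loc[complete] = self.score(*vals)
        return out


def load_locked_model(path=None) -> LockedScnpModel:
    """Load the locked DX_SCNP artifact (or a compatible JSON file)."""
    if path is None:
        text = (resources.files("scnp.data") / LOCKED_MODEL_RESOURCE
                ).read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    d = json.loads(text)
    comps = d["components"]
    return LockedScnpModel(
        name=d["name"],
        intercept=float(d["intercept"]),
        coefficients=tuple(float(c["coefficient"]) for c in comps),
        node_bindings=tuple((c["node_id"], c["metric"]) for c in comps),
        transforms=tuple((c["transform"], float(c["center"])) for c in comps),
    )


_LOCKED = None


def score_dx_scnp(n1, n2):
    """Locked DX_SCNP score from the two 24 h AraC+Dauno Uu node metrics.

    ``n1`` is the cPARP Uu value, ``n2`` the CD34 Uu value; both must lie
    in [0, 1].  Scalar or array inputs.
    """
    global _LOCKED
    if _LOCKED is None:
        _LOCKED = load_locked_model()
    return _LOCKED.score(n1, n2)


# ---------------------------------------------------------------------------
# Small, fast logistic fits (used inside bootstrap loops)
# ---------------------------------------------------------------------------

def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 30,
                   tol: float = 1e-9, ridge: float = 1e-6
                   ) -> tuple[np.ndarray, bool]:
    """Newton/IRLS logistic fit with a tiny ridge for numerical stability.

    Returns (beta including intercept as element 0, separated_flag).  The
    flag trips when coefficients grow without bound (quasi-separation);
    callers treat such fits as valid rankers but unreliable estimators.
    """
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    separated = False
    converged = False
    for _ in range(max_iter):
        eta = Z @ beta
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        g = Z.T @ (y - mu) - ridge * beta
        H = (Z * w[:, None]).T @ Z + ridge * np.eye(p + 1)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e4:
            separated = True
            break
    # non-convergence with runaway coefficients is quasi-separation: the
    # likelihood keeps improving as the slope grows without bound
    if not converged and np.max(np.abs(beta)) > 30.0:
        separated = True
    return beta, separated


def _predict_lp(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return beta[0] + X @ beta[1:]


# ---------------------------------------------------------------------------
# Prescreening
# ---------------------------------------------------------------------------

def prescreen_nodes(node_matrix: pd.DataFrame, outcomes: pd.Series | np.ndarray,
                    alpha: float = 0.05, top_k: int = 15,
                    rng: np.random.Generator | None = None,
                    n_trees: int = 500, min_keep: int = 0) -> pd.DataFrame:
    """Initial node-metric subset for combination modeling.

    Union, with provenance tags, of three screens run on complete-ish data
    (features missing for a patient are median-filled inside the random
    forest and penalized fits only; the univariate test uses the observed
    values):

    1. univariate two-sample rank test (responders vs RD) at level ``alpha``;
    2. top-``top_k`` random-forest permutation importances;
    3. nonzero coefficients of an all-node L1-penalized logistic fit.

    Returns a DataFrame indexed by feature name with boolean columns
    ``univariate``, ``forest``, ``penalized`` and the univariate p-value,
    restricted to features selected by at least one screen.  All-missing
    features are dropped with a log entry.  Deterministic given ``rng``
    and invariant to patient order.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    if rng is None:
        rng = np.random.default_rng(0)
    y = np.asarray(outcomes, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("need both outcome classes to prescreen")

    X = node_matrix.copy()
    all_missing = [c for c in X.columns if X[c].isna().all()]
    for c in all_missing:
        logger.info("prescreen: dropping all-missing node metric %s", c)
    X = X.drop(columns=all_missing)
    features = list(X.columns)

    # canonicalize patient order so the selection is invariant to the order
    # rows arrive in (the stochastic screens are order-sensitive otherwise)
    order = np.lexsort(tuple(np.nan_to_num(X[c].to_numpy(), nan=-1e300)
                             for c in features) + (y,))
    X = X.iloc[order].reset_index(drop=True)
    y = y[order]

    # 1. univariate Mann-Whitney screen on observed values
    pvals = {}
    for c in features:
        obs = X[c].notna().to_numpy()
        vals, yy = X[c].to_numpy()[obs], y[obs]
        if np.unique(yy).size < 2:
            pvals[c] = 1.0
            continue
        p_hi = exact_mw_test(vals, yy, alternative="greater", rng=rng)
        p_lo = exact_mw_test(vals, yy, alternative="less", rng=rng)
        pvals[c] = min(1.0, 2.0 * min(p_hi, p_lo))  # two-sided
    univ = {c for c in features if pvals[c] <= alpha}

    # median-filled matrix for the multivariate screens
    Xf = X.fillna(X.median()).to_numpy(dtype=float)
    seed = int(rng.integers(2 ** 31 - 1))
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(Xf, y)
    imp = permutation_importance(rf, Xf, y, n_repeats=5, random_state=seed)
    order = np.argsort(imp.importances_mean)[::-1]
    forest = {features[i] for i in order[:top_k] if imp.importances_mean[i] > 0}

    coefs = fit_penalized_logistic(Xf, y, rng=rng)
    penal = {features[i] for i in range(len(features)) if coefs[i] != 0.0}

    selected = {c for c in features if c in univ or c in forest or c in penal}
    if len(selected) < min_keep:
        # a usable initial subset cannot be empty: back-fill with the
        # smallest univariate p-values even though they missed the screens
        for c in sorted(features, key=lambda c: pvals[c]):
            selected.add(c)
            if len(selected) >= min_keep:
                break
    rows = [{"feature": c, "univariate": c in univ, "forest": c in forest,
             "penalized": c in penal, "p_value": pvals[c]}
            for c in features if c in selected]
    out = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["univariate", "forest", "penalized", "p_value"])
    return out.sort_values("p_value")


def fit_penalized_logistic(X, y, Cs: Sequence[float] | None = None,
                           cv: int = 10, one_se: bool = True,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    """L1-penalized (LASSO) logistic coefficients with CV-chosen penalty.

    The penalty is selected by ``cv``-fold cross-validated deviance over a
    log-spaced grid; with ``one_se`` the strongest penalty within one
    standard error of the best is used.  Features are standardized
    internally; returned coefficients are on the original scale.  Zeroed
    coefficients are returned as exact zeros.  Separable data at weak
    penalties is handled by the penalty itself — there is no unpenalized
    fallback.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold
    from sklearn.metrics import log_loss

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("constant outcome; nothing to fit")
    if rng is None:
        rng = np.random.default_rng(0)
    if Cs is None:
        Cs = np.logspace(-2.5, 1.5, 20)

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    seed = int(rng.integers(2 ** 31 - 1))
    n_splits = min(cv, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few members of the rare class for CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(Z, y))

    dev = np.zeros((len(Cs), len(folds)))
    for i, C in enumerate(Cs):
        for j, (tr, te) in enumerate(folds):
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000)
            clf.fit(Z[tr], y[tr])
            p = clf.predict_proba(Z[te])[:, 1]
            dev[i, j] = 2.0 * log_loss(y[te], p, labels=[0, 1],
                                       normalize=False)
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(len(folds))
    best = int(np.argmin(mean_dev))
    if one_se:
        limit = mean_dev[best] + se_dev[best]
        # strongest penalty (smallest C) still within one SE of the best
        candidates = [i for i in range(len(Cs)) if mean_dev[i] <= limit]
        chosen = min(candidates, key=lambda i: Cs[i])
    else:
        chosen = best
    clf = LogisticRegression(l1_ratio=1.0, C=Cs[chosen], solver="liblinear",
                             max_iter=2000)
    clf.fit(Z, y)
    return (clf.coef_[0] / sd).astype(float)


# ---------------------------------------------------------------------------
# Combination models, optimism adjustment, OOB AUROC
# ---------------------------------------------------------------------------

@dataclass
class CandidateModel:
    """One 2-to-4-node logistic combination model and its rankings."""

    features: tuple[str, ...]
    coefficients: np.ndarray
    apparent_auroc: float
    adjusted_auroc: float
    oob_auroc: float | None = None
    n_used: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 2 <= len(self.features) <= 4:
            raise ValueError("combination models use 2-4 nodes")


def _fit_spec(X: np.ndarray, y: np.ndarray):
    beta, separated = _irls_logistic(X, y)
    return beta, separated


def adjust_auroc_optimism(X, y, B: int = 500,
                          rng: np.random.Generator | None = None,
                          resample_indices: Callable[[int], np.ndarray] | None = None
                          ) -> tuple[float, float]:
    """Harrell's bootstrap optimism adjustment of a logistic model's AUROC.

    For each of ``B`` bootstrap resamples, the model is refit on the
    resample and the optimism is the bootstrap-sample AUROC minus that
    model's AUROC on the original data; the adjusted AUROC is the apparent
    AUROC minus the mean optimism.  A resample missing one outcome class is
    redrawn (logged).  ``resample_indices`` overrides the resampler (for
    degenerate-case testing).

    Returns (apparent, adjusted).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if rng is None:
        rng = np.random.default_rng()
    n = len(y)
    beta, _ = _fit_spec(X, y)
    apparent = auroc_trapezoid(_predict_lp(X, beta), y)

    optimism = 0.0
    for _ in range(B):
        for attempt in range(100):
            idx = (resample_indices(n) if resample_indices is not None
                   else rng.integers(0, n, size=n))
            if np.unique(y[idx]).size == 2:
                break
            logger.info("optimism bootstrap: degenerate class, redrawing")
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample")
        bb, _ = _fit_spec(X[idx], y[idx])
        boot_auc = auroc_trapezoid(_predict_lp(X[idx], bb), y[idx])
        orig_auc = auroc_trapezoid(_predict_lp(X, bb), y)
        optimism += boot_auc - orig_auc
    return apparent, apparent - optimism / B


def oob_auroc(X, y, B: int = 200, rng: np.random.Generator | None = None,
              max_extra: int = 1000) -> float:
    """Out-of-bag AUROC of a logistic model specification.

    Each bootstrap fit scores the patients left out of its resample;
    per-patient OOB scores are averaged over the draws that left the
    patient out, and the AUROC of those averages against the outcomes is
    returned.  If some patient is never out-of-bag after ``B`` draws, more
    draws are added (logged) up to ``B + max_extra``.
    """
    if B < 50:
        raise ValueError("B must be >= 50 for a stable OOB estimate")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if rng is None:
        rng = np.random.default_rng()
    n = len(y)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    draws = 0
    while draws < B or (counts == 0).any():
        if draws >= B + max_extra:
            raise RuntimeError("some patients never out-of-bag; increase B")
        idx = rng.integers(0, n, size=n)
        if np.unique(y[idx]).size < 2:
            continue
        draws += 1
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if not oob.any():
            continue
        beta, _ = _fit_spec(X[idx], y[idx])
        sums[oob] += _predict_lp(X[oob], beta)
        counts[oob] += 1
        if draws == B and (counts == 0).any():
            logger.info("oob_auroc: %d patients never OOB after B=%d; "
                        "extending draws", int((counts == 0).sum()), B)
    return auroc_trapezoid(sums / counts, y)


def enumerate_combination_models(candidates: Sequence[str],
                                 node_matrix: pd.DataFrame,
                                 outcomes,
                                 kmax: int = 4, B: int = 500,
                                 rng: np.random.Generator | None = None,
                                 compute_oob: bool = False,
                                 oob_B: int = 200) -> list[CandidateModel]:
    """Fit and rank all 2-to-``kmax``-node logistic combination models.

    Each subset of the candidate node metrics is fit by (unpenalized)
    logistic regression on its complete cases and scored by the
    optimism-adjusted AUROC (``B`` bootstrap resamples); models are
    returned ranked by adjusted AUROC, descending.  Subsets with fewer than
    two complete cases per class are skipped with a log entry.  The ranking
    is invariant to the input order of ``candidates``.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate node metrics")
    if rng is None:
        rng = np.random.default_rng()
    y_all = np.asarray(outcomes, dtype=int)
    models = []
    for k in range(2, min(kmax, len(candidates)) + 1):
        for subset in combinations(sorted(candidates), k):
            sub = node_matrix[list(subset)]
            ok = sub.notna().all(axis=1).to_numpy()
            X, y = sub.to_numpy(dtype=float)[ok], y_all[ok]
            if min((y == 1).sum(), (y == 0).sum()) < 2:
                logger.info("skipping %s: <2 complete cases in a class", subset)
                continue
            sub_rng = np.random.default_rng(rng.integers(2 ** 31 - 1))
            beta, separated = _fit_spec(X, y)
            apparent, adjusted = adjust_auroc_optimism(X, y, B=B, rng=sub_rng)
            flags = ["separated"] if separated else []
            if adjusted > apparent:
                flags.append("optimism<0")
            model = CandidateModel(features=subset, coefficients=beta,
                                   apparent_auroc=apparent,
                                   adjusted_auroc=adjusted,
                                   n_used=int(ok.sum()), flags=flags)
            if compute_oob:
                model.oob_auroc = oob_auroc(X, y, B=oob_B, rng=sub_rng)
            models.append(model)
    models.sort(key=lambda m: (-m.adjusted_auroc, m.features))
    return models


# ---------------------------------------------------------------------------
# Clinical classifiers
# ---------------------------------------------------------------------------

LEVEL1_INPUTS = [
    "age", "bm_blast_pct", "wbc", "pb_blast_pct", "anc_pct", "anc_abs",
    "mono_pct", "mono_abs", "hemoglobin", "platelets",
    "performance_status", "fab_class", "onset",
]
LEVEL2_EXTRA = ["cytogenetic_risk", "pct_cd34", "flt3_itd_ratio",
                "flt3_itd", "npm1"]


@dataclass
class ClinicalModel:
    """Penalized-logistic clinical classifier (level 1 or 2 input set)."""

    level: int
    features: list[str]
    coefficients: np.ndarray
    constructible: bool
    oob_auroc: float | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        if not self.constructible:
            raise ScoringError("model not constructible (all coefficients zero)")
        return _expit(X @ self.coefficients)


def _clinical_design(records, level: int, pct_cd34=None) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Numeric design matrix from patient records (binary-coded categories)."""
    rows, y = [], []
    for p in records:
        if p.outcome == "TRM":
            continue
        row = {
            "age": p.age, "bm_blast_pct": p.bm_blast_pct, "wbc": p.wbc,
            "pb_blast_pct": p.pb_blast_pct, "anc_pct": p.anc_pct,
            "anc_abs": p.anc_abs, "mono_pct": p.mono_pct,
            "mono_abs": p.mono_abs, "hemoglobin": p.hemoglobin,
            "platelets": p.platelets,
            "performance_status": 1.0 if p.performance_status == "2-3" else 0.0,
            "fab_class": 1.0 if p.fab_class == "M0/M1/M2/M7" else 0.0,
            "onset": 1.0 if p.onset == "secondary" else 0.0,
        }
        if level == 2:
            if p.cytogenetic_risk == "unknown":
                raise ValueError(
                    f"{p.patient_id}: cytogenetic risk not imputed; run "
                    "impute_clinical first")
            if pct_cd34 is None or p.patient_id not in pct_cd34:
                raise ValueError(
                    f"{p.patient_id}: %CD34+ missing (phenotyping input "
                    "required for the level-2 model)")
            if p.flt3_itd == "unknown" or p.npm1 == "unknown":
                raise ValueError(
                    f"{p.patient_id}: molecular markers not imputed")
            row["cytogenetic_risk"] = {"better": -1.0, "intermediate": 0.0,
                                       "poor": 1.0}[p.cytogenetic_risk]
            row["pct_cd34"] = float(pct_cd34[p.patient_id])
            row["flt3_itd_ratio"] = p.flt3_itd_ratio
            row["flt3_itd"] = 1.0 if p.flt3_itd == "mutant" else 0.0
            row["npm1"] = 1.0 if p.npm1 == "mutant" else 0.0
        rows.append(row)
        y.append(1 if p.responder else 0)
    features = LEVEL1_INPUTS + (LEVEL2_EXTRA if level == 2 else [])
    X = np.array([[r[f] for f in features] for r in rows], dtype=float)
    return X, features, np.array(y, dtype=int)


def build_dx_clinical(records, level: int = 1, pct_cd34=None,
                      rng: np.random.Generator | None = None,
                      compute_oob: bool = False) -> ClinicalModel:
    """Build the clinical response classifier at input level 1 or 2.

    Level 1 uses only the clinical covariates available at diagnosis;
    level 2 adds cytogenetic risk, %CD34+ cells (from the assay's
    phenotyping well, supplied as a patient_id -> percent mapping),
    FLT3-ITD (continuous ratio and binary) and NPM1 status.  Records must
    already be imputed (see :func:`scnp.cohort.impute_clinical`).  The fit
    is L1-penalized logistic regression; if the penalty shrinks every
    coefficient to zero the model is flagged not constructible.
    """
    if level not in (1, 2):
        raise ValueError("level must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng(0)
    X, features, y = _clinical_design(records, level, pct_cd34)
    coefs = fit_penalized_logistic(X, y, rng=rng)
    constructible = bool(np.any(coefs != 0.0))
    model = ClinicalModel(level=level, features=features,
                          coefficients=coefs, constructible=constructible)
    if compute_oob and constructible:
        keep = coefs != 0.0
        model.oob_auroc = oob_auroc(X[:, keep], y, rng=rng)
    return model
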