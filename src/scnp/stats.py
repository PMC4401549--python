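"""Classifier-validation statistics.

Everything downstream of a score column lives here: the empirical AUROC and
its identity with the scaled Mann-Whitney U statistic, the one-sided exact
test of AUROC = 0.5, bootstrap (BCa) and DeLong confidence intervals, the
combined-model redundancy test, power simulation under a binormal score
model, paired-tissue concordance, and subgroup performance tables.

Conventions
-----------
* ``labels`` are binary; 1 marks the positive class (responder, CR/CRi) and
  0 the negative class (resistant disease).
* AUROC is computed as U/(n1*n0) with tied score pairs given half credit,
  so identical score distributions give exactly 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AurocResult",
    "auroc_trapezoid",
    "exact_mw_test",
    "bca_ci",
    "delong_ci",
    "combined_independence_test",
    "power_simulation",
    "paired_concordance",
    "subgroup_performance",
]


# ---------------------------------------------------------------------------
# AUROC / Mann-Whitney machinery
# ---------------------------------------------------------------------------

def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both outcome classes must be present")
    return scores, labels.astype(int)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic for ``x`` versus ``y`` with midrank (half-credit) ties.

    U counts, over all len(x)*len(y) pairs, the pairs where the x value is
    larger, plus half the tied pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def auroc_trapezoid(scores, labels) -> float:
    """Empirical (trapezoidal) AUROC of ``scores`` against binary ``labels``.

    Identical to the Mann-Whitney U statistic comparing positive-class and
    negative-class scores, scaled to the unit interval by the number of
    class pairs: AUROC = U / (n1 * n0), ties given half credit.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    return mann_whitney_u(pos, neg) / (pos.size * neg.size)


@lru_cache(maxsize=128)
def _exact_u_sf(n1: int, n0: int) -> np.ndarray:
    """Survival function P(U >= u) of the null Mann-Whitney U distribution.

    Exact counting over the C(n1+n0, n1) equally likely rank assignments of
    the positive class, by the standard dynamic-programming recurrence on
    the number of partitions; assumes continuous (tie-free) scores.
    Returns an array of length n1*n0 + 1 indexed by u.
    """
    n = n1 + n0
    wmax = sum(range(n0 + 1, n + 1))  # largest possible rank sum of positives
    # dp[j, w]: number of ways to pick j of the ranks seen so far with rank
    # sum w; process ranks 1..n in turn.
    dp = np.zeros((n1 + 1, wmax + 1), dtype=float)
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        for j in range(n1, 0, -1):  # descending: each rank used at most once
            dp[j, rank:] += dp[j - 1, :-rank]
    wmin = n1 * (n1 + 1) // 2
    counts = dp[n1, wmin:wmin + n1 * n0 + 1]  # index by U = W - wmin
    sf = np.cumsum(counts[::-1])[::-1] / counts.sum()
    return sf


def _enumerated_u_sf(n1: int, n0: int) -> np.ndarray:
    """Brute-force null SF of U by enumerating all rank subsets (oracle)."""
    from itertools import combinations

    umax = n1 * n0
    counts = np.zeros(umax + 1)
    for ranks in combinations(range(1, n1 + n0 + 1), n1):
        u = sum(ranks) - n1 * (n1 + 1) // 2
        counts[u] += 1
    sf = np.cumsum(counts[::-1])[::-1] / counts.sum()
    return sf


def exact_mw_test(scores, labels, alternative: str = "greater",
                  rng: np.random.Generator | None = None,
                  n_perm: int = 10_000) -> float:
    """One-sided exact test of H0: AUROC = 0.5.

    For tie-free data the exact null distribution of U is computed by
    dynamic programming over rank assignments.  With ties present the null
    is approximated by a Monte Carlo permutation distribution (``n_perm``
    label shuffles; pass ``rng`` for reproducibility), because the DP null
    assumes continuity.

    Parameters
    ----------
    alternative : "greater" tests AUROC > 0.5 (positives score higher);
        "less" tests AUROC < 0.5.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = pos.size, neg.size
    u = mann_whitney_u(pos, neg)
    if alternative == "less":
        u = n1 * n0 - u

    has_ties = np.unique(scores).size < scores.size
    if not has_ties:
        sf = _exact_u_sf(n1, n0)
        return float(sf[int(round(u))])
    # ties: permutation null with half-credit U
    if rng is None:
        rng = np.random.default_rng(0)
    ranks = sps.rankdata(scores)
    obs = u
    count = 0
    base = n1 * (n1 + 1) / 2.0
    for _ in range(n_perm):
        idx = rng.permutation(scores.size)[:n1]
        u_perm = ranks[idx].sum() - base
        if alternative == "less":
            u_perm = n1 * n0 - u_perm
        if u_perm >= obs - 1e-9:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class AurocResult:
    """Point estimate plus inference for one AUROC analysis."""

    auroc: float
    p_value: float | None = None
    ci: tuple[float, float] | None = None
    ci_method: str | None = None
    level: float = 0.95
    n_pos: int = 0
    n_neg: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.auroc <= 1.0):
            raise ValueError("AUROC outside [0, 1]")


def _auroc_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUROC for stacked bootstrap samples.

    ``pos`` is (B, n1) and ``neg`` is (B, n0); returns length-B AUROCs using
    midranks within each row.
    """
    both = np.concatenate([pos, neg], axis=1)
    ranks = sps.rankdata(both, axis=1)
    n1 = pos.shape[1]
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * neg.shape[1])


def bca_ci(scores, labels, B: int = 2000, level: float = 0.95,
           rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Bias-corrected-and-accelerated bootstrap CI for the AUROC.

    The bootstrap is stratified: patients are resampled with replacement
    within the responder and non-responder classes so every replicate keeps
    both classes.  The bias-correction constant z0 comes from the fraction
    of bootstrap AUROCs below the point estimate; the acceleration constant
    from the jackknife skewness.  A degenerate bootstrap distribution
    (all replicates equal) falls back to the percentile interval with a
    warning.
    """
    if B < 200:
        raise ValueError("B must be at least 200 for a stable BCa interval")
    scores, labels = _validate_scores_labels(scores, labels)
    if rng is None:
        rng = np.random.default_rng()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    est = mann_whitney_u(pos, neg) / (pos.size * neg.size)

    bpos = rng.integers(0, pos.size, size=(B, pos.size))
    bneg = rng.integers(0, neg.size, size=(B, neg.size))
    boot = _auroc_matrix(pos[bpos], neg[bneg])

    alpha = 1.0 - level
    if np.ptp(boot) == 0.0:
        warnings.warn("degenerate bootstrap AUROC distribution; "
                      "falling back to percentile interval")
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))

    prop = (np.sum(boot < est) + 0.5 * np.sum(boot == est)) / B
    prop = min(max(prop, 1.0 / (2 * B)), 1 - 1.0 / (2 * B))
    z0 = sps.norm.ppf(prop)

    # jackknife over all patients for acceleration
    jack = np.empty(scores.size)
    k = 0
    for i in range(pos.size):
        jack[k] = mann_whitney_u(np.delete(pos, i), neg) / ((pos.size - 1) * neg.size)
        k += 1
    for j in range(neg.size):
        jack[k] = mann_whitney_u(pos, np.delete(neg, j)) / (pos.size * (neg.size - 1))
        k += 1
    d = jack.mean() - jack
    denom = 6.0 * (np.sum(d ** 2) ** 1.5)
    a = np.sum(d ** 3) / denom if denom > 0 else 0.0

    zlo, zhi = sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)
    def _adj(z):
        num = z0 + z
        return sps.norm.cdf(z0 + num / (1 - a * num))
    lo, hi = np.quantile(boot, [_adj(zlo), _adj(zhi)])
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def delong_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC and DeLong structural components (V10 per positive, V01 per negative)."""
    scores, labels = _validate_scores_labels(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auroc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(auroc), v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> AurocResult:
    """Wald interval for the AUROC using the DeLong variance estimator.

    The variance is var(V10)/n1 + var(V01)/n0 with the structural
    components V10, V01; the interval is truncated to [0, 1].  Perfect
    separation gives zero variance and a degenerate interval, which is
    flagged rather than hidden.
    """
    auroc, v10, v01 = delong_components(scores, labels)
    n1, n0 = v10.size, v01.size
    if n1 < 2 or n0 < 2:
        raise ValueError("DeLong variance needs >= 2 patients per class")
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    flags = []
    if var == 0.0:
        flags.append("degenerate-zero-variance")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    half = z * math.sqrt(var)
    ci = (float(max(0.0, auroc - half)), float(min(1.0, auroc + half)))
    return AurocResult(auroc=auroc, ci=ci, ci_method="DeLong", level=level,
                       n_pos=n1, n_neg=n0, flags=flags)


# ---------------------------------------------------------------------------
# Combined model, power, concordance, subgroups
# ---------------------------------------------------------------------------

def combined_independence_test(scnp_scores, clinical_scores, outcomes,
                               method: str = "wald") -> float:
    """Test whether the SCNP score adds to the clinical score.

    Fits an unpenalized logistic regression of outcome on both score
    columns together (each controlling for the other) and returns the
    p-value for the SCNP coefficient: non-significance suggests the SCNP
    predictions are redundant given the clinical model.

    ``method`` is "wald" (default) or "lr" (likelihood-ratio against the
    clinical-only model).
    """
    import statsmodels.api as sm

    s = np.asarray(scnp_scores, dtype=float)
    c = np.asarray(clinical_scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not (s.shape == c.shape == y.shape):
        raise ValueError("inputs must be equal-length complete triples")
    if np.ptp(s) == 0 or np.ptp(c) == 0:
        raise ValueError("constant score column; model not identifiable")
    r = np.corrcoef(s, c)[0, 1]
    if abs(r) > 0.999:
        raise ValueError(
            f"SCNP and clinical scores are collinear (|r| = {abs(r):.4f}); "
            "the combined model cannot separate their contributions")
    X = sm.add_constant(np.column_stack([s, c]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if method == "wald":
            return float(fit.pvalues[1])
        if method == "lr":
            reduced = sm.Logit(y, sm.add_constant(c)).fit(disp=0, maxiter=200)
            lr = 2 * (fit.llf - reduced.llf)
            return float(sps.chi2.sf(max(lr, 0.0), df=1))
    raise ValueError("method must be 'wald' or 'lr'")


def binormal_mu(auroc: float) -> float:
    """Separation of the binormal score model attaining a given true AUROC.

    Positive scores ~ N(mu, 1) and negative ~ N(0, 1) give
    AUROC = Phi(mu / sqrt(2)), so mu = sqrt(2) * Phi^-1(AUROC).
    """
    return math.sqrt(2.0) * sps.norm.ppf(auroc)


def power_simulation(n_total: int, response_rate: float, true_auroc: float,
                     alpha: float = 0.05, reps: int = 2000,
                     rng: np.random.Generator | None = None) -> float:
    """Simulated power of the one-sided exact Mann-Whitney AUROC test.

    Each replicate draws ``round(n_total * response_rate)`` responder scores
    from N(mu, 1) and the remainder from N(0, 1), with mu calibrated so the
    true AUROC equals ``true_auroc``; power is the fraction of replicates
    whose exact one-sided p-value is <= alpha.  Because the scores are
    continuous, the exact null distribution of U depends only on the class
    sizes and is computed once.
    """
    if not 0.5 < true_auroc < 1.0:
        raise ValueError("true_auroc must lie in (0.5, 1)")
    if not 0.0 < response_rate < 1.0:
        raise ValueError("response_rate must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    n1 = int(round(n_total * response_rate))
    n0 = n_total - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be nonempty at this design")
    mu = binormal_mu(true_auroc)
    sf = _exact_u_sf(n1, n0)

    pos = rng.normal(mu, 1.0, size=(reps, n1))
    neg = rng.normal(0.0, 1.0, size=(reps, n0))
    both = np.concatenate([pos, neg], axis=1)
    ranks = sps.rankdata(both, axis=1)
    u = np.rint(ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0).astype(int)
    pvals = sf[u]
    return float(np.mean(pvals <= alpha))


def paired_concordance(bm_scores: dict, pb_scores: dict,
                       threshold: float = 0.5):
    """Concordance of classifier scores between paired BM and PB samples.

    Both inputs map patient id -> score.  Returns (Pearson r, DataFrame of
    the overlapping patients with both scores and a per-patient concordance
    flag at the score midpoint ``threshold``).
    """
    import pandas as pd

    common = sorted(set(bm_scores) & set(pb_scores))
    if len(common) < 2:
        raise ValueError("need >= 2 patients with both tissues")
    bm = np.array([bm_scores[p] for p in common], dtype=float)
    pb = np.array([pb_scores[p] for p in common], dtype=float)
    r = float(sps.pearsonr(bm, pb)[0])
    table = pd.DataFrame({
        "patient_id": common,
        "bm_score": bm,
        "pb_score": pb,
        "concordant": (bm >= threshold) == (pb >= threshold),
    })
    return r, table


def subgroup_performance(scores, labels, groups, level: float = 0.95):
    """Per-subgroup AUROC with DeLong confidence intervals.

    ``groups`` maps subgroup name -> boolean mask (or index array) over the
    cohort; typical groupings are sex, age above/below the median, WBC
    above/below the median, and cytogenetic risk (with unknown risk mapped
    to intermediate upstream).  A subgroup missing one of the outcome
    classes is reported as not computable instead of raising.

    Returns dict: name -> AurocResult (flagged "not-computable" with
    auroc = nan carrier replaced by a flags-only result) .
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = {}
    for name, mask in groups.items():
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        s, y = scores[idx], labels[idx]
        if np.unique(y).size < 2 or (y == 1).sum() < 2 or (y == 0).sum() < 2:
            out[name] = AurocResult(auroc=0.5, n_pos=int((y == 1).sum()),
                                    n_neg=int((y == 0).sum()),
                                    flags=["not-computable"])
            continue
        res = delong_ci(s, y, level=level)
        res.p_value = exact_mw_test(s, y)
        out[name] = res
    return out


def median_split(values, labels_low: str = "le_median",
                 labels_high: str = "gt_median"):
    """Split a numeric covariate at its median.

    Values equal to the median go to the low (``<= median``) side, so for
    odd n the low side holds ceil(n/2) patients.  Returns dict of two masks.
    """
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    lo = v <= med
    return {labels_low: lo, labels_high: ~lo}
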