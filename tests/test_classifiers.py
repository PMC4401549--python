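"""Locked-model and training-pipeline tests."""

import hashlib
import math
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from scnp.classifiers import (load_locked_model, score_dx_scnp, ScoringError,
                              prescreen_nodes, fit_penalized_logistic,
                              enumerate_combination_models,
                              adjust_auroc_optimism, oob_auroc,
                              build_dx_clinical, _irls_logistic)
from scnp.simulate import SimulationConfig, _draw_patient
from scnp.cohort import impute_clinical


def reference_score(n1, n2):
    """Independent evaluation of the locked formula, written out directly."""
    c1 = (n1 - 0.5) ** 2 if n1 > 0.5 else 0.0
    c2 = (0.5 - n2) ** 2 if n2 < 0.5 else 0.0
    chi = -1.26004 + 95.60133 * c1 + 34.94358 * c2
    return math.exp(chi) / (1.0 + math.exp(chi))


class TestLockedModel:
    def test_hinge_boundary_at_half(self):
        # both transforms vanish at the 0.5 boundary
        assert score_dx_scnp(0.5, 0.5) == pytest.approx(
            1 / (1 + math.exp(1.26004)))
        assert score_dx_scnp(0.5, 0.5) == pytest.approx(0.2212, abs=5e-4)

    def test_printed_formula_example(self):
        # n1=0.7, n2=0.3: both hinge terms are 0.04
        got = score_dx_scnp(0.7, 0.3)
        lp = -1.26004 + 95.60133 * 0.04 + 34.94358 * 0.04
        assert lp == pytest.approx(3.9617564)
        assert got == pytest.approx(1 / (1 + math.exp(-lp)))
        assert got == pytest.approx(0.9813, abs=5e-4)

    def test_matches_reference_evaluation(self, rng):
        n1 = rng.random(1000)
        n2 = rng.random(1000)
        got = score_dx_scnp(n1, n2)
        want = np.array([reference_score(a, b) for a, b in zip(n1, n2)])
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    def test_monotone_and_continuous_on_grid(self):
        g = np.linspace(0, 1, 101)
        s_n1 = score_dx_scnp(g, np.full_like(g, 0.4))
        s_n2 = score_dx_scnp(np.full_like(g, 0.6), g)
        assert (np.diff(s_n1) >= -1e-15).all()   # nondecreasing in n1
        assert (np.diff(s_n2) <= 1e-15).all()    # nonincreasing in n2
        eps = 1e-9
        assert score_dx_scnp(0.5 + eps, 0.5) == pytest.approx(
            score_dx_scnp(0.5 - eps, 0.5), abs=1e-6)
        assert score_dx_scnp(0.5, 0.5 + eps) == pytest.approx(
            score_dx_scnp(0.5, 0.5 - eps), abs=1e-6)

    def test_artifact_checksum_guards_drift(self):
        blob = (resources.files("scnp.data") / "locked_dxscnp.json"
                ).read_bytes()
        assert hashlib.sha256(blob).hexdigest() == (
            "9c0a7b6d221a03d2b0f467c78d9d0cc313fbaa723398a511a22783ea6ca65f2c")
        model = load_locked_model()
        assert model.coefficients == (95.60133, 34.94358)
        assert model.intercept == -1.26004

    def test_out_of_range_and_missing_inputs_rejected(self):
        with pytest.raises(ScoringError):
            score_dx_scnp(1.2, 0.4)
        with pytest.raises(ScoringError):
            score_dx_scnp(float("nan"), 0.4)

    def test_score_table_skips_incomplete_patients(self):
        model = load_locked_model()
        idx = pd.MultiIndex.from_tuples([("P1", "BM"), ("P2", "BM")])
        mat = pd.DataFrame({"AraC+Dauno|24h|cPARP|Uu": [0.8, np.nan],
                            "AraC+Dauno|24h|CD34|Uu": [0.2, 0.3]}, index=idx)
        scores = model.score_table(mat)
        assert np.isfinite(scores.loc[("P1", "BM")])
        assert np.isnan(scores.loc[("P2", "BM")])


def _noise_matrix(rng, n=60, p=10, prefix="node"):
    X = rng.normal(size=(n, p))
    cols = [f"{prefix}{j}|Uu" for j in range(p)]
    return pd.DataFrame(X, columns=cols)


class TestPrescreen:
    def test_recovers_planted_node(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = (rng.random(60) < 0.6).astype(int)
            X = _noise_matrix(rng)
            X["planted|Uu"] = y * 1.5 + rng.normal(0, 1, 60)
            sel = prescreen_nodes(X, y, rng=rng)
            hits += "planted|Uu" in sel.index
        assert hits >= 9

    def test_null_false_selection_rate(self):
        univ_hits, total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = (rng.random(40) < 0.5).astype(int)
            if y.sum() < 5 or y.sum() > 35:
                continue
            X = _noise_matrix(rng, n=40, p=20)
            sel = prescreen_nodes(X, y, alpha=0.05, rng=rng)
            univ_hits += int(sel["univariate"].sum()) if len(sel) else 0
            total += 20
        # expected univariate false-positive rate ~ alpha
        rate = univ_hits / total
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(7)
        y = (rng.random(50) < 0.6).astype(int)
        X = _noise_matrix(rng, n=50, p=8)
        X["planted|Uu"] = y * 2.0 + rng.normal(0, 1, 50)
        sel1 = prescreen_nodes(X, y, rng=np.random.default_rng(1))
        perm = np.random.default_rng(2).permutation(50)
        sel2 = prescreen_nodes(X.iloc[perm].reset_index(drop=True), y[perm],
                               rng=np.random.default_rng(1))
        assert set(sel1.index) == set(sel2.index)

    def test_all_missing_feature_dropped(self, rng):
        y = (rng.random(40) < 0.5).astype(int)
        X = _noise_matrix(rng, n=40, p=4)
        X["gone|Uu"] = np.nan
        sel = prescreen_nodes(X, y, rng=rng)
        assert "gone|Uu" not in sel.index


class TestPenalizedLogistic:
    def test_strong_penalty_shrinks_all_to_zero(self, rng):
        X = rng.normal(size=(80, 6))
        y = (rng.random(80) < 0.5).astype(int)
        coefs = fit_penalized_logistic(X, y, Cs=[1e-4], rng=rng)
        assert (coefs == 0.0).all()

    def test_single_strong_predictor_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            y = (rng.random(200) < 1 / (1 + np.exp(-2 * x))).astype(int)
            X = np.column_stack([x, rng.normal(size=(200, 4))])
            coefs = fit_penalized_logistic(X, y, rng=rng)
            hits += coefs[0] > 0
        assert hits >= 9

    def test_separation_guard_in_irls(self):
        # perfectly separable toy data: unpenalized coefficients diverge
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        beta, separated = _irls_logistic(X, y, ridge=0.0)
        assert separated

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_penalized_logistic(rng.normal(size=(20, 2)), np.ones(20, int))


class TestCombinationModels:
    def test_combinatorics_count(self, rng):
        y = (rng.random(60) < 0.6).astype(int)
        X = _noise_matrix(rng, n=60, p=5)
        models = enumerate_combination_models(list(X.columns), X, y,
                                              kmax=4, B=5, rng=rng)
        assert len(models) == math.comb(5, 2) + math.comb(5, 3) + math.comb(5, 4)

    def test_ranking_invariant_to_candidate_order(self):
        rng = np.random.default_rng(3)
        y = (rng.random(80) < 0.6).astype(int)
        X = _noise_matrix(rng, n=80, p=5)
        X["a|Uu"] = y * 1.2 + rng.normal(0, 1, 80)
        cands = list(X.columns)
        m1 = enumerate_combination_models(cands, X, y, kmax=2, B=20,
                                          rng=np.random.default_rng(5))
        m2 = enumerate_combination_models(cands[::-1], X, y, kmax=2, B=20,
                                          rng=np.random.default_rng(5))
        assert [m.features for m in m1] == [m.features for m in m2]

    def test_recovers_planted_pair(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 100
            y = (rng.random(n) < 0.6).astype(int)
            X = _noise_matrix(rng, n=n, p=4)
            X["sig1|Uu"] = y * 1.5 + rng.normal(0, 1, n)
            X["sig2|Uu"] = -y * 1.5 + rng.normal(0, 1, n)
            models = enumerate_combination_models(list(X.columns), X, y,
                                                  kmax=2, B=30, rng=rng)
            top = set(models[0].features)
            hits += {"sig1|Uu", "sig2|Uu"} <= top
        assert hits >= 8

    def test_sparse_class_subsets_skipped(self, rng):
        y = np.r_[np.ones(3, int), np.zeros(40, int)]
        X = _noise_matrix(rng, n=43, p=3)
        X.loc[:2, "node0|Uu"] = np.nan  # kills all responders for node0 pairs
        models = enumerate_combination_models(list(X.columns), X, y,
                                              kmax=2, B=5, rng=rng)
        assert all("node0|Uu" not in m.features for m in models)


class TestOptimismAndOob:
    def test_null_adjusted_auroc_near_half(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 2))
            y = rng.permutation(np.r_[np.ones(60, int), np.zeros(40, int)])
            _, adj = adjust_auroc_optimism(X, y, B=200, rng=rng)
            vals.append(adj)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_adjusted_rarely_exceeds_apparent(self):
        worse = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 3))
            y = (rng.random(60) < 0.5 + 0.2 * (X[:, 0] > 0)).astype(int)
            app, adj = adjust_auroc_optimism(X, y, B=100, rng=rng)
            worse += adj > app
        assert worse <= 1

    def test_full_data_bootstrap_gives_zero_adjustment(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        app, adj = adjust_auroc_optimism(
            X, y, B=1, rng=rng, resample_indices=lambda n: np.arange(n))
        assert adj == pytest.approx(app)

    def test_oob_separable_near_one(self, rng):
        x = np.r_[np.zeros(30), np.ones(30)] + rng.normal(0, 0.05, 60)
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        assert oob_auroc(x[:, None], y, B=100, rng=rng) > 0.97

    def test_oob_null_does_not_exceed_chance(self):
        # OOB estimates are pessimistic under the null: noise fits
        # anti-correlate with their held-out patients, so the average sits
        # at or slightly below 0.5 — never systematically above it.
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 2))
            y = np.r_[np.ones(40, int), np.zeros(40, int)]
            vals.append(oob_auroc(X, y, B=80, rng=rng))
        assert np.mean(vals) < 0.5 + 0.04
        assert np.mean(vals) > 0.30

    def test_apparent_exceeds_oob_on_signal(self):
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 4))
            y = (rng.random(60) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
            from scnp.classifiers import _fit_spec, _predict_lp
            from scnp.stats import auroc_trapezoid
            beta, _ = _fit_spec(X, y)
            apparent = auroc_trapezoid(_predict_lp(X, beta), y)
            gaps.append(apparent - oob_auroc(X, y, B=60, rng=rng))
        assert np.mean(gaps) > 0


def _cohort_records(n, seed, **cfg_kw):
    cfg = SimulationConfig(n_patients=n, seed=seed, **cfg_kw)
    rng = np.random.default_rng(seed)
    return [_draw_patient(i, cfg, rng) for i in range(n)], cfg


class TestClinicalModels:
    def test_level1_not_constructible_on_outcome_independent_cohort(self):
        # clinical covariates are independent of outcome by construction;
        # on this cohort the penalty shrinks every coefficient to zero and
        # the model is flagged as not constructible
        records, _ = _cohort_records(80, seed=0)
        model = build_dx_clinical(records, level=1,
                                  rng=np.random.default_rng(0))
        assert not model.constructible
        with pytest.raises(ScoringError):
            model.score(np.zeros((1, len(model.features))))

    def test_level1_null_models_have_no_transferable_skill(self):
        # chance correlations can make a null cohort yield a nonzero fit;
        # whatever is selected must not predict outcome in fresh cohorts
        from scnp.stats import auroc_trapezoid
        from scnp.classifiers import _clinical_design
        aurocs = []
        for seed in range(8):
            records, _ = _cohort_records(80, seed=seed)
            model = build_dx_clinical(records, level=1,
                                      rng=np.random.default_rng(seed))
            if not model.constructible:
                continue
            fresh, _ = _cohort_records(200, seed=1000 + seed)
            X, _, y = _clinical_design(fresh, 1, None)
            aurocs.append(auroc_trapezoid(model.score(X), y))
        if aurocs:
            assert np.mean(aurocs) == pytest.approx(0.5, abs=0.05)

    def test_level2_planted_cytogenetics_recovered(self):
        # tight latent-score -> outcome link plus a strong planted
        # cytogenetics association
        hits = 0
        for seed in range(10):
            records, _ = _cohort_records(200, seed=seed,
                                         cytogenetics_effect=3.0,
                                         response_slope=8.0,
                                         response_intercept=-2.5)
            records, _ = impute_clinical(records)
            cd34 = {r.patient_id: 40.0 for r in records}
            model = build_dx_clinical(records, level=2, pct_cd34=cd34,
                                      rng=np.random.default_rng(seed))
            k = model.features.index("cytogenetic_risk")
            hits += model.coefficients[k] != 0.0
        assert hits >= 9

    def test_level2_requires_imputation_and_cd34(self):
        records, _ = _cohort_records(60, seed=1)
        has_unknown = any(r.cytogenetic_risk == "unknown" for r in records)
        assert has_unknown
        with pytest.raises(ValueError, match="imputed|CD34"):
            build_dx_clinical(records, level=2,
                              pct_cd34={r.patient_id: 10.0 for r in records})
        imputed, _ = impute_clinical(records)
        with pytest.raises(ValueError, match="CD34"):
            build_dx_clinical(imputed, level=2, pct_cd34=None)
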