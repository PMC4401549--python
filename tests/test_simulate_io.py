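"""Synthetic-cohort generator and event-file round-trip tests."""

import numpy as np
import pandas as pd
import pytest

import scnp
from scnp.io import read_events, write_events, EventFileError
from scnp.metrics import metric_uu
from scnp.simulate import (SimulationConfig, simulate_cohort, simulate_well,
                           patients_to_frame, ConfigurationError,
                           _draw_patient)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"trm_rate": 1.5}, {"p_bm": -0.1}, {"n_patients": 0},
        {"mean_events_per_well": 0}, {"cparp_effect": float("inf")},
        {"debris_frac": 0.6, "dead_frac": 0.5},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kw).validate()

    def test_unknown_modulator_rejected(self):
        cfg = SimulationConfig(seed=0)
        p = _draw_patient(0, cfg, np.random.default_rng(0))
        with pytest.raises(ConfigurationError, match="unknown modulator"):
            simulate_well(p, "BM", "mystery-drug", 1.0, cfg,
                          np.random.default_rng(0))


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = SimulationConfig(n_patients=4, mean_events_per_well=300, seed=21)
        p1, w1, b1 = simulate_cohort(cfg)
        p2, w2, b2 = simulate_cohort(
            SimulationConfig(n_patients=4, mean_events_per_well=300, seed=21))
        assert patients_to_frame(p1).equals(patients_to_frame(p2))
        assert len(w1) == len(w2)
        for a, b in zip(w1, w2):
            assert a.well_id == b.well_id
            pd.testing.assert_frame_equal(a.data, b.data)
        for x, y in zip(b1, b2):
            for ch in x.peak_intensities:
                for pa, pb in zip(x.peak_intensities[ch],
                                  y.peak_intensities[ch]):
                    np.testing.assert_array_equal(pa, pb)

    def test_same_rng_state_same_well(self):
        cfg = SimulationConfig(seed=0)
        p = _draw_patient(0, cfg, np.random.default_rng(0))
        w1 = simulate_well(p, "BM", "unmodulated", 0.25, cfg,
                           np.random.default_rng(77), n_events=500)
        w2 = simulate_well(p, "BM", "unmodulated", 0.25, cfg,
                           np.random.default_rng(77), n_events=500)
        pd.testing.assert_frame_equal(w1.data, w2.data)


class TestCohortStructure:
    def test_well_plan_complete_and_labels_present(self, small_cohort):
        patients, wells, beads = small_cohort
        by_sample = {}
        for w in wells:
            by_sample.setdefault((w.patient_id, w.tissue), set()).add(
                (w.modulator, w.time_hours))
        expected = set(scnp.simulate.WELL_PLAN)
        for p in patients:
            for t in p.tissue_types:
                assert by_sample[(p.patient_id, t)] == expected
        assert all("labels" in w.meta for w in wells)

    def test_every_patient_has_tissue(self, small_cohort):
        patients, _, _ = small_cohort
        assert all(len(p.tissue_types) >= 1 for p in patients)

    def test_responders_have_higher_latent_chemosensitivity(self):
        cfg = SimulationConfig(n_patients=400, mean_events_per_well=1, seed=2)
        rng = np.random.default_rng(cfg.seed)
        patients = [_draw_patient(i, cfg, rng) for i in range(400)]
        s_resp = [p.latent_chemosensitivity for p in patients if p.responder]
        s_rd = [p.latent_chemosensitivity for p in patients
                if p.outcome == "RD"]
        rate = len(s_resp) / (len(s_resp) + len(s_rd))
        assert np.mean(s_resp) > np.mean(s_rd) + 0.1
        assert rate == pytest.approx(0.72, abs=0.06)

    def test_trm_independent_of_latent_score(self):
        cfg = SimulationConfig(n_patients=2000, mean_events_per_well=1,
                               seed=3, trm_rate=0.3)
        rng = np.random.default_rng(cfg.seed)
        patients = [_draw_patient(i, cfg, rng) for i in range(2000)]
        s_trm = [p.latent_chemosensitivity for p in patients
                 if p.outcome == "TRM"]
        assert np.mean(s_trm) == pytest.approx(0.5, abs=0.05)

    def test_n_events_poisson_moments(self):
        cfg = SimulationConfig(seed=4, mean_events_per_well=400)
        rng = np.random.default_rng(4)
        p = _draw_patient(0, cfg, rng)
        counts = [simulate_well(p, "BM", "unmodulated", 0.25, cfg,
                                rng).n_events for _ in range(100)]
        assert np.mean(counts) == pytest.approx(400, abs=3 * 2.0)
        assert np.var(counts) == pytest.approx(400, rel=0.5)


class TestPlantedEffect:
    @staticmethod
    def _uu_on_labeled_blasts(patient, cfg, rng, latent=None):
        treated = simulate_well(patient, "BM", "AraC+Dauno", 24.0, cfg, rng,
                                n_events=1000, latent_s=latent)
        untreated = simulate_well(patient, "BM", "untreated", 24.0, cfg, rng,
                                  n_events=1000, latent_s=latent)
        m = treated.data.loc[treated.meta["labels"] == "blast", "cPARP"]
        u = untreated.data.loc[untreated.meta["labels"] == "blast", "cPARP"]
        return metric_uu(m, u)

    def test_uu_shift_monotone_in_effect_size(self):
        means = []
        for effect in (0.0, 0.25, 0.5):
            cfg = SimulationConfig(seed=5, cparp_effect=effect)
            diffs = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                p = _draw_patient(0, cfg, rng)
                hi = self._uu_on_labeled_blasts(p, cfg, rng, latent=0.9)
                lo = self._uu_on_labeled_blasts(p, cfg, rng, latent=0.1)
                diffs.append(hi - lo)
            means.append(np.mean(diffs))
        assert means[0] < means[1] < means[2]
        assert abs(means[0]) < 0.02  # no planted effect, no shift

    def test_zero_effect_null(self):
        cfg = SimulationConfig(seed=6, cparp_effect=0.0, cd34_effect=0.0,
                               aqua_death_effect=0.0)
        rng = np.random.default_rng(6)
        uus = []
        for i in range(30):
            p = _draw_patient(i, cfg, rng)
            uus.append((p.responder,
                        self._uu_on_labeled_blasts(p, cfg, rng)))
        resp = [u for r, u in uus if r]
        rest = [u for r, u in uus if not r]
        if resp and rest:
            assert abs(np.mean(resp) - np.mean(rest)) < 0.03


class TestStrongPlantedEffect:
    def test_strong_effect_drives_locked_classifier(self, node_panel):
        """A tight chemosensitivity-outcome link yields a responder-vs-RD
        mean Uu(cPARP) shift near +0.2, and the locked classifier then
        separates outcomes with AUROC above 0.75 on the simulated cohort."""
        from scnp.pipeline import (cohort_node_matrix, outcome_series,
                                   locked_classifier_performance)
        panel = [n for n in node_panel if n.modulator == "AraC+Dauno"]
        gaps, aurocs = [], []
        for seed in range(3):
            cfg = SimulationConfig(n_patients=60, seed=300 + seed,
                                   mean_events_per_well=1200,
                                   p_bm=1.0, p_pb=0.0,
                                   response_slope=8.0,
                                   response_intercept=-2.5)
            patients, wells, beads = simulate_cohort(cfg)
            mat = cohort_node_matrix(wells, beads, panel, min_cells=100)
            y = outcome_series(patients, mat.index)
            keep = y.notna()
            col = mat.loc[keep, "AraC+Dauno|24h|cPARP|Uu"]
            yv = y[keep].astype(int)
            gaps.append(col[yv == 1].mean() - col[yv == 0].mean())
            aurocs.append(locked_classifier_performance(
                patients, mat, "BM")["auroc"])
        assert np.mean(gaps) == pytest.approx(0.2, abs=0.07)
        assert np.mean(aurocs) > 0.75


class TestSecondaryDiscordance:
    def test_pb_decoupled_only_for_secondary(self):
        cfg = SimulationConfig(n_patients=30, mean_events_per_well=400,
                               seed=8, p_bm=1.0, p_pb=1.0,
                               secondary_fraction=0.5,
                               secondary_discordance=1.0)
        patients, wells, _ = simulate_cohort(cfg)
        # mean blast cPARP in the treated well tracks the latent score; for
        # de novo patients BM and PB should agree far better than secondary
        key = {}
        for w in wells:
            if w.modulator == "AraC+Dauno":
                b = w.data.loc[w.meta["labels"] == "blast", "cPARP"]
                key[(w.patient_id, w.tissue)] = np.log10(b).mean()
        gaps = {"de_novo": [], "secondary": []}
        for p in patients:
            if set(p.tissue_types) == {"BM", "PB"}:
                gaps[p.onset].append(abs(key[(p.patient_id, "BM")]
                                         - key[(p.patient_id, "PB")]))
        assert np.mean(gaps["secondary"]) > np.mean(gaps["de_novo"])


class TestRoundTrip:
    def _well(self):
        cfg = SimulationConfig(seed=12)
        p = _draw_patient(0, cfg, np.random.default_rng(12))
        w = simulate_well(p, "PB", "FLT3L", 0.25, cfg,
                          np.random.default_rng(12), n_events=200)
        return w.replace(meta={"scale": "raw"})  # labels are not serialized

    def test_csv_roundtrip_exact(self, tmp_path):
        w = self._well()
        path = write_events(w, tmp_path / "well.csv", dialect="csv")
        back = read_events(path, dialect="csv")
        assert back.well_id == w.well_id and back.tissue == w.tissue
        assert back.modulator == w.modulator
        np.testing.assert_array_equal(back.data.to_numpy(dtype=np.float32),
                                      w.data.to_numpy())

    def test_fcs_roundtrip_float32(self, tmp_path):
        w = self._well()
        path = write_events(w, tmp_path / "well.fcs", dialect="fcs3")
        back = read_events(path, dialect="fcs3")
        assert back.channels == w.channels
        assert back.patient_id == w.patient_id
        assert back.time_hours == w.time_hours
        np.testing.assert_allclose(back.data.to_numpy(),
                                   w.data.to_numpy(dtype=np.float32),
                                   rtol=0, atol=0)

    def test_empty_table_roundtrip(self, tmp_path):
        w = self._well()
        empty = w.replace(data=w.data.iloc[:0])
        for dialect, name in (("csv", "e.csv"), ("fcs3", "e.fcs")):
            back = read_events(write_events(empty, tmp_path / name, dialect),
                               dialect)
            assert back.n_events == 0
            assert back.channels == w.channels

    def test_malformed_files_name_location(self, tmp_path):
        bad = tmp_path / "bad.fcs"
        bad.write_bytes(b"not an fcs file at all, certainly not enough bytes")
        with pytest.raises(EventFileError, match="offset"):
            read_events(bad, dialect="fcs3")
        orphan = tmp_path / "orphan.csv"
        orphan.write_text("event_index,FSC\n0,1.0\n")
        with pytest.raises(EventFileError, match="sidecar"):
            read_events(orphan, dialect="csv")
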