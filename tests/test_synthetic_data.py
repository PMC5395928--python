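"""Generator contracts: determinism, planted structure, forward-model consistency."""

import numpy as np
import pytest

from nirsconn import connectivity as conn
from nirsconn import preprocess as pp
from nirsconn import synthetic_data as sd
from nirsconn.errors import ConfigurationError


class TestDeterminism:
    def test_same_seed_byte_identical(self, fast_config):
        a = sd.simulate_resting_recording(fast_config, "CG03")
        b = sd.simulate_resting_recording(fast_config, "CG03")
        assert np.array_equal(a.optical_density, b.optical_density)

    def test_subjects_differ(self, fast_config):
        a = sd.simulate_resting_recording(fast_config, "HD01")
        b = sd.simulate_resting_recording(fast_config, "HD02")
        assert not np.allclose(a.optical_density, b.optical_density)

    def test_cohort_metadata_reproducible(self):
        cfg = sd.SimulationConfig(n_hd=2, n_cg=2, duration_rest_s=200.0,
                                  duration_task_s=100.0,
                                  task_events=((30.0, 10.0, "gamble"),
                                               (60.0, 10.0, "gamble")),
                                  seed=5)
        m1 = sd.metadata_table(sd.simulate_cohort(cfg)[0])
        m2 = sd.metadata_table(sd.simulate_cohort(cfg)[0])
        assert m1.equals(m2)


class TestCouplingMatrices:
    def test_default_group_matrices_valid(self, fast_config):
        for g in sd.GROUPS:
            R = fast_config.group_coupling(g)
            assert np.allclose(R, R.T)
            assert np.allclose(np.diag(R), 1.0)
            assert np.linalg.eigvalsh(R).min() > -1e-8

    def test_non_psd_matrix_rejected(self, montage):
        bad = np.full((12, 12), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(ConfigurationError):
            sd.SimulationConfig(
                coupling_matrix_by_group={"HD": bad, "CG": bad}
            ).group_coupling("HD")

    def test_nearest_correlation_projects_to_psd(self, rng):
        a = rng.uniform(-1, 1, (12, 12))
        R = (a + a.T) / 2
        np.fill_diagonal(R, 1.0)
        fixed = sd.nearest_correlation(R)
        assert np.linalg.eigvalsh(fixed).min() > -1e-9
        assert np.allclose(np.diag(fixed), 1.0)


class TestPlantedCorrelationRecovery:
    def test_perfect_coupling_limit(self, montage):
        """rho=1 with all noise sources off gives mirrored pairs r = 1."""
        cfg = sd.SimulationConfig(
            duration_rest_s=240.0, interhemispheric_rho={"HD": 1.0, "CG": 1.0},
            coupling_levels={"HD": (1.0, 1.0, 1.0), "CG": (1.0, 1.0, 1.0)},
            subject_rho_sd=0.0, edge_rho_range=None, artifact_rate_per_min=0.0,
            physio_amplitudes={}, od_noise_sd=0.0, hb_noise_frac=0.0, seed=2)
        rec = sd.simulate_resting_recording(cfg, "HD01")
        series = pp.preprocess_recording(
            rec, pp.PreprocessConfig(motion="none"))
        res = conn.interhemispheric_correlation(series, montage)
        for r in res.pair_r["HbO"].values():
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_mean_recovery_within_tolerance(self, montage):
        """Planted rho=0.8: Monte-Carlo mean over 20 subjects lands within
        +-0.05 after band-pass filtering."""
        cfg = sd.SimulationConfig(
            interhemispheric_rho={"HD": 0.8, "CG": 0.8},
            subject_rho_sd=0.0, edge_rho_range=None, artifact_rate_per_min=0.0,
            seed=11)
        vals = []
        for i in range(20):
            rec = sd.simulate_resting_recording(cfg, f"HD{i + 1:02d}")
            rec = pp.trim_initial(rec)
            series = pp.od_to_concentration(rec)
            series = pp.bandpass(series, cfg.latent_band_hz)
            res = conn.interhemispheric_correlation(series, montage)
            vals.append(res.roi_means["HbO"]["overall"])
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)


class TestForwardModelConsistency:
    def test_concentrations_recovered_through_mbll(self, fast_config, montage):
        """Artifact/physio-free simulation inverted by the preprocessing
        MBLL step correlates > 0.99 with the planted concentrations."""
        cfg = sd.SimulationConfig(duration_rest_s=240.0,
                                  artifact_rate_per_min=0.0,
                                  physio_amplitudes={}, od_noise_sd=0.0,
                                  seed=9)
        rec = sd.simulate_resting_recording(cfg, "CG01")
        series = pp.od_to_concentration(rec)
        # regenerate the same planted concentrations
        R = sd.subject_target_matrix(cfg, "CG01", "CG")
        rng = sd._rng_for(cfg, "CG01", stream=1)
        n = rec.n_samples
        latents = sd._mixed_latents(rng, R, n, cfg.sampling_rate_hz,
                                    cfg.latent_band_hz)
        hbo = cfg.hbo_sd_uM * latents
        for c in range(12):
            r = np.corrcoef(series.hbo[:, c], hbo[:, c])[0, 1]
            assert r > 0.99


class TestTaskSimulation:
    def test_events_round_trip(self, tmp_path, fast_config):
        from nirsconn import montage_io as mio
        rec = sd.simulate_task_recording(fast_config, "HD01")
        path = tmp_path / "task.tsv"
        mio.write_recording(rec, path)
        back = mio.read_recording(path)
        assert [e[:2] for e in back.events] == [e[:2] for e in rec.events]

    def test_null_beta_gives_null_tmap(self, montage):
        """With no planted response the GLM t-statistics center on zero."""
        from nirsconn import localizer_glm as lg
        cfg = sd.SimulationConfig(duration_task_s=180.0,
                                  artifact_rate_per_min=0.0, task_beta_uM=0.0,
                                  seed=13)
        tstats = []
        for i in range(5):
            rec = sd.simulate_task_recording(cfg, f"HD{i + 1:02d}")
            rec = pp.trim_initial(rec)
            series = pp.od_to_concentration(rec)
            X, names = lg.build_design_matrix(rec.events, rec.duration_s,
                                              cfg.sampling_rate_hz)
            tstats.extend(lg.fit_glm(series, X, names).tstat)
        # single-subject t values are inflated by autocorrelated residuals,
        # but with no planted response they must center on zero
        tstats = np.asarray(tstats)
        sem = tstats.std(ddof=1) / np.sqrt(tstats.size)
        assert abs(tstats.mean()) < 3 * sem + 1e-12

    def test_empty_event_list_rejected(self, fast_config):
        cfg = sd.SimulationConfig(duration_rest_s=240.0, duration_task_s=120.0,
                                  task_events=(), seed=1)
        with pytest.raises(ConfigurationError):
            sd.simulate_task_recording(cfg, "HD01")

    def test_unknown_active_channel_rejected(self, fast_config):
        with pytest.raises(ConfigurationError):
            sd.simulate_task_recording(fast_config, "HD01",
                                       active_channels={99})


class TestCohort:
    def test_metadata_row_count_under_defaults(self):
        cfg = sd.SimulationConfig(duration_rest_s=200.0, duration_task_s=100.0,
                                  task_events=((30.0, 10.0, "gamble"),
                                               (60.0, 10.0, "gamble")),
                                  seed=3)
        subjects, truth = sd.simulate_cohort(cfg)
        meta = sd.metadata_table(subjects)
        assert len(meta) == 15
        assert (meta["group"] == "HD").sum() == 8
        assert (meta["group"] == "CG").sum() == 7
        assert set(truth.subject_edge_z) == set(meta.index)

    def test_too_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.simulate_cohort(sd.SimulationConfig(
                n_hd=1, duration_rest_s=200.0, duration_task_s=100.0,
                task_events=((30.0, 10.0, "gamble"),)))

    def test_ground_truth_serializes(self, tmp_path):
        cfg = sd.SimulationConfig(n_hd=2, n_cg=2, duration_rest_s=200.0,
                                  duration_task_s=100.0,
                                  task_events=((30.0, 10.0, "gamble"),
                                               (60.0, 10.0, "gamble")),
                                  seed=4)
        subjects, truth = sd.simulate_cohort(cfg)
        sd.write_cohort(subjects, truth, tmp_path)
        assert (tmp_path / "ground_truth.json").exists()
        assert (tmp_path / "metadata.tsv").exists()
        assert (tmp_path / "HD01_rest.tsv").exists()
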