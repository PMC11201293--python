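import numpy as np
import pytest

import restdyn as rd
from restdyn.synthetic import PATIENT, CONTROL, build_atlas


class TestTransitionMatrix:
    def test_stationary_and_switch_rate(self):
        pi = np.array([0.3, 0.25, 0.25, 0.2])
        for rate in (0.02, 0.08, 0.3):
            a = rd.transition_matrix(pi, rate)
            np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(pi @ a, pi, atol=1e-12)
            expected_sr = float(pi @ (1.0 - np.diag(a)))
            assert expected_sr == pytest.approx(rate, abs=1e-12)

    def test_infeasible_rate_names_maximum(self):
        pi = np.array([0.9, 0.05, 0.05])
        with pytest.raises(rd.ParameterizationError, match="maximum feasible"):
            rd.transition_matrix(pi, 0.9)

    def test_zero_rate_allows_any_fo(self):
        a = rd.transition_matrix(np.array([0.5, 0.3, 0.2]), 0.0)
        np.testing.assert_array_equal(a, np.eye(3))


class TestStatePaths:
    def test_zero_rate_gives_constant_paths(self):
        cfg = rd.SimulationConfig(
            n_patients=5, n_controls=5, n_parcels=4, n_volumes=50,
            patient_switch_rate=0.0, seed=3,
        )
        paths = rd.generate_state_paths(cfg, PATIENT)
        for p in paths:
            assert np.all(p == p[0])

    def test_single_state_chain(self):
        cfg = rd.SimulationConfig(
            n_patients=2, n_controls=2, n_parcels=4, n_volumes=30, n_states=1,
            patient_switch_rate=0.0, control_switch_rate=0.0, seed=0,
        )
        (p,) = rd.generate_state_paths(cfg, CONTROL, n_subjects=1)
        assert np.all(p == 0)

    def test_law_of_large_numbers_switch_rate(self):
        # 500 control paths at T=230: mean empirical SR converges to 0.06
        cfg = rd.SimulationConfig(
            n_patients=1, n_controls=500, n_parcels=4, n_volumes=230, seed=9
        )
        paths = rd.generate_state_paths(cfg, CONTROL)
        srs = [np.mean(np.diff(p) != 0) for p in paths]
        assert np.mean(srs) == pytest.approx(0.06, abs=0.005)

    def test_stationary_occupancy_matches_fo_profile(self):
        cfg = rd.SimulationConfig(
            n_patients=300, n_controls=1, n_parcels=4, n_volumes=230, seed=4
        )
        paths = rd.generate_state_paths(cfg, PATIENT)
        fo = np.mean(
            [np.bincount(p, minlength=cfg.n_states) / p.size for p in paths], axis=0
        )
        np.testing.assert_allclose(fo, cfg.occupancies(PATIENT), atol=0.02)


class TestNodeSeries:
    def test_noise_free_single_state_is_constant(self):
        cfg = rd.SimulationConfig(
            n_patients=0, n_controls=1, n_parcels=5, n_volumes=40, n_states=1,
            patient_switch_rate=0.0, control_switch_rate=0.0,
            noise_sd=0.0, drift_sd=0.0, seed=1,
        )
        co = rd.generate_cohort(cfg)
        x = co.node_series[co.subjects(CONTROL)[0]]
        means = co.truth["state_means"][0]
        np.testing.assert_allclose(x, np.tile(means, (40, 1)), atol=1e-12)

    def test_planted_amplitude_deficit_lowers_falff(self):
        cfg = rd.SimulationConfig(
            n_patients=40, n_controls=40, n_parcels=10, n_volumes=230,
            affected_parcels={3: 0.5}, seed=21,
        )
        co = rd.generate_cohort(cfg)

        def group_falff(group):
            vals = []
            for s in co.subjects(group):
                detr = rd.detrend_linear(co.node_series[s])
                vals.append(rd.falff(detr, cfg.tr_seconds)[2])
            return np.mean(vals)

        assert group_falff(PATIENT) < group_falff(CONTROL)

    def test_band_content_present(self, small_cohort):
        x = small_cohort.node_series[small_cohort.subjects()[0]]
        filt = rd.bandpass(x, 2.0)
        assert (filt**2).sum() > 0.05 * (x**2).sum()

    def test_seeded_regeneration_is_bit_identical(self):
        cfg = rd.SimulationConfig(
            n_patients=3, n_controls=3, n_parcels=6, n_volumes=60, seed=5
        )
        a = rd.generate_cohort(cfg)
        b = rd.generate_cohort(cfg)
        for sub in a.node_series:
            assert a.node_series[sub].tobytes() == b.node_series[sub].tobytes()


class TestVolumes:
    def test_atlas_hosts_all_parcels(self):
        cfg = rd.SimulationConfig(n_patients=1, n_controls=1, seed=0)
        atlas = build_atlas(cfg)  # 90 parcels on the 15^3 default grid
        counts = np.bincount(atlas.ravel())
        assert counts[1:].size == 90
        assert counts[1:].min() >= 27

    def test_grid_too_small_names_requirement(self):
        cfg = rd.SimulationConfig(n_parcels=90, voxel_grid=(12, 12, 12))
        with pytest.raises(ValueError, match="2430"):
            build_atlas(cfg)  # 1728 voxels cannot host 90 x 27
        cfg = rd.SimulationConfig(
            n_patients=1, n_controls=1, n_parcels=10, voxel_grid=(5, 5, 5)
        )
        with pytest.raises(ValueError, match="270"):
            build_atlas(cfg)

    def test_noise_free_roundtrip_recovers_node_series(self):
        cfg = rd.SimulationConfig(
            n_patients=1, n_controls=1, n_parcels=6, n_volumes=40,
            voxel_grid=(6, 6, 6), voxel_noise_sd=0.0, affected_parcels={}, seed=8,
        )
        co = rd.generate_cohort(cfg, make_volumes=True)
        for sub in co.subjects():
            vol = co.volumes[sub]
            for p in range(1, 7):
                region = vol[co.atlas == p]  # (V_p, T)
                np.testing.assert_allclose(
                    region.mean(axis=0), co.node_series[sub][:, p - 1], atol=1e-10
                )

    def test_truth_sr_consistent_with_paths(self, small_cohort):
        for sub, path in small_cohort.truth["state_paths"].items():
            assert small_cohort.truth["sr"][sub] == pytest.approx(
                np.mean(np.diff(path) != 0)
            )


class TestConfigValidation:
    def test_bad_affected_parcel_rejected(self):
        with pytest.raises(ValueError, match="affected"):
            rd.SimulationConfig(n_parcels=10, affected_parcels={11: 0.5})

    def test_occupancies_sum_to_one(self):
        cfg = rd.SimulationConfig()
        for group in (PATIENT, CONTROL):
            assert cfg.occupancies(group).sum() == pytest.approx(1.0)
        assert cfg.occupancies(PATIENT)[0] > cfg.occupancies(CONTROL)[0]
        assert cfg.occupancies(PATIENT)[2] < cfg.occupancies(CONTROL)[2]
        assert cfg.occupancies(PATIENT)[5] < cfg.occupancies(CONTROL)[5]


def test_write_and_load_roundtrip(tmp_path):
    cfg = rd.SimulationConfig(
        n_patients=2, n_controls=2, n_parcels=5, n_volumes=30, seed=2
    )
    co = rd.generate_cohort(cfg)
    out = rd.write_cohort(co, tmp_path / "cohort")
    manifest, series = rd.synthetic.load_node_series(out)
    assert set(manifest["subject"]) == set(co.subjects())
    for sub in co.subjects():
        np.testing.assert_allclose(series[sub], co.node_series[sub], atol=1e-9)
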