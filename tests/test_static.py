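import numpy as np
import pandas as pd
import pytest

import restdyn as rd
from restdyn.static import SLOW4, SLOW5

from conftest import brute_force_kendall_w


class TestFalff:
    def test_flat_series_is_degenerate_zero(self):
        val, flag = rd.falff(np.zeros(100), 2.0, return_flags=True)
        assert val == 0.0 and flag

    def test_slow5_tone_dominates_band(self):
        t = np.arange(230) * 2.0
        x = rd.detrend_linear(np.sin(2 * np.pi * 0.02 * t)).ravel()
        assert rd.falff(x, 2.0, band=SLOW5) > 0.9

    def test_white_noise_matches_bin_fraction(self, rng):
        x = rd.detrend_linear(rng.standard_normal((230, 300)))
        vals = rd.falff(x, 2.0, band=SLOW5)
        freqs = np.fft.rfftfreq(230, 2.0)
        frac = ((freqs >= SLOW5[0]) & (freqs <= SLOW5[1])).sum() / (freqs > 0).sum()
        assert vals.mean() == pytest.approx(frac, abs=0.01)

    @pytest.mark.parametrize("spectrum", ["power", "amplitude"])
    def test_band_fractions_sum_below_one(self, rng, spectrum):
        x = rd.detrend_linear(rng.standard_normal((230, 50)))
        f1 = rd.falff(x, 2.0, band=SLOW5, spectrum=spectrum)
        f2 = rd.falff(x, 2.0, band=SLOW4, spectrum=spectrum)
        assert np.all(f1 >= 0) and np.all(f2 >= 0)
        assert np.all(f1 + f2 <= 1 + 1e-9)

    def test_empty_band_errors(self):
        with pytest.raises(ValueError, match="no frequency bin"):
            rd.falff(np.random.default_rng(0).standard_normal(10), 2.0, band=(0.011, 0.012))


class TestKendallW:
    def test_identical_series_give_one(self, rng):
        row = rng.standard_normal(30)
        assert rd.kendall_w(np.tile(row, (27, 1))) == pytest.approx(1.0)

    def test_adversarial_toy_matches_brute_force(self):
        series = np.array(
            [[4.0, 1.0, 3.0, 2.0], [1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0]]
        )
        assert rd.kendall_w(series) == pytest.approx(
            brute_force_kendall_w(series), abs=1e-12
        )

    def test_independent_series_give_small_w(self, rng):
        ws = [rd.kendall_w(rng.standard_normal((27, 230))) for _ in range(100)]
        assert np.quantile(ws, 0.99) < 0.15


class TestReho:
    def test_identical_region_center_is_one(self, rng):
        atlas = np.ones((3, 3, 3), dtype=int)
        vol = np.tile(rng.standard_normal(40), (3, 3, 3, 1))
        w = rd.reho(vol, atlas)
        assert w[1, 1, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("neighborhood", [7, 19, 27])
    def test_matches_per_voxel_brute_force(self, rng, neighborhood):
        from restdyn.static import _neighbor_kernel

        atlas = (rng.random((4, 4, 4)) > 0.2).astype(int)
        atlas[2, 2, 2] = 1
        vol = rng.standard_normal((4, 4, 4, 20))
        w = rd.reho(vol, atlas, neighborhood=neighborhood)
        offsets = np.argwhere(_neighbor_kernel(neighborhood) > 0) - 1
        for x in range(4):
            for y in range(4):
                for z in range(4):
                    if atlas[x, y, z] == 0:
                        continue
                    rows = []
                    for dx, dy, dz in offsets:
                        xx, yy, zz = x + dx, y + dy, z + dz
                        if 0 <= xx < 4 and 0 <= yy < 4 and 0 <= zz < 4 and atlas[xx, yy, zz]:
                            rows.append(vol[xx, yy, zz])
                    expected = brute_force_kendall_w(np.array(rows))
                    assert w[x, y, z] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        atlas = np.ones((3, 3, 3), dtype=int)
        vol = rng.standard_normal((3, 3, 3, 25))
        w1 = rd.reho(vol, atlas)
        w2 = rd.reho(np.exp(vol), atlas)  # strictly monotone, rank-preserving
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_too_few_time_points(self, rng):
        with pytest.raises(ValueError, match="3 time points"):
            rd.reho(rng.standard_normal((3, 3, 3, 2)), np.ones((3, 3, 3), int))


class TestDegreeCentrality:
    def test_identical_voxels_fully_connected(self, rng):
        x = np.tile(rng.standard_normal(50)[:, None], (1, 6))
        bdc, wdc = rd.degree_centrality(x)
        np.testing.assert_array_equal(bdc, 5.0)
        np.testing.assert_allclose(wdc, 5.0, atol=1e-9)

    def test_threshold_one_gives_no_edges(self, rng):
        bdc, wdc = rd.degree_centrality(rng.standard_normal((60, 5)), r_threshold=1.0)
        assert bdc.max() == 0 and wdc.max() == 0

    def test_correlated_pair_vs_independent_voxel(self, rng):
        base = rng.standard_normal(230)
        x = np.column_stack([base, base + 1e-6 * rng.standard_normal(230),
                             rng.standard_normal(230)])
        bdc, _ = rd.degree_centrality(x, r_threshold=0.25)
        assert bdc[0] >= 1 and bdc[1] >= 1
        assert bdc[2] == 0

    def test_zero_variance_voxel_flagged(self, rng):
        x = rng.standard_normal((40, 4))
        x[:, 2] = 3.0
        bdc, wdc, flags = rd.degree_centrality(x, return_flags=True)
        assert flags[2] and not flags[0]
        assert bdc[2] == 0

    def test_monotone_in_threshold(self, rng):
        x = rng.standard_normal((100, 8)) + 0.5 * rng.standard_normal((100, 1))
        prev_b, prev_w = rd.degree_centrality(x, r_threshold=0.1)
        for thr in (0.25, 0.5, 0.75):
            b, w = rd.degree_centrality(x, r_threshold=thr)
            assert np.all(b <= prev_b) and np.all(w <= prev_w + 1e-12)
            prev_b, prev_w = b, w


class TestParcelAggregate:
    def test_constant_map(self):
        atlas = np.arange(1, 9).reshape(2, 2, 2)
        out = rd.parcel_aggregate(np.full((2, 2, 2), 3.5), atlas)
        np.testing.assert_allclose(out.to_numpy(), 3.5)

    def test_one_voxel_parcels_identity(self, rng):
        atlas = np.arange(1, 9).reshape(2, 2, 2)
        vals = rng.standard_normal((2, 2, 2))
        out = rd.parcel_aggregate(vals, atlas)
        np.testing.assert_allclose(out.to_numpy(), vals.ravel())

    def test_matches_groupby_oracle(self, rng):
        atlas = rng.integers(1, 5, size=(4, 4, 4))
        vals = rng.standard_normal((4, 4, 4))
        out = rd.parcel_aggregate(vals, atlas)
        oracle = (
            pd.DataFrame({"lab": atlas.ravel(), "v": vals.ravel()})
            .groupby("lab")["v"].mean()
        )
        np.testing.assert_allclose(out.to_numpy(), oracle.to_numpy())

    def test_empty_parcel_listed(self, rng):
        atlas = np.full((2, 2, 2), 1)
        atlas[0, 0, 0] = 3  # label 2 missing
        with pytest.raises(ValueError, match=r"\[2\]"):
            rd.parcel_aggregate(rng.standard_normal((2, 2, 2)), atlas)


class TestModes:
    def test_voxel_and_node_falff_agree_on_noise_free_volumes(self):
        cfg = rd.SimulationConfig(
            n_patients=0, n_controls=1, n_parcels=5, n_volumes=120,
            voxel_grid=(6, 6, 6), voxel_noise_sd=0.0, affected_parcels={}, seed=13,
        )
        co = rd.generate_cohort(cfg, make_volumes=True)
        sub = co.subjects()[0]
        vox = rd.extract_static_voxel(co.volumes[sub], co.atlas, 2.0)
        node = rd.extract_static_node(co.node_series[sub], 2.0)
        np.testing.assert_allclose(vox["f1ALFF"], node["f1ALFF"], atol=1e-8)
        np.testing.assert_allclose(vox["f2ALFF"], node["f2ALFF"], atol=1e-8)

    def test_node_mode_refuses_reho(self, rng):
        with pytest.raises(ValueError, match="ReHo"):
            rd.extract_static_node(rng.standard_normal((120, 5)), 2.0, include_reho=True)

    def test_voxel_block_shape_and_names(self, small_cohort):
        cfg = rd.SimulationConfig(
            n_patients=1, n_controls=0, n_parcels=5, n_volumes=120,
            voxel_grid=(6, 6, 6), seed=3,
        )
        co = rd.generate_cohort(cfg, make_volumes=True)
        blk = rd.extract_static_voxel(co.volumes[co.subjects()[0]], co.atlas, 2.0)
        assert list(blk.columns) == ["f1ALFF", "f2ALFF", "ReHo", "BDC", "WDC"]
        assert list(blk.index) == [1, 2, 3, 4, 5]
        assert ((blk["ReHo"] >= 0) & (blk["ReHo"] <= 1)).all()
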