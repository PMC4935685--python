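import numpy as np
import pytest

import songculture as sc
from songculture.dtw import (
    DissimilarityMatrix,
    FeatureScaling,
    UnitContour,
    _cost_matrix,
    dtw_distance,
    frame_distance,
    pairwise_matrix,
)

SCALING = FeatureScaling(sd_ff=500.0, sd_mf=600.0, sd_fc=0.1, sd_harm=0.1, q=5.0)


def brute_force_min_mean(C: np.ndarray) -> float:
    """Exhaustive enumeration of all monotone warp paths; minimum mean cost."""
    n, m = C.shape
    best = [np.inf]

    def rec(i, j, total, length):
        total += C[i, j]
        length += 1
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], total / length)
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                rec(i + di, j + dj, total, length)

    rec(0, 0, 0.0, 0)
    return best[0]


def random_unit(rng, n_frames, uid="u", step=0.5):
    t = np.arange(n_frames) * step
    return UnitContour(
        unit_id=uid,
        t_ms=t,
        ff=rng.uniform(400, 4000, n_frames),
        mf=rng.uniform(1000, 6000, n_frames),
        fc=rng.uniform(0, 1, n_frames),
        harm=rng.uniform(0, 1, n_frames),
    )


def constant_unit(duration_ms, step_ms, uid="c"):
    n = int(round(duration_ms / step_ms))
    t = np.arange(n) * step_ms
    return UnitContour(
        unit_id=uid, t_ms=t, ff=np.full(n, 800.0), mf=np.full(n, 3000.0),
        fc=np.full(n, 0.5), harm=np.full(n, 0.9),
        duration_ms=t[-1] - t[0] + step_ms,
    )


class TestFrameDistance:
    def test_identical_frames_zero(self):
        f = np.array([800.0, 3000.0, 0.5, 0.9])
        assert frame_distance(f, 1.0, f, 1.0, SCALING, 10.0) == 0.0

    def test_time_term_unit_contribution(self):
        f = np.array([800.0, 3000.0, 0.5, 0.9])
        l_max = 10.0
        dt = l_max / SCALING.q
        assert frame_distance(f, 0.0, f, dt, SCALING, l_max) == pytest.approx(1.0)

    def test_one_sd_in_one_feature(self):
        a = np.array([800.0, 3000.0, 0.5, 0.9])
        b = a + np.array([SCALING.sd_ff, 0, 0, 0])
        assert frame_distance(a, 2.0, b, 2.0, SCALING, 10.0) == pytest.approx(1.0)

    def test_invalid_duration_rejected(self):
        f = np.array([800.0, 3000.0, 0.5, 0.9])
        with pytest.raises(ValueError):
            frame_distance(f, 0.0, f, 0.0, SCALING, 0.0)


class TestDTWDistance:
    def test_identical_units_zero(self, rng):
        u = random_unit(rng, 8)
        assert dtw_distance(u, u, SCALING) == 0.0

    def test_matches_brute_force_on_small_units(self, rng):
        for _ in range(40):
            u = random_unit(rng, rng.integers(1, 7))
            v = random_unit(rng, rng.integers(1, 7))
            expected = brute_force_min_mean(_cost_matrix(u, v, SCALING))
            assert dtw_distance(u, v, SCALING) == pytest.approx(expected, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(20):
            u = random_unit(rng, rng.integers(2, 30))
            v = random_unit(rng, rng.integers(2, 30))
            assert dtw_distance(u, v, SCALING) == pytest.approx(
                dtw_distance(v, u, SCALING), abs=1e-12
            )

    def test_length_ratio_invariance(self):
        """2 ms vs 4 ms constant units are exactly as far apart as 20 vs 40 ms."""
        d_small = dtw_distance(constant_unit(2, 0.5), constant_unit(4, 0.5), SCALING)
        d_large = dtw_distance(constant_unit(20, 5.0), constant_unit(40, 5.0), SCALING)
        assert d_small > 0
        assert d_small == pytest.approx(d_large, abs=1e-9)

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            UnitContour(unit_id="x", t_ms=np.array([]), ff=np.array([]),
                        mf=np.array([]), fc=np.array([]), harm=np.array([]))


class TestMissingValues:
    def test_unvoiced_frames_imputed(self):
        u = UnitContour(
            unit_id="v", t_ms=np.arange(4) * 0.5,
            ff=np.array([800.0, np.nan, np.nan, 1100.0]),
            mf=np.full(4, 3000.0), fc=np.full(4, 0.5), harm=np.full(4, 0.9),
        )
        np.testing.assert_allclose(u.ff, [800.0, 900.0, 1000.0, 1100.0])

    def test_entirely_unvoiced_rejected(self):
        with pytest.raises(ValueError, match="unvoiced"):
            UnitContour(
                unit_id="w", t_ms=np.arange(3) * 0.5, ff=np.full(3, np.nan),
                mf=np.full(3, 3000.0), fc=np.full(3, 0.5), harm=np.full(3, 0.9),
            )


class TestPairwiseMatrix:
    def test_identical_units_all_zero(self, rng):
        u = random_unit(rng, 6)
        units = [
            UnitContour(unit_id=f"u{i}", t_ms=u.t_ms, ff=u.ff, mf=u.mf, fc=u.fc, harm=u.harm)
            for i in range(3)
        ]
        D = pairwise_matrix(units, SCALING)
        np.testing.assert_allclose(D.values, 0.0)

    def test_matches_independent_calls(self, rng):
        units = [random_unit(rng, rng.integers(3, 10), uid=f"u{i}") for i in range(8)]
        D = pairwise_matrix(units, SCALING)
        for i in range(8):
            for j in range(i + 1, 8):
                assert D.values[i, j] == pytest.approx(
                    dtw_distance(units[i], units[j], SCALING), abs=1e-12
                )

    def test_permutation_relabels_consistently(self, rng):
        units = [random_unit(rng, 5, uid=f"u{i}") for i in range(5)]
        D = pairwise_matrix(units, SCALING)
        perm = [3, 1, 4, 0, 2]
        D2 = pairwise_matrix([units[i] for i in perm], SCALING)
        np.testing.assert_allclose(D2.values, D.values[np.ix_(perm, perm)], atol=1e-12)

    def test_roundtrip_csv_and_phylip(self, rng, tmp_path):
        units = [random_unit(rng, 4, uid=f"u{i}") for i in range(4)]
        D = pairwise_matrix(units, SCALING)
        D.to_csv(tmp_path / "d.csv")
        back = DissimilarityMatrix.from_csv(tmp_path / "d.csv")
        np.testing.assert_allclose(back.values, D.values, atol=1e-12)
        assert back.unit_ids == D.unit_ids
        D.to_phylip(tmp_path / "d.phy")
        back2 = DissimilarityMatrix.from_phylip(tmp_path / "d.phy")
        np.testing.assert_allclose(back2.values, D.values, atol=1e-9)


class TestScaling:
    def test_pooled_sds_positive_and_time_weight_default(self, small_two_class):
        _, _, units, _, _, _ = small_two_class
        scaling = FeatureScaling.from_units(units)
        assert min(scaling.sds) > 0
        assert scaling.q == 5.0

    def test_syllable_units_keep_real_time_axis(self, default_dataset):
        motifs, _, _, _, _, _ = default_dataset
        syl_units = sc.motifs_to_units(motifs, level="syllable")
        for u in syl_units:
            assert np.all(np.diff(u.t_ms) > 0)
            # duration includes internal gaps, hence >= frame span
            assert u.duration_ms >= u.t_ms[-1] - u.t_ms[0]
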