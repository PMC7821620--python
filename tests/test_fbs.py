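"""Feature-brain similarity mapping and model comparison."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from genrefmri import fbs
from genrefmri.encoding import EncodingModel
from genrefmri.maps import GenreWeightMap


class TestReferenceProfiles:
    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 7))
        g = np.repeat(np.arange(10), 12)
        refs = fbs.genre_reference_profiles(X, g, trs_per_clip=4)
        for gi in range(10):
            assert np.abs(refs.values[gi] - X[g == gi].mean(axis=0)).max() < 1e-12
        assert np.all(refs.n_clips_per_genre == 3)

    def test_constant_genre(self):
        X = np.vstack([np.full((5, 3), 2.0), np.zeros((5, 3))])
        g = np.array([0] * 5 + [1] * 5)
        refs = fbs.genre_reference_profiles(X, g, n_genres=2, trs_per_clip=5)
        assert np.all(refs.values[0] == 2.0)

    def test_missing_genre_rejected(self):
        with pytest.raises(ValueError):
            fbs.genre_reference_profiles(np.zeros((4, 2)), np.zeros(4, int),
                                         n_genres=3)


class TestVoxelTuning:
    def test_identity_basis_equals_delay_average(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(20, 5))
        model = EncodingModel(W, 1.0, 4)
        t_plain = fbs.voxel_tuning(model)
        t_id = fbs.voxel_tuning(model, basis=np.eye(4))
        expected = W.reshape(5, 4, 5).mean(axis=0).T
        assert np.allclose(t_plain.values, expected)
        assert np.allclose(t_id.values, expected)

    def test_basis_column_back_projects_to_axis(self):
        rng = np.random.default_rng(2)
        B, _ = np.linalg.qr(rng.normal(size=(8, 3)))
        w = np.zeros((3, 1))
        w[1] = 1.0
        model = EncodingModel(np.tile(w, (5, 1)), 1.0, 3)
        tuning = fbs.voxel_tuning(model, basis=B)
        assert np.allclose(tuning.values[0], B[:, 1])

    def test_roundtrip_in_span(self):
        rng = np.random.default_rng(3)
        B, _ = np.linalg.qr(rng.normal(size=(10, 4)))
        v = B @ rng.normal(size=4)
        back = B @ (B.T @ v)
        assert np.abs(back - v).max() < 1e-8


class TestFBSMap:
    def test_identical_and_flipped_rows(self):
        rng = np.random.default_rng(4)
        refs = fbs.ReferenceFeatureProfiles(rng.normal(size=(2, 30)))
        tuning = fbs.VoxelTuningProfiles(
            np.vstack([refs.values[0], -refs.values[1]])
        )
        out = fbs.fbs_map(tuning, refs)
        assert out.values[0, 0] == pytest.approx(1.0)
        assert out.values[1, 1] == pytest.approx(-1.0)

    def test_matches_corrcoef_oracle(self):
        rng = np.random.default_rng(5)
        T = fbs.VoxelTuningProfiles(rng.normal(size=(6, 40)))
        R = fbs.ReferenceFeatureProfiles(rng.normal(size=(3, 40)))
        out = fbs.fbs_map(T, R).values
        for v in range(6):
            for g in range(3):
                assert out[v, g] == pytest.approx(
                    np.corrcoef(T.values[v], R.values[g])[0, 1], abs=1e-12
                )

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        T = fbs.VoxelTuningProfiles(rng.normal(size=(4, 25)))
        R = fbs.ReferenceFeatureProfiles(rng.normal(size=(2, 25)))
        out1 = fbs.fbs_map(T, R).values
        T2 = fbs.VoxelTuningProfiles(3.0 * T.values + 7.0)
        out2 = fbs.fbs_map(T2, R).values
        assert np.abs(out1 - out2).max() < 1e-10

    def test_zero_variance_row_is_missing(self):
        T = fbs.VoxelTuningProfiles(np.zeros((2, 10)))
        R = fbs.ReferenceFeatureProfiles(np.random.default_rng(0).normal(size=(2, 10)))
        out = fbs.fbs_map(T, R).values
        assert np.all(np.isnan(out))


class TestMapCorrespondence:
    def test_identity(self):
        rng = np.random.default_rng(7)
        G = rng.normal(size=(10, 50))
        fmap = fbs.FBSMap(G.T.copy())
        r, mean = fbs.map_correspondence(fmap, GenreWeightMap(G), np.ones(50, bool))
        assert np.allclose(r, 1.0)
        assert mean == pytest.approx(np.mean(r))

    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(8)
        hits = 0
        for s in range(20):
            rr = np.random.default_rng(s)
            fmap = fbs.FBSMap(rr.normal(size=(1000, 10)))
            gmap = GenreWeightMap(rr.normal(size=(10, 1000)))
            r, _ = fbs.map_correspondence(fmap, gmap, np.ones(1000, bool))
            hits += np.abs(r).max() < 0.1
        assert hits >= 19

    def test_empty_roi_rejected(self):
        fmap = fbs.FBSMap(np.zeros((5, 10)))
        with pytest.raises(ValueError):
            fbs.map_correspondence(fmap, GenreWeightMap(np.zeros((10, 5))),
                                   np.zeros(5, bool))


def _wilcoxon_enum_oracle(d, alternative):
    """Exhaustive 2^n sign-flip enumeration of the signed-rank null."""
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws, dtype=float)
    if alternative == "greater":
        return np.mean(ws >= w_obs - 1e-12)
    if alternative == "less":
        return np.mean(ws <= w_obs + 1e-12)
    w_small = min(w_obs, ranks.sum() - w_obs)
    return min(1.0, np.mean(ws <= w_small + 1e-12)
               + np.mean(ws >= ranks.sum() - w_small - 1e-12))


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        out = fbs.model_comparison(
            {"mtf": np.ones(10), "cochlear": np.ones(10)}, reference="mtf"
        )
        assert out["cochlear"]["p"] == 1.0

    def test_uniform_shift_one_sided(self):
        a = np.linspace(0.1, 0.5, 10)
        stat, p = fbs.wilcoxon_exact(a + 0.2 - a, alternative="greater")
        assert p == pytest.approx(1.0 / 1024)

    def test_matches_enumeration_on_random_data(self):
        """Implementation agrees with the exhaustive oracle, 20 datasets."""
        rng = np.random.default_rng(9)
        for i in range(20):
            d = np.round(rng.normal(size=10), 3)
            for alt in ("two-sided", "greater", "less"):
                _, p = fbs.wilcoxon_exact(d, alternative=alt)
                assert p == pytest.approx(_wilcoxon_enum_oracle(d, alt), abs=1e-12)

    def test_antisymmetry_of_one_sided_p(self):
        rng = np.random.default_rng(10)
        d = rng.normal(size=10)
        _, pg = fbs.wilcoxon_exact(d, alternative="greater")
        _, pl = fbs.wilcoxon_exact(-d, alternative="less")
        assert pg == pytest.approx(pl, abs=1e-12)

    def test_reference_required(self):
        with pytest.raises(KeyError):
            fbs.model_comparison({"a": np.ones(10)}, reference="mtf")


class TestCollapseProfile:
    def test_constant_profile(self):
        out = fbs.collapse_profile(np.full(2000, 3.5))
        assert out.shape == (10, 10)
        assert np.allclose(out, 3.5)

    def test_indicator_of_one_cell(self):
        p = np.zeros(2000)
        si, ri = 4, 7
        for f in range(20):
            p[f * 100 + si * 10 + ri] = 1.0
        out = fbs.collapse_profile(p)
        assert out[si, ri] == 1.0
        assert out.sum() == 1.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(11)
        p = rng.normal(size=2000)
        out = fbs.collapse_profile(p)
        for si in range(10):
            for ri in range(10):
                val = np.mean([p[f * 100 + si * 10 + ri] for f in range(20)])
                assert out[si, ri] == pytest.approx(val, abs=1e-12)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            fbs.collapse_profile(np.zeros(100))
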