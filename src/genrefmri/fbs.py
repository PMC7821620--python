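"""Feature-brain similarity (FBS) mapping and acoustic-model comparison.

FBS asks how well a voxel's tuning in an acoustic feature space matches
the mean feature profile of each category: for voxel v and genre g,

    FBS(v, g) = Pearson r( tuning_v , reference_g )

where ``tuning_v`` is the voxel's delay-averaged encoding weight vector,
back-projected through the stored PCA basis to the interpretable feature
space when the model was fitted on reduced features, and ``reference_g``
is the mean feature vector over the genre's training clips.  An FBS map
(V x 10) can then be compared with the categorical genre-weight map; the
per-genre correlations between the two maps, compared across acoustic
models with an exact Wilcoxon signed-rank test over the 10 genres, rank
the models by how well they explain the categorical organization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import EncodingModel
from .maps import GenreWeightMap


@dataclass
class ReferenceFeatureProfiles:
    """Per-genre mean feature vectors over training clips (10 x D)."""

    values: np.ndarray
    feature_model_id: str = ""
    n_clips_per_genre: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite reference profiles")


def genre_reference_profiles(
    features: np.ndarray, genre_of_row: np.ndarray, n_genres: int = 10,
    trs_per_clip: int = 10, feature_model_id: str = "",
) -> ReferenceFeatureProfiles:
    """Mean feature vector over all training TR rows of each genre."""
    X = np.asarray(features, dtype=float)
    g = np.asarray(genre_of_row, dtype=int)
    if X.shape[0] != g.size:
        raise ValueError("row/label length mismatch")
    out = np.zeros((n_genres, X.shape[1]))
    counts = np.zeros(n_genres, dtype=int)
    for gi in range(n_genres):
        sel = g == gi
        if not np.any(sel):
            raise ValueError(f"no training rows for genre {gi}")
        out[gi] = X[sel].mean(axis=0)
        counts[gi] = int(sel.sum()) // trs_per_clip
    return ReferenceFeatureProfiles(out, feature_model_id, counts)


@dataclass
class VoxelTuningProfiles:
    """Delay-averaged (and, if reduced, back-projected) weights (V x D)."""

    values: np.ndarray
    feature_model_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def voxel_tuning(model: EncodingModel, basis: np.ndarray | None = None) -> VoxelTuningProfiles:
    """Average the 5 delay blocks; back-project K-dim weights to the
    D-dim interpretable space through the PCA basis when supplied."""
    avg = model.delay_blocks().mean(axis=0).T  # (V, K)
    if basis is not None:
        basis = np.asarray(basis, dtype=float)
        if basis.shape[1] != avg.shape[1]:
            raise ValueError("basis K does not match model feature count")
        avg = avg @ basis.T  # (V, D)
    return VoxelTuningProfiles(avg, model.feature_model_id)


@dataclass
class FBSMap:
    """Voxel x genre Pearson correlations; NaN where tuning is degenerate."""

    values: np.ndarray
    feature_model_id: str = ""


def _standardize_rows(X: np.ndarray):
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    ok = sd > 0
    Xs = np.zeros_like(Xc)
    Xs[ok] = Xc[ok] / sd[ok][:, None]
    return Xs, ok


def fbs_map(tuning: VoxelTuningProfiles, refs: ReferenceFeatureProfiles) -> FBSMap:
    """FBS(v, g) = Pearson r between tuning row v and reference row g."""
    T = tuning.values
    R = refs.values
    if T.shape[1] != R.shape[1]:
        raise ValueError("feature dimension mismatch")
    D = T.shape[1]
    Ts, t_ok = _standardize_rows(T)
    Rs, r_ok = _standardize_rows(R)
    vals = (Ts @ Rs.T) / D
    vals = np.clip(vals, -1.0, 1.0)
    vals[~t_ok, :] = np.nan
    vals[:, ~r_ok] = np.nan
    return FBSMap(vals, tuning.feature_model_id)


def map_correspondence(fbs: FBSMap, gmap: GenreWeightMap, roi_mask: np.ndarray):
    """Per-genre Pearson correlation, across ROI voxels, between the FBS
    column and the genre-weight row; returns (per_genre r (10,), mean)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if not np.any(roi):
        raise ValueError("empty ROI")
    F = fbs.values[roi]
    G = gmap.values[:, roi].T
    n_genres = G.shape[1]
    r = np.zeros(n_genres)
    for g in range(n_genres):
        f = F[:, g]
        ok = np.isfinite(f)
        x, y = f[ok], G[ok, g]
        if x.size < 2 or x.std() == 0 or y.std() == 0:
            r[g] = 0.0
        else:
            r[g] = np.corrcoef(x, y)[0, 1]
    return r, float(r.mean())


def wilcoxon_exact(diff: np.ndarray, alternative: str = "two-sided"):
    """Exact-distribution Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon's rule); the null distribution enumerates
    all 2^n sign assignments of the ranked absolute differences, so exact
    p-values are valid with ties among the ranks.  All-zero differences
    give p = 1 (no signed ranks).  Returns ``(W_plus, p)``.
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # enumerate all sign assignments
    signs = np.array(np.meshgrid(*([[0, 1]] * n))).T.reshape(-1, n)
    w_all = signs @ ranks
    w_minus = ranks.sum() - w_plus
    if alternative == "greater":
        p = np.mean(w_all >= w_plus - 1e-12)
    elif alternative == "less":
        p = np.mean(w_all <= w_plus + 1e-12)
    else:
        w_small = min(w_plus, w_minus)
        p = min(1.0, np.mean(w_all <= w_small + 1e-12) + np.mean(w_all >= ranks.sum() - w_small - 1e-12))
    return w_plus, float(p)


def model_comparison(
    per_genre_r: dict, reference: str = "mtf", alternative: str = "two-sided"
) -> dict:
    """Wilcoxon signed-rank comparison of per-genre map correspondences.

    ``per_genre_r`` maps model id -> (10,) per-genre correlations; each
    non-reference model is compared against ``reference`` on the 10 paired
    differences.  Returns {model: {'statistic': W+, 'p': p}}.
    """
    if reference not in per_genre_r:
        raise KeyError(f"reference model {reference!r} missing")
    if len(per_genre_r) < 2:
        raise ValueError("need at least two models")
    ref = np.asarray(per_genre_r[reference], dtype=float)
    out = {}
    for name, vals in per_genre_r.items():
        if name == reference:
            continue
        stat, p = wilcoxon_exact(ref - np.asarray(vals, dtype=float), alternative)
        out[name] = {"statistic": stat, "p": p}
    return out


def collapse_profile(profile: np.ndarray, n_freq_ranges: int = 20,
                     n_scales: int = 10, n_rates: int = 10) -> np.ndarray:
    """Average a raw MTF profile over its 20 frequency ranges, giving the
    10 x 10 (Ω x ω) modulation matrix used for visualization."""
    p = np.asarray(profile, dtype=float)
    if p.size != n_freq_ranges * n_scales * n_rates:
        raise ValueError("profile is not in the canonical (freq, Ω, ω) layout")
    return p.reshape(n_freq_ranges, n_scales, n_rates).mean(axis=0)
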