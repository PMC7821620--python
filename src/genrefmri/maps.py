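"""Genre-weight maps and their PCA embedding.

The genre-label encoding weights (5 delay blocks x 10 genres x V voxels)
are averaged over delays to a 10 x V genre-weight map per subject.  Maps
are concatenated across subjects along the voxel axis, and PCA over the
10-dimensional genre axis (voxels as observations, centered, unscaled)
yields a loading matrix placing the 10 genres in a low-dimensional
representational space and a score matrix placing every voxel in the same
space.  PC1/PC2 loadings give the 2-D genre embedding; min-max-normalized
PC1–3 loadings (genres) and per-subject scores (voxels) give RGB colors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import EncodingModel


@dataclass
class GenreWeightMap:
    """Delay-averaged genre-label weights (10 x V)."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 10:
            raise ValueError("genre-weight map must have exactly 10 rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite weights")


def average_delays(model: EncodingModel, subject_id: str = "") -> GenreWeightMap:
    """Mean over the 5 delay blocks per (genre, voxel)."""
    if model.n_features != 10:
        raise ValueError("expected a 10-feature (genre-label) model")
    return GenreWeightMap(model.delay_blocks().mean(axis=0), subject_id)


def _minmax(x: np.ndarray, axis=0) -> np.ndarray:
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (x - lo) / span


@dataclass
class GenrePCA:
    scores: np.ndarray  # (sum V_i, 10)
    loadings: np.ndarray  # (10, 10), orthonormal columns
    explained_variance: np.ndarray  # (10,), fractions
    genre_2d: np.ndarray  # (10, 2)
    genre_rgb: np.ndarray  # (10, 3) in [0, 1]
    voxel_rgb: np.ndarray  # (sum V_i, 3) in [0, 1]
    normalized_scores: np.ndarray  # per-subject min-max to [0, 1]
    subject_slices: list  # [(start, stop), ...] into the voxel axis


def pca_embed(maps: list[GenreWeightMap]) -> GenrePCA:
    """PCA of concatenated genre-weight maps over the genre axis.

    Observations are voxels (rows), variables are the 10 genres; data are
    centered across voxels but not variance-scaled (weights share units).
    Component signs are fixed by making each loading column's
    largest-magnitude entry positive.
    """
    X = np.hstack([m.values for m in maps])  # (10, sum V)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 voxels in total")
    D = X.T  # (sum V, 10), observations x variables
    Dc = D - D.mean(axis=0)
    U, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    loadings = Vt.T  # (10, 10)
    # deterministic sign: largest-|.| entry of each loading column positive
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
    scores = Dc @ loadings
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)

    slices, start = [], 0
    for m in maps:
        stop = start + m.values.shape[1]
        slices.append((start, stop))
        start = stop

    norm_scores = np.empty_like(scores)
    for a, b in slices:
        norm_scores[a:b] = _minmax(scores[a:b], axis=0)

    return GenrePCA(
        scores=scores,
        loadings=loadings,
        explained_variance=evr,
        genre_2d=loadings[:, :2],
        genre_rgb=_minmax(loadings[:, :3], axis=0),
        voxel_rgb=norm_scores[:, :3],
        normalized_scores=norm_scores,
        subject_slices=slices,
    )


def voxel_glyph(gmap: GenreWeightMap, voxel_id: int, genre_2d: np.ndarray):
    """Per-genre glyphs for one voxel: (x, y, radius, sign).

    Radius equals the absolute genre weight at the voxel; the sign carries
    the weight's polarity; positions are the 2-D genre coordinates.
    """
    if not 0 <= voxel_id < gmap.values.shape[1]:
        raise IndexError("voxel_id out of range")
    w = gmap.values[:, voxel_id]
    return genre_2d[:, 0], genre_2d[:, 1], np.abs(w), np.sign(w)
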