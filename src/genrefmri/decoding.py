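"""Genre decoding: ridge regression onto label indicators, per-TR argmax,
clip-level majority voting, confusion matrices and their comparison.

The decoder mirrors the encoding analysis: delay-embedded voxel responses
(T x 5V, restricted to the ROI) are regressed onto the one-hot genre-label
matrix with an L2 penalty — deliberately a linear regression rather than a
categorical classifier.  Each test TR gets the argmax genre of the decoded
label matrix; each clip gets the genre most frequently assigned across its
TRs (majority voting).  A feature-based variant substitutes stimulus
features for responses and shares every operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .encoding import RidgeEncoder, select_lambda, DEFAULT_LAMBDA_GRID


def delay_embed_responses(R: np.ndarray, run_boundaries=None) -> np.ndarray:
    """Concatenate 5 response copies at TR lags -1..-5 (T x 5V).

    Hemodynamics delay the measured signal relative to the stimulus, so the
    label at time t is carried by responses at t+1..t+5 TR — the mirror
    image of the feature delay embedding used for encoding.  Rows near a
    run's end, where future responses are unavailable, are zero-padded.
    """
    R = np.asarray(R, dtype=float)
    T, V = R.shape
    if run_boundaries is None:
        run_boundaries = [(0, T)]
    out = np.zeros((T, 5 * V))
    for a, b in run_boundaries:
        for k in range(1, 6):
            out[a : b - k, (k - 1) * V : k * V] = R[a + k : b]
    return out


class GenreDecoder(BaseEstimator, ClassifierMixin):
    """Ridge regression decoder over delay-embedded responses.

    ``fit(R_delayed, G)`` takes the (T x 5V) response matrix and the one-hot
    (T x n_genres) label matrix.  ``decision_function`` returns the decoded
    label matrix Ĝ; ``predict`` returns per-TR argmax genre indices (ties
    broken toward the lowest index).

    Attributes
    ----------
    W_ : (5V, n_genres) decoding weights
    """

    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def fit(self, R_delayed, G):
        R = R_delayed.values if hasattr(R_delayed, "values") else np.asarray(R_delayed)
        G = np.asarray(G, dtype=float)
        if R.shape[1] == 0:
            raise ValueError("empty ROI: no response columns to decode from")
        enc = RidgeEncoder(alpha=self.alpha).fit(R, G)
        self.W_ = enc.W_
        self.classes_ = np.arange(G.shape[1])
        self.n_features_in_ = R.shape[1]
        return self

    def decision_function(self, R_delayed):
        check_is_fitted(self, "W_")
        R = R_delayed.values if hasattr(R_delayed, "values") else np.asarray(R_delayed)
        return R @ self.W_

    def predict(self, R_delayed):
        return np.argmax(self.decision_function(R_delayed), axis=1)


def fit_decoder(
    R_D,
    G,
    grid=DEFAULT_LAMBDA_GRID,
    n_resamples: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
    chunk_size: int = 10,
) -> GenreDecoder:
    """Fit a decoder with the same resampled λ selection protocol as the
    encoding analysis (here per label column, then averaged to one λ)."""
    lam, _ = select_lambda(
        R_D, np.asarray(G, dtype=float), grid, n_resamples, train_frac, seed,
        chunk_size, per_voxel=False,
    )
    return GenreDecoder(alpha=lam).fit(R_D, G)


def decode_timepoints(model: GenreDecoder, R_D_test) -> np.ndarray:
    """Per-TR genre indices: argmax of the decoded label matrix (ties break
    toward the lowest index)."""
    return model.predict(R_D_test)


def majority_vote(tr_labels: np.ndarray, trs_per_clip: int = 10) -> np.ndarray:
    """Clip-level labels: the modal per-TR label within each clip's block
    of ``trs_per_clip`` rows; ties break toward the lowest index."""
    labels = np.asarray(tr_labels, dtype=int)
    if labels.size % trs_per_clip != 0:
        raise ValueError("label count not divisible by trs_per_clip")
    blocks = labels.reshape(-1, trs_per_clip)
    return np.array([np.argmax(np.bincount(b)) for b in blocks])


@dataclass
class ConfusionMatrix:
    """Column-percentage classification matrix.

    Rows are classified (predicted) genres, columns are correct genres;
    each column with at least one clip sums to 100.
    """

    values: np.ndarray  # (n_genres, n_genres), percentages
    n_clips: np.ndarray  # (n_genres,), clips per correct-genre column

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        sums = self.values.sum(axis=0)
        present = self.n_clips > 0
        if not np.allclose(sums[present], 100.0, atol=1e-9):
            raise ValueError("columns must sum to 100")

    @property
    def accuracy(self) -> float:
        """Overall clip accuracy (%), weighted by column clip counts."""
        correct = np.diag(self.values) / 100.0 * self.n_clips
        return float(100.0 * correct.sum() / self.n_clips.sum())


def confusion(true_labels, predicted_labels, n_genres: int = 10) -> ConfusionMatrix:
    """Column-normalized percentage confusion matrix."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size != p.size:
        raise ValueError("label vectors must have equal length")
    if np.any((t < 0) | (t >= n_genres)) or np.any((p < 0) | (p >= n_genres)):
        raise ValueError(f"labels must be in 0..{n_genres - 1}")
    counts = np.zeros((n_genres, n_genres))
    for ti, pi in zip(t, p):
        counts[pi, ti] += 1
    col = counts.sum(axis=0)
    vals = np.zeros_like(counts)
    nz = col > 0
    vals[:, nz] = 100.0 * counts[:, nz] / col[nz]
    return ConfusionMatrix(vals, col.astype(int))


def matrix_similarity(M1, M2, method: str = "spearman",
                      include_diagonal: bool = True) -> float:
    """Rank (or linear) correlation over the vectorized confusion cells."""
    A = M1.values if isinstance(M1, ConfusionMatrix) else np.asarray(M1, dtype=float)
    B = M2.values if isinstance(M2, ConfusionMatrix) else np.asarray(M2, dtype=float)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    if include_diagonal:
        a, b = A.ravel(), B.ravel()
    else:
        off = ~np.eye(A.shape[0], dtype=bool)
        a, b = A[off], B[off]
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")
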