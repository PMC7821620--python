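"""Voxel-wise encoding: preprocessing, delay embedding, ridge fitting,
resampled regularization selection, accuracy maps with FDR, ROI masks.

Each voxel's response is modeled as a linear function of stimulus features
carrying five hemodynamic delays (1.5–7.5 s, i.e. TR lags 1–5):
``R ≈ F_delayed @ W`` with an L2 (ridge) penalty.  Prediction accuracy is
the Pearson correlation between predicted and measured test responses,
with one-sided p-values from the t-transform of r and Benjamini–Hochberg
FDR control across voxels.  A genre-representing ROI is obtained by
repeating fit/evaluate over random 80/20 resamples of the training data
and keeping voxels significant in more than 80% of resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

DELAYS_S = (1.5, 3.0, 4.5, 6.0, 7.5)
N_DELAYS = len(DELAYS_S)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 6, 9))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _truncated_running_median(x: np.ndarray, w: int) -> np.ndarray:
    """Running median with window ``w`` truncated at the edges (the window
    shrinks near the boundaries instead of padding)."""
    T = x.shape[0]
    if w >= T:
        return np.broadcast_to(np.median(x, axis=0), x.shape).copy()
    half = w // 2
    med = np.empty_like(x)
    interior = np.lib.stride_tricks.sliding_window_view(x, w, axis=0)
    med[half : half + interior.shape[0]] = np.median(interior, axis=-1)
    for t in range(half):
        med[t] = np.median(x[: t + half + 1], axis=0)
    for t in range(half + interior.shape[0], T):
        med[t] = np.median(x[t - half :], axis=0)
    return med


def preprocess_bold(
    R: np.ndarray,
    tr: float = 1.5,
    window: float = 240.0,
    run_boundaries=None,
):
    """Detrend (truncated-window running median) and z-score, per run and
    per voxel.  Zero-variance voxels are left all-zero and flagged.

    Returns ``(R_clean, flagged)`` where ``flagged`` is a boolean (V,) mask
    of voxels with zero variance in at least one run.
    """
    R = np.asarray(R, dtype=float)
    if run_boundaries is None:
        run_boundaries = [(0, R.shape[0])]
    w = int(round(window / tr))
    out = np.empty_like(R)
    flagged = np.zeros(R.shape[1], dtype=bool)
    for a, b in run_boundaries:
        block = R[a:b]
        detrended = block - _truncated_running_median(block, w)
        mu = detrended.mean(axis=0)
        sd = detrended.std(axis=0)
        zero = sd == 0
        sd_safe = np.where(zero, 1.0, sd)
        z = (detrended - mu) / sd_safe
        z[:, zero] = 0.0
        flagged |= zero
        out[a:b] = z
    return out, flagged


# ---------------------------------------------------------------------------
# delay embedding
# ---------------------------------------------------------------------------


@dataclass
class DelayedFeatureMatrix:
    """Feature matrix with 5 concatenated TR-lag blocks (T x 5N)."""

    values: np.ndarray
    n_features: int
    run_boundaries: list
    delays: tuple = DELAYS_S

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != N_DELAYS * self.n_features:
            raise ValueError("column count must equal 5N")

    @property
    def shape(self):
        return self.values.shape

    def block(self, lag: int) -> np.ndarray:
        """Columns of TR-lag ``lag`` (1-based)."""
        k = lag - 1
        return self.values[:, k * self.n_features : (k + 1) * self.n_features]


def delay_embed(F: np.ndarray, run_boundaries=None) -> DelayedFeatureMatrix:
    """Concatenate 5 delayed copies of F (TR lags 1..5), zero-padded at run
    starts; no block crosses a run boundary."""
    F = np.asarray(F, dtype=float)
    T, N = F.shape
    if run_boundaries is None:
        run_boundaries = [(0, T)]
    for a, b in run_boundaries:
        if b - a < N_DELAYS:
            raise ValueError("run shorter than the maximum lag")
    out = np.zeros((T, N_DELAYS * N))
    for a, b in run_boundaries:
        for k in range(1, N_DELAYS + 1):
            out[a + k : b, (k - 1) * N : k * N] = F[a : b - k]
    return DelayedFeatureMatrix(out, N, list(run_boundaries))


# ---------------------------------------------------------------------------
# ridge fitting
# ---------------------------------------------------------------------------


class RidgeEncoder(BaseEstimator, RegressorMixin):
    """Multi-output ridge regression via SVD, with scalar or per-target λ.

    Solves ``W = (FᵀF + λI)⁻¹ FᵀR`` with no intercept and no column left
    unpenalized (features and responses are centered/standardized by the
    preprocessing).  ``alpha`` may be a positive scalar or an array with one
    value per response column (per-voxel regularization).

    Attributes
    ----------
    W_ : (n_features, n_targets) weight matrix
    coef_ : (n_targets, n_features), sklearn orientation
    """

    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def fit(self, F, R):
        F = np.asarray(F, dtype=float)
        R = np.asarray(R, dtype=float)
        if R.ndim == 1:
            R = R[:, None]
        if not (np.all(np.isfinite(F)) and np.all(np.isfinite(R))):
            raise ValueError("non-finite inputs")
        alpha = np.asarray(self.alpha, dtype=float)
        if np.any(alpha < 0):
            raise ValueError("alpha must be >= 0")
        U, s, Vt = np.linalg.svd(F, full_matrices=False)
        tol = s.max() * max(F.shape) * np.finfo(float).eps if s.size else 0.0
        if np.any(alpha == 0.0) and (np.sum(s > tol) < F.shape[1]):
            raise np.linalg.LinAlgError("singular system at lambda=0")
        UtR = U.T @ R
        if alpha.ndim == 0:
            d = s / (s**2 + alpha)
            self.W_ = Vt.T @ (d[:, None] * UtR)
        else:
            if alpha.size != R.shape[1]:
                raise ValueError("per-target alpha length mismatch")
            d = s[:, None] / (s[:, None] ** 2 + alpha[None, :])
            self.W_ = Vt.T @ (d * UtR)
        self.coef_ = self.W_.T
        self.n_features_in_ = F.shape[1]
        return self

    def predict(self, F):
        check_is_fitted(self, "W_")
        return np.asarray(F, dtype=float) @ self.W_


@dataclass
class EncodingModel:
    """Fitted voxel-wise encoding model."""

    W: np.ndarray  # (5N x V)
    lam: np.ndarray | float
    n_features: int  # N (per delay block)
    feature_model_id: str = ""
    n_nuisance: int = 0  # trailing nuisance features per block, if any
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite weights")

    @property
    def n_voxels(self) -> int:
        return self.W.shape[1]

    def delay_blocks(self) -> np.ndarray:
        """Weights reshaped to (5, N, V)."""
        return self.W.reshape(N_DELAYS, self.n_features, self.n_voxels)

    def predict(self, F_delayed) -> np.ndarray:
        F = F_delayed.values if hasattr(F_delayed, "values") else np.asarray(F_delayed)
        return F @ self.W


def fit_ridge(F_E, R, lam, feature_model_id: str = "") -> EncodingModel:
    """L2-regularized linear regression of responses on delayed features."""
    F = F_E.values if hasattr(F_E, "values") else np.asarray(F_E)
    n_features = F_E.n_features if hasattr(F_E, "n_features") else F.shape[1] // N_DELAYS
    enc = RidgeEncoder(alpha=lam).fit(F, R)
    return EncodingModel(enc.W_, lam, n_features, feature_model_id)


def _resample_split(T: int, train_frac: float, chunk_size: int, rng):
    """Random 80/20 split over contiguous chunks of ``chunk_size`` rows."""
    n_chunks = int(np.ceil(T / chunk_size))
    order = rng.permutation(n_chunks)
    n_train = int(round(train_frac * n_chunks))
    train_rows, val_rows = [], []
    for j, c in enumerate(order):
        rows = np.arange(c * chunk_size, min((c + 1) * chunk_size, T))
        (train_rows if j < n_train else val_rows).append(rows)
    return np.concatenate(train_rows), np.concatenate(val_rows)


def pearson_by_column(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (T x V) arrays; 0 where undefined."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    na = np.sqrt((A**2).sum(axis=0))
    nb = np.sqrt((B**2).sum(axis=0))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=0) / denom
    r = np.where(denom > 0, r, 0.0)
    return np.clip(r, -1.0, 1.0)


def select_lambda(
    F_E,
    R,
    grid=DEFAULT_LAMBDA_GRID,
    n_resamples: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
    chunk_size: int = 10,
    per_voxel: bool = True,
):
    """Resampled regularization selection.

    For each candidate λ and each of ``n_resamples`` random 80/20 splits
    (contiguous chunks, to respect temporal autocorrelation) the model is
    fitted on the 80% and validated by Pearson r on the 20%.  Per voxel the
    λ maximizing mean validation r is chosen (ties: smallest λ); with
    ``per_voxel=False`` a single λ maximizing the grand mean is returned.

    Returns ``(lam, mean_r)`` where ``mean_r`` is (len(grid), V).
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    F = F_E.values if hasattr(F_E, "values") else np.asarray(F_E)
    R = np.asarray(R, dtype=float)
    rng = np.random.default_rng(seed)
    T, V = R.shape
    mean_r = np.zeros((grid.size, V))
    for _ in range(n_resamples):
        tr_rows, val_rows = _resample_split(T, train_frac, chunk_size, rng)
        Ftr, Fval = F[tr_rows], F[val_rows]
        Rtr, Rval = R[tr_rows], R[val_rows]
        U, s, Vt = np.linalg.svd(Ftr, full_matrices=False)
        UtR = U.T @ Rtr
        for gi, lam in enumerate(grid):
            d = s / (s**2 + lam)
            W = Vt.T @ (d[:, None] * UtR)
            mean_r[gi] += pearson_by_column(Fval @ W, Rval)
    mean_r /= n_resamples
    if per_voxel:
        lam = grid[np.argmax(mean_r, axis=0)]
    else:
        lam = float(grid[np.argmax(mean_r.mean(axis=1))])
    return lam, mean_r


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class AccuracyMap:
    r: np.ndarray  # (V,)
    p: np.ndarray  # (V,)
    q_significant: np.ndarray  # (V,), bool
    fdr_q: float = 0.05


def accuracy_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """One-sided p-values from the t-transform of Pearson r, df = n - 2."""
    df = n - 2
    if df <= 0:
        return np.ones_like(r)
    rr = np.clip(r, -0.9999999, 0.9999999)
    t = rr * np.sqrt(df / (1.0 - rr**2))
    return stats.t.sf(t, df)


def evaluate(model: EncodingModel, F_E_test, R_test_avg, fdr_q: float = 0.05) -> AccuracyMap:
    """Pearson prediction accuracy per voxel with BH-FDR significance."""
    pred = model.predict(F_E_test)
    R = np.asarray(R_test_avg, dtype=float)
    r = pearson_by_column(pred, R)
    # voxels with zero-variance prediction or measurement: r=0, p=1
    undef = (pred.std(axis=0) == 0) | (R.std(axis=0) == 0)
    p = accuracy_pvalues(r, R.shape[0])
    p[undef] = 1.0
    sig = multipletests(p, alpha=fdr_q, method="fdr_bh")[0]
    return AccuracyMap(r, p, sig, fdr_q)


@dataclass
class ROIMask:
    mask: np.ndarray  # (V,), bool
    selection_frequency: np.ndarray  # (V,), in [0, 1]
    n_resamples: int = 50
    frequency_threshold: float = 0.8


def roi_from_resampling(
    F_E,
    R,
    lam,
    n_resamples: int = 50,
    train_frac: float = 0.8,
    freq_threshold: float = 0.8,
    fdr_q: float = 0.05,
    seed: int = 0,
    chunk_size: int = 10,
) -> ROIMask:
    """Genre-representing ROI: voxels significant (BH-FDR on the 20%
    validation split) in more than ``freq_threshold`` of resampled fits."""
    F = F_E.values if hasattr(F_E, "values") else np.asarray(F_E)
    n_feat = F_E.n_features if hasattr(F_E, "n_features") else F.shape[1] // N_DELAYS
    R = np.asarray(R, dtype=float)
    rng = np.random.default_rng(seed)
    T, V = R.shape
    counts = np.zeros(V)
    for _ in range(n_resamples):
        tr_rows, val_rows = _resample_split(T, train_frac, chunk_size, rng)
        model = EncodingModel(
            RidgeEncoder(alpha=lam).fit(F[tr_rows], R[tr_rows]).W_, lam, n_feat
        )
        amap = evaluate(model, F[val_rows], R[val_rows], fdr_q)
        counts += amap.q_significant
    freq = counts / n_resamples
    return ROIMask(freq > freq_threshold, freq, n_resamples, freq_threshold)


# ---------------------------------------------------------------------------
# voice-nuisance variant
# ---------------------------------------------------------------------------


def concat_delayed(F_main: DelayedFeatureMatrix, F_nuis: DelayedFeatureMatrix) -> np.ndarray:
    """Column-concatenate two delay-embedded matrices (main first)."""
    if F_main.shape[0] != F_nuis.shape[0]:
        raise ValueError("row mismatch between main and nuisance features")
    return np.hstack([F_main.values, F_nuis.values])


def fit_with_nuisance(F_main, F_nuisance, R, lam) -> EncodingModel:
    """Fit on [F_main | F_nuisance] (each delay-embedded); the model records
    the block split so the nuisance can be excluded at test."""
    Fcat = concat_delayed(F_main, F_nuisance)
    enc = RidgeEncoder(alpha=lam).fit(Fcat, R)
    model = EncodingModel(
        enc.W_,
        lam,
        F_main.n_features + F_nuisance.n_features,
        n_nuisance=F_nuisance.n_features,
    )
    model.preprocessing["n_main_cols"] = F_main.values.shape[1]
    return model


def predict_excluding_nuisance(model: EncodingModel, F_main_test) -> np.ndarray:
    """Predict with the main feature block only, dropping nuisance columns
    and their weights."""
    F = F_main_test.values if hasattr(F_main_test, "values") else np.asarray(F_main_test)
    n_main = model.preprocessing.get("n_main_cols")
    if n_main is None:
        raise ValueError("model was not fitted with a nuisance block")
    if F.shape[1] != n_main:
        raise ValueError("main feature column mismatch")
    return F @ model.W[:n_main]
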