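"""Acoustic feature models at TR resolution.

Five feature spaces are extracted from mono waveforms:

* ``cochlear`` — energies of a bank of 128 overlapping band-pass filters
  (gammatone-shaped magnitude responses) spanning 100–8,000 Hz, computed
  from 25-ms analysis windows with a 10-ms hop and averaged within each TR.
* ``mtf`` — spectro-temporal modulation energies: the cochleogram is
  convolved with quadrature pairs of 2-D Gabor filters tuned to 10 spectral
  modulation scales Ω (cyc/oct) and 10 temporal modulation rates ω (Hz),
  separately for upward and downward sweeps; local energies are
  log-compressed, averaged within TRs and within 20 non-overlapping
  log-spaced frequency ranges, and the two sweep directions are averaged,
  yielding 20 × 10 × 10 = 2000 features ordered (frequency, Ω, ω).
* ``mfcc`` — 12 mel-frequency cepstral coefficients on a 100–8,000 Hz mel
  filterbank, TR-averaged.
* ``mirt`` — 24 classic music-information-retrieval descriptors (loudness,
  timbre, rhythm, tonality), TR-averaged.

The spectral-modulation axis Ω is measured in cycles per octave, which is
only an exact notion on a log-frequency channel grid; channel spacing
therefore defaults to logarithmic (an ERB-spaced option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

# Canonical modulation filter tunings (Hz and cyc/oct).
RATES = (2.8, 4.0, 5.7, 8.0, 11.3, 16.0, 22.6, 32.0, 45.3, 64.0)
SCALES = (0.35, 0.50, 0.71, 1.0, 1.41, 2.0, 2.83, 4.0, 5.66, 8.0)

N_COCHLEAR_CHANNELS = 128
N_FREQ_RANGES = 20
FMIN = 100.0
FMAX = 8000.0
WINDOW_S = 0.025
HOP_S = 0.010
MTF_RAW_DIM = N_FREQ_RANGES * len(SCALES) * len(RATES)


def cochlear_center_freqs(
    n_channels: int = N_COCHLEAR_CHANNELS,
    fmin: float = FMIN,
    fmax: float = FMAX,
    spacing: str = "log",
) -> np.ndarray:
    """Center frequencies of the cochlear filterbank.

    ``spacing='log'`` gives geometric spacing (constant cyc/oct grid);
    ``spacing='erb'`` gives an ERB-rate spaced grid.
    """
    if spacing == "log":
        return np.geomspace(fmin, fmax, n_channels)
    if spacing == "erb":
        # Glasberg & Moore ERB-rate scale.
        def hz_to_erb(f):
            return 21.4 * np.log10(1.0 + 4.37e-3 * f)

        def erb_to_hz(e):
            return (10.0 ** (e / 21.4) - 1.0) / 4.37e-3

        return erb_to_hz(np.linspace(hz_to_erb(fmin), hz_to_erb(fmax), n_channels))
    raise ValueError(f"unknown spacing {spacing!r}")


@dataclass
class Cochleogram:
    """Time-frequency energy representation (frames x channels)."""

    energies: np.ndarray  # (n_frames, n_channels), nonnegative
    frame_hop: float  # seconds
    window: float  # seconds
    center_freqs: np.ndarray  # (n_channels,), strictly increasing

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.energies.ndim != 2:
            raise ValueError("energies must be 2-D (frames x channels)")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center_freqs must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.energies.shape[0]

    @property
    def n_channels(self) -> int:
        return self.energies.shape[1]


@dataclass
class FeatureMatrix:
    """Per-TR features for one feature model."""

    values: np.ndarray  # (T_TR, N)
    model: str
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class MTFRawFeatures:
    """Raw modulation-energy features, (T_TR x 2000), ordered (freq, Ω, ω)."""

    values: np.ndarray
    scales: tuple = SCALES
    rates: tuple = RATES
    n_freq_ranges: int = N_FREQ_RANGES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_freq_ranges * len(self.scales) * len(self.rates)
        if self.values.shape[1] != expected:
            raise ValueError(
                f"expected {expected} columns, got {self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite MTF features")


def _power_spectrogram(samples: np.ndarray, sample_rate: float):
    """Framed power spectrum: Hann window 25 ms, hop 10 ms.

    Frame k covers samples [k*hop, k*hop + nwin); the signal is zero-padded
    at the end so that n_frames = floor(n_samples / hop).
    """
    x = np.asarray(samples, dtype=float)
    nwin = int(round(WINDOW_S * sample_rate))
    hop = int(round(HOP_S * sample_rate))
    if x.size < nwin:
        raise ValueError("clip shorter than one analysis window")
    n_frames = x.size // hop
    pad = (n_frames - 1) * hop + nwin - x.size
    if pad > 0:
        x = np.concatenate([x, np.zeros(pad)])
    frames = np.lib.stride_tricks.sliding_window_view(x, nwin)[::hop][:n_frames]
    win = np.hanning(nwin)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nwin, 1.0 / sample_rate)
    return spec, freqs


def _gammatone_weights(freqs: np.ndarray, center_freqs: np.ndarray) -> np.ndarray:
    """(n_channels x n_bins) power-response weights of 4th-order gammatone
    magnitude shapes; each row normalized to unit sum."""
    erb = 24.7 * (4.37e-3 * center_freqs + 1.0)
    b = 1.019 * erb
    d = (freqs[None, :] - center_freqs[:, None]) / b[:, None]
    w = (1.0 + d**2) ** -4
    return w / w.sum(axis=1, keepdims=True)


def cochleogram(
    clip,
    n_channels: int = N_COCHLEAR_CHANNELS,
    fmin: float = FMIN,
    fmax: float = FMAX,
    spacing: str = "log",
) -> Cochleogram:
    """Cochlear filterbank energies per 10-ms frame.

    ``clip`` is any object with ``samples`` and ``sample_rate`` attributes,
    or a ``(samples, sample_rate)`` tuple.
    """
    if hasattr(clip, "samples"):
        samples, sr = clip.samples, clip.sample_rate
    else:
        samples, sr = clip
    if sr < 16000:
        raise ValueError("sample_rate must be >= 16 kHz")
    spec, freqs = _power_spectrogram(samples, sr)
    cfs = cochlear_center_freqs(n_channels, fmin, fmax, spacing)
    weights = _gammatone_weights(freqs, cfs)
    energies = spec @ weights.T
    return Cochleogram(energies, HOP_S, WINDOW_S, cfs)


def _frames_per_tr(coch: Cochleogram, tr: float) -> int:
    fpt = tr / coch.frame_hop
    if abs(fpt - round(fpt)) > 1e-6:
        raise ValueError("TR is not an integer multiple of the frame hop")
    return int(round(fpt))


def _tr_average(frame_values: np.ndarray, fpt: int) -> np.ndarray:
    """Average frame-indexed rows within consecutive TR blocks."""
    n_tr = frame_values.shape[0] // fpt
    if n_tr == 0:
        raise ValueError("clip shorter than one TR")
    v = frame_values[: n_tr * fpt]
    return v.reshape(n_tr, fpt, -1).mean(axis=1)


def cochlear_features(coch: Cochleogram, tr: float = 1.5) -> FeatureMatrix:
    """TR-averaged cochlear filterbank output (T_TR x 128)."""
    fpt = _frames_per_tr(coch, tr)
    values = _tr_average(coch.energies, fpt)
    names = [f"coch_{f:.0f}Hz" for f in coch.center_freqs]
    return FeatureMatrix(values, "cochlear", names)


# ---------------------------------------------------------------------------
# MTF filterbank
# ---------------------------------------------------------------------------

_MAX_IR_SECONDS = 1.0  # cap on temporal impulse-response length
_TRUNC_SIGMA = 2.5


def mtf_filter(
    scale: float,
    rate: float,
    direction: int,
    dx_oct: float,
    dt_s: float,
    max_channels: int,
) -> np.ndarray:
    """Complex 2-D Gabor kernel for one (Ω, ω, sweep direction).

    Rows index log-frequency (spacing ``dx_oct`` octaves), columns index
    time (spacing ``dt_s`` seconds).  Real and imaginary parts form the
    quadrature pair; the kernel is L2-normalized.  ``direction=+1`` is a
    downward sweep, ``-1`` upward.
    """
    sig_x = 2.0 / scale  # octaves (constant-Q; resolves the half-octave scale grid)
    sig_t = 0.5 / rate  # seconds (constant-Q)
    hx = int(np.ceil(_TRUNC_SIGMA * sig_x / dx_oct))
    hx = min(hx, max_channels // 2)
    ht = int(np.ceil(_TRUNC_SIGMA * sig_t / dt_s))
    ht = min(ht, int(round(0.5 * _MAX_IR_SECONDS / dt_s)))
    x = np.arange(-hx, hx + 1) * dx_oct
    t = np.arange(-ht, ht + 1) * dt_s
    env = np.exp(-0.5 * (x[:, None] / sig_x) ** 2 - 0.5 * (t[None, :] / sig_t) ** 2)
    phase = 2.0 * np.pi * (scale * x[:, None] + direction * rate * t[None, :])
    h = env * np.exp(1j * phase)
    return h / np.sqrt(np.sum(np.abs(h) ** 2))


def _gabor_factors(scale, rate, dx_oct, dt_s, max_channels):
    """1-D factors (gx, gt) of the downward-sweep kernel: the 2-D Gabor is
    rank-1, ``h = outer(gx, gt) / (||gx|| ||gt||)``; the upward sweep uses
    ``conj(gt)``."""
    sig_x = 2.0 / scale
    sig_t = 0.5 / rate
    hx = min(int(np.ceil(_TRUNC_SIGMA * sig_x / dx_oct)), max_channels // 2)
    ht = min(int(np.ceil(_TRUNC_SIGMA * sig_t / dt_s)),
             int(round(0.5 * _MAX_IR_SECONDS / dt_s)))
    x = np.arange(-hx, hx + 1) * dx_oct
    t = np.arange(-ht, ht + 1) * dt_s
    gx = np.exp(-0.5 * (x / sig_x) ** 2) * np.exp(2j * np.pi * scale * x)
    gt = np.exp(-0.5 * (t / sig_t) ** 2) * np.exp(2j * np.pi * rate * t)
    return gx / np.linalg.norm(gx), gt / np.linalg.norm(gt)


def _freq_range_groups(center_freqs: np.ndarray, n_ranges: int = N_FREQ_RANGES):
    """Assign channels to non-overlapping log-spaced frequency ranges."""
    edges = np.geomspace(center_freqs[0], center_freqs[-1], n_ranges + 1)
    idx = np.clip(np.searchsorted(edges, center_freqs, side="right") - 1, 0, n_ranges - 1)
    return [np.where(idx == g)[0] for g in range(n_ranges)]


def mtf_energy(
    coch: Cochleogram,
    tr: float = 1.5,
    scales: tuple = SCALES,
    rates: tuple = RATES,
    n_freq_ranges: int = N_FREQ_RANGES,
    log_floor_rel: float = 1e-8,
) -> MTFRawFeatures:
    """Spectro-temporal modulation-energy features.

    For each (Ω, ω, sweep direction) the log-frequency x time cochleogram is
    convolved ('same', zero-padded) with a quadrature Gabor pair; the local
    modulation energy (sum of squared quadrature outputs) is log-compressed
    with a floor of ``log_floor_rel`` times the per-clip maximum energy,
    averaged within TRs and within ``n_freq_ranges`` log-spaced frequency
    ranges, and finally averaged over the two sweep directions.
    """
    S = coch.energies.T  # (channels, frames)
    n_ch, n_fr = S.shape
    fpt = _frames_per_tr(coch, tr)
    n_tr = n_fr // fpt
    if n_tr == 0:
        raise ValueError("cochleogram shorter than one TR")
    dx = np.log2(coch.center_freqs[-1] / coch.center_freqs[0]) / (n_ch - 1)
    factors = [
        [_gabor_factors(sc, ra, dx, coch.frame_hop, n_ch) for ra in rates]
        for sc in scales
    ]

    max_kx = max(factors[si][0][0].size for si in range(len(scales)))
    max_kt = max(factors[si][ri][1].size
                 for si in range(len(scales)) for ri in range(len(rates)))
    Px = sfft.next_fast_len(n_ch + max_kx - 1)
    Pt = sfft.next_fast_len(n_fr + max_kt - 1)

    # The 2-D Gabor kernels are rank-1 separable, so the 'same' 2-D
    # convolution is one frequency-axis convolution per scale (shared by
    # all rates) followed by time-axis convolutions per (rate, direction).
    FS0 = sfft.fft(S, n=Px, axis=0)
    groups = _freq_range_groups(coch.center_freqs, n_freq_ranges)
    n_s, n_r = len(scales), len(rates)

    energies = np.empty((n_s, n_r, 2, n_ch, n_fr))
    for si in range(n_s):
        gx = factors[si][0][0]
        A = sfft.ifft(FS0 * sfft.fft(gx, n=Px)[:, None], axis=0)
        A = A[gx.size // 2 : gx.size // 2 + n_ch]
        FA = sfft.fft(A, n=Pt, axis=1)
        for ri in range(n_r):
            gt = factors[si][ri][1]
            GT = sfft.fft(gt, n=Pt)
            ot = gt.size // 2
            z_down = sfft.ifft(FA * GT[None, :], axis=1)[:, ot : ot + n_fr]
            # upward sweep kernel is conj(gt)
            GTu = sfft.fft(np.conj(gt), n=Pt)
            z_up = sfft.ifft(FA * GTu[None, :], axis=1)[:, ot : ot + n_fr]
            energies[si, ri, 0] = np.abs(z_down) ** 2
            energies[si, ri, 1] = np.abs(z_up) ** 2

    global_max = energies.max()
    eps = log_floor_rel * global_max if global_max > 0 else log_floor_rel
    le = np.log(np.maximum(energies, eps))
    # TR average over frames, then frequency-range average over channels.
    le_tr = le[..., : n_tr * fpt].reshape(n_s, n_r, 2, n_ch, n_tr, fpt).mean(axis=-1)
    acc = np.stack([le_tr[:, :, :, members].mean(axis=3) for members in groups])
    collapsed = acc.mean(axis=3)  # (n_freq_ranges, n_s, n_r, n_tr) over directions
    values = collapsed.transpose(3, 0, 1, 2).reshape(n_tr, -1)
    return MTFRawFeatures(values, tuple(scales), tuple(rates), n_freq_ranges)


def modulation_peak(mtf: MTFRawFeatures):
    """Dominant (scale_idx, rate_idx) of time-averaged MTF features.

    The collapsed (Ω x ω) matrix (mean over TRs and frequency ranges) is
    reduced by max-marginals: the best rate is the one whose best scale
    cell is largest, and symmetrically for the scale — robust to the
    broadband background gradient along the Ω axis.
    """
    n_s, n_r = len(mtf.scales), len(mtf.rates)
    coll = mtf.values.mean(axis=0).reshape(mtf.n_freq_ranges, n_s, n_r).mean(axis=0)
    return int(np.argmax(coll.max(axis=1))), int(np.argmax(coll.max(axis=0)))


class MTFReducer(BaseEstimator, TransformerMixin):
    """PCA reduction of raw MTF features retaining a variance fraction.

    Fit on training stimuli only; the stored basis and column means are
    frozen for projecting test stimuli and for back-projecting voxel
    weights to the interpretable 2000-dimensional space.

    Attributes
    ----------
    basis_ : (D, K) orthonormal columns
    mean_ : (D,) training column means
    n_components_ : K, the smallest count reaching ``variance_threshold``
    explained_variance_fraction_ : variance fraction retained by K components
    """

    def __init__(self, variance_threshold: float = 0.99):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.allclose(X.var(axis=0).sum(), 0.0):
            raise ValueError("degenerate input: zero total variance")
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_threshold - 1e-12) + 1)
        k = min(k, len(cum))
        self.basis_ = pca.components_[:k].T  # (D, K)
        self.mean_ = pca.mean_
        self.n_components_ = k
        self.explained_variance_fraction_ = float(cum[k - 1])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.basis_

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        return Z @ self.basis_.T + self.mean_


def mtf_reduce(training_values: np.ndarray, variance_threshold: float = 0.99):
    """Fit an :class:`MTFReducer` on training rows; return (reducer, reduced)."""
    reducer = MTFReducer(variance_threshold).fit(training_values)
    return reducer, reducer.transform(training_values)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------


def _mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def _mel_filterbank(freqs, n_mels, fmin, fmax):
    pts = _mel_inv(np.linspace(_mel(fmin), _mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, c, hi = pts[i], pts[i + 1], pts[i + 2]
        up = (freqs - lo) / (c - lo)
        down = (hi - freqs) / (hi - c)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


@dataclass
class DescriptorFeatures:
    """Named scalar descriptors per TR (MIRT: 24 columns, MFCC: 12)."""

    values: np.ndarray
    names: list
    model: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.names):
            raise ValueError("column/name count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite descriptor values")


def mfcc_features(
    clip, tr: float = 1.5, n_mfcc: int = 12, n_mels: int = 40,
    fmin: float = FMIN, fmax: float = FMAX,
) -> DescriptorFeatures:
    """TR-averaged MFCCs (coefficients 1..n_mfcc, 0th energy term dropped)."""
    spec, freqs = _power_spectrogram(clip.samples, clip.sample_rate)
    fb = _mel_filterbank(freqs, n_mels, fmin, fmax)
    mel_e = spec @ fb.T
    log_mel = np.log(np.maximum(mel_e, 1e-12 * max(mel_e.max(), 1e-300)))
    cep = sfft.dct(log_mel, type=2, axis=1, norm="ortho")[:, 1 : n_mfcc + 1]
    fpt = int(round(tr / HOP_S))
    values = _tr_average(cep, fpt)
    return DescriptorFeatures(values, [f"mfcc_{i+1}" for i in range(n_mfcc)], "mfcc")


# ---------------------------------------------------------------------------
# MIRT-style music descriptors
# ---------------------------------------------------------------------------

MIRT_NAMES = (
    ["rms", "zcr", "high_low_ratio", "centroid", "rolloff", "entropy",
     "flatness", "roughness", "spread", "flux"]
    + [f"subband_flux_{i+1}" for i in range(9)]
    + ["pulse_clarity", "fluctuation_centroid", "fluctuation_entropy",
       "mode", "key_clarity"]
)

# Krumhansl-Schmuckler key profiles (major, minor).
_KS_MAJOR = np.array([6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39,
                      3.66, 2.29, 2.88])
_KS_MINOR = np.array([6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98,
                      2.69, 3.34, 3.17])


def _frame_times(n_frames, hop_s, win_s):
    return np.arange(n_frames) * hop_s + 0.5 * win_s


def _assign_tr(values, times, tr, n_tr):
    """Average frame values into TR bins by frame-center time; empty bins
    take the nearest frame's value."""
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    out = np.zeros((n_tr, values.shape[1]))
    bins = np.clip((times / tr).astype(int), 0, n_tr - 1)
    for t in range(n_tr):
        sel = bins == t
        if np.any(sel):
            out[t] = values[sel].mean(axis=0)
        else:
            j = np.argmin(np.abs(times - (t + 0.5) * tr))
            out[t] = values[j]
    return out


def _spectral_descriptors(mag, freqs, prev_mag):
    """Per-frame timbral descriptors from a magnitude spectrum."""
    power = mag**2
    tot = power.sum(axis=1)
    safe = np.maximum(tot, 1e-300)
    p = power / safe[:, None]
    centroid = p @ freqs
    spread = np.sqrt(np.maximum((p * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1), 0.0))
    cum = np.cumsum(power, axis=1)
    roll_idx = np.argmax(cum >= 0.85 * tot[:, None], axis=1)
    rolloff = freqs[roll_idx]
    ent = -(p * np.log2(np.maximum(p, 1e-300))).sum(axis=1) / np.log2(p.shape[1])
    gm = np.exp(np.mean(np.log(np.maximum(power, 1e-300)), axis=1))
    am = power.mean(axis=1)
    flatness = np.where(am > 0, gm / np.maximum(am, 1e-300), 1.0)
    flux = np.sqrt(((mag - prev_mag) ** 2).sum(axis=1))
    hl = power[:, freqs >= 1500.0].sum(axis=1) / np.maximum(
        power[:, freqs < 1500.0].sum(axis=1), 1e-300
    )
    silent = tot <= 0
    for arr in (centroid, spread, rolloff, ent, hl):
        arr[silent] = 0.0
    flatness[silent] = 1.0
    return centroid, spread, rolloff, ent, flatness, flux, hl


def _roughness(mag, freqs, n_peaks=12):
    """Plomp–Levelt roughness from the strongest spectral peaks per frame."""
    out = np.zeros(mag.shape[0])
    k = min(n_peaks, mag.shape[1])
    idx = np.argpartition(mag, -k, axis=1)[:, -k:]
    for i in range(mag.shape[0]):
        f = freqs[idx[i]]
        a = mag[i, idx[i]]
        order = np.argsort(f)
        f, a = f[order], a[order]
        df = f[None, :] - f[:, None]
        fmin_pair = np.minimum(f[None, :], f[:, None])
        s = 0.24 / (0.0207 * fmin_pair + 18.96)
        x = s * np.abs(df)
        diss = np.exp(-3.5 * x) - np.exp(-5.75 * x)
        amp = a[None, :] * a[:, None]
        out[i] = np.sum(np.triu(amp * diss, k=1))
    return out


def _chroma(mag, freqs):
    sel = freqs > 0
    pc = (np.round(12.0 * np.log2(np.maximum(freqs[sel], 1e-6) / 440.0)) + 69) % 12
    chroma = np.zeros(12)
    power = (mag[:, sel] ** 2).sum(axis=0)
    for c in range(12):
        chroma[c] = power[pc == c].sum()
    return chroma


def _key_mode(chroma):
    if chroma.sum() <= 0 or np.allclose(chroma, chroma[0]):
        return 0.0, 0.0
    rs_maj = [np.corrcoef(chroma, np.roll(_KS_MAJOR, k))[0, 1] for k in range(12)]
    rs_min = [np.corrcoef(chroma, np.roll(_KS_MINOR, k))[0, 1] for k in range(12)]
    best_maj, best_min = max(rs_maj), max(rs_min)
    return best_maj - best_min, max(best_maj, best_min)


def mirt_features(clip, tr: float = 1.5, fmin: float = FMIN, fmax: float = FMAX) -> DescriptorFeatures:
    """24 music descriptors, TR-averaged.

    Loudness/timbral descriptors use 25-ms frames with 50% overlap;
    rhythm/tonal descriptors use 3-s frames with 33% overlap.  Definitions
    are standard closed forms (see docs/methods.md); spectra are restricted
    to ``fmin``–``fmax``.
    """
    x = np.asarray(clip.samples, dtype=float)
    sr = clip.sample_rate
    dur = x.size / sr
    if dur < 3.0:
        raise ValueError("clip shorter than 3 s")
    n_tr = int(x.size // int(round(tr * sr)))

    # --- short frames (25 ms, 50% overlap) ---
    nwin = int(round(0.025 * sr))
    hop = nwin // 2
    n_frames = 1 + (x.size - nwin) // hop
    frames = np.lib.stride_tricks.sliding_window_view(x, nwin)[::hop][:n_frames]
    times_s = _frame_times(n_frames, hop / sr, nwin / sr)

    rms = np.sqrt((frames**2).mean(axis=1))
    zcr = (np.abs(np.diff(np.signbit(frames), axis=1)).sum(axis=1)) / nwin

    win = np.hanning(nwin)
    spec = np.abs(np.fft.rfft(frames * win, axis=1))
    freqs = np.fft.rfftfreq(nwin, 1.0 / sr)
    band = (freqs >= fmin) & (freqs <= fmax)
    spec, freqs = spec[:, band], freqs[band]
    prev = np.vstack([spec[:1], spec[:-1]])
    centroid, spread, rolloff, ent, flat, flux, hl = _spectral_descriptors(spec, freqs, prev)
    rough = _roughness(spec, freqs)

    # sub-band flux on 9 log-spaced (octave-like) bands covering [fmin, fmax]
    edges = np.geomspace(fmin, fmax, 10)
    sb_flux = np.zeros((n_frames, 9))
    for b in range(9):
        sel = (freqs >= edges[b]) & (freqs < max(edges[b + 1], edges[b] + 1))
        if np.any(sel):
            sb = spec[:, sel]
            sb_prev = np.vstack([sb[:1], sb[:-1]])
            sb_flux[:, b] = np.sqrt(((sb - sb_prev) ** 2).sum(axis=1))

    short = np.column_stack([rms, zcr, hl, centroid, rolloff, ent, flat, rough,
                             spread, flux, sb_flux])
    short_tr = _assign_tr(short, times_s, tr, n_tr)

    # --- long frames (3 s, 33% overlap) ---
    nlong = int(round(3.0 * sr))
    lhop = int(round(nlong * (1 - 1 / 3)))
    n_long = max(1, 1 + (x.size - nlong) // lhop)
    ltimes = _frame_times(n_long, lhop / sr, nlong / sr)

    # onset envelope from half-wave-rectified RMS flux at the short hop
    onset = np.maximum(np.diff(rms, prepend=rms[0]), 0.0)
    fr_rate = sr / hop

    long_vals = np.zeros((n_long, 5))
    for i in range(n_long):
        a = i * lhop
        # pulse clarity: max normalized autocorrelation of the onset
        # envelope at lags corresponding to 40-200 bpm
        oa = int(round(a / hop))
        oseg = onset[oa : oa + int(round(nlong / hop))]
        oseg = oseg - oseg.mean()
        ac = np.correlate(oseg, oseg, mode="full")[oseg.size - 1 :]
        lag_lo = int(round(fr_rate * 60.0 / 200.0))
        lag_hi = min(int(round(fr_rate * 60.0 / 40.0)), ac.size - 1)
        pulse = ac[lag_lo : lag_hi + 1].max() / ac[0] if ac[0] > 0 else 0.0

        # fluctuation spectrum <= 10 Hz from band-envelope modulations
        f0 = int(round(a / hop))
        f1 = min(n_frames, f0 + int(round(nlong / hop)))
        fl_cen, fl_ent = 0.0, 0.0
        if f1 - f0 > 8:
            envs = sb_flux[f0:f1]  # proxy band envelopes
            fspec = np.abs(np.fft.rfft(envs - envs.mean(axis=0), axis=0))
            ffreqs = np.fft.rfftfreq(envs.shape[0], 1.0 / fr_rate)
            keep = (ffreqs > 0) & (ffreqs <= 10.0)
            fs = fspec[keep].sum(axis=1)
            if fs.sum() > 0:
                pf = fs / fs.sum()
                fl_cen = float(pf @ ffreqs[keep])
                fl_ent = float(-(pf * np.log2(np.maximum(pf, 1e-300))).sum())

        chroma = _chroma(spec[f0:f1], freqs)
        mode, key_clar = _key_mode(chroma)
        long_vals[i] = [pulse, fl_cen, fl_ent, mode, key_clar]

    long_tr = _assign_tr(long_vals, ltimes, tr, n_tr)
    values = np.hstack([short_tr, long_tr])
    return DescriptorFeatures(values, list(MIRT_NAMES), "mirt")
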