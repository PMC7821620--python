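"""Synthetic stimuli and simulated voxel responses with known ground truth.

Real music genres differ in their spectro-temporal modulation statistics;
since the downstream analysis consumes only those statistics, synthetic
"genres" are modulation *archetypes*: each has a carrier-weight profile
over the 128 cochlear channels, a temporal-rate profile over the 10 MTF
rates ω, a spectral-scale profile over the 10 MTF scales Ω, and a
voice probability.  Clips are seeded superpositions of moving-ripple tone
clouds whose ripple velocities and densities follow the archetype's
profiles — controllable ground truth for every downstream stage.

Simulated brains assign each tuned voxel a smooth tuning bump over an
interpretable feature space plus a 5-tap hemodynamic delay kernel;
responses are the delayed-feature x true-weight product plus i.i.d.
Gaussian noise (AR(1) optional).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .features import RATES, SCALES, N_COCHLEAR_CHANNELS, cochlear_center_freqs

DEFAULT_SAMPLE_RATE = 22050
DEFAULT_DURATION = 15.0
DEFAULT_FADE = 2.0
DEFAULT_RMS = 0.1
# Default hemodynamic delay kernel over lags 1..5 TR (sums to 1).
DEFAULT_DELAY_KERNEL = np.array([0.1, 0.25, 0.3, 0.25, 0.1])


@dataclass
class GenreArchetype:
    """Modulation archetype standing in for a music genre."""

    genre_id: int
    name: str
    carrier_weights: np.ndarray  # (128,), nonnegative, sums to 1
    rate_profile: np.ndarray  # (10,), nonnegative, sums to 1
    scale_profile: np.ndarray  # (10,), nonnegative, sums to 1
    voice_prob: float

    def __post_init__(self):
        for attr in ("carrier_weights", "rate_profile", "scale_profile"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if np.any(v < 0):
                raise ValueError(f"{attr} must be nonnegative")
            s = v.sum()
            if not np.isclose(s, 1.0, atol=1e-8):
                raise ValueError(f"{attr} must sum to 1 (got {s})")
            setattr(self, attr, v)
        if not 0.0 <= self.voice_prob <= 1.0:
            raise ValueError("voice_prob must be in [0, 1]")


@dataclass
class AudioClip:
    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    genre_id: int = -1
    voice_flag: bool = False
    fade: float = DEFAULT_FADE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class GroundTruthBrain:
    """Known voxel tuning used to simulate responses.

    Non-ROI voxels have all-zero tuning; ``noise_sd`` is calibrated so
    that signal/noise variance equals the requested SNR for tuned voxels
    under approximately standardized, weakly correlated features.
    """

    tuning: np.ndarray  # (V, D)
    delay_kernel: np.ndarray  # (5,), nonnegative, sums to 1
    noise_sd: np.ndarray  # (V,), positive
    roi_flags: np.ndarray  # (V,), bool
    archetype_of_voxel: np.ndarray = field(default=None)  # (V,), int, -1 untuned

    def __post_init__(self):
        self.tuning = np.asarray(self.tuning, dtype=float)
        self.delay_kernel = np.asarray(self.delay_kernel, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        self.roi_flags = np.asarray(self.roi_flags, dtype=bool)
        if self.delay_kernel.size != 5:
            raise ValueError("delay_kernel must have length 5")
        if np.any(self.delay_kernel < 0):
            raise ValueError("delay_kernel must be nonnegative")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be positive")
        untuned = ~self.roi_flags
        if np.any(np.abs(self.tuning[untuned]) > 0):
            raise ValueError("non-ROI voxels must have all-zero tuning")

    @property
    def n_voxels(self) -> int:
        return self.tuning.shape[0]

    @property
    def n_features(self) -> int:
        return self.tuning.shape[1]


def _bump(n: int, center: float, sigma: float, floor: float = 0.01) -> np.ndarray:
    v = np.exp(-0.5 * ((np.arange(n) - center) / sigma) ** 2) + floor
    return v / v.sum()


def profile_mode(profile: np.ndarray) -> int:
    return int(np.argmax(profile))


def make_archetypes(
    n_genres: int,
    seed: int,
    max_rate_mode: int = 7,
    max_scale_mode: int = 3,
    voice_probs=None,
    mode_sigma: float = 0.7,
    max_cosine: float = 0.95,
    max_tries: int = 200,
) -> list[GenreArchetype]:
    """Draw ``n_genres`` mutually dissimilar modulation archetypes.

    Each archetype gets a distinct (rate-mode, scale-mode) combination among
    the first ``max_rate_mode`` rates and ``max_scale_mode`` scales.  High
    rates are excluded by default because they are poorly resolved at the
    10-ms cochleogram hop, and ripple densities above ~1 cyc/oct because
    the 25-ms analysis window and cochlear-channel bandwidths smear them.  ``voice_probs`` defaults to a confounded
    pattern: even genre ids are mostly voiced (0.9), odd mostly not (0.1).

    Raises ``RuntimeError`` if the pairwise cosine-dissimilarity invariant
    (< ``max_cosine`` on concatenated rate||scale profiles) cannot be met
    within ``max_tries`` redraws.
    """
    if n_genres < 2:
        raise ValueError("n_genres must be >= 2")
    rng = np.random.default_rng(seed)
    if voice_probs is None:
        voice_probs = [0.9 if g % 2 == 0 else 0.1 for g in range(n_genres)]

    combos = [(r, s) for r in range(max_rate_mode) for s in range(max_scale_mode)]
    for _ in range(max_tries):
        if n_genres <= len(combos):
            chosen = [combos[i] for i in rng.choice(len(combos), n_genres, replace=False)]
        else:
            chosen = [combos[i] for i in rng.choice(len(combos), n_genres, replace=True)]
        archetypes = []
        for g, (rmode, smode) in enumerate(chosen):
            raw = rng.normal(size=N_COCHLEAR_CHANNELS)
            kernel = np.hanning(81)
            smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
            cw = np.exp(2.0 * smooth)
            archetypes.append(
                GenreArchetype(
                    genre_id=g,
                    name=f"genre{g:02d}",
                    carrier_weights=cw / cw.sum(),
                    rate_profile=_bump(len(RATES), rmode, mode_sigma),
                    scale_profile=_bump(len(SCALES), smode, mode_sigma),
                    voice_prob=float(voice_probs[g]),
                )
            )
        if _max_pairwise_cosine(archetypes) < max_cosine:
            return archetypes
    raise RuntimeError("could not achieve archetype dissimilarity within max_tries")


def _max_pairwise_cosine(archetypes) -> float:
    profiles = np.array(
        [np.concatenate([a.rate_profile, a.scale_profile]) for a in archetypes]
    )
    norm = profiles / np.linalg.norm(profiles, axis=1, keepdims=True)
    cos = norm @ norm.T
    np.fill_diagonal(cos, -1.0)
    return float(cos.max())


def synthesize_clip(
    archetype: GenreArchetype,
    duration: float = DEFAULT_DURATION,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    rms_target: float = DEFAULT_RMS,
    fade: float = DEFAULT_FADE,
    n_ripples: int = 2,
    n_tones: int = 48,
    voice_flag=None,
) -> AudioClip:
    """Synthesize a seeded moving-ripple tone cloud for one archetype.

    The clip superposes amplitude-modulated narrowband tones on a
    log-spaced carrier grid weighted by ``carrier_weights``.  The dominant
    ripple component sits exactly at the archetype's (rate, scale) profile
    modes; additional components are drawn from the profiles.  A
    formant-like harmonic band is added when the voice flag is set.  The
    waveform is faded (monotone raised-cosine ramps) and RMS-normalized.
    """
    if sample_rate <= 0 or duration <= 0:
        raise ValueError("invalid sample_rate or duration")
    if duration <= 2 * fade:
        raise ValueError("duration must exceed twice the fade length")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    cfs = cochlear_center_freqs()
    tone_idx = np.linspace(0, cfs.size - 1, n_tones).round().astype(int)
    tone_f = cfs[tone_idx]
    tone_w = archetype.carrier_weights[tone_idx]
    tone_w = tone_w / tone_w.max()
    x_oct = np.log2(tone_f / cfs[0])

    # ripple components: first at the profile modes, rest drawn from profiles
    comp = [(profile_mode(archetype.rate_profile), profile_mode(archetype.scale_profile), 1.0)]
    for _ in range(n_ripples - 1):
        ri = rng.choice(len(RATES), p=archetype.rate_profile)
        si = rng.choice(len(SCALES), p=archetype.scale_profile)
        comp.append((int(ri), int(si), 0.35))

    wave = np.zeros(n)
    block = 16
    for ri, si, amp in comp:
        omega, scale = RATES[ri], SCALES[si]
        direction = rng.choice([-1.0, 1.0])
        phi = rng.uniform(0, 2 * np.pi)
        psi = rng.uniform(0, 2 * np.pi, size=n_tones)
        mod_t = 2 * np.pi * direction * omega * t
        for j0 in range(0, n_tones, block):
            j1 = min(j0 + block, n_tones)
            w = tone_w[j0:j1]
            keep = w >= 1e-3
            if not np.any(keep):
                continue
            env = 1.0 + np.sin(
                mod_t[None, :]
                + (2 * np.pi * scale * x_oct[j0:j1][keep] + phi)[:, None]
            )
            carrier = np.sin(
                2 * np.pi * tone_f[j0:j1][keep][:, None] * t[None, :]
                + psi[j0:j1][keep][:, None]
            )
            wave += amp * (w[keep][:, None] * env * carrier).sum(axis=0)

    if voice_flag is None:
        voice_flag = bool(rng.random() < archetype.voice_prob)
    if voice_flag:
        f0 = rng.uniform(150.0, 250.0)
        formants = ((500.0, 1.0), (1500.0, 0.7), (2500.0, 0.4))
        vib = 1.0 + 0.02 * np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi))
        voice = np.zeros(n)
        for h in range(1, int(3000.0 // f0) + 1):
            fh = h * f0
            a = sum(w * np.exp(-0.5 * ((fh - fc) / 300.0) ** 2) for fc, w in formants)
            voice += a * np.sin(2 * np.pi * fh * vib * t + rng.uniform(0, 2 * np.pi))
        vr = np.sqrt(np.mean(voice**2))
        wr = np.sqrt(np.mean(wave**2))
        if vr > 0:
            wave += 0.3 * (wr / vr) * voice

    wave = _apply_fade(wave, sample_rate, fade)
    cur = np.sqrt(np.mean(wave**2))
    if cur > 0:
        wave *= rms_target / cur
    return AudioClip(wave, sample_rate, archetype.genre_id, voice_flag, fade)


def _apply_fade(x: np.ndarray, sample_rate: int, fade: float) -> np.ndarray:
    nf = int(round(fade * sample_rate))
    if nf == 0:
        return x
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nf) / nf))
    out = x.copy()
    out[:nf] *= ramp
    out[-nf:] *= ramp[::-1]
    return out


def pink_noise(duration: float, sample_rate: int = DEFAULT_SAMPLE_RATE, seed: int = 0,
               rms_target: float = DEFAULT_RMS) -> AudioClip:
    """Seeded 1/f noise, standing in for recorded scanner noise."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    f[0] = f[1] if f.size > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n)
    x *= rms_target / np.sqrt(np.mean(x**2))
    return AudioClip(x, sample_rate, fade=0.0)


def add_scanner_noise(clip: AudioClip, noise: AudioClip, relative_rms: float) -> AudioClip:
    """Mix noise at a given RMS relative to the clip; no re-normalization."""
    if relative_rms < 0:
        raise ValueError("relative_rms must be >= 0")
    if noise.sample_rate != clip.sample_rate:
        raise ValueError("sample-rate mismatch between clip and noise")
    n = clip.samples.size
    reps = int(np.ceil(n / noise.samples.size))
    nz = np.tile(noise.samples, reps)[:n]
    nz_rms = np.sqrt(np.mean(nz**2))
    if relative_rms == 0 or nz_rms == 0:
        mixed = clip.samples.copy()
    else:
        mixed = clip.samples + nz * (relative_rms * clip.rms / nz_rms)
    return AudioClip(mixed, clip.sample_rate, clip.genre_id, clip.voice_flag, clip.fade)


def make_ground_truth_brain(
    D: int,
    V: int,
    n_tuned: int,
    archetypes,
    snr: float,
    seed: int,
    delay_kernel=None,
    mtf_layout: bool | None = None,
) -> GroundTruthBrain:
    """Simulated brain: smooth tuning bumps biased toward archetype profiles.

    When ``D`` matches the raw MTF dimension (or ``mtf_layout=True``), each
    tuned voxel's tuning is an outer product of Gaussian bumps over
    (frequency range, Ω, ω), with the Ω/ω bump centers at the assigned
    archetype's profile modes.  Otherwise a smooth 1-D bump in index space
    is used.  Tuning rows have unit L2 norm; ``noise_sd`` is set from
    ``snr`` assuming standardized features.
    """
    if n_tuned > V:
        raise ValueError("n_tuned must be <= V")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    if delay_kernel is None:
        delay_kernel = DEFAULT_DELAY_KERNEL
    delay_kernel = np.asarray(delay_kernel, dtype=float)
    from .features import MTF_RAW_DIM, N_FREQ_RANGES

    if mtf_layout is None:
        mtf_layout = D == MTF_RAW_DIM

    tuning = np.zeros((V, D))
    arch_of = np.full(V, -1, dtype=int)
    for v in range(n_tuned):
        a = archetypes[v % len(archetypes)]
        arch_of[v] = a.genre_id
        if mtf_layout:
            fr_bump = _bump(N_FREQ_RANGES, rng.uniform(2, N_FREQ_RANGES - 3), 3.0, 0.0)
            s_bump = _bump(len(SCALES), profile_mode(a.scale_profile) + rng.normal(0, 0.3), 1.0, 0.0)
            r_bump = _bump(len(RATES), profile_mode(a.rate_profile) + rng.normal(0, 0.3), 1.0, 0.0)
            row = np.einsum("f,s,r->fsr", fr_bump, s_bump, r_bump).ravel()
        else:
            center = (a.genre_id + 0.5) * D / max(len(archetypes), 1)
            row = _bump(D, center + rng.normal(0, 0.05 * D), max(0.05 * D, 1.0), 0.0)
        row = row + 0.05 * row.max() * rng.normal(size=D)
        tuning[v] = row / np.linalg.norm(row)

    roi = np.zeros(V, dtype=bool)
    roi[:n_tuned] = True
    sig = np.linalg.norm(tuning, axis=1) * np.linalg.norm(delay_kernel)
    base = np.median(sig[:n_tuned]) if n_tuned else 1.0
    noise_sd = np.where(roi, sig / np.sqrt(snr), base / np.sqrt(snr))
    return GroundTruthBrain(tuning, delay_kernel, noise_sd, roi, arch_of)


def true_weights(brain: GroundTruthBrain) -> np.ndarray:
    """Ground-truth encoding weights (5D x V): tuning x delay kernel per lag."""
    blocks = [dk * brain.tuning.T for dk in brain.delay_kernel]
    return np.concatenate(blocks, axis=0)


def simulate_responses(
    F_delayed: np.ndarray,
    brain: GroundTruthBrain,
    seed: int,
    ar1: float = 0.0,
) -> np.ndarray:
    """R = F_delayed @ W_true + noise  (T x V).

    Noise is i.i.d. Gaussian per voxel with the brain's ``noise_sd``; an
    AR(1) temporal correlation can be requested via ``ar1``.
    """
    F = np.asarray(F_delayed, dtype=float)
    if F.shape[1] != 5 * brain.n_features:
        raise ValueError(
            f"F_delayed has {F.shape[1]} columns, expected {5 * brain.n_features}"
        )
    rng = np.random.default_rng(seed)
    R = F @ true_weights(brain)
    eps = rng.normal(size=R.shape)
    if ar1 != 0.0:
        for tt in range(1, eps.shape[0]):
            eps[tt] = ar1 * eps[tt - 1] + np.sqrt(1 - ar1**2) * eps[tt]
    return R + eps * brain.noise_sd[None, :]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_wav(path, clip: AudioClip) -> None:
    """PCM 16-bit mono WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (x * 32767).astype(np.int16))


def read_wav(path) -> AudioClip:
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return AudioClip(np.asarray(data, dtype=float), int(sr))


def write_manifest(path, rows: list[dict]) -> None:
    """Stimulus inventory as TSV (clip_id, genre, voice_flag, seed)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_brain(path_prefix, brain: GroundTruthBrain) -> None:
    """JSON metadata + flat float64 binary tuning matrix."""
    prefix = Path(path_prefix)
    brain.tuning.astype("<f8").tofile(prefix.with_suffix(".tuning.bin"))
    meta = {
        "n_voxels": int(brain.n_voxels),
        "n_features": int(brain.n_features),
        "dtype": "<f8",
        "order": "C",
        "delay_kernel": brain.delay_kernel.tolist(),
        "noise_sd": brain.noise_sd.tolist(),
        "roi_flags": brain.roi_flags.astype(int).tolist(),
        "archetype_of_voxel": brain.archetype_of_voxel.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def read_brain(path_prefix) -> GroundTruthBrain:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    tuning = np.fromfile(prefix.with_suffix(".tuning.bin"), dtype="<f8").reshape(
        meta["n_voxels"], meta["n_features"]
    )
    return GroundTruthBrain(
        tuning,
        np.array(meta["delay_kernel"]),
        np.array(meta["noise_sd"]),
        np.array(meta["roi_flags"], dtype=bool),
        np.array(meta["archetype_of_voxel"]),
    )
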