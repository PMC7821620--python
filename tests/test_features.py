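"""Acoustic feature extraction: cochleogram, MTF, PCA reduction, MFCC, MIRT."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from genrefmri import features, synth
from genrefmri.features import (
    Cochleogram, mtf_filter, cochlear_center_freqs, RATES, SCALES,
)


def _tone_clip(freq, duration=3.0, sr=22050, am=None):
    t = np.arange(int(duration * sr)) / sr
    x = np.sin(2 * np.pi * freq * t)
    if am is not None:
        x *= 1.0 + np.sin(2 * np.pi * am * t)
    return synth.AudioClip(x, sr)


class TestCochleogram:
    def test_silence_gives_zero(self):
        clip = synth.AudioClip(np.zeros(22050 * 3), 22050)
        coch = features.cochleogram(clip)
        assert np.all(coch.energies == 0)

    def test_pure_tone_peaks_at_nearest_channel(self):
        coch = features.cochleogram(_tone_clip(1000.0))
        ch = np.argmax(coch.energies.mean(axis=0))
        nearest = np.argmin(np.abs(coch.center_freqs - 1000.0))
        assert abs(ch - nearest) <= 1

    def test_energy_homogeneity(self):
        clip = _tone_clip(500.0)
        c1 = features.cochleogram(clip)
        c2 = features.cochleogram(synth.AudioClip(2 * clip.samples, 22050))
        assert np.allclose(c2.energies, 4 * c1.energies, rtol=1e-10)

    def test_center_freqs_increasing_within_band(self):
        for spacing in ("log", "erb"):
            cfs = cochlear_center_freqs(spacing=spacing)
            assert cfs[0] == pytest.approx(100.0)
            assert cfs[-1] == pytest.approx(8000.0)
            assert np.all(np.diff(cfs) > 0)

    def test_too_short_clip_rejected(self):
        with pytest.raises(ValueError):
            features.cochleogram(synth.AudioClip(np.zeros(100), 22050))


class TestCochlearFeatures:
    def test_shape_per_tr(self, short_cochleogram):
        fm = features.cochlear_features(short_cochleogram, tr=1.5)
        assert fm.values.shape == (4, 128)  # 6-s clip -> 4 TRs

    def test_constant_input_preserved(self):
        cfs = np.geomspace(100, 8000, 128)
        const = np.full((300, 128), 7.0)
        coch = Cochleogram(const, 0.010, 0.025, cfs)
        fm = features.cochlear_features(coch, tr=1.5)
        assert np.allclose(fm.values, 7.0)


class TestMTFEnergy:
    def test_raw_dimension(self, short_cochleogram):
        m = features.mtf_energy(short_cochleogram)
        assert m.values.shape[1] == 2000

    def test_matches_direct_convolution_oracle(self, tiny_cochleogram):
        """FFT implementation equals a direct 2-D quadrature convolution."""
        scales, rates = (0.5, 2.0), (4.0, 16.0)
        out = features.mtf_energy(
            tiny_cochleogram, tr=0.15, scales=scales, rates=rates,
            n_freq_ranges=4,
        )
        S = tiny_cochleogram.energies.T
        n_ch, n_fr = S.shape
        cfs = tiny_cochleogram.center_freqs
        dx = np.log2(cfs[-1] / cfs[0]) / (n_ch - 1)
        fpt, n_tr = 15, n_fr // 15
        groups = features._freq_range_groups(cfs, 4)
        energies, gmax = {}, 0.0
        for d in (+1, -1):
            for si, sc in enumerate(scales):
                for ri, ra in enumerate(rates):
                    h = mtf_filter(sc, ra, d, dx, 0.010, n_ch)
                    e = np.abs(convolve2d(S, h, mode="same")) ** 2
                    energies[(si, ri, d)] = e
                    gmax = max(gmax, e.max())
        eps = 1e-8 * gmax
        vals = np.zeros((n_tr, 4, len(scales), len(rates)))
        for (si, ri, d), e in energies.items():
            le = np.log(np.maximum(e, eps))
            le_tr = le[:, : n_tr * fpt].reshape(n_ch, n_tr, fpt).mean(axis=2)
            for g, mem in enumerate(groups):
                vals[:, g, si, ri] += 0.5 * le_tr[mem].mean(axis=0).T
        assert np.abs(vals.reshape(n_tr, -1) - out.values).max() < 1e-8

    def test_am_tone_peaks_at_matching_rate(self):
        clip = _tone_clip(1000.0, duration=6.0, am=4.0)
        m = features.mtf_energy(features.cochleogram(clip))
        _, ri = features.modulation_peak(m)
        assert RATES[ri] == 4.0

    def test_static_ripple_peaks_at_matching_scale(self):
        cfs = cochlear_center_freqs()
        x_oct = np.log2(cfs / cfs[0])
        prof = 1.0 + np.sin(2 * np.pi * 1.0 * x_oct)
        coch = Cochleogram(np.tile(prof, (300, 1)), 0.010, 0.025, cfs)
        si, _ = features.modulation_peak(features.mtf_energy(coch))
        assert SCALES[si] == 1.0

    def test_amplitude_scaling_shifts_log_energy(self, tiny_cochleogram):
        m1 = features.mtf_energy(tiny_cochleogram, tr=0.15,
                                 scales=(1.0,), rates=(4.0,), n_freq_ranges=2)
        scaled = Cochleogram(
            10.0 * tiny_cochleogram.energies, 0.010, 0.025,
            tiny_cochleogram.center_freqs,
        )
        m2 = features.mtf_energy(scaled, tr=0.15, scales=(1.0,), rates=(4.0,),
                                 n_freq_ranges=2)
        diffs = m2.values - m1.values
        assert np.allclose(diffs, np.log(100.0), atol=1e-6)


class TestMTFReducer:
    def test_rank3_input_needs_3_components(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 40))
        red = features.MTFReducer(variance_threshold=0.95).fit(X)
        assert red.n_components_ == 3

    def test_basis_orthonormal_and_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 30))
        red = features.MTFReducer(0.99).fit(X)
        B = red.basis_
        assert np.allclose(B.T @ B, np.eye(B.shape[1]), atol=1e-8)
        Z = red.transform(X)
        Xr = red.inverse_transform(Z)
        # back-projection preserves >= 99% of the variance
        resid = ((X - Xr) ** 2).sum()
        assert resid / ((X - X.mean(0)) ** 2).sum() <= 0.01 + 1e-9

    def test_orthogonal_complement_projects_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 20))
        red = features.MTFReducer(0.99).fit(X)
        v = rng.normal(size=20)
        v -= red.basis_ @ (red.basis_.T @ v)  # orthogonal complement
        assert np.abs(red.transform(v[None, :] + red.mean_)).max() < 1e-8

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            features.MTFReducer().fit(np.ones((10, 5)))


class TestDescriptors:
    def test_mfcc_shape_and_determinism(self, short_clip):
        f1 = features.mfcc_features(short_clip, tr=1.5)
        f2 = features.mfcc_features(short_clip, tr=1.5)
        assert f1.values.shape == (4, 12)
        assert np.array_equal(f1.values, f2.values)

    def test_mirt_shape_and_names(self, short_clip):
        f = features.mirt_features(short_clip, tr=1.5)
        assert f.values.shape == (4, 24)
        assert len(set(f.names)) == 24

    def test_mirt_silence(self):
        clip = synth.AudioClip(np.zeros(22050 * 3), 22050)
        f = features.mirt_features(clip, tr=1.5)
        by_name = dict(zip(f.names, f.values.T))
        assert np.all(by_name["rms"] == 0)
        assert np.all(by_name["zcr"] == 0)

    def test_flatness_noise_exceeds_tone(self):
        rng = np.random.default_rng(0)
        noise = synth.AudioClip(rng.normal(size=22050 * 3), 22050)
        tone = _tone_clip(1000.0)
        fn = features.mirt_features(noise, tr=1.5)
        ft = features.mirt_features(tone, tr=1.5)
        idx = fn.names.index("flatness")
        assert fn.values[:, idx].mean() > ft.values[:, idx].mean()

    def test_short_clip_rejected(self):
        clip = synth.AudioClip(np.zeros(22050 * 2), 22050)
        with pytest.raises(ValueError):
            features.mirt_features(clip)
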