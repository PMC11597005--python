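"""Spectral oracles: Parseval, closed-form sinusoid power, band integrals."""

import numpy as np
import pandas as pd
import pytest

from tcresleep import io as tio
from tcresleep.spectral import (DEFAULT_BANDS, BandScheme, EpochSpectrum,
                                band_powers, band_weight_matrix,
                                compute_band_powers, label_epochs,
                                multitaper_psd, segment_epochs, spectrogram)

FS = 512.0


def rec_of(data, labels=None, fs=FS):
    data = np.atleast_2d(data)
    labels = labels or ["Cz"] * data.shape[0]
    return tio.Recording(channel_labels=labels,
                         channel_modality=["TCRE"] * data.shape[0],
                         sample_rate=fs, data=data)


class TestSegmentation:
    def test_truncation_rule(self):
        r = rec_of(np.zeros((1, int(12 * FS))))
        ranges = segment_epochs(r, 5.0)
        assert len(ranges) == 2
        assert ranges[0] == (0, 2560) and ranges[1] == (2560, 5120)

    def test_six_analysis_epochs_per_scored_epoch(self):
        r = rec_of(np.zeros((1, int(60 * FS))))
        ranges = segment_epochs(r, 5.0)
        scored = [int(i * 5 // 30) for i in range(len(ranges))]
        assert scored == [0] * 6 + [1] * 6

    def test_too_short_warns_and_returns_empty(self):
        r = rec_of(np.zeros((1, 100)))
        with pytest.warns(UserWarning):
            assert segment_epochs(r, 5.0) == []


class TestMultitaper:
    def test_zero_signal_zero_psd(self):
        f, p = multitaper_psd(np.zeros(2560), FS)
        assert np.all(p == 0.0)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 2560))
        f, p = multitaper_psd(x, FS)
        integral = np.trapezoid(p, f, axis=-1).mean()
        assert integral == pytest.approx(1.0, rel=0.05)

    def test_sinusoid_power_closed_form(self):
        amp = 20.0  # μV
        t = np.arange(2560) / FS
        x = amp * np.sin(2 * np.pi * 10.0 * t)
        f, p = multitaper_psd(x, FS)
        in_alpha = (f >= 8) & (f < 12)
        power = np.trapezoid(p[in_alpha], f[in_alpha])
        assert power == pytest.approx(amp ** 2 / 2, rel=0.05)

    def test_inconsistent_taper_count_rejected(self):
        with pytest.raises(ValueError):
            multitaper_psd(np.zeros(256), FS, nw=2.0, n_tapers=7)

    def test_agrees_with_mne_reference(self):
        from mne.time_frequency import psd_array_multitaper
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2560)
        f1, p1 = multitaper_psd(x, FS)
        # same DPSS family: full bandwidth 2*NW*fs/n = 1.6 Hz
        p2, f2 = psd_array_multitaper(
            x - x.mean(), FS, bandwidth=1.6, adaptive=False,
            normalization="full", verbose="error")
        assert np.allclose(f1, f2)
        # MNE eigenvalue-weights its taper average; ours is unweighted,
        # so agreement is close but not exact
        assert np.max(np.abs(p1 - p2)) < 0.05 * p2.max()
        assert np.trapezoid(p1, f1) == pytest.approx(np.trapezoid(p2, f2),
                                                     rel=0.01)


class TestBandPowers:
    def spectrum(self, psd, n=2560):
        f = np.fft.rfftfreq(n, 1 / FS)
        return EpochSpectrum(0, "Cz", f, psd)

    def test_flat_psd_gives_bandwidth_fractions(self):
        f = np.fft.rfftfreq(2560, 1 / FS)
        rec = band_powers(self.spectrum(np.ones_like(f)))
        widths = DEFAULT_BANDS.widths
        expected = 100 * widths / widths.sum()
        got = np.array([rec["relative"][b] for b in DEFAULT_BANDS.names])
        assert np.allclose(got, expected, atol=1e-9)
        # the documented fractions of the 31.5 Hz span
        assert expected == pytest.approx(
            [12.698413, 11.111111, 12.698413, 9.523810, 53.968254], abs=1e-4)

    def test_band_additivity_exact(self):
        rng = np.random.default_rng(1)
        f = np.fft.rfftfreq(2560, 1 / FS)
        psd = rng.random(f.size)
        W = band_weight_matrix(f, DEFAULT_BANDS)
        total_bands = (W @ psd).sum()
        # fine-grid oracle: trapezoid over [0.5, 32) with interpolated edges
        fine = np.linspace(0.5, 32.0, 200_001)
        oracle = np.trapezoid(np.interp(fine, f, psd), fine)
        assert total_bands == pytest.approx(oracle, rel=1e-6)

    def test_pure_sinusoid_concentrates_in_alpha(self):
        t = np.arange(2560) / FS
        x = 10 * np.sin(2 * np.pi * 10.0 * t)
        f, p = multitaper_psd(x, FS)
        rec = band_powers(EpochSpectrum(0, "Cz", f, p))
        assert rec["relative"]["alpha"] > 99.0

    def test_relative_sums_to_100(self):
        rng = np.random.default_rng(2)
        f, p = multitaper_psd(rng.standard_normal(2560), FS)
        rec = band_powers(EpochSpectrum(0, "Cz", f, p))
        assert sum(rec["relative"].values()) == pytest.approx(100.0,
                                                              rel=1e-9)

    def test_zero_spectrum_flagged_degenerate(self):
        f = np.fft.rfftfreq(2560, 1 / FS)
        rec = band_powers(self.spectrum(np.zeros_like(f)))
        assert rec["degenerate"] and rec["relative"] is None

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2560)
        c = 7.3
        f, p1 = multitaper_psd(x, FS)
        _, p2 = multitaper_psd(c * x, FS)
        r1 = band_powers(EpochSpectrum(0, "Cz", f, p1))
        r2 = band_powers(EpochSpectrum(0, "Cz", f, p2))
        for b in DEFAULT_BANDS.names:
            assert r2["absolute"][b] == pytest.approx(
                c ** 2 * r1["absolute"][b], rel=1e-9)
            assert r2["relative"][b] == pytest.approx(r1["relative"][b],
                                                      rel=1e-9)

    def test_band_scheme_validation(self):
        with pytest.raises(ValueError):
            BandScheme(bands=(("delta", 0.5, 4.5), ("theta", 5.0, 8.0)))


class TestSpectrogram:
    def test_window_count(self):
        r = rec_of(np.random.default_rng(0).standard_normal((1, int(60 * FS))))
        times, f, db = spectrogram(r, "Cz", window=30.0, step=5.0)
        assert db.shape[0] == 7  # (60-30)/5 + 1

    def test_unit_white_psd_is_zero_db(self):
        rng = np.random.default_rng(1)
        # white noise with variance fs/2 -> PSD 1 μV²/Hz one-sided
        x = rng.normal(0, np.sqrt(FS / 2), (1, int(120 * FS)))
        _, f, db = spectrogram(rec_of(x), "Cz")
        mid = (f > 10) & (f < 200)
        assert abs(db[:, mid].mean()) < 0.5

    def test_missing_channel(self):
        r = rec_of(np.zeros((1, int(30 * FS))))
        with pytest.raises(KeyError):
            spectrogram(r, "Pz")


class TestLabelling:
    def frame(self, n):
        return pd.DataFrame({"epoch_index": np.arange(n), "x": 0.0})

    def test_single_scored_epoch_labels_six(self):
        hyp = tio.Hypnogram(stages=["N2"])
        out, dropped = label_epochs(self.frame(6), hyp)
        assert list(out["stage"]) == ["N2"] * 6 and dropped == 0

    def test_exact_tiling_drops_nothing(self):
        hyp = tio.Hypnogram(stages=["N2"] * 12)
        out, dropped = label_epochs(self.frame(72), hyp)
        assert len(out) == 72 and dropped == 0

    def test_uncovered_tail_dropped(self):
        hyp = tio.Hypnogram(stages=["N2"] * 11)
        out, dropped = label_epochs(self.frame(72), hyp)
        assert len(out) == 66 and dropped == 6
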