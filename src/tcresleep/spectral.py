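"""Multitaper spectral estimation and band-power extraction.

The analysis chain is: cut each channel into non-overlapping 5-s epochs,
estimate a DPSS-multitaper power spectral density per epoch (μV²/Hz),
integrate it over five canonical frequency bands (delta 0.5–4.5, theta
4.5–8, alpha 8–12, sigma 12–15, beta 15–32 Hz), and express each band as
a percentage of the five-band total.  A 30-s-window spectrogram on a 5-s
grid supports whole-night visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .io import Hypnogram, Recording, STAGES

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "EpochSpectrum",
    "segment_epochs",
    "multitaper_psd",
    "band_powers",
    "band_weight_matrix",
    "spectrogram",
    "label_epochs",
    "compute_band_powers",
]

#: Default analysis epoch length (s).
EPOCH_S: float = 5.0

#: Default multitaper time-bandwidth product and taper count.
DEFAULT_NW: float = 4.0
DEFAULT_N_TAPERS: int = 7


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous, non-overlapping frequency bands [low, high) Hz."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.5, 4.5),
        ("theta", 4.5, 8.0),
        ("alpha", 8.0, 12.0),
        ("sigma", 12.0, 15.0),
        ("beta", 15.0, 32.0),
    )

    def __post_init__(self) -> None:
        prev_high = None
        for name, low, high in self.bands:
            if not low < high:
                raise ValueError(f"band {name}: low must be < high")
            if prev_high is not None and abs(low - prev_high) > 1e-12:
                raise ValueError("bands must be contiguous and non-overlapping")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def low(self) -> float:
        return self.bands[0][1]

    @property
    def high(self) -> float:
        return self.bands[-1][2]

    @property
    def widths(self) -> np.ndarray:
        return np.array([h - l for _, l, h in self.bands])


DEFAULT_BANDS = BandScheme()


@dataclass
class EpochSpectrum:
    """One epoch's one-sided PSD in μV²/Hz on an ascending frequency grid."""

    epoch_index: int
    channel: str
    frequencies: np.ndarray
    psd: np.ndarray


def segment_epochs(recording: Recording,
                   epoch_length: float = EPOCH_S) -> list[tuple[int, int]]:
    """Half-open sample ranges of consecutive non-overlapping epochs.

    Epoch ``i`` covers ``[i*L, (i+1)*L)`` seconds from the recording start;
    a trailing partial epoch is discarded.  An empty list (with a warning)
    is returned when the recording is shorter than one epoch.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n_per = int(round(epoch_length * recording.sample_rate))
    n_epochs = recording.n_samples // n_per
    if n_epochs == 0:
        warnings.warn("recording shorter than one epoch; no epochs produced",
                      stacklevel=2)
        return []
    return [(i * n_per, (i + 1) * n_per) for i in range(n_epochs)]


def _dpss_tapers(n: int, nw: float, n_tapers: int) -> np.ndarray:
    if n_tapers < 1 or n_tapers > 2 * nw - 1 + 1e-9:
        raise ValueError(
            f"taper count {n_tapers} inconsistent with time-bandwidth {nw} "
            f"(need 1 <= K <= 2*NW-1)"
        )
    return dpss(n, nw, n_tapers)


def multitaper_psd(epoch_signal: np.ndarray, sample_rate: float,
                   nw: float = DEFAULT_NW,
                   n_tapers: int = DEFAULT_N_TAPERS,
                   detrend: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """DPSS multitaper one-sided PSD of one or more epochs.

    Parameters
    ----------
    epoch_signal
        ``(..., n_samples)`` array in μV.  Leading dimensions are batched.
    sample_rate
        Hz.
    nw
        Time-bandwidth product (half-bandwidth = nw / epoch_length Hz).
    n_tapers
        Number of DPSS tapers averaged (at most ``2*nw - 1``).
    detrend
        Remove the per-epoch mean before tapering, so DC offset does not
        leak into the delta band.

    Returns
    -------
    frequencies, psd
        Grid of ``n_samples // 2 + 1`` frequencies with resolution
        ``sample_rate / n_samples`` Hz, and the PSD in μV²/Hz with matching
        leading dimensions.  Satisfies Parseval: the trapezoidal integral
        of the PSD approximates the signal variance.
    """
    x = np.asarray(epoch_signal, dtype=np.float64)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("epoch must contain at least 2 samples")
    tapers = _dpss_tapers(n, nw, n_tapers)  # (K, n), unit energy
    if detrend:
        x = x - x.mean(axis=-1, keepdims=True)
    xt = x[..., None, :] * tapers
    spec = np.fft.rfft(xt, axis=-1)
    psd = (spec.real ** 2 + spec.imag ** 2).mean(axis=-2) * (2.0 / sample_rate)
    psd[..., 0] *= 0.5
    if n % 2 == 0:
        psd[..., -1] *= 0.5
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    return freqs, psd


def band_weight_matrix(frequencies: np.ndarray,
                       scheme: BandScheme = DEFAULT_BANDS) -> np.ndarray:
    """Linear weights mapping a PSD vector to per-band trapezoidal integrals.

    Band edges that fall between grid points are handled by linear
    interpolation of the PSD at the edge, so adjacent bands share their
    boundary ordinate and band powers are exactly additive: the sum over
    bands equals the trapezoidal integral over the full scheme span.
    """
    f = np.asarray(frequencies, dtype=np.float64)
    nf = f.size
    W = np.zeros((len(scheme.bands), nf))
    for bi, (_, lo, hi) in enumerate(scheme.bands):
        if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
            raise ValueError(
                f"spectrum grid [{f[0]}, {f[-1]}] does not cover band "
                f"[{lo}, {hi})"
            )
        # node positions: lo, interior grid points, hi
        i0 = int(np.searchsorted(f, lo + 1e-12, side="left"))
        i1 = int(np.searchsorted(f, hi - 1e-12, side="right"))
        nodes = np.concatenate(([lo], f[i0:i1], [hi]))
        # interpolation weights of each node onto psd ordinates
        node_w: list[dict[int, float]] = []
        for t in nodes:
            j = int(np.clip(np.searchsorted(f, t, side="right") - 1, 0, nf - 2))
            frac = (t - f[j]) / (f[j + 1] - f[j])
            node_w.append({j: 1.0 - frac, j + 1: frac})
        # trapezoid over consecutive nodes
        for k in range(len(nodes) - 1):
            h = 0.5 * (nodes[k + 1] - nodes[k])
            for j, wgt in node_w[k].items():
                W[bi, j] += h * wgt
            for j, wgt in node_w[k + 1].items():
                W[bi, j] += h * wgt
    return W


def band_powers(spectrum: EpochSpectrum,
                scheme: BandScheme = DEFAULT_BANDS) -> dict:
    """Absolute (μV²), relative (%) and maximum band power of one epoch.

    The relative denominator is the five-band sum only; an all-zero
    spectrum yields ``relative=None`` flagged degenerate rather than a
    division by zero.
    """
    W = band_weight_matrix(spectrum.frequencies, scheme)
    absolute = W @ spectrum.psd
    total = float(absolute.sum())
    out = {
        "epoch_index": spectrum.epoch_index,
        "channel": spectrum.channel,
        "absolute": dict(zip(scheme.names, absolute.tolist())),
        "max_power": float(absolute.max()),
        "degenerate": total <= 0.0,
    }
    if total > 0.0:
        out["relative"] = dict(
            zip(scheme.names, (100.0 * absolute / total).tolist())
        )
    else:
        out["relative"] = None
    return out


def spectrogram(recording: Recording, channel: str,
                window: float = 30.0, step: float = 5.0,
                reference: float = 1.0,
                nw: float = DEFAULT_NW,
                n_tapers: int = DEFAULT_N_TAPERS,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multitaper spectrogram in dB relative to ``reference`` μV.

    Windows of ``window`` seconds start every ``step`` seconds; values are
    ``10*log10(PSD / reference² Hz⁻¹)``.

    Returns
    -------
    times, frequencies, matrix
        Window start times (s), the frequency grid, and a
        ``(n_windows, n_freqs)`` dB matrix.
    """
    x = recording.channel(channel)  # KeyError if absent
    fs = recording.sample_rate
    n_win = int(round(window * fs))
    n_step = int(round(step * fs))
    if recording.n_samples < n_win:
        raise ValueError("recording shorter than one spectrogram window")
    starts = np.arange(0, recording.n_samples - n_win + 1, n_step)
    segs = np.stack([x[s:s + n_win] for s in starts])
    freqs, psd = multitaper_psd(segs, fs, nw=nw, n_tapers=n_tapers)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(psd / reference ** 2)
    return starts / fs, freqs, db


def label_epochs(records: pd.DataFrame, hypnogram: Hypnogram,
                 epoch_length: float = EPOCH_S) -> tuple[pd.DataFrame, int]:
    """Attach the containing 30-s scored stage to each analysis epoch.

    Analysis epoch ``i`` inherits the stage of scored epoch
    ``floor(i * epoch_length / 30)``.  Records outside the scored range are
    dropped; the drop count is returned alongside the labelled frame.
    """
    scored = (records["epoch_index"].to_numpy() * epoch_length
              // hypnogram.epoch_length).astype(int)
    covered = scored < len(hypnogram)
    n_dropped = int((~covered).sum())
    out = records.loc[covered].copy()
    stage_arr = np.array(hypnogram.stages, dtype=object)
    out["stage"] = stage_arr[scored[covered]]
    return out, n_dropped


def compute_band_powers(recording: Recording,
                        scheme: BandScheme = DEFAULT_BANDS,
                        epoch_length: float = EPOCH_S,
                        nw: float = DEFAULT_NW,
                        n_tapers: int = DEFAULT_N_TAPERS,
                        participant: str | int | None = None,
                        site_of: dict[str, str] | None = None,
                        ) -> pd.DataFrame:
    """Per (5-s epoch × channel) absolute/relative band powers for a recording.

    Returns a wide table with one row per epoch per channel and columns
    ``participant, channel, site, modality, epoch_index, abs_<band>...,
    rel_<band>..., max_power, degenerate``.  Channels are processed one at
    a time to bound memory at long durations.
    """
    ranges = segment_epochs(recording, epoch_length)
    names = scheme.names
    frames = []
    n_per = int(round(epoch_length * recording.sample_rate))
    n_epochs = len(ranges)
    for ci, label in enumerate(recording.channel_labels):
        x = recording.data[ci, : n_epochs * n_per].reshape(n_epochs, n_per)
        freqs, psd = multitaper_psd(x, recording.sample_rate,
                                    nw=nw, n_tapers=n_tapers)
        W = band_weight_matrix(freqs, scheme)
        absolute = psd @ W.T  # (n_epochs, n_bands)
        total = absolute.sum(axis=1)
        degenerate = total <= 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            relative = 100.0 * absolute / total[:, None]
        relative[degenerate] = np.nan
        df = pd.DataFrame({"epoch_index": np.arange(n_epochs)})
        df["channel"] = label
        df["modality"] = recording.channel_modality[ci]
        df["site"] = site_of.get(label, label) if site_of else label
        for bi, name in enumerate(names):
            df[f"abs_{name}"] = absolute[:, bi]
        for bi, name in enumerate(names):
            df[f"rel_{name}"] = relative[:, bi]
        df["max_power"] = absolute.max(axis=1)
        df["degenerate"] = degenerate
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if participant is not None:
        out.insert(0, "participant", participant)
    return out
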