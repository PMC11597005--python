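"""Synthetic dual-modality sleep recordings with known ground truth.

Generates paired focal (TCRE-like) and conventional (EEG-like) scalp
recordings plus a hypnogram, with the statistical structure the analysis
downstream must detect:

* stage-dependent band spectra (a 1/f background plus oscillatory bumps
  whose per-band shares follow a per-stage template),
* broadband (>15 Hz) muscle artifact — a tonic stage-dependent floor and
  sparse high-amplitude bursts — coupled more strongly into the
  conventional channels than the focal ones,
* spatial mixing of latent per-site cortical sources through a Gaussian
  distance kernel that is broad for conventional EEG and near-identity
  for the focal modality,
* optional site-restricted ("focal") oscillations, e.g. a right-parietal
  beta source.

Everything is reproducible bit-for-bit under a fixed seed.  The module
also provides a records-level simulator (:func:`simulate_band_power_records`)
for calibration studies of the statistics layer that do not need signal
synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_SITES, Hypnogram, Recording, STAGES, default_montage
from .spectral import BandScheme, DEFAULT_BANDS

__all__ = [
    "SynthConfig",
    "FocalFeature",
    "ConfigError",
    "default_templates",
    "generate_hypnogram",
    "generate_recording_pair",
    "simulate_band_power_records",
    "DEFAULT_TRANSITIONS",
]


class ConfigError(ValueError):
    """Inconsistent synthetic-generator configuration."""


# Per-stage relative-power targets (%) for the conventional-EEG template.
# Chosen to sit inside the canonical band structure of adult sleep:
# delta dominant and growing W -> N3, sigma elevated in N2 (spindles),
# alpha strongest in relaxed wake.
_EEG_TEMPLATE: dict[str, dict[str, float]] = {
    "W":   {"delta": 30.0, "theta": 15.0, "alpha": 25.0, "sigma": 8.0, "beta": 22.0},
    "N1":  {"delta": 45.0, "theta": 25.0, "alpha": 12.0, "sigma": 6.0, "beta": 12.0},
    "N2":  {"delta": 55.0, "theta": 18.0, "alpha": 8.0, "sigma": 11.0, "beta": 8.0},
    "N3":  {"delta": 75.0, "theta": 10.0, "alpha": 5.0, "sigma": 5.0, "beta": 5.0},
    "REM": {"delta": 45.0, "theta": 22.0, "alpha": 13.0, "sigma": 6.0, "beta": 14.0},
}

# Oscillatory centre frequencies (Hz), one per band, inside the band edges.
_CENTRES = {"delta": 1.5, "theta": 6.0, "alpha": 10.0, "sigma": 13.5, "beta": 22.0}

# Overall signal scale per stage (μV RMS): slow-wave sleep is the largest
# and slowest, wake the smallest and fastest.  The scale is set so that
# typical per-band powers sit below the 400 μV² noisy-epoch criterion —
# the regime the analysis operates in, where only artifact bursts and the
# extreme clean tail exceed the threshold.
_STAGE_RMS = {"W": 8.0, "N1": 9.0, "N2": 11.0, "N3": 16.0, "REM": 9.0}

# Tonic muscle-artifact floor per stage (μV RMS at unit coupling): highest
# in wake, suppressed through NREM, near-atonia in REM.
_EMG_TONIC = {"W": 2.0, "N1": 1.2, "N2": 0.8, "N3": 0.5, "REM": 0.7}

# Probability that a given 5-s window contains a movement burst.
_EMG_BURST_RATE = {"W": 0.05, "N1": 0.02, "N2": 0.01, "N3": 0.005, "REM": 0.01}

#: First-order 30-s stage-transition probabilities (rows/cols in STAGES
#: order) of a plausible overnight chain: sleep consolidates through N2,
#: N3 is sticky, REM recurs from N2.
DEFAULT_TRANSITIONS = np.array([
    #  W     N1    N2     N3    REM
    [0.950, 0.040, 0.010, 0.000, 0.000],   # W
    [0.050, 0.800, 0.140, 0.000, 0.010],   # N1
    [0.010, 0.020, 0.900, 0.050, 0.020],   # N2
    [0.005, 0.005, 0.060, 0.920, 0.010],   # N3
    [0.010, 0.020, 0.050, 0.000, 0.920],   # REM
])


def default_templates(tcre_delta_boost: float = 5.0,
                      ) -> dict[str, dict[str, dict[str, float]]]:
    """Per-modality, per-stage band-share templates (%, summing to 100).

    The focal template equals the conventional one with ``tcre_delta_boost``
    percentage points moved into delta (the remaining bands shrink
    proportionally), reproducing the headline contrast the analysis must
    recover: focal recordings relatively richer in delta, poorer in the
    faster bands.
    """
    eeg = {s: dict(t) for s, t in _EEG_TEMPLATE.items()}
    tcre = {}
    for stage, shares in eeg.items():
        delta = shares["delta"] + tcre_delta_boost
        rest = 100.0 - delta
        rest0 = 100.0 - shares["delta"]
        tcre[stage] = {
            b: (delta if b == "delta" else v * rest / rest0)
            for b, v in shares.items()
        }
    return {"EEG": eeg, "TCRE": tcre}


@dataclass(frozen=True)
class FocalFeature:
    """A site-restricted oscillation: boost one band's share at one source.

    ``gain`` multiplies the band's template share by ``1 + gain`` at the
    named latent source (shares are then renormalised, so total source
    power is unchanged).  ``stages=None`` applies in every stage.
    """

    site: str
    band: str
    gain: float = 1.0
    stages: tuple[str, ...] | None = None


@dataclass
class SynthConfig:
    """Configuration of the paired-recording generator.

    Defaults describe a full-night study: 9 h at 512 Hz over 18 scalp
    sites, conventional channels mixing neighbouring sources broadly and
    receiving muscle artifact at full gain, focal channels nearly local
    with attenuated artifact coupling.
    """

    duration: float = 32_400.0          # s (9 h)
    sample_rate: float = 512.0          # Hz
    sites: tuple[str, ...] = DEFAULT_SITES
    seed: int = 0

    # hypnogram model: a fixed sequence wins over the Markov chain
    stage_sequence: tuple[str, ...] | None = None
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial_stage: str = "W"

    # spectral content
    templates: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=default_templates)
    stage_rms: Mapping[str, float] = field(default_factory=lambda: dict(_STAGE_RMS))
    one_over_f_exponent: float = 1.0
    oscillation_fraction: float = 0.5   # share of band power in the bump
    focal_features: tuple[FocalFeature, ...] = (
        FocalFeature("P4", "beta", gain=1.0),
        FocalFeature("O1", "alpha", gain=1.0, stages=("REM",)),
        FocalFeature("O2", "alpha", gain=1.0, stages=("REM",)),
    )

    # muscle artifact
    emg_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"EEG": 1.0, "TCRE": 0.25})
    emg_tonic_rms: Mapping[str, float] = field(
        default_factory=lambda: dict(_EMG_TONIC))
    emg_burst_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(_EMG_BURST_RATE))
    emg_burst_rms: float = 60.0         # μV at unit coupling
    emg_low_hz: float = 15.0
    emg_high_hz: float = 100.0

    # spatial mixing kernel width per modality (unit-disc distance)
    mixing_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"EEG": 0.45, "TCRE": 0.08})

    # between-participant variability
    participant_share_sd: float = 1.0   # pp jitter on band shares
    participant_rms_sd: float = 0.10    # lognormal sigma on stage RMS

    crossfade: float = 0.5              # s, epoch-boundary fade
    band_scheme: BandScheme = DEFAULT_BANDS

    def __post_init__(self) -> None:
        # coerce plain-data forms (e.g. from YAML configs)
        self.sites = tuple(self.sites)
        self.focal_features = tuple(
            FocalFeature(**f) if isinstance(f, dict) else f
            for f in self.focal_features)
        if self.stage_sequence is not None:
            self.stage_sequence = tuple(self.stage_sequence)
        if any(g < 0 for g in self.emg_coupling.values()):
            raise ConfigError("emg couplings must be >= 0")
        for mod, per_stage in self.templates.items():
            for stage, shares in per_stage.items():
                total = sum(shares.values())
                if abs(total - 100.0) > 1e-6:
                    raise ConfigError(
                        f"template {mod}/{stage} shares sum to {total}, not 100")
        for feat in self.focal_features:
            if feat.site not in self.sites:
                raise ConfigError(
                    f"focal feature site {feat.site!r} not among config sites")
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.shape != (5, 5) or np.any(T < 0) or \
                np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-8):
            raise ConfigError("transition matrix rows must be >= 0 and sum to 1")

    @property
    def n_scored(self) -> int:
        return int(self.duration // 30.0)


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

def generate_hypnogram(config: SynthConfig) -> Hypnogram:
    """Stage sequence of ``duration/30`` epochs, fixed or first-order Markov."""
    n = config.n_scored
    if config.stage_sequence is not None:
        seq = list(config.stage_sequence)
        if len(seq) < n:
            raise ConfigError(
                f"fixed stage sequence length {len(seq)} shorter than "
                f"{n} scored epochs")
        return Hypnogram(stages=seq[:n])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    T = np.asarray(config.transition_matrix, dtype=float)
    idx = {s: i for i, s in enumerate(STAGES)}
    state = idx[config.initial_stage]
    stages = []
    for _ in range(n):
        stages.append(STAGES[state])
        state = rng.choice(5, p=T[state])
    return Hypnogram(stages=stages)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _band_shape(f: np.ndarray, lo: float, hi: float, centre: float,
                alpha: float, osc_frac: float) -> np.ndarray:
    """Unnormalised in-band PSD shape: 1/f^alpha floor + Gaussian bump."""
    inband = (f >= lo) & (f < hi)
    shape = np.zeros_like(f)
    fsafe = np.maximum(f, 1e-6)
    bg = np.where(inband, fsafe ** (-alpha), 0.0)
    if bg.sum() > 0:
        bg /= bg.sum()
    sig = (hi - lo) / 6.0
    bump = np.where(inband, np.exp(-0.5 * ((f - centre) / sig) ** 2), 0.0)
    if bump.sum() > 0:
        bump /= bump.sum()
    shape = (1.0 - osc_frac) * bg + osc_frac * bump
    return shape


def _source_amplitude_spectra(config: SynthConfig, modality: str,
                              shares_by_stage: dict[str, dict[str, float]],
                              n_seg: int) -> dict[tuple[str, str], np.ndarray]:
    """rfft amplitude (|Z_k|) per (stage, site) for one modality."""
    fs = config.sample_rate
    f = np.fft.rfftfreq(n_seg, 1.0 / fs)
    df = fs / n_seg
    out = {}
    scheme = config.band_scheme
    for stage in STAGES:
        var_total = config.stage_rms[stage] ** 2
        base_shares = shares_by_stage[stage]
        for site in config.sites:
            shares = dict(base_shares)
            for feat in config.focal_features:
                if feat.site == site and feat.band in shares and (
                        feat.stages is None or stage in feat.stages):
                    shares[feat.band] *= (1.0 + feat.gain)
            total = sum(shares.values())
            shares = {b: 100.0 * v / total for b, v in shares.items()}
            S = np.zeros_like(f)
            for name, lo, hi in scheme.bands:
                shape = _band_shape(f, lo, hi, _CENTRES[name],
                                    config.one_over_f_exponent,
                                    config.oscillation_fraction)
                band_var = var_total * shares[name] / 100.0
                # shape sums to 1 over bins -> PSD with integral band_var
                S += shape * band_var / df
            amp = n_seg * np.sqrt(S * df / 2.0)
            amp[0] = 0.0
            if n_seg % 2 == 0:
                amp[-1] = 0.0
            out[(stage, site)] = amp
    return out


def _overlap_add(segments_fn, n_scored: int, seg_len: int, body_len: int,
                 fade: int, total: int, out: np.ndarray) -> None:
    """Accumulate cross-faded per-epoch segments into ``out`` (1-D)."""
    if fade > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(fade) / fade))
    for e in range(n_scored):
        seg = segments_fn(e)
        w = np.ones(seg_len)
        if fade > 0:
            if e > 0:
                w[:fade] = ramp
            w[body_len:body_len + fade] = ramp[::-1]
        lo = e * body_len
        hi = min(lo + seg_len, total)
        out[lo:hi] += (seg * w)[: hi - lo]


def _flat_band_amplitude(n_seg: int, fs: float, lo: float, hi: float,
                         rms: float) -> np.ndarray:
    f = np.fft.rfftfreq(n_seg, 1.0 / fs)
    df = fs / n_seg
    mask = (f >= lo) & (f <= hi)
    S = np.zeros_like(f)
    if mask.sum() > 0:
        S[mask] = rms ** 2 / (mask.sum() * df)
    amp = n_seg * np.sqrt(S * df / 2.0)
    amp[0] = 0.0
    if n_seg % 2 == 0:
        amp[-1] = 0.0
    return amp


def _mixing_weights(config: SynthConfig, modality: str) -> np.ndarray:
    """Gaussian distance kernel over montage coordinates, power-preserving.

    Rows are L2-normalised: sources are phase-independent, so a channel's
    expected power is the Σw²-weighted sum of source powers, and unit row
    energy keeps channel power equal to (equal-power) source power in
    both modalities.
    """
    montage = default_montage(config.sites)
    xy = np.array([montage.positions[s] for s in config.sites])
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    sigma = config.mixing_sigma[modality]
    W = np.exp(-d2 / (2.0 * sigma ** 2))
    return W / np.sqrt((W ** 2).sum(axis=1, keepdims=True))


def generate_recording_pair(config: SynthConfig,
                            hypnogram: Hypnogram | None = None,
                            ) -> tuple[Recording, Recording]:
    """Synthesize simultaneous focal (TCRE) and conventional (EEG) recordings.

    Per 30-s scored epoch and site, a latent cortical source is drawn in
    the frequency domain (deterministic amplitude from the stage template,
    uniform random phase) and cross-faded at epoch boundaries.  Focal
    channels are the narrow-kernel mix of sources; conventional channels
    the broad-kernel mix.  A shared per-site muscle-artifact process
    (tonic floor plus scheduled bursts, band-limited to
    ``[emg_low_hz, emg_high_hz]``) is added to each channel scaled by the
    modality's coupling gain.

    Returns ``(tcre_recording, eeg_recording)``; channel labels are the
    site name for the focal modality and ``"<site>-M1"`` for the
    conventional one.
    """
    if hypnogram is None:
        hypnogram = generate_hypnogram(config)
    n_scored = config.n_scored
    if len(hypnogram) < n_scored:
        raise ConfigError("hypnogram does not cover the configured duration")
    fs = config.sample_rate
    body = int(round(30.0 * fs))
    fade = int(round(config.crossfade * fs))
    seg_len = body + fade
    total = n_scored * body
    n_sites = len(config.sites)

    ss = np.random.SeedSequence([config.seed, 1])
    rng_jitter, rng_emg, rng_tcre, rng_eeg = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    # participant-level jitter, shared across modalities
    share_jit = {
        stage: rng_jitter.normal(0.0, config.participant_share_sd,
                                 len(config.band_scheme.names))
        for stage in STAGES
    }
    rms_factor = {
        stage: float(np.exp(rng_jitter.normal(0.0, config.participant_rms_sd)))
        for stage in STAGES
    }
    cfg = replace(
        config,
        stage_rms={s: config.stage_rms[s] * rms_factor[s] for s in STAGES},
    )

    def jittered_shares(modality: str) -> dict[str, dict[str, float]]:
        names = config.band_scheme.names
        out = {}
        for stage in STAGES:
            raw = np.array([config.templates[modality][stage][b] for b in names])
            raw = np.maximum(raw + share_jit[stage], 0.5)
            raw *= 100.0 / raw.sum()
            out[stage] = dict(zip(names, raw))
        return out

    stages_used = [hypnogram[e] for e in range(n_scored)]

    # shared muscle artifact per site (unit coupling)
    emg = np.zeros((n_sites, total))
    tonic_amp = {
        stage: _flat_band_amplitude(seg_len, fs, config.emg_low_hz,
                                    config.emg_high_hz,
                                    config.emg_tonic_rms[stage])
        for stage in STAGES
    }
    nbins = seg_len // 2 + 1
    for si in range(n_sites):
        def tonic_segment(e, si=si):
            phases = rng_emg.uniform(0.0, 2.0 * np.pi, nbins)
            z = tonic_amp[stages_used[e]] * np.exp(1j * phases)
            return np.fft.irfft(z, seg_len)
        _overlap_add(tonic_segment, n_scored, seg_len, body, fade, total,
                     emg[si])
    # bursts: per 5-s window, Bernoulli by the stage's burst rate
    w5 = int(round(5.0 * fs))
    n5 = total // w5
    burst_amp = _flat_band_amplitude(w5, fs, config.emg_low_hz,
                                     config.emg_high_hz, config.emg_burst_rms)
    edge = int(round(0.1 * fs))
    taper = np.ones(w5)
    if edge > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
        taper[:edge] = r
        taper[-edge:] = r[::-1]
    nb5 = w5 // 2 + 1
    for si in range(n_sites):
        for wi in range(n5):
            stage = stages_used[int(wi * 5.0 // 30.0)]
            hit = rng_emg.random() < config.emg_burst_rate[stage]
            if hit:
                phases = rng_emg.uniform(0.0, 2.0 * np.pi, nb5)
                burst = np.fft.irfft(burst_amp * np.exp(1j * phases), w5)
                emg[si, wi * w5:(wi + 1) * w5] += burst * taper

    recordings = {}
    for modality, rng_mod in (("TCRE", rng_tcre), ("EEG", rng_eeg)):
        shares = jittered_shares(modality)
        amps = _source_amplitude_spectra(cfg, modality, shares, seg_len)
        sources = np.zeros((n_sites, total))
        for si, site in enumerate(config.sites):
            def segment(e, site=site):
                phases = rng_mod.uniform(0.0, 2.0 * np.pi, nbins)
                z = amps[(stages_used[e], site)] * np.exp(1j * phases)
                return np.fft.irfft(z, seg_len)
            _overlap_add(segment, n_scored, seg_len, body, fade, total,
                         sources[si])
        W = _mixing_weights(config, modality)
        channels = W @ sources
        del sources
        channels += config.emg_coupling[modality] * emg
        suffix = "" if modality == "TCRE" else "-M1"
        recordings[modality] = Recording(
            channel_labels=[f"{s}{suffix}" for s in config.sites],
            channel_modality=[modality] * n_sites,
            sample_rate=fs,
            data=channels,
        )
    return recordings["TCRE"], recordings["EEG"]


def _component_transfer_matrix(config: SynthConfig,
                               nw: float, n_tapers: int,
                               epoch_length: float,
                               nfft: int = 1 << 15) -> np.ndarray:
    """Expected measured band powers per unit true component power.

    Row i of the returned ``(n_bands + 1, n_bands)`` matrix gives, for one
    unit of power in spectral component i (the five per-band source
    shapes, then the flat muscle-artifact shape), the expected power a
    DPSS-multitaper estimate assigns to each analysis band: the true
    component spectrum convolved with the average taper spectral window,
    then integrated over the bands.  Captures edge leakage (e.g. delta
    power smeared below the 0.5 Hz band edge is lost).
    """
    from scipy.signal.windows import dpss

    from .spectral import band_weight_matrix

    fs = config.sample_rate
    n = int(round(epoch_length * fs))
    tapers = dpss(n, nw, n_tapers)
    V = np.fft.fft(tapers, nfft, axis=-1)
    H = (np.abs(V) ** 2).mean(axis=0)        # two-sided window, fftfreq order
    df = fs / nfft
    H /= H.sum() * df
    freqs = np.fft.fftfreq(nfft, 1.0 / fs)
    absf = np.abs(freqs)
    scheme = config.band_scheme

    shapes = []
    for name, lo, hi in scheme.bands:
        s = _band_shape(absf, lo, hi, _CENTRES[name],
                        config.one_over_f_exponent,
                        config.oscillation_fraction)
        shapes.append(s)
    emg = ((absf >= config.emg_low_hz)
           & (absf <= config.emg_high_hz)).astype(float)
    shapes.append(emg)

    pos = freqs >= 0
    f_pos = freqs[pos]
    order = np.argsort(f_pos)
    Wb = band_weight_matrix(f_pos[order], scheme)
    FH = np.fft.fft(H)
    B = np.zeros((len(shapes), len(scheme.bands)))
    for i, s in enumerate(shapes):
        total = s.sum() * df
        if total <= 0:
            continue
        s = s / total                         # unit power, two-sided grid
        smeared = np.real(np.fft.ifft(np.fft.fft(s) * FH)) * df
        one_sided = 2.0 * smeared[pos][order]
        one_sided[0] *= 0.5
        B[i] = Wb @ one_sided
    return B


def expected_relative_power(config: SynthConfig, modality: str,
                            estimator: tuple[float, int, float] | None = None,
                            include_bursts: bool = False,
                            ) -> dict[str, dict[str, float]]:
    """Analytic expected channel-mean relative power (%) per stage/band.

    Ground truth for the generator, independent of signal synthesis:
    channel band power is the Σw²-weighted mix of per-site source band
    powers (template shares with focal-feature adjustments) plus the
    tonic muscle artifact at the modality's coupling gain, and, with
    ``include_bursts``, the scheduled burst artifact (relevant when
    flagging does not remove a modality's bursts).  With ``estimator``
    = (nw, n_tapers, epoch_length) the expectation runs through the
    multitaper transfer matrix, accounting for spectral-window leakage;
    without it the true (un-smeared) band powers are used.
    """
    W2 = _mixing_weights(config, modality) ** 2
    scheme = config.band_scheme
    names = scheme.names
    n_bands = len(names)
    if estimator is not None:
        B = _component_transfer_matrix(config, *estimator)
    else:
        B = np.zeros((n_bands + 1, n_bands))
        B[:n_bands, :n_bands] = np.eye(n_bands)
        emg_span = config.emg_high_hz - config.emg_low_hz
        for bi, (_, lo, hi) in enumerate(scheme.bands):
            overlap = max(0.0, min(hi, config.emg_high_hz)
                          - max(lo, config.emg_low_hz))
            B[n_bands, bi] = overlap / emg_span
    gain = config.emg_coupling[modality]
    out: dict[str, dict[str, float]] = {}
    for stage in STAGES:
        var = config.stage_rms[stage] ** 2
        P = np.zeros((len(config.sites), n_bands))
        for si, site in enumerate(config.sites):
            shares = dict(config.templates[modality][stage])
            for feat in config.focal_features:
                if feat.site == site and (feat.stages is None
                                          or stage in feat.stages):
                    shares[feat.band] *= (1.0 + feat.gain)
            total = sum(shares.values())
            P[si] = [var * shares[b] / total for b in names]
        tonic_var = (gain * config.emg_tonic_rms[stage]) ** 2
        C_clean = (W2 @ P) @ B[:n_bands] + tonic_var * B[n_bands]
        rel = 100.0 * C_clean / C_clean.sum(axis=1, keepdims=True)
        if include_bursts:
            # shares are averaged per epoch, so burst epochs enter as a
            # mixture component at the burst rate, not as pooled power
            burst_var = (gain * config.emg_burst_rms) ** 2
            C_burst = C_clean + burst_var * B[n_bands]
            rel_burst = 100.0 * C_burst / C_burst.sum(axis=1, keepdims=True)
            r = config.emg_burst_rate[stage]
            rel = (1.0 - r) * rel + r * rel_burst
        out[stage] = dict(zip(names, rel.mean(axis=0)))
    return out


# ---------------------------------------------------------------------------
# Records-level simulator for the statistics layer
# ---------------------------------------------------------------------------

def simulate_band_power_records(
    n_participants: int = 10,
    epochs_per_cell: int = 50,
    stages: Sequence[str] = STAGES,
    base_shares: Mapping[str, Mapping[str, float]] | None = None,
    modality_offset: Mapping[str, float] | None = None,
    participant_sd: float = 2.0,
    epoch_sd: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate epoch-level relative-power records without signal synthesis.

    For each participant × modality × stage cell, ``epochs_per_cell``
    epochs are drawn per band as ``share + participant_intercept +
    epoch_noise``; the focal modality additionally receives
    ``modality_offset[band]`` percentage points.  Shares are *not*
    renormalised across bands, so an injected offset is exactly the
    expected modality difference for that band — the property the
    mixed-model recovery and null-calibration oracles need.  Intended for
    statistical calibration only, not as a stand-in for the signal-level
    generator.
    """
    rng = np.random.default_rng(seed)
    if base_shares is None:
        base_shares = _EEG_TEMPLATE
    bands = list(next(iter(base_shares.values())).keys())
    modality_offset = dict(modality_offset or {})
    rows = []
    for p in range(n_participants):
        intercept = {b: rng.normal(0.0, participant_sd) for b in bands}
        for modality in ("EEG", "TCRE"):
            for stage in stages:
                mu = {
                    b: base_shares[stage][b] + intercept[b]
                    + (modality_offset.get(b, 0.0) if modality == "TCRE" else 0.0)
                    for b in bands
                }
                noise = rng.normal(0.0, epoch_sd, (epochs_per_cell, len(bands)))
                for e in range(epochs_per_cell):
                    row = {
                        "participant": f"P{p:02d}",
                        "modality": modality,
                        "stage": stage,
                        "channel": "Cz" if modality == "TCRE" else "Cz-M1",
                        "site": "Cz",
                        "epoch_index": e,
                        "degenerate": False,
                    }
                    for bi, b in enumerate(bands):
                        row[f"rel_{b}"] = mu[b] + noise[e, bi]
                    rows.append(row)
    return pd.DataFrame(rows)
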