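# Methods

This note documents the models, parameters and numerical choices behind
`tcresleep`, what the synthetic generator does and does not emulate, and
the known limitations.

## Spectral estimation

Each channel is cut into non-overlapping 5-s epochs from t = 0; a trailing
partial epoch is discarded (no padding rule exists for partial epochs, and
half-open `[iL, (i+1)L)` indexing keeps the 5-s ↔ 30-s alignment exact:
analysis epoch *i* belongs to scored epoch `⌊5i/30⌋`).

The PSD is a DPSS multitaper estimate: time-bandwidth product NW = 4 with
2·NW − 1 = 7 tapers on each 5-s epoch (half-bandwidth 0.8 Hz), the
standard quantitative-EEG compromise between variance and leakage; both
are configurable. Tapers are unit-energy, the average across tapers is
unweighted, and the one-sided PSD in μV²/Hz satisfies Parseval (the
trapezoidal integral matches the signal variance; verified on white noise
to 5 % over 200 epochs). Each epoch is mean-detrended before tapering so a
DC offset cannot leak into delta. A unit test cross-checks the estimator
against MNE's `psd_array_multitaper`, which differs only in eigenvalue-
weighting the taper average (≤ a few percent pointwise).

Band powers integrate the PSD over delta [0.5, 4.5), theta [4.5, 8),
alpha [8, 12), sigma [12, 15), beta [15, 32) Hz by a trapezoidal rule with
linear interpolation at band edges, so adjacent bands share their boundary
ordinate and band powers are exactly additive over the 0.5–32 Hz span.
Relative power divides by the five-band sum only (not total Nyquist
power). An all-zero epoch would make that ratio undefined; such epochs are
flagged `degenerate`, carry missing relative powers, and are excluded from
statistics with their count logged — real signals never hit this, but the
null generator config does.

The per-epoch **maximum power** used for artifact detection is the maximum
over the five absolute band powers, because the thresholds are stated in
μV² (band-power units), not μV²/Hz; a maximum-PSD-bin variant would change
units. Spectrograms use 30-s windows every 5 s, in dB re 1 μV
(`10·log10(S / 1 μV²Hz⁻¹)`).

## Noisy-epoch characterisation

Max powers are mapped through `log10(x + c)` with c = 0.01 μV² (guards
against zeros while distorting values ≥ 1 μV² negligibly), then
robust-scaled: subtract the median, divide by the IQR (Q3 − Q1,
linear-interpolation quantiles — the convention of the reference
robust-scaler implementation; agreement is tested to 1e-12). One scaler is
fitted per modality, pooled over channels and participants; per-site
fitting is available by config (`noise_fit_scope: per_channel`) since the
pooling scope is a genuinely open choice, as is whether wake epochs enter
the fit (they do here).

The conventional-EEG threshold (400 μV², a published amplitude criterion
for sleep EEG, configurable) is mapped into the focal modality by
inverting the focal scaler at the conventional threshold's standardised
position: `10^(z·IQR_t + m_t) − c`. This is the identity for identical
scalers, strictly increasing in the reference threshold, and flagging is
invariant to whether the comparison happens in raw or scaled space (the
transform is strictly monotone). An epoch is noisy iff its max power
**strictly** exceeds the threshold; the boundary case is declared and
tested. Epochs flagged noisy are excluded from the stage statistics by
default (configurable), with counts in the run manifest — whether such
exclusion should precede the mixed models is not externally fixed, so it
is a switch.

## Stage statistics

Stage summaries report, per band × modality × stage, the mean of
participant means with the between-participant standard error
(`sd/√n`, 0 when a single participant contributes) — the group-mean
error-bar convention, deliberately not the pooled-epoch SE.

The mixed model per band is `rel ~ signal_type * stage` with a random
intercept per participant, REML estimation and Wald inference (no
Satterthwaite/Kenward–Roger correction). By default it is fitted on
participant × modality × stage cell means ("aggregated" mode): at desk
scale the epoch count per cell is large, cell means are nearly Gaussian,
and the fit is orders of magnitude faster; epoch-level fitting is a flag.
Per-stage TCRE − EEG contrasts are the modality main effect plus the
stage's interaction coefficient, with covariance-propagated SEs. Contrast
p-values are unadjusted by default (a Bonferroni option exists). Singular
or non-converged fits are returned flagged, never raised; degenerate data
(all observations identical) produce a flagged NaN result.

Null calibration: with zero injected modality effect, the fraction of
contrast p-values below 0.05 over 200 seeded replicates is checked against
[0.03, 0.075] — the binomial Monte-Carlo band around 5 % for ~1000 draws,
widened slightly because Wald z-inference carries no small-sample df
correction.

## Site comparison

Per site, noisy/clean counts of the two modalities form a 2×2 table
(marginal counts, not epoch-paired, so the modalities may contribute
different epoch totals). OR = ad/bc; the CI is Woolf's logit interval with
z at the two-sided level α/n_sites (α = 0.05, n_sites defaulting to the
18 analysed sites); significance is the two-sided Fisher exact p (sum of
hypergeometric probabilities ≤ the observed table's), compared against the
Bonferroni-adjusted α. With a zero cell the OR is reported as 0/∞ and
flagged rather than corrected (the exact p needs no correction); a
Haldane–Anscombe +0.5 variant is available. The exact test is verified
against full hypergeometric enumeration for tables with total ≤ 40.

Topography outputs are per-site mean relative-power matrices; optional
grids use inverse-distance weighting (a convex combination, so grid values
never leave the site-value range) on a unit-disc projection of the 10–20
positions. Spherical-spline rendering is intentionally out of scope.

## Synthetic generator

The generator emulates a dual-modality overnight study: by default 9 h at
512 Hz over 18 sites (Fpz, Fp1, Fp2, F7, F3, Fz, F4, F8, T3, C3, Cz, C4,
T4, P3, Pz, P4, O1, O2 — the published site list is not exhaustive, so
this set is a stand-in consistent with the named sites), with a
first-order Markov hypnogram (sticky W and N3, REM recurring from N2) or a
fixed stage sequence.

Per 30-s scored epoch and site, a latent source is synthesised in the
frequency domain: each band's target share is realised as a 1/f (α = 1)
in-band floor plus a Gaussian oscillatory bump (centres 1.5, 6, 10, 13.5,
22 Hz — inside the band edges; bump fraction 0.5), with deterministic
amplitudes and uniform random phases, cross-faded 0.5 s at epoch
boundaries. Deterministic amplitudes make per-epoch band powers tight
around the template, which the tests rely on. Per-stage template shares
follow canonical adult sleep (delta growing W → N3, sigma peaking in N2);
the focal template moves +5 pp into delta (other bands shrink
proportionally) — the modality contrast the analysis must recover. Stage
RMS runs 8 μV (W) to 16 μV (N3): the scale is set so typical band powers
sit below the 400 μV² criterion, the regime the threshold method operates
in, where only artifact bursts and the extreme clean tail are flagged.

Muscle artifact is flat-spectrum noise band-limited to 15–100 Hz (its
beta-range footprint is what makes wake EEG "fast"): a tonic stage floor
(2 μV RMS in W down to 0.5 μV in N3) plus 60 μV RMS bursts occupying whole
5-s windows at stage-dependent rates (5 % in W down to 0.5 % in N3). One
artifact process per site feeds both modalities, scaled by the coupling
gain — 1.0 for conventional channels, 0.25 for focal ones. The 0.25 ratio
is a free parameter, not an empirical attenuation measurement. Spatial
mixing is a Gaussian distance kernel over montage coordinates
(σ = 0.45 disc units for conventional, 0.08 ≈ identity for focal) with
L2-normalised rows: sources are phase-independent, so unit row energy
preserves channel power while still blending neighbouring sources for the
conventional modality. Optional focal features (default: a right-parietal
beta source, occipital REM alpha) boost one band's share at one latent
source. Between-participant variability: ±1 pp share jitter (shared
across modalities, as a participant trait) and 10 % lognormal RMS jitter.
Everything is reproducible bit-for-bit from the seed, and streams are
separated so that, e.g., changing the conventional coupling gain leaves
the focal channels bit-identical.

An analytic expectation oracle (`expected_relative_power`) computes the
generator's ground-truth channel-mean relative powers: mixed source band
powers plus in-band artifact, optionally pushed through the multitaper
transfer matrix (each component spectrum convolved with the average DPSS
spectral window, then band-integrated) to account for edge leakage — at
NW = 4 on 5-s epochs roughly 2 pp of a 35 % delta share smears below the
0.5 Hz edge. Burst epochs enter as a mixture component at the burst rate
because shares are averaged per epoch. The oracle matches measured shares
to a few tenths of a percentage point and anchors the parameter-recovery
acceptance test.

**What the generator does not emulate:** real head-volume conduction (the
kernel is not a forward model), spindle/K-complex morphology, eye/cardiac
artifact, non-stationarity within a stage epoch, arousals, and reference
effects of specific derivations. Passing tests therefore demonstrate that
the pipeline recovers known spectral, artifact and spatial structure from
signal level upward — not that any physiological claim holds in real
recordings.

## Problem sizes

Tests run on scaled-down data chosen as the package's CI defaults: unit
tests use minutes-long, six-site recordings; the parameter-recovery
acceptance test and `scripts/acceptance.py` use an 8-participant × 1-h
× 18-site cohort, and the full-night epoch-arithmetic check generates one
9-h two-site recording. The full 9-h × 18-site default is supported but
needs several GB of memory and a few minutes per participant.

## Known limitations

- EDF writing is 16-bit with a symmetric physical range per channel;
  dynamic range beyond ~90 dB is quantised away. EDF+ annotations are not
  supported.
- The hypnogram dialects (stage-per-line text, simple CSV) are stand-ins;
  vendor export schemas vary and should be converted upstream.
- Wald inference without df correction is slightly anticonservative for
  very small cohorts; the aggregated default keeps cell counts high.
- Per-participant stratified odds ratios (rather than pooled counts) are
  noted as an extension; pooled counts are implemented.
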