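# tcresleep

Quantitative comparison of **focal** sleep-EEG recordings — tripolar
concentric ring electrodes (TCRE), whose differential output approximates
the local surface Laplacian — against **conventional** referenced EEG
recorded simultaneously from the same 10–20 scalp sites.

The package is for sleep and clinical-neurophysiology researchers who want
to quantify, on dual-modality polysomnography, (i) how relative spectral
power differs between a focal and a conventional derivation across sleep
stages, and (ii) how often each modality loses 5-s epochs to muscle/movement
artifact. Because raw dual-modality sleep recordings are rarely shareable,
the package ships a seeded synthetic generator that produces paired
recordings with known ground truth, so the entire analysis chain is testable
end to end.

## The analysis

For each channel, non-overlapping 5-s epochs get a DPSS-multitaper power
spectral density `S(f)` (time-bandwidth NW = 4, 7 tapers). Absolute band
power is the area under `S(f)` over the five canonical bands

> delta [0.5, 4.5) · theta [4.5, 8) · alpha [8, 12) · sigma [12, 15) · beta [15, 32) Hz

and relative power is each band as a percentage of the five-band sum, so the
five values of an epoch always total 100 %. Each 5-s epoch inherits the
stage (W, N1, N2, N3, REM) of its containing 30-s scored epoch.

**Noisy-epoch characterisation.** An epoch is noisy when its maximum band
power `x` exceeds a modality-specific threshold. The conventional-EEG
threshold is a fixed criterion (default 400 μV²). The focal equivalent is
derived by robust quantile matching: with `z(x) = (log10(x + 0.01) − m) / IQR`
fitted per modality, the focal threshold is `z⁻¹_TCRE(z_EEG(400))`. Per site,
the 2×2 noisy/clean counts of the two modalities give an odds ratio with a
Woolf confidence interval at a Bonferroni-adjusted level and a two-sided
Fisher exact p.

**Stage statistics.** Per band, a linear mixed model (REML)

> `rel ~ signal_type * stage + (1 | participant)`

tests signal-type and stage effects; per-stage TCRE − EEG contrasts are Wald
tests on linear combinations of the fixed effects. Topography outputs are
per-site relative-power matrices (optionally interpolated onto the unit disc
by inverse-distance weighting).

## Worked example

```python
from tcresleep import PipelineConfig, run_pipeline

config = PipelineConfig(
    synthetic={"n_participants": 4, "duration": 900.0},
    outdir="demo_out", seed=42, log_level="WARNING")
report = run_pipeline(config)

print(report.outdir.joinpath("summary.txt").read_text())
delta = report.contrasts.query("band == 'delta'")
print(delta[["stage", "estimate", "se", "p"]].round(3).to_string(index=False))
```

prints

```
tcresleep run summary
======================

TCRE: 12960 epochs in, 12960 labelled, 0 dropped, 2 noisy (0.02%)
EEG: 12960 epochs in, 12960 labelled, 0 dropped, 428 noisy (3.30%)
EEG threshold: 400.0 uV^2; derived focal equivalents: {'pooled': 378.9194904304213}

stage summary rows: 40
sites with adjusted-significant OR: 18 / 18

stage  estimate    se   p
   N1     4.204 0.490 0.0
   N2     4.731 0.400 0.0
   N3     5.069 0.490 0.0
    W     4.387 0.346 0.0
```

Reading this: the conventional modality lost 3.3 % of 5-s epochs to
artifact versus 0.02 % for the focal modality (the generator couples muscle
artifact four times more strongly into conventional channels); 378.9 μV² is
the focal threshold derived by quantile matching from the 400 μV²
conventional criterion; and the per-stage delta contrasts recover the
generator's injected +5 percentage-point focal delta offset (estimates 4.2
to 5.1, shrunk slightly by multitaper edge leakage and residual artifact —
see `docs/methods.md`).

The same pipeline runs on recorded data: list EDF pairs, a stage file and a
montage CSV under `participants:` in the YAML config instead of
`synthetic:`. A thin CLI (`tcresleep run | synth | spectra | noise |
compare | explain-defaults`) wraps the library.

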