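"""End-to-end orchestration: config → tables, manifest and summary.

Runs the full comparison on either recorded EDF pairs or the synthetic
generator: band powers → stage labels → per-modality noise models and
the cross-modality equivalent threshold → noisy-epoch flags → stage
summaries → per-band mixed models with per-stage contrasts → per-site
odds ratios → topography site tables.  Identical config and seed produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import noise as tnoise
from . import sites as tsites
from . import stats as tstats
from .spectral import (DEFAULT_BANDS, BandScheme, compute_band_powers,
                       label_epochs)
from .synth import SynthConfig, generate_hypnogram, generate_recording_pair

log = logging.getLogger("tcresleep")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one place.

    Exactly one of ``participants`` (recorded files) or ``synthetic``
    (generator settings, with an ``n_participants`` key) must be given.
    """

    participants: list[dict] | None = None
    synthetic: dict | None = None
    montage_path: str | None = None

    epoch_length: float = 5.0
    nw: float = 4.0
    n_tapers: int = 7

    offset: float = tnoise.DEFAULT_OFFSET
    eeg_threshold: float = tnoise.DEFAULT_EEG_THRESHOLD
    noise_fit_scope: str = "pooled"          # or "per_channel"

    aggregate_stats: bool = True
    exclude_noisy: bool = True
    contrast_adjust: str | None = None

    n_comparisons: int | None = None
    confidence: float = 0.95

    outdir: str = "tcresleep_out"
    seed: int = 0
    log_level: str = "INFO"
    write_epoch_table: bool = True
    write_topo_grids: bool = False
    topo_grid_n: int = 32

    def __post_init__(self) -> None:
        if (self.participants is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'participants' (file inputs) or "
                "'synthetic' must be configured")
        if self.noise_fit_scope not in ("pooled", "per_channel"):
            raise ValueError("noise_fit_scope must be 'pooled' or 'per_channel'")
        if self.participants is not None:
            for entry in self.participants:
                for key in ("id", "tcre_edf", "eeg_edf", "hypnogram"):
                    if key not in entry:
                        raise ValueError(f"participant entry missing {key!r}")
                for key in ("tcre_edf", "eeg_edf", "hypnogram"):
                    if not Path(entry[key]).exists():
                        raise FileNotFoundError(entry[key])


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Read a YAML pipeline config; keyword overrides win over file keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


@dataclass
class PipelineReport:
    """In-memory results plus the paths of everything written."""

    records: pd.DataFrame
    noise_models: dict[str, tnoise.NoiseModel]
    flag_summaries: dict[str, pd.DataFrame]
    stage_summary: pd.DataFrame
    mixed_models: dict[str, tstats.MixedModelResult]
    contrasts: pd.DataFrame | None
    site_table: pd.DataFrame | None
    topo_table: pd.DataFrame
    manifest: dict
    outdir: Path


def _participant_seed(seed: int, i: int) -> int:
    return int((seed * 100_003 + 17 * i + 1) % (2 ** 31))


def _iter_cohort(config: PipelineConfig,
                 montage: tio.Montage | None,
                 ) -> Iterator[tuple[str, tio.Recording, tio.Recording,
                                     tio.Hypnogram, tio.Montage]]:
    if config.synthetic is not None:
        opts = dict(config.synthetic)
        n_participants = int(opts.pop("n_participants", 1))
        for i in range(n_participants):
            scfg = SynthConfig(**opts, seed=_participant_seed(config.seed, i))
            m = montage or tio.default_montage(scfg.sites)
            hyp = generate_hypnogram(scfg)
            rec_t, rec_e = generate_recording_pair(scfg, hyp)
            yield f"S{i:02d}", rec_t, rec_e, hyp, m
    else:
        if montage is None:
            raise ValueError("file inputs require a montage file")
        for entry in config.participants:
            rec_t = tio.read_recording(entry["tcre_edf"], montage)
            rec_e = tio.read_recording(entry["eeg_edf"], montage)
            hyp = tio.read_hypnogram(entry["hypnogram"])
            yield str(entry["id"]), rec_t, rec_e, hyp, montage


def _fit_flags(records: pd.DataFrame, config: PipelineConfig,
               ) -> tuple[pd.Series, dict, dict, dict]:
    """Fit noise models, derive the focal threshold, flag every epoch."""
    flags = pd.Series(False, index=records.index)
    models: dict[str, tnoise.NoiseModel] = {}
    summaries: dict[str, pd.DataFrame] = {}
    derived: dict[str, float] = {}
    ok = ~records["degenerate"].astype(bool)

    def fit_pair(sub: pd.DataFrame, label: str):
        eeg_rows = sub["modality"] == "EEG"
        m_eeg = tnoise.fit_noise_model(
            sub.loc[eeg_rows & ok.loc[sub.index], "max_power"],
            offset=config.offset, raw_threshold=config.eeg_threshold,
            modality="EEG")
        m_tcre = tnoise.fit_noise_model(
            sub.loc[~eeg_rows & ok.loc[sub.index], "max_power"],
            offset=config.offset, modality="TCRE")
        thr = tnoise.equivalent_threshold(m_eeg, m_tcre)
        m_tcre.raw_threshold = thr
        m_tcre.scaled_threshold = m_eeg.scaled_threshold
        derived[label] = thr
        for model, rows in ((m_eeg, eeg_rows), (m_tcre, ~eeg_rows)):
            fl, summ = tnoise.flag_noisy_epochs(sub.loc[rows], model)
            flags.loc[fl.index] = fl
            key = model.modality if label == "pooled" else f"{model.modality}:{label}"
            models[key] = model
            summaries[key] = summ

    if config.noise_fit_scope == "pooled":
        fit_pair(records, "pooled")
    else:
        for site, sub in records.groupby("site"):
            fit_pair(sub, str(site))
    return flags, models, summaries, derived


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the whole analysis; write tables, manifest and summary."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = DEFAULT_BANDS
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config": _config_dict(config),
        "config_sha256": _config_hash(config),
        "versions": _versions(),
        "counts": {},
        "failure": None,
    }
    stage = "setup"
    try:
        montage = (tio.read_montage(config.montage_path)
                   if config.montage_path else None)

        stage = "band_powers"
        frames = []
        counts: dict[str, dict[str, int]] = {}
        the_montage = montage
        for pid, rec_t, rec_e, hyp, m in _iter_cohort(config, montage):
            the_montage = m
            for rec in (rec_t, rec_e):
                modality = rec.channel_modality[0]
                site_of = {c: m.site_of(c) for c in rec.channel_labels}
                bp = compute_band_powers(
                    rec, scheme, config.epoch_length, config.nw,
                    config.n_tapers, participant=pid, site_of=site_of)
                labelled, dropped = label_epochs(bp, hyp, config.epoch_length)
                cm = counts.setdefault(modality, {
                    "epochs_in": 0, "epochs_labelled": 0,
                    "epochs_dropped": 0, "degenerate": 0})
                cm["epochs_in"] += len(bp)
                cm["epochs_labelled"] += len(labelled)
                cm["epochs_dropped"] += dropped
                cm["degenerate"] += int(labelled["degenerate"].sum())
                frames.append(labelled)
            log.info("participant %s: band powers done", pid)
        records = pd.concat(frames, ignore_index=True)
        del frames

        stage = "noise_model"
        flags, models, flag_summaries, derived = _fit_flags(records, config)
        records["noisy"] = flags.to_numpy()
        for modality, cm in counts.items():
            cm["noisy"] = int(records.loc[records["modality"] == modality,
                                          "noisy"].sum())
        manifest["counts"] = counts
        manifest["thresholds"] = {
            "eeg_uV2": config.eeg_threshold,
            "tcre_equivalent_uV2": derived,
        }
        log.info("noise models fitted; derived focal thresholds: %s", derived)

        stage = "stage_summary"
        stage_summary = tstats.summarize_by_stage(
            records, exclude_noisy=config.exclude_noisy)

        stage = "mixed_models"
        mixed: dict[str, tstats.MixedModelResult] = {}
        contrast_frames = []
        n_participants = records["participant"].nunique()
        if n_participants >= 2:
            for band in scheme.names:
                try:
                    mm = tstats.fit_band_mixed_model(
                        records, band, aggregate=config.aggregate_stats,
                        exclude_noisy=config.exclude_noisy)
                except ValueError as exc:
                    log.warning("mixed model %s skipped: %s", band, exc)
                    continue
                mixed[band] = mm
                if np.isfinite(mm.fe_params.to_numpy()).any():
                    contrast_frames.append(
                        tstats.pairwise_contrasts(mm, config.contrast_adjust))
                log.info("mixed model %s: converged=%s singular=%s",
                         band, mm.converged, mm.singular)
        else:
            log.warning("fewer than 2 participants; mixed models skipped")
        contrasts = (pd.concat(contrast_frames, ignore_index=True)
                     if contrast_frames else None)

        stage = "site_comparison"
        site_table = None
        if records.groupby("site")["modality"].nunique().max() == 2:
            site_table = tsites.compare_sites(
                records, n_comparisons=config.n_comparisons,
                confidence=config.confidence)

        stage = "topography"
        per_site = (
            records.loc[~records["noisy"] & ~records["degenerate"]]
            .groupby(["modality", "stage", "site", "participant"])
            [[f"rel_{b}" for b in scheme.names]].mean()
            .groupby(["modality", "stage", "site"]).mean()
            .reset_index()
        )
        topo_table = per_site.melt(
            id_vars=["modality", "stage", "site"], var_name="band",
            value_name="mean_relative_power")
        topo_table["band"] = topo_table["band"].str.replace("rel_", "",
                                                            regex=False)
        if config.write_topo_grids and the_montage is not None:
            gdir = outdir / "topography_grids"
            gdir.mkdir(exist_ok=True)
            for (modality, st, band), grp in topo_table.groupby(
                    ["modality", "stage", "band"]):
                vals = dict(zip(grp["site"], grp["mean_relative_power"]))
                tm = tsites.topographic_matrix(
                    vals, the_montage, band=band, stage=st,
                    modality=modality, grid_n=config.topo_grid_n)
                np.savetxt(gdir / f"{modality}_{st}_{band}.csv",
                           tm.grid, delimiter=",")

        stage = "write"
        if config.write_epoch_table:
            tio.write_table(records, outdir / "band_powers.csv")
        tio.write_table(stage_summary, outdir / "stage_summary.csv")
        tio.write_table(topo_table, outdir / "topography_sites.csv")
        if contrasts is not None:
            tio.write_table(contrasts, outdir / "contrasts.csv")
        if site_table is not None:
            tio.write_table(site_table, outdir / "site_odds_ratios.csv")
        for key, model in models.items():
            model.to_json(outdir / f"noise_model_{key.replace(':', '_')}.json")
        for key, summ in flag_summaries.items():
            tio.write_table(summ,
                            outdir / f"noisy_{key.replace(':', '_')}.csv")
        if mixed:
            rows = []
            for band, mm in mixed.items():
                for name in mm.fe_params.index:
                    rows.append({
                        "band": band, "term": name,
                        "estimate": mm.fe_params[name],
                        "se": mm.bse[name], "p": mm.pvalues[name],
                        "converged": mm.converged, "singular": mm.singular,
                    })
            tio.write_table(pd.DataFrame(rows), outdir / "mixed_models.csv")
        manifest["convergence"] = {
            b: {"converged": m.converged, "singular": m.singular}
            for b, m in mixed.items()}
    except Exception as exc:
        manifest["failure"] = {"stage": stage, "error": repr(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    _write_summary(outdir / "summary.txt", manifest, stage_summary,
                   site_table)
    return PipelineReport(
        records=records, noise_models=models, flag_summaries=flag_summaries,
        stage_summary=stage_summary, mixed_models=mixed, contrasts=contrasts,
        site_table=site_table, topo_table=topo_table, manifest=manifest,
        outdir=outdir,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__
    return {
        "tcresleep": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_summary(path: Path, manifest: dict,
                   stage_summary: pd.DataFrame,
                   site_table: pd.DataFrame | None) -> None:
    lines = ["tcresleep run summary", "=" * 22, ""]
    for modality, cm in manifest["counts"].items():
        lines.append(
            f"{modality}: {cm['epochs_in']} epochs in, "
            f"{cm['epochs_labelled']} labelled, {cm['epochs_dropped']} "
            f"dropped, {cm.get('noisy', 0)} noisy "
            f"({100 * cm.get('noisy', 0) / max(cm['epochs_labelled'], 1):.2f}%)")
    thr = manifest.get("thresholds", {})
    if thr:
        lines.append(f"EEG threshold: {thr['eeg_uV2']} uV^2; derived focal "
                     f"equivalents: {thr['tcre_equivalent_uV2']}")
    lines.append("")
    lines.append(f"stage summary rows: {len(stage_summary)}")
    if site_table is not None:
        n_sig = int(site_table["significant_adjusted"].sum())
        lines.append(f"sites with adjusted-significant OR: {n_sig} / "
                     f"{len(site_table)}")
    path.write_text("\n".join(lines) + "\n")
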