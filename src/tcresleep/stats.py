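"""Stage-stratified summaries and mixed-effects modelling of relative power.

The central model, fitted separately per frequency band, is a linear
mixed model of relative power on signal type (focal vs conventional),
sleep stage, and their interaction, with a random intercept per
participant (REML estimation, Wald inference).  Per-stage focal-minus-
conventional contrasts are linear combinations of the fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StageSummary",
    "MixedModelResult",
    "summarize_by_stage",
    "fit_band_mixed_model",
    "pairwise_contrasts",
]


def _rel_columns(records: pd.DataFrame) -> list[str]:
    cols = [c for c in records.columns if c.startswith("rel_")]
    if not cols:
        raise ValueError("records contain no rel_<band> columns")
    return cols


def _clean(records: pd.DataFrame, exclude_noisy: bool,
           exclude_degenerate: bool) -> pd.DataFrame:
    out = records
    if exclude_degenerate and "degenerate" in out.columns:
        out = out.loc[~out["degenerate"].astype(bool)]
    if exclude_noisy and "noisy" in out.columns:
        out = out.loc[~out["noisy"].astype(bool)]
    return out


def summarize_by_stage(records: pd.DataFrame,
                       exclude_noisy: bool = True,
                       exclude_degenerate: bool = True) -> pd.DataFrame:
    """Group mean and standard error of relative power per band/modality/stage.

    The group mean is the mean of participant means; the standard error is
    the between-participant standard deviation of those means divided by
    √n_participants (0 when only one participant contributes), matching the
    error-bar convention of group-mean figures.  Stages with no epochs are
    simply absent from the output.
    """
    data = _clean(records, exclude_noisy, exclude_degenerate)
    rel_cols = _rel_columns(data)
    rows = []
    for (modality, stage), grp in data.groupby(["modality", "stage"],
                                               sort=True):
        pm = grp.groupby("participant")[rel_cols].mean()
        n_part = len(pm)
        for col in rel_cols:
            vals = pm[col].to_numpy()
            se = (float(np.std(vals, ddof=1)) / np.sqrt(n_part)
                  if n_part > 1 else 0.0)
            rows.append({
                "band": col[len("rel_"):],
                "modality": modality,
                "stage": stage,
                "mean": float(np.mean(vals)),
                "se": se,
                "n_epochs": int(len(grp)),
                "n_participants": n_part,
            })
    return pd.DataFrame(rows)


# kept as a named alias for the summary-table row schema
StageSummary = pd.DataFrame


@dataclass
class MixedModelResult:
    """Fitted per-band mixed model and the pieces contrasts need."""

    band: str
    formula: str
    converged: bool
    singular: bool
    fe_params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_fe: pd.DataFrame
    group_var: float
    resid_var: float
    n_obs: int
    has_interaction: bool
    reference_modality: str
    reference_stage: str
    modality_levels: tuple[str, ...]
    stage_levels: tuple[str, ...]

    def term(self, fragment_a: str, fragment_b: str | None = None) -> str:
        """Find the unique design column containing the given fragments."""
        hits = [
            n for n in self.fe_params.index
            if fragment_a in n
            and (fragment_b in n if fragment_b is not None else ":" not in n)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"no unique term for ({fragment_a!r}, {fragment_b!r}): {hits}")
        return hits[0]


def fit_band_mixed_model(records: pd.DataFrame, band: str,
                         aggregate: bool = True,
                         exclude_noisy: bool = True,
                         exclude_degenerate: bool = True,
                         interaction: bool = True,
                         reference_modality: str = "EEG",
                         reference_stage: str = "W") -> MixedModelResult:
    """REML mixed model of one band's relative power.

    Fixed effects: signal type, sleep stage and (by default) their
    interaction; random intercept per participant.  With
    ``aggregate=True`` the model is fitted on participant × modality ×
    stage cell means — the desk-scale default — otherwise on epoch-level
    records.

    A non-converged or variance-degenerate fit is returned flagged
    (``converged``/``singular``), never silently and never as an
    exception; genuine design problems (one participant, one modality,
    one stage) raise ``ValueError``.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    col = f"rel_{band}"
    if col not in records.columns:
        raise ValueError(f"no column {col!r} in records")
    data = _clean(records, exclude_noisy, exclude_degenerate)
    data = data.dropna(subset=[col])
    if data["participant"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 participants")
    if data["modality"].nunique() < 2:
        raise ValueError("mixed model needs both modalities")
    if data["stage"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 stages")

    if aggregate:
        data = (data.groupby(["participant", "modality", "stage"],
                             sort=True, as_index=False)[col].mean())

    op = "*" if interaction else "+"
    formula = (f"{col} ~ C(modality, Treatment('{reference_modality}')) "
               f"{op} C(stage, Treatment('{reference_stage}'))")
    stage_levels = tuple(sorted(data["stage"].unique()))
    modality_levels = tuple(sorted(data["modality"].unique()))

    converged, singular = True, False
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            model = smf.mixedlm(formula, data, groups=data["participant"])
            res = model.fit(reml=True)
        converged = bool(getattr(res, "converged", True))
        for w in wlist:
            if issubclass(w.category, ConvergenceWarning):
                converged = False
            if "singular" in str(w.message).lower() or \
                    "boundary" in str(w.message).lower():
                singular = True
        k_fe = len(res.fe_params)
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        group_var = float(np.asarray(res.cov_re).ravel()[0])
        resid_var = float(res.scale)
        if group_var <= 1e-12 or resid_var <= 1e-12:
            singular = True
        fe = res.fe_params
        bse = res.bse_fe
        pvals = res.pvalues[:k_fe]
    except Exception:
        # degenerate data (e.g. all observations identical): flagged
        names = ["Intercept"]
        fe = pd.Series(np.nan, index=names)
        bse = pd.Series(np.nan, index=names)
        pvals = pd.Series(np.nan, index=names)
        cov = np.full((1, 1), np.nan)
        group_var = resid_var = float("nan")
        converged, singular = False, True

    return MixedModelResult(
        band=band,
        formula=formula,
        converged=converged,
        singular=singular,
        fe_params=fe,
        bse=pd.Series(np.asarray(bse), index=fe.index),
        pvalues=pd.Series(np.asarray(pvals), index=fe.index),
        cov_fe=pd.DataFrame(cov, index=fe.index, columns=fe.index),
        group_var=group_var,
        resid_var=resid_var,
        n_obs=int(len(data)),
        has_interaction=interaction,
        reference_modality=reference_modality,
        reference_stage=reference_stage,
        modality_levels=modality_levels,
        stage_levels=stage_levels,
    )


def pairwise_contrasts(model: MixedModelResult,
                       adjust: str | None = None) -> pd.DataFrame:
    """Within-stage focal-minus-conventional differences from the fitted model.

    For each stage the contrast is the modality main effect plus, off the
    reference stage, the corresponding interaction coefficient; Wald
    standard errors come from the fixed-effect covariance.  ``adjust``
    may be ``"bonferroni"`` (off by default: the primary report is the
    unadjusted per-stage p).
    """
    if not model.has_interaction:
        raise ValueError("pairwise contrasts require an interaction model")
    if not np.isfinite(model.fe_params.to_numpy()).any():
        raise ValueError("model fit is degenerate; no contrasts available")
    other = [m for m in model.modality_levels
             if m != model.reference_modality]
    if len(other) != 1:
        raise ValueError("contrasts are defined for exactly two modalities")
    frag_mod = f"[T.{other[0]}]"
    main = model.term(frag_mod)
    rows = []
    names = list(model.fe_params.index)
    cov = model.cov_fe.to_numpy()
    for stage in model.stage_levels:
        L = np.zeros(len(names))
        L[names.index(main)] = 1.0
        if stage != model.reference_stage:
            inter = model.term(frag_mod, f"[T.{stage}]")
            L[names.index(inter)] = 1.0
        est = float(L @ model.fe_params.to_numpy())
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"band": model.band, "stage": stage,
                     "estimate": est, "se": se, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p"] * len(out), 1.0)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
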