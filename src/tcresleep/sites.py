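"""Per-site contingency analysis of noisy epochs and scalp-topography data.

For each 10–20 site, noisy-epoch counts of the conventional and focal
channels form a 2×2 table; the odds ratio (conventional vs focal odds of
an epoch being noisy), a Woolf logit confidence interval at a
Bonferroni-adjusted level, and a two-sided Fisher exact p quantify the
difference.  Topography outputs are per-site data matrices (optionally
interpolated onto a unit-disc grid); rendering is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Montage

__all__ = [
    "SiteComparison",
    "TopographyMatrix",
    "site_contingency",
    "odds_ratio_fisher",
    "compare_sites",
    "topographic_matrix",
]


@dataclass
class SiteComparison:
    """One site's 2×2 noisy-epoch comparison.

    ``counts`` rows are (conventional EEG, focal TCRE); columns are
    (noisy, clean).  ``ci_low``/``ci_high`` are Woolf logit limits at
    confidence level ``1 - 0.05/n_sites_adjusted_for``; they are NaN when
    any cell is zero (the odds ratio is then 0 or infinite and flagged).
    """

    site: str
    counts: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_sites_adjusted_for: int
    confidence: float = 0.95
    degenerate_or: bool = False

    def as_row(self) -> dict:
        a, b = self.counts[0]
        c, d = self.counts[1]
        alpha_adj = (1.0 - self.confidence) / self.n_sites_adjusted_for
        return {
            "site": self.site,
            "eeg_noisy": int(a), "eeg_clean": int(b),
            "tcre_noisy": int(c), "tcre_clean": int(d),
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p_value,
            "significant_adjusted": bool(self.p_value < alpha_adj),
        }


def site_contingency(flags_eeg, flags_tcre) -> np.ndarray:
    """2×2 counts [[EEG noisy, EEG clean], [TCRE noisy, TCRE clean]].

    The two flag vectors may differ in length (counts are marginal per
    modality, not epoch-paired).
    """
    fe = np.asarray(flags_eeg, dtype=bool)
    ft = np.asarray(flags_tcre, dtype=bool)
    if fe.size == 0 or ft.size == 0:
        raise ValueError("flag vectors must be non-empty")
    return np.array([
        [int(fe.sum()), int((~fe).sum())],
        [int(ft.sum()), int((~ft).sum())],
    ])


def odds_ratio_fisher(counts: np.ndarray, n_comparisons: int = 1,
                      confidence: float = 0.95,
                      site: str = "", haldane: bool = False,
                      ) -> SiteComparison:
    """Odds ratio with Bonferroni-adjusted Woolf CI and Fisher exact p.

    OR = (a·d)/(b·c).  The CI is ``exp(log OR ± z·√(1/a+1/b+1/c+1/d))``
    with ``z`` at two-sided level ``(1-confidence)/n_comparisons``.  The
    two-sided Fisher p sums hypergeometric probabilities not exceeding
    that of the observed table and needs no zero-cell correction; with a
    zero cell the OR is 0 or ∞ and flagged (``haldane=True`` instead adds
    0.5 to every cell for the OR and CI only).
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(t < 0):
        raise ValueError("negative counts")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    a, b = t[0]
    c, d = t[1]
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])

    tt = t + 0.5 if haldane else t
    degenerate = bool(np.any(t == 0))
    if haldane or not degenerate:
        aa, bb = tt[0]
        cc, dd = tt[1]
        orr = (aa * dd) / (bb * cc)
        z = sps.norm.ppf(1.0 - (1.0 - confidence) / n_comparisons / 2.0)
        half = z * np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ci_low = float(np.exp(np.log(orr) - half))
        ci_high = float(np.exp(np.log(orr) + half))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            orr = (a * d) / (b * c) if b * c > 0 else (
                np.inf if a * d > 0 else np.nan)
        ci_low = ci_high = float("nan")
    return SiteComparison(
        site=site, counts=np.asarray(counts), odds_ratio=float(orr),
        ci_low=ci_low, ci_high=ci_high, p_value=p,
        n_sites_adjusted_for=int(n_comparisons), confidence=confidence,
        degenerate_or=degenerate and not haldane,
    )


def compare_sites(records: pd.DataFrame, n_comparisons: int | None = None,
                  confidence: float = 0.95) -> pd.DataFrame:
    """Site-by-site odds-ratio table from a flagged band-power table.

    ``records`` needs ``site``, ``modality`` and boolean ``noisy`` columns
    and both modalities at each analysed site; ``n_comparisons`` defaults
    to the number of such sites.
    """
    sites = [
        s for s, g in records.groupby("site")
        if g["modality"].nunique() == 2
    ]
    if not sites:
        raise ValueError("no site has both modalities")
    if n_comparisons is None:
        n_comparisons = len(sites)
    rows = []
    for s in sites:
        g = records.loc[records["site"] == s]
        counts = site_contingency(
            g.loc[g["modality"] == "EEG", "noisy"],
            g.loc[g["modality"] == "TCRE", "noisy"],
        )
        rows.append(odds_ratio_fisher(counts, n_comparisons, confidence,
                                      site=s).as_row())
    return pd.DataFrame(rows)


@dataclass
class TopographyMatrix:
    """Per-site scalar field plus an optional interpolated unit-disc grid."""

    band: str
    stage: str
    modality: str
    sites: list[str]
    values: np.ndarray            # per-site scalars, montage order
    coordinates: np.ndarray       # (n_sites, 2)
    excluded_sites: list[str] = field(default_factory=list)
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    grid: np.ndarray | None = None


def topographic_matrix(site_values: dict[str, float], montage: Montage,
                       band: str = "", stage: str = "", modality: str = "",
                       grid_n: int = 0, idw_power: float = 2.0,
                       ) -> TopographyMatrix:
    """Assemble per-site values in montage order, optionally IDW-gridded.

    Inverse-distance weighting is a convex combination of site values, so
    grid values never leave the [min, max] range of the sites; grid nodes
    outside the unit disc are NaN.  Sites present in the montage but
    absent from ``site_values`` are excluded and listed.  At least 3
    valid sites are required.
    """
    sites = [s for s in montage.sites if s in site_values
              and np.isfinite(site_values[s])]
    excluded = [s for s in montage.sites if s not in sites]
    if len(sites) < 3:
        raise ValueError("topography needs values at >= 3 sites")
    xy = np.array([montage.positions[s] for s in sites])
    vals = np.array([float(site_values[s]) for s in sites])
    out = TopographyMatrix(band=band, stage=stage, modality=modality,
                           sites=sites, values=vals, coordinates=xy,
                           excluded_sites=excluded)
    if grid_n > 0:
        gx = np.linspace(-1.0, 1.0, grid_n)
        gy = np.linspace(-1.0, 1.0, grid_n)
        X, Y = np.meshgrid(gx, gy)
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        d = np.sqrt(((pts[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        grid = np.empty(len(pts))
        exact = d < 1e-12
        has_exact = exact.any(axis=1)
        with np.errstate(divide="ignore"):
            w = d ** (-idw_power)
        w[~np.isfinite(w)] = 0.0
        denom = w.sum(axis=1)
        grid = (w @ vals) / np.where(denom > 0, denom, 1.0)
        for i in np.nonzero(has_exact)[0]:
            grid[i] = vals[np.argmax(exact[i])]
        grid[(pts ** 2).sum(1) > 1.0] = np.nan
        out.grid_x, out.grid_y = gx, gy
        out.grid = grid.reshape(grid_n, grid_n)
    return out
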