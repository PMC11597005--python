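"""Exact-test oracles and topography-matrix properties."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from tcresleep import (default_montage, odds_ratio_fisher, site_contingency,
                       topographic_matrix)
from tcresleep.sites import compare_sites


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestContingency:
    def test_direct_count(self):
        counts = site_contingency([True, False, False],
                                  [False, False, False])
        assert counts.tolist() == [[1, 2], [0, 3]]

    def test_identical_vectors_identical_rows(self):
        flags = [True, False, True, True]
        counts = site_contingency(flags, flags)
        assert counts[0].tolist() == counts[1].tolist()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            site_contingency([], [True])

    def test_unequal_lengths_allowed(self):
        counts = site_contingency([True] * 3, [False] * 5)
        assert counts.sum() == 8

    def test_injected_rates_within_binomial_bounds(self):
        rng = np.random.default_rng(0)
        n = 6480
        fe = rng.random(n) < 0.02
        ft = rng.random(n) < 0.01
        counts = site_contingency(fe, ft)
        for row, p in zip(counts, (0.02, 0.01)):
            rate = row[0] / row.sum()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(rate - p) < 3 * se


class TestOddsRatioFisher:
    def test_no_association(self):
        sc = odds_ratio_fisher([[5, 5], [5, 5]])
        assert sc.odds_ratio == 1.0 and sc.p_value == pytest.approx(1.0)

    def test_diagonal_table_exact_p_and_infinite_or(self):
        sc = odds_ratio_fisher([[10, 0], [0, 10]])
        assert sc.p_value == pytest.approx(2 / comb(20, 10), rel=1e-12)
        assert np.isinf(sc.odds_ratio) and sc.degenerate_or

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(150):
            t = rng.integers(0, 11, (2, 2))
            if t.sum() == 0 or t.sum() > 40:
                continue
            sc = odds_ratio_fisher(t.tolist())
            assert sc.p_value == pytest.approx(fisher_oracle(t), abs=1e-12)

    def test_p_invariant_under_row_and_column_swaps(self):
        t = np.array([[7, 3], [2, 9]])
        p0 = odds_ratio_fisher(t).p_value
        assert odds_ratio_fisher(t[::-1]).p_value == pytest.approx(p0,
                                                                   rel=1e-12)
        assert odds_ratio_fisher(t[:, ::-1]).p_value == pytest.approx(
            p0, rel=1e-12)

    def test_or_reciprocal_symmetry(self):
        t = np.array([[7, 3], [2, 9]])
        or1 = odds_ratio_fisher(t).odds_ratio
        or2 = odds_ratio_fisher(t[::-1]).odds_ratio
        assert or1 * or2 == pytest.approx(1.0, rel=1e-12)

    def test_bonferroni_one_comparison_is_unadjusted(self):
        t = [[12, 30], [5, 40]]
        sc1 = odds_ratio_fisher(t, n_comparisons=1)
        sc18 = odds_ratio_fisher(t, n_comparisons=18)
        # unadjusted CI equals the plain 95% Woolf interval
        from scipy import stats as sps
        a, b, c, d = 12, 30, 5, 40
        half = sps.norm.ppf(0.975) * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(sc1.odds_ratio) - half)
        assert sc1.ci_low == pytest.approx(lo, rel=1e-12)
        # adjustment can only widen
        assert sc18.ci_low < sc1.ci_low < sc1.ci_high < sc18.ci_high

    def test_ci_brackets_or_for_positive_cells(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(1, 30, (2, 2))
            sc = odds_ratio_fisher(t.tolist(), n_comparisons=18)
            assert sc.ci_low <= sc.odds_ratio <= sc.ci_high

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_fisher([[1, -1], [0, 2]])

    def test_haldane_option_gives_finite_or(self):
        sc = odds_ratio_fisher([[10, 0], [0, 10]], haldane=True)
        assert np.isfinite(sc.odds_ratio) and np.isfinite(sc.ci_low)


class TestCompareSites:
    def test_per_site_table(self):
        rng = np.random.default_rng(3)
        rows = []
        for site in ("Cz", "Pz"):
            for modality, rate in (("EEG", 0.2), ("TCRE", 0.05)):
                for _ in range(300):
                    rows.append({"site": site, "modality": modality,
                                 "noisy": bool(rng.random() < rate)})
        table = compare_sites(pd.DataFrame(rows))
        assert len(table) == 2
        assert (table["odds_ratio"] > 1).all()
        assert table["significant_adjusted"].all()


class TestTopography:
    def test_constant_field_is_flat(self, small_montage):
        vals = {s: 20.0 for s in small_montage.sites}
        tm = topographic_matrix(vals, small_montage, grid_n=16)
        inside = np.isfinite(tm.grid)
        assert np.allclose(tm.grid[inside], 20.0)

    def test_peak_at_hot_site(self):
        montage = default_montage(("C3", "Cz", "C4", "P4", "O1", "O2"))
        vals = {s: (100.0 if s == "P4" else 0.0) for s in montage.sites}
        tm = topographic_matrix(vals, montage, grid_n=41)
        iy, ix = np.unravel_index(np.nanargmax(tm.grid), tm.grid.shape)
        x, y = tm.grid_x[ix], tm.grid_y[iy]
        px, py = montage.positions["P4"]
        assert np.hypot(x - px, y - py) < 0.08

    def test_convexity_bounds(self, small_montage):
        rng = np.random.default_rng(4)
        vals = {s: float(rng.uniform(0, 100)) for s in small_montage.sites}
        tm = topographic_matrix(vals, small_montage, grid_n=21)
        inside = np.isfinite(tm.grid)
        assert tm.grid[inside].min() >= min(vals.values()) - 1e-9
        assert tm.grid[inside].max() <= max(vals.values()) + 1e-9

    def test_too_few_sites_rejected(self, small_montage):
        with pytest.raises(ValueError):
            topographic_matrix({"Cz": 1.0, "C3": 2.0}, small_montage)

    def test_missing_sites_listed(self, small_montage):
        vals = {s: 1.0 for s in small_montage.sites if s != "O1"}
        tm = topographic_matrix(vals, small_montage)
        assert tm.excluded_sites == ["O1"]
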