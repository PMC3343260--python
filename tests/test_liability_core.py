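"""Pair-table likelihood and constrained polychoric estimation."""

import numpy as np
import pandas as pd
import pytest

import twinace as ta
from twinace.liability_core import (
    CorrelationStructure,
    ThresholdSet,
    aggregate_cells,
    pair_table_loglik,
    profile_interval,
)
from twinace._mvnorm import bvn_cdf, bvn_rect_prob


def _pair_df(rows):
    """rows: (pair_id, zygosity, member, affected, bv_cat)."""
    return pd.DataFrame(
        rows, columns=["pair_id", "zygosity", "member", "affected", "bv_cat"]
    )


class TestPairTableLoglik:
    def test_independence_factorizes_into_marginals(self):
        # all correlations zero, all thresholds at the median: every
        # (affected, category) margin has mass 1/2, so each pair cell has
        # probability (1/2)^4
        struct = CorrelationStructure(0.0, 0.0, 0.0, 0.0, 0.0,
                                      r_sz_mz=0.0, r_sz_dz=0.0)
        thr = ThresholdSet(sz_threshold=0.0, bv_thresholds=np.array([0.0]))
        df = _pair_df([
            ("p1", "MZ", 1, 0, 1), ("p1", "MZ", 2, 1, 2),
            ("p2", "DZ", 1, 1, 1), ("p2", "DZ", 2, 0, 1),
            ("p3", "MZ", 1, 0, 2), ("p3", "MZ", 2, 0, 2),
        ])
        ll = pair_table_loglik(struct, thr, df)
        assert ll == pytest.approx(3 * np.log(0.0625), abs=1e-5)

    def test_member_swap_invariance(self, small_cohort):
        df, _ = small_cohort
        swapped = df.copy()
        swapped["member"] = 3 - swapped["member"]
        struct = CorrelationStructure(-0.2, 0.7, 0.4, -0.15, -0.08)
        thr = ThresholdSet(
            sz_threshold=ta.threshold_from_prevalence(0.01),
            bv_thresholds=np.array([-0.84, -0.25, 0.25, 0.84]),
        )
        assert pair_table_loglik(struct, thr, df) == pair_table_loglik(
            struct, thr, swapped
        )

    def test_singleton_contributes_bivariate_margin(self):
        struct = CorrelationStructure(-0.22, 0.76, 0.38, -0.1648, -0.0824)
        thr = ThresholdSet(sz_threshold=2.0, bv_thresholds=np.array([0.0]))
        pairs = _pair_df([
            ("p1", "MZ", 1, 0, 1), ("p1", "MZ", 2, 0, 2),
            ("p2", "DZ", 1, 0, 1), ("p2", "DZ", 2, 0, 1),
        ])
        single = _pair_df([("s1", "MZ", 1, 1, 2)])
        ll_pairs = pair_table_loglik(struct, thr, pairs, )
        ll_all = pair_table_loglik(
            struct, thr, pd.concat([pairs, single]),
        )
        expected = np.log(
            bvn_rect_prob(struct.r_within, (2.0, 0.0), (np.inf, np.inf))
        )
        assert ll_all - ll_pairs == pytest.approx(expected, abs=1e-9)

    def test_impossible_cell_returns_neg_inf(self):
        # a perfect correlation makes a discordant-category cell impossible
        struct = CorrelationStructure(0.0, 1.0, 0.0, 0.0, 0.0)
        thr = ThresholdSet(sz_threshold=2.0, bv_thresholds=np.array([0.0]))
        df = _pair_df([("p1", "MZ", 1, 0, 1), ("p1", "MZ", 2, 0, 2),
                       ("p2", "DZ", 1, 0, 1), ("p2", "DZ", 2, 0, 1)])
        assert pair_table_loglik(struct, thr, df) == -np.inf

    def test_missing_category_marginalizes(self):
        struct = CorrelationStructure(-0.22, 0.76, 0.38, -0.1648, -0.0824)
        thr = ThresholdSet(sz_threshold=2.0, bv_thresholds=np.array([0.0]))
        base = [("p1", "MZ", 1, 0, 1)]
        with_missing = _pair_df(base + [("p1", "MZ", 2, 0, np.nan)])
        # a high-resolution rule isolates the (exact) marginalization
        # identity from integration error
        npts = 2 ** 15
        ll = pair_table_loglik(struct, thr, with_missing, n_points=npts)
        # marginalizing the second member's category leaves a 3-variate
        # probability; sum of the two category cells must reproduce it
        cells = [
            pair_table_loglik(struct, thr,
                              _pair_df(base + [("p1", "MZ", 2, 0, c)]),
                              n_points=npts)
            for c in (1, 2)
        ]
        assert np.exp(ll) == pytest.approx(sum(np.exp(c) for c in cells),
                                           abs=1e-7)


class TestAggregateCells:
    def test_mirrored_cells_pool(self):
        a = aggregate_cells(_pair_df([
            ("p1", "MZ", 1, 0, 1), ("p1", "MZ", 2, 1, 3),
            ("p2", "MZ", 1, 1, 3), ("p2", "MZ", 2, 0, 1),
        ]), n_categories=5)
        keys, counts = a.pair_cells["MZ"]
        assert keys.shape[0] == 1
        assert counts[0] == 2

    def test_rejects_malformed_pairs(self):
        with pytest.raises(ValueError):
            aggregate_cells(_pair_df([
                ("p1", "MZ", 1, 0, 1), ("p1", "DZ", 2, 0, 1),
            ]), n_categories=5)
        with pytest.raises(ValueError):
            aggregate_cells(_pair_df([
                ("p1", "MZ", 1, 0, 1), ("p1", "MZ", 2, 0, 1),
                ("p1", "MZ", 2, 0, 2),
            ]), n_categories=5)


class TestProfileInterval:
    def test_analytic_quadratic_oracle(self):
        # nll = 5 (x-1)^2 + 2.5 (y-x)^2: profiling over y gives
        # 2*dnll = 10 (x-1)^2, so the 95% endpoints sit at 1 +- sqrt(.384)
        def nll(theta):
            x, y = theta
            return 5.0 * (x - 1.0) ** 2 + 2.5 * (y - x) ** 2

        lo, hi = profile_interval(nll, np.array([1.0, 1.0]), 0, 0.0)
        half = np.sqrt(3.841458820694124 / 10.0)
        assert lo == pytest.approx(1.0 - half, abs=1e-3)
        assert hi == pytest.approx(1.0 + half, abs=1e-3)
        # -2 dlnL at the reported endpoints is the chi-square cutoff
        for v in (lo, hi):
            assert 2.0 * (5.0 * (v - 1.0) ** 2) == pytest.approx(
                3.841458820694124, abs=0.01
            )


class TestFitStructure:
    def test_tetrachoric_ml_matches_grid_oracle(
        self, singleton_tetrachoric_data
    ):
        # on independent individuals the pair likelihood collapses to the
        # classical 2x2 tetrachoric likelihood, whose ML estimate a brute
        # grid over r locates independently
        from _oracles import tetrachoric_grid_ml
        df, prevalence, _ = singleton_tetrachoric_data
        struct, thr, fit = ta.fit_structure(df, prevalence=prevalence,
                                            n_categories=2)
        r_grid = tetrachoric_grid_ml(df, prevalence)
        assert struct.r_within == pytest.approx(r_grid, abs=1e-2)

    def test_fixed_constants_never_move(self, small_cohort):
        df, _ = small_cohort
        struct, thr, fit = ta.fit_structure(df)
        assert struct.r_sz_mz == 0.92
        assert struct.r_sz_dz == 0.515
        assert fit.params["r_sz_mz"] == 0.92
        assert fit.params["r_sz_dz"] == 0.515
        assert thr.sz_threshold == ta.threshold_from_prevalence(0.01)

    def test_requires_both_zygosities(self, small_cohort):
        df, _ = small_cohort
        with pytest.raises(ValueError):
            ta.fit_structure(df[df["zygosity"] == "MZ"])

    def test_coarsening_to_binary_is_consistent(self, cerebrum):
        # collapsing five classes to two moves the constrained within-person
        # correlation only slightly at large n
        cfg = ta.SimulationConfig(n_mz_pairs=10_000, n_dz_pairs=10_000,
                                  seed=31)
        df = ta.simulate_pairs(cerebrum, cfg)
        df5, _, _ = ta.prepare(df)
        struct5, _, _ = ta.fit_structure(df5)
        df2 = df.copy()
        from twinace.preprocess import quantile_bin
        df2["bv_cat"], _ = quantile_bin(df5["bv"].to_numpy() * 1.0, k=2)
        struct2, _, _ = ta.fit_structure(df2, n_categories=2)
        assert abs(struct5.r_within - struct2.r_within) < 0.05

    def test_null_within_correlation_covered_by_ci(self):
        # generating model with no cross-trait channel at all
        paths = ta.PathCoefficients.from_components(
            0.6, 0.1, 0.3, r_g=0.0, r_c=0.0, r_e=0.0
        )
        cfg = ta.SimulationConfig(n_mz_pairs=1000, n_dz_pairs=1000, seed=17)
        df = ta.simulate_pairs(paths, cfg)
        df, _, _ = ta.prepare(df)
        struct, _, fit = ta.fit_structure(df, ci=["r_within"])
        lo, hi = struct.ci["r_within"]
        assert lo < struct.r_within < hi
        assert lo < 0.0 < hi
        assert hi - lo < 0.5
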