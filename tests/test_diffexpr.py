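import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hybridcor import (
    DataError,
    PipelineConfig,
    adjust_fdr,
    estimate_prior,
    per_hybrid_de_counts,
    percent,
    reliability_threshold,
    select_differential,
)
from hybridcor.diffexpr import moderated_f_test
from hybridcor.io import FactorialDesign

from conftest import toy_expression


class TestReliabilityThreshold:
    def test_zero_spread(self):
        assert reliability_threshold([5.0, 5.0, 5.0]) == 5.0

    def test_hand_computed(self):
        # mean 7, sample sd 1 -> 7 + 3
        assert reliability_threshold([6.0, 7.0, 8.0]) == pytest.approx(10.0)

    def test_permutation_invariant(self):
        a = [3.1, 4.5, 2.2, 5.0]
        assert reliability_threshold(a) == pytest.approx(reliability_threshold(a[::-1]))

    def test_needs_two_values(self):
        with pytest.raises(DataError):
            reliability_threshold([5.0])


def brute_force_bh(p):
    """Step-up BH by direct definition: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(1.0, running)
    return q


class TestAdjustFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            adjust_fdr([0.5, 1.2])

    def test_all_permutations_match_brute_force(self):
        base = [0.001, 0.011, 0.02, 0.2, 0.6, 0.94]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(adjust_fdr(perm), brute_force_bh(perm), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25))
    def test_matches_brute_force_and_dominates_p(self, ps):
        q = adjust_fdr(ps)
        np.testing.assert_allclose(q, brute_force_bh(ps), atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-15).all()


class TestModeratedF:
    def test_no_signal_toy(self):
        """Identical replicate values everywhere: F = 0, p = 1 even with zero
        within-line variance (the prior keeps the denominator positive)."""
        em = toy_expression({"a": [9.0, 9.0, 9.0], "b": [7.0, 7.0, 7.0]}, n_spike=0)
        prior, tab = moderated_f_test(em.values, em.sample_lines())
        np.testing.assert_allclose(tab["F"], 0.0)
        np.testing.assert_allclose(tab["p"], 1.0)
        assert prior.s0sq > 0

    def test_requires_replication(self):
        em = toy_expression({"a": [9.0, 9.0, 9.0]}, reps=1, n_spike=0)
        with pytest.raises(DataError, match="replicate"):
            moderated_f_test(em.values, em.sample_lines())

    def test_equal_variance_limit_matches_pooled_f(self):
        """When gene variances are homogeneous the prior df goes to infinity
        and the moderated F approaches the F computed with the common
        variance."""
        rng = np.random.default_rng(0)
        G, k, r = 2000, 3, 3
        x = rng.normal(size=(G, k * r)) * 0.3  # one shared variance
        vals = pd.DataFrame(x, index=[f"g{i}" for i in range(G)])
        lines = pd.Series(np.repeat(["A", "B", "C"], r), index=vals.columns)
        prior, tab = moderated_f_test(vals, lines)
        assert prior.d0 > 20 or math.isinf(prior.d0)
        # ordinary F with the common pooled variance, all probes
        line_arr = lines.to_numpy()
        means = np.stack([x[:, line_arr == l].mean(axis=1) for l in ("A", "B", "C")], axis=1)
        msb = r * means.var(axis=1, ddof=1)
        pooled = tab["s2"].mean()
        np.testing.assert_allclose(tab["F"], msb / pooled, rtol=0.25)
        assert prior.s0sq == pytest.approx(pooled, rel=0.1)

    def test_null_simulation_recovers_prior_and_uniform_p(self):
        """Null matrix with variances from a scaled inverse-chi-square(4, 0.05):
        the moment-matching estimate recovers (d0, s0sq) and p is uniform."""
        rng = np.random.default_rng(5)
        G, k, r = 2000, 4, 3
        sig2 = 0.05 * 4 / rng.chisquare(4, size=G)
        x = rng.normal(size=(G, k * r)) * np.sqrt(sig2)[:, None]
        vals = pd.DataFrame(x, index=[f"g{i}" for i in range(G)])
        lines = pd.Series(np.repeat([f"L{j}" for j in range(k)], r), index=vals.columns)
        prior, tab = moderated_f_test(vals, lines)
        assert abs(prior.d0 - 4) / 4 < 0.3
        assert abs(prior.s0sq - 0.05) / 0.05 < 0.2
        assert stats.kstest(tab["p"], "uniform").statistic < 0.05


def _four_probe_screen():
    """One survivor plus one probe failing each filter, by construction."""
    lines = ("F1", "F2", "D01")
    em = toy_expression(
        {
            "ok": [9.0, 10.0, 9.5],          # passes everything
            "low_int": [6.95, 7.6, 7.0],     # differential but mean < 8
            "no_fc": [9.2, 9.2, 9.2],        # flat across lines
            "unreliable": [4.0, 4.2, 4.6],   # below the spike-in threshold
        },
        lines=lines, reps=3, sigma=0.05, seed=2,
    )
    design = FactorialDesign(pd.DataFrame(
        {"hybrid_id": ["F1xD01", "F2xD01"], "flint_parent": ["F1", "F2"],
         "dent_parent": ["D01", "D01"]}
    ))
    return em, design


class TestSelectDifferential:
    def test_toy_filter_attribution(self, pcfg):
        em, design = _four_probe_screen()
        screen = select_differential(em, pcfg, design)
        t = screen.table
        assert list(screen.de_ids) == ["ok"]
        assert not t.loc["low_int", "intensity_pass"] and t.loc["low_int", "fc_pass"]
        assert not t.loc["no_fc", "fc_pass"] and t.loc["no_fc", "reliable"]
        assert not t.loc["unreliable", "reliable"]

    def test_spikeins_never_differential(self, small_products):
        screen, *_ = small_products
        assert not (screen.table["de_pass"] & screen.table["is_spikein"]).any()

    def test_spikein_diagnostic_reported(self, small_products):
        screen, *_ = small_products
        assert 0 <= screen.spikein_min_q <= 1

    def test_threshold_monotonicity(self, small_dataset, pcfg):
        """Raising fc_min or intensity_min never grows the differential set
        when the tested family is held fixed (no fold-change prefilter; with
        the prefilter on, the BH family itself changes with fc_min)."""
        expr, design, *_ = small_dataset
        fixed_family = pcfg.with_(prefilter_fc=False)
        base = set(select_differential(expr, fixed_family).de_ids)
        stricter = select_differential(
            expr, fixed_family.with_(fc_min=1.6, intensity_min=8.5)
        )
        assert set(stricter.de_ids) <= base
        # intensity_min alone never enters the BH family, so the subset
        # property also holds with the default prefilter
        base2 = set(select_differential(expr, pcfg).de_ids)
        stricter2 = select_differential(expr, pcfg.with_(intensity_min=8.5))
        assert set(stricter2.de_ids) <= base2


class TestPerHybridCounts:
    def test_identical_parents_give_zero(self, pcfg):
        """F1 and D01 share every probe's level, so the F1 x D01 hybrid has no
        parentally differential gene; F2 differs strongly on both probes."""
        em = toy_expression(
            {"g1": [9.0, 12.0, 9.0], "g2": [10.0, 13.0, 10.0]},
            lines=("F1", "F2", "D01"), reps=3, sigma=0.05, seed=4,
        )
        design = FactorialDesign(pd.DataFrame(
            {"hybrid_id": ["F1xD01", "F2xD01"], "flint_parent": ["F1", "F2"],
             "dent_parent": ["D01", "D01"]}
        ))
        screen = select_differential(em, pcfg, design)
        counts = per_hybrid_de_counts(screen, design, pcfg)
        assert counts.loc["F1xD01", "n_de"] == 0
        assert counts.loc["F2xD01", "n_de"] == 2

    def test_counts_bounded_by_global_set(self, small_dataset, pcfg):
        expr, design, *_ = small_dataset
        screen = select_differential(expr, pcfg, design)
        counts = per_hybrid_de_counts(screen, design, pcfg)
        assert (counts["n_de"] <= screen.table["de_pass"].sum()).all()
        assert counts.attrs["mean_de"] >= 0

    def test_constructed_pair_outcomes(self, pcfg):
        """Extreme effects make the per-pair outcome unambiguous: probes g1,
        g2 split F1 vs D01 only; g3 splits F2 vs D01 only."""
        em = toy_expression(
            {
                "g1": [12.0, 9.0, 9.0],
                "g2": [13.0, 9.0, 9.0],
                "g3": [9.0, 12.0, 9.0],
                "g4": [9.0, 9.0, 9.0],
            },
            lines=("F1", "F2", "D01"), reps=3, sigma=0.05, seed=6,
        )
        design = FactorialDesign(pd.DataFrame(
            {"hybrid_id": ["F1xD01", "F2xD01"], "flint_parent": ["F1", "F2"],
             "dent_parent": ["D01", "D01"]}
        ))
        screen = select_differential(em, pcfg, design)
        counts = per_hybrid_de_counts(screen, design, pcfg)
        assert counts.loc["F1xD01", "n_de"] == 2  # g1, g2
        assert counts.loc["F2xD01", "n_de"] == 1  # g3

    def test_missing_line_rejected(self, pcfg):
        em, _ = _four_probe_screen()
        bad = FactorialDesign(pd.DataFrame(
            {"hybrid_id": ["x"], "flint_parent": ["F9"], "dent_parent": ["D01"]}
        ))
        with pytest.raises(DataError, match="F9"):
            select_differential(em, pcfg, bad)


def test_percent_rounding():
    assert percent(468, 745) == 62.8
    assert percent(3350, 43381) == 7.7
    with pytest.raises(DataError):
        percent(1, 0)
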