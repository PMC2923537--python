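import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hybridcor import (
    DataError,
    bca_ci,
    compute_heterosis,
    compute_midparent,
    correlate_matrix,
    correlate_trait,
    trait_permutation_test,
)
from hybridcor.io import FactorialDesign


def _grid_design(nf=3, nd=3):
    rows = [(f"F{i}xD{j}", f"F{i}", f"D{j}") for i in range(nf) for j in range(nd)]
    return FactorialDesign(
        pd.DataFrame(rows, columns=["hybrid_id", "flint_parent", "dent_parent"])
    )


class TestMidparent:
    def test_simple_average(self):
        lm = pd.DataFrame({"F0": [8.0], "D0": [10.0]}, index=["g"])
        d = FactorialDesign(pd.DataFrame(
            {"hybrid_id": ["h"], "flint_parent": ["F0"], "dent_parent": ["D0"]}
        ))
        assert compute_midparent(lm, d).at["g", "h"] == 9.0

    def test_identical_parents_identity(self):
        lm = pd.DataFrame({"F0": [7.3], "D0": [7.3]}, index=["g"])
        d = FactorialDesign(pd.DataFrame(
            {"hybrid_id": ["h"], "flint_parent": ["F0"], "dent_parent": ["D0"]}
        ))
        assert compute_midparent(lm, d).at["g", "h"] == 7.3

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(3)
        design = _grid_design()
        lines = sorted({*design.table["flint_parent"], *design.table["dent_parent"]})
        lm = pd.DataFrame(rng.normal(9, 1, size=(10, 6)), columns=lines,
                          index=[f"g{i}" for i in range(10)])
        L = compute_midparent(lm, design)
        for h, p1, p2 in design.parent_pairs():
            np.testing.assert_allclose(L[h], (lm[p1] + lm[p2]) / 2)
        # L always lies between the parental means
        lo = np.minimum.reduce([lm[p1].to_numpy() for _, p1, _ in design.parent_pairs()])
        assert np.isfinite(L.to_numpy()).all()

    def test_missing_parent_named(self):
        lm = pd.DataFrame({"F0": [8.0]}, index=["g"])
        d = FactorialDesign(pd.DataFrame(
            {"hybrid_id": ["hX"], "flint_parent": ["F0"], "dent_parent": ["D9"]}
        ))
        with pytest.raises(DataError, match="hX"):
            compute_midparent(lm, d)


class TestHeterosis:
    def test_hand_values(self, small_dataset):
        from hybridcor.io import TraitTable

        perse = pd.DataFrame(
            {"yield_perse": [8.0, 8.0], "gdmc_perse": [70.0, 74.0]},
            index=pd.Index(["F0", "D0"], name="line_id"),
        )
        tab = pd.DataFrame({"PY": [10.0], "PD": [72.0]}, index=pd.Index(["h"], name="hybrid_id"))
        d = FactorialDesign(pd.DataFrame(
            {"hybrid_id": ["h"], "flint_parent": ["F0"], "dent_parent": ["D0"]}
        ))
        het = compute_heterosis(TraitTable(table=tab), perse, d)
        assert het.at["h", "HY"] == 2.0   # F1 above mid-parent
        assert het.at["h", "HD"] == 0.0   # F1 exactly at mid-parent

    def test_generator_round_trip(self, small_dataset):
        """Recomputing heterosis from the emitted per-se line values matches
        the generator's own HY/HD exactly."""
        expr, design, traits, _ = small_dataset
        het = compute_heterosis(traits, traits.line_perse, design)
        np.testing.assert_allclose(het["HY"], traits.table["HY"], atol=1e-10)
        np.testing.assert_allclose(het["HD"], traits.table["HD"], atol=1e-10)

    def test_missing_perse_rejected(self, small_dataset):
        expr, design, traits, _ = small_dataset
        with pytest.raises(DataError):
            compute_heterosis(traits, traits.line_perse.iloc[:3], design)


class TestCorrelateTrait:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, t, p = correlate_trait(x, 2 * x + 1)
        assert (r, p) == (1.0, 0.0)

    def test_orthogonal_deviations(self):
        r, t, p = correlate_trait([1, 2, 3, 4], [1, 2, 2, 1])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_vector_flagged_not_fatal(self):
        r, t, p = correlate_trait([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 98))
        r, t, p = correlate_trait(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=50),
           st.floats(min_value=-100, max_value=100),
           st.booleans())
    def test_affine_invariance(self, scale, shift, flip):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=(2, 30))
        r0, _, p0 = correlate_trait(x, y)
        a = -scale if flip else scale
        r1, _, p1 = correlate_trait(x, a * y + shift)
        assert r1 == pytest.approx(-r0 if flip else r0, abs=1e-9)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_matrix_version_consistent(self, small_products):
        _, L, trait_frame, records = small_products
        pid = L.index[5]
        r, t, p = correlate_trait(L.loc[pid].to_numpy(), trait_frame["PY"].to_numpy())
        assert records.at[pid, "r_PY"] == pytest.approx(r, abs=1e-12)
        assert records.at[pid, "p_PY"] == pytest.approx(p, rel=1e-9)

    def test_q_dominates_and_preserves_order(self, small_products):
        *_, records = small_products
        sub = records.dropna(subset=["p_PY"])
        assert (sub["q_PY"] >= sub["p_PY"] - 1e-15).all()
        order = sub.sort_values("p_PY")
        assert order["q_PY"].is_monotonic_increasing


class TestBcaCI:
    def test_collinear_degenerate(self):
        x = np.arange(8.0)
        assert bca_ci(x, 3 * x, B=200, seed=1) == (1.0, 1.0)

    def test_reduces_to_percentile_when_symmetric(self):
        """With no bias and no skew the BCa endpoints sit on the plain
        percentile endpoints (same resamples)."""
        n = 400  # large n keeps the jackknife acceleration near zero
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=(2, n))
        lo, hi = bca_ci(x, y, B=10000, seed=5)
        # replicate the resampling stream to obtain the percentile interval
        rng2 = np.random.default_rng(5)
        idx = rng2.integers(0, n, size=(10000, n))
        xs, ys = x[idx], y[idx]
        xc = xs - xs.mean(axis=1, keepdims=True)
        yc = ys - ys.mean(axis=1, keepdims=True)
        theta = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        plo, phi = np.quantile(theta, [0.025, 0.975])
        assert abs(lo - plo) < 0.01 and abs(hi - phi) < 0.01

    def test_endpoints_bounded(self):
        rng = np.random.default_rng(31)
        for i in range(10):
            x, y = rng.normal(size=(2, 12))
            lo, hi = bca_ci(x, y, B=400, seed=i)
            assert -1 <= lo <= hi <= 1

    def test_needs_four_pairs(self):
        with pytest.raises(DataError):
            bca_ci([1, 2, 3], [3, 2, 1], B=100)


class TestPermutationTest:
    def test_self_correlation_minimal_p(self):
        y = np.random.default_rng(2).normal(size=20)
        r, p = trait_permutation_test(y, y, n_perm=9999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1e-4)

    def test_add_one_floor(self):
        y = np.random.default_rng(3).normal(size=20)
        _, p = trait_permutation_test(y, 2 * y + 1, n_perm=99, seed=0)
        assert p >= 1 / 100

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError):
            trait_permutation_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_agrees_with_t_test_asymptotically(self):
        """Independent Gaussians, n = 98: the Monte Carlo permutation p tracks
        the parametric t-test p to within 0.02 across seeds."""
        rng = np.random.default_rng(13)
        worst = 0.0
        for s in range(100):
            x, y = rng.normal(size=(2, 98))
            _, _, p_t = correlate_trait(x, y)
            _, p_perm = trait_permutation_test(x, y, n_perm=9999, seed=s)
            worst = max(worst, abs(p_perm - p_t))
        assert worst < 0.02
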