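"""Cross-assay integration: correlation, classes, induction, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from capmeth import integration as itg
from capmeth.types import InsufficientDataError

from _oracles import bh_stepup, hypergeom_tail


class TestCorrelate:
    def test_perfect_anticorrelation_and_correlation(self):
        x = pd.Series([1.0, 2.0, 5.0, 9.0], index=list("abcd"))
        r_neg, n = itg.correlate(x, -x)
        r_pos, _ = itg.correlate(x, x)
        assert r_neg == pytest.approx(-1.0) and r_pos == pytest.approx(1.0)
        assert n == 4

    def test_pearson_matches_closed_form(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([2.0, 1.0, 4.0, 3.0], index=list("abcd"))
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std(ddof=0) * y.std(ddof=0))
        r, _ = itg.correlate(x, y)
        assert r == pytest.approx(float(expected), rel=1e-12)

    def test_intersection_drops_nonfinite_and_unshared(self):
        x = pd.Series([1.0, 2.0, 3.0, np.nan, 5.0], index=list("abcde"))
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("abcdef"))
        _, n = itg.correlate(x, y)
        assert n == 4

    def test_too_few_genes(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(InsufficientDataError):
            itg.correlate(x, x)


class TestMedianSplit:
    def test_strict_above_median_is_high(self):
        v = pd.Series([10.0, 20.0, 30.0, 40.0], index=list("abcd"))
        labels = itg.median_split(v)  # median 25
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_all_equal_goes_low(self):
        v = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        assert (itg.median_split(v) == "low").all()

    def test_pair(self):
        v = pd.Series([1.0, 2.0], index=list("ab"))
        assert itg.median_split(v)["b"] == "high"

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_partition_property(self, values):
        v = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        labels = itg.median_split(v)
        assert len(labels) == len(v)
        assert set(labels.unique()) <= {"high", "low"}
        assert (v[labels == "high"] > v.median()).all()
        assert (v[labels == "low"] <= v.median()).all()


class TestHighConfidence:
    def _tables(self, meth_vals, captag_vals):
        idx = pd.Index([f"g{i}" for i in range(len(meth_vals))], name="gene_id")
        meth = pd.DataFrame({"pct_methylation": meth_vals}, index=idx)
        tag = pd.DataFrame({"pct_input_corrected": captag_vals}, index=idx)
        return meth, tag

    def test_perfect_anticorrelation_classifies_everyone(self):
        vals = np.linspace(0, 100, 10)
        meth, tag = self._tables(vals, 100 - vals)
        labels = itg.high_confidence(meth, tag)
        assert (labels["high_confidence_high"] ^ labels["high_confidence_low"]).all()

    def test_concordant_gene_in_neither_class(self):
        meth, tag = self._tables([90, 10, 50, 30], [9, 1, 5, 3])
        labels = itg.high_confidence(meth, tag)
        g0 = labels.loc["g0"]  # high methylation but also high % input
        assert not g0["high_confidence_high"] and not g0["high_confidence_low"]

    def test_independent_labels_give_quarter_intersections(self):
        rng = np.random.default_rng(17)
        meth, tag = self._tables(rng.random(1000), rng.random(1000))
        labels = itg.high_confidence(meth, tag)
        # under independence each intersection is Binomial(1000, 1/4)
        sigma = np.sqrt(1000 * 0.25 * 0.75)
        for col in ("high_confidence_high", "high_confidence_low"):
            assert abs(labels[col].sum() - 250) <= 3 * sigma

    def test_disjoint_universes_error(self):
        meth, _ = self._tables([1, 2, 3], [1, 2, 3])
        tag = pd.DataFrame(
            {"pct_input_corrected": [1.0]}, index=pd.Index(["other"], name="gene_id")
        )
        with pytest.raises(InsufficientDataError):
            itg.high_confidence(meth, tag)


class TestInducedSubset:
    @pytest.mark.parametrize("ratio, flag", [(2.0, True), (1.99, False)])
    def test_boundary_inclusive(self, ratio, flag):
        out = itg.induced_subset(pd.Series({"g": ratio}), pd.Series({"g": 1.0}))
        assert bool(out.loc["g", "induced"]) is flag

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        mn = pd.Series(rng.uniform(1, 10, 50))
        rich = pd.Series(rng.uniform(1, 10, 50))
        a = itg.induced_subset(mn, rich)["induced"]
        b = itg.induced_subset(2 * mn, 2 * rich)["induced"]
        assert a.equals(b)

    def test_zero_rich_not_evaluable(self):
        out = itg.induced_subset(pd.Series({"g": 5.0}), pd.Series({"g": 0.0}))
        assert not bool(out.loc["g", "evaluable"])


class TestEnrich:
    def test_degenerate_full_table(self):
        genes = {f"g{i}" for i in range(10)}
        res = itg.enrich(genes, {"T": genes}, genes)
        assert res.loc["T", "p_value"] == pytest.approx(1.0)

    def test_hypergeometric_tail_example(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = itg.enrich(query, {"T": term}, universe)  # k=5, K=20, n=10, N=100
        assert res.loc["T", "p_value"] == pytest.approx(
            hypergeom_tail(5, 100, 20, 10), rel=1e-12
        )

    def test_equal_pvalues_are_bh_fixed_point(self):
        universe = {f"g{i}" for i in range(40)}
        terms = {f"T{j}": {f"g{i}" for i in range(j, j + 10)} for j in range(0, 30, 10)}
        query = {f"g{i}" for i in range(0, 40, 4)}
        res = itg.enrich(query, terms, universe)
        if res["p_value"].nunique() == 1:
            np.testing.assert_allclose(res["q_value"], res["p_value"])
        # BH always matches the brute-force step-up regardless
        np.testing.assert_allclose(
            res.sort_index()["q_value"],
            bh_stepup(res.sort_index()["p_value"].to_numpy()),
            rtol=1e-12,
        )

    def test_counts_and_monotonicity_invariants(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(200)]
        terms = {
            f"T{j}": set(rng.choice(universe, size=rng.integers(5, 40), replace=False))
            for j in range(15)
        }
        query = set(rng.choice(universe, size=50, replace=False))
        res = itg.enrich(query, terms, universe)
        assert ((res["k"] >= 0) & (res["k"] <= res[["K", "n"]].min(axis=1))).all()
        assert res["p_value"].is_monotonic_increasing
        assert res.loc[res["p_value"].sort_values().index, "q_value"].is_monotonic_increasing

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            itg.enrich(set(), {}, set())


class TestFisherOracle:
    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            assert itg.fisher_overrep_p(k, N, K, n) == pytest.approx(
                hypergeom_tail(k, N, K, n), rel=1e-10, abs=1e-300
            )


@given(
    st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20)
)
@settings(deadline=None, derandomize=True)
def test_bh_matches_brute_force_stepup(pvals):
    """The BH q-values used for enrichment equal the literal step-up rule."""
    from statsmodels.stats.multitest import multipletests

    q = multipletests(np.array(pvals), method="fdr_bh")[1]
    np.testing.assert_allclose(q, bh_stepup(np.array(pvals)), rtol=1e-12, atol=1e-15)
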