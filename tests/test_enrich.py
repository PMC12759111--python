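"""Tests of the Fisher-exact machinery, clock/DHS enrichment and the
genomic-feature tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from methylopace.enrich import (ContingencyTable, bh_adjust, clock_enrichment,
                                dhs_enrichment, feature_distribution,
                                fisher_exact_2x2)
from methylopace.scan import CpGCallTable
from methylopace.simulate import GENOMIC_FEATURES


def enumeration_fisher_p(a, b, c, d):
    """Independent oracle: sum hypergeometric probabilities of all tables
    with the observed margins whose probability <= observed (1e-7 slack)."""
    N = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    probs = sps.hypergeom.pmf(ks, N, c1, r1)
    p_obs = sps.hypergeom.pmf(a, N, c1, r1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def _calls_from_categories(categories: pd.Series) -> CpGCallTable:
    table = pd.DataFrame({"category": categories, "converged": True,
                          "degenerate": False})
    table.index.name = "cpg"
    return CpGCallTable(table=table, slopes=pd.DataFrame(),
                        family_alpha=0.05, criterion="lrt_mixture",
                        n_tests=len(table))


class TestFisher:
    def test_perfect_independence(self):
        res = fisher_exact_2x2(ContingencyTable(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_example_table_against_enumeration(self):
        res = fisher_exact_2x2(ContingencyTable(5, 1, 2, 10))
        assert res.odds_ratio == pytest.approx(25.0)
        assert res.pvalue == pytest.approx(
            enumeration_fisher_p(5, 1, 2, 10), abs=1e-10)

    def test_row_swap_inverts_or_preserves_p(self):
        fwd = fisher_exact_2x2(ContingencyTable(5, 1, 2, 10))
        rev = fisher_exact_2x2(ContingencyTable(2, 10, 5, 1))
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)
        assert rev.pvalue == pytest.approx(fwd.pvalue, abs=1e-12)

    def test_double_swap_invariance(self):
        fwd = fisher_exact_2x2(ContingencyTable(7, 2, 3, 9))
        swp = fisher_exact_2x2(ContingencyTable(9, 3, 2, 7))
        assert swp.odds_ratio == pytest.approx(fwd.odds_ratio)
        assert swp.pvalue == pytest.approx(fwd.pvalue, abs=1e-12)

    def test_exhaustive_sweep_small_totals(self):
        # every table with total <= 30 matches the enumeration oracle
        worst = 0.0
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = ContingencyTable(a, b, c, d)
                        arr = t.array
                        if (arr.sum(0) == 0).any() or (arr.sum(1) == 0).any():
                            continue
                        p = fisher_exact_2x2(t).pvalue
                        worst = max(worst, abs(p - enumeration_fisher_p(
                            a, b, c, d)))
        assert worst < 1e-9

    def test_matches_scipy_reference(self, rng):
        # independent library oracle on random tables
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            mine = fisher_exact_2x2(ContingencyTable(a, b, c, d)).pvalue
            ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_zero_cell_haldane_correction(self):
        res = fisher_exact_2x2(ContingencyTable(0, 5, 5, 5))
        assert res.zero_cell
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_empty_margin_flagged_not_crashed(self):
        res = fisher_exact_2x2(ContingencyTable(0, 0, 3, 7))
        assert res.degenerate_margin
        assert res.pvalue == 1.0

    def test_invalid_cells(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestBH:
    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_monotone_and_order_preserving(self, ps):
        adj = bh_adjust(ps)
        ps = np.asarray(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestClockEnrichment:
    @staticmethod
    def _universe(n=2000):
        return pd.Index([f"cg{i:05d}" for i in range(n)])

    def test_planted_clock_subset_of_age_associated(self, rng):
        uni = self._universe()
        cats = pd.Series("neither", index=uni)
        assoc = uni[:400]
        cats[assoc] = "age_associated"
        calls = _calls_from_categories(cats)
        clock = list(rng.choice(assoc, size=60, replace=False))
        out = clock_enrichment(calls, {"hannum": clock}).set_index(
            ["clock", "category"])
        row = out.loc[("hannum", "age_associated")]
        assert row["odds_ratio"] > 1
        assert row["p"] < 0.05

    def test_universe_restriction(self, rng):
        uni = self._universe(500)
        cats = pd.Series("neither", index=uni)
        cats[uni[:100]] = "age_varying"
        calls = _calls_from_categories(cats)
        clock = list(uni[:50])
        base = clock_enrichment(calls, {"c": clock})
        noisy = clock_enrichment(calls, {"c": clock + ["cg_foreign_1",
                                                       "cg_foreign_2"]})
        pd.testing.assert_frame_equal(base, noisy)

    def test_null_clock_rarely_bh_significant(self, rng):
        uni = self._universe(1000)
        cats = pd.Series("neither", index=uni)
        cats[uni[:200]] = "age_associated"
        cats[uni[200:260]] = "age_varying"
        calls = _calls_from_categories(cats)
        n_runs, hits = 200, 0
        for _ in range(n_runs):
            clocks = {f"c{k}": list(rng.choice(uni, 50, replace=False))
                      for k in range(5)}
            out = clock_enrichment(calls, clocks)
            hits += bool((out["p_adj"] < 0.05).any())
        assert hits <= 0.05 * n_runs

    def test_empty_intersection_is_na(self):
        uni = self._universe(100)
        calls = _calls_from_categories(pd.Series("neither", index=uni))
        out = clock_enrichment(calls, {"empty": ["cg_not_here"]})
        assert out["empty"].all()
        assert out["p"].isna().all()

    def test_inclusive_category_sets_count_both(self):
        uni = self._universe(100)
        cats = pd.Series("neither", index=uni)
        cats[uni[:10]] = "both"
        calls = _calls_from_categories(cats)
        out = clock_enrichment(calls, {"c": list(uni[:10])}).set_index(
            ["clock", "category"])
        # the 'both' CpGs fill the clock ∩ category cell for either category
        assert out.loc[("c", "age_associated"), "odds_ratio"] > 1
        assert out.loc[("c", "age_varying"), "odds_ratio"] > 1


class TestDHS:
    @staticmethod
    def _fixture(n_varying, n_assoc, frac_varying, frac_assoc):
        ids = pd.Index([f"cg{i}" for i in range(n_varying + n_assoc)])
        cats = pd.Series(["age_varying"] * n_varying +
                         ["age_associated"] * n_assoc, index=ids)
        flags = pd.Series(0, index=ids)
        flags.iloc[:int(n_varying * frac_varying)] = 1
        start = n_varying
        flags.iloc[start:start + int(n_assoc * frac_assoc)] = 1
        return _calls_from_categories(cats), flags

    def test_balanced_fixture_is_null(self):
        calls, flags = self._fixture(2000, 2000, 0.5, 0.5)
        res = dhs_enrichment(calls, flags)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.01)
        assert res.pvalue > 0.05

    def test_constructed_enrichment_or_and_p(self):
        # DHS fraction 0.6 in 3000 age-varying vs 0.5 in 120000
        # age-associated: OR = (1800*60000)/(1200*60000) = 1.5
        calls, flags = self._fixture(3000, 120000, 0.6, 0.5)
        res = dhs_enrichment(calls, flags)
        assert res.odds_ratio == pytest.approx(1.5, abs=1e-9)
        assert res.pvalue < 0.001

    def test_flag_complement_inverts_or(self):
        calls, flags = self._fixture(300, 1200, 0.6, 0.5)
        fwd = dhs_enrichment(calls, flags)
        rev = dhs_enrichment(calls, 1 - flags)
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)

    def test_missing_flag_raises(self):
        calls, flags = self._fixture(10, 10, 0.5, 0.5)
        with pytest.raises(ValueError, match="missing"):
            dhs_enrichment(calls, flags.iloc[:-1])


class TestFeatureDistribution:
    @staticmethod
    def _fixture(rng, n=4000, concentrate=None):
        ids = pd.Index([f"cg{i}" for i in range(n)])
        cats = pd.Series(rng.choice(["age_associated", "age_varying"], n),
                         index=ids)
        feats = pd.Series(rng.choice(GENOMIC_FEATURES, n), index=ids)
        if concentrate:
            feats[cats == concentrate] = "TSS200"
        return _calls_from_categories(cats), feats

    def test_proportions_normalize(self, rng):
        calls, feats = self._fixture(rng)
        counts, props, _ = feature_distribution(calls, feats)
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)
        assert counts.to_numpy().sum() == 4000

    def test_independent_features_give_uniform_p(self):
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(200):
            calls, feats = self._fixture(rng, n=800)
            ps.append(feature_distribution(calls, feats)[2])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_dependence_detected(self, rng):
        calls, feats = self._fixture(rng, n=10000,
                                     concentrate="age_varying")
        _, _, p = feature_distribution(calls, feats)
        assert p < 1e-6

    def test_unknown_labels_listed(self, rng):
        calls, feats = self._fixture(rng, n=50)
        feats.iloc[0] = "Promoter???"
        with pytest.raises(ValueError, match="Promoter"):
            feature_distribution(calls, feats)
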