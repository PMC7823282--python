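"""Unit and oracle tests for the built-in DEG callers."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refnof1 import CountMatrix, adapt_external, bh_adjust, call_degs
from refnof1.callers import (METHODS, _mwu_pmf, hypergeom_two_sided_p,
                             pooled_exact, rank_sum, significant_genes)
from refnof1.errors import CapabilityError, ConfigurationError, \
    ValidationError
from refnof1.io import ExternalDEGTable
from tests.conftest import random_count_matrix


def exact_hypergeom_oracle(k_obs, t, lib_a, lib_b):
    """Independent two-sided p by exact rational enumeration of all tables."""
    k_min, k_max = max(0, t - lib_b), min(t, lib_a)
    probs = {k: Fraction(math.comb(lib_a, k) * math.comb(lib_b, t - k),
                         math.comb(lib_a + lib_b, t))
             for k in range(k_min, k_max + 1)}
    obs = probs[k_obs]
    return float(sum(p for p in probs.values() if p <= obs))


def _two_sample_matrix(counts_a, counts_b):
    genes = [f"g{i}" for i in range(len(counts_a))]
    frame = pd.DataFrame({"a": counts_a, "b": counts_b}, index=genes)
    return CountMatrix(frame, pd.Series({"a": "A", "b": "B"}))


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_dominates_raw_and_is_stable(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        q = bh_adjust(p)
        assert np.all(q >= p)
        assert np.all(bh_adjust(q) >= q - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestPooledExact:
    def test_identical_pooled_proportions_give_p_one(self):
        cm = _two_sample_matrix([10, 90], [20, 180])
        res = call_degs("pooled_exact", cm)
        assert res.loc["g0", "pvalue"] == pytest.approx(1.0)
        assert not res["significant"].any()

    def test_ten_vs_zero_of_thousand_matches_enumeration(self):
        p = hypergeom_two_sided_p(10, 10, 1000, 1000)
        assert p == pytest.approx(exact_hypergeom_oracle(10, 10, 1000, 1000),
                                  abs=1e-12)
        # symmetric libraries: both extreme tables are equally probable
        assert p == pytest.approx(2 * math.comb(1000, 10)
                                  / math.comb(2000, 10), rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            lib_a, lib_b = rng.integers(1, 31, size=2)
            t = int(rng.integers(0, lib_a + lib_b + 1))
            k_min, k_max = max(0, t - lib_b), min(t, lib_a)
            k = int(rng.integers(k_min, k_max + 1))
            assert hypergeom_two_sided_p(k, t, int(lib_a), int(lib_b)) == \
                pytest.approx(exact_hypergeom_oracle(k, t, int(lib_a),
                                                     int(lib_b)), abs=1e-10)

    def test_large_table_float_path_matches_fisher(self):
        # scipy's two-sided Fisher test as an independent reference
        for (ka, kb, la, lb) in [(120, 80, 100_000, 100_000),
                                 (40, 70, 50_000, 80_000)]:
            table = [[ka, la - ka], [kb, lb - kb]]
            expected = stats.fisher_exact(table)[1]
            got = hypergeom_two_sided_p(ka, ka + kb, la, lb)
            assert got == pytest.approx(expected, rel=1e-6)

    def test_runs_on_single_sample_pairs(self):
        cm = _two_sample_matrix([50, 10, 0], [5, 10, 30])
        res = call_degs("pooled_exact", cm)
        assert len(res) == 3
        assert ((res["pvalue"] >= 0) & (res["pvalue"] <= 1)).all()


class TestRankSum:
    def test_maximal_separation_three_vs_three(self):
        # the second, constant gene keeps library sizes non-degenerate
        counts = pd.DataFrame(
            [[10, 11, 12, 100, 110, 120],
             [1000, 1000, 1000, 1000, 1000, 1000]], index=["g0", "gfill"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        cm = CountMatrix(counts, pd.Series(
            {"a1": "A", "a2": "A", "a3": "A",
             "b1": "B", "b2": "B", "b3": "B"}))
        res = rank_sum(cm)
        # 2 of the 20 equally likely rank assignments are this extreme
        assert res.loc["g0", "pvalue"] == pytest.approx(0.1)

    def test_exact_p_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        cm = random_count_matrix(rng, n_genes=40, n_per_condition=4,
                                 mean=500.0)
        res = rank_sum(cm)
        y = cm.counts.to_numpy(dtype=float) / \
            (cm.library_sizes.to_numpy() / cm.library_sizes.mean())
        for i, g in enumerate(cm.gene_ids):
            if len(np.unique(y[i])) < 8:
                continue
            expected = stats.mannwhitneyu(y[i, :4], y[i, 4:],
                                          method="exact")[1]
            assert res.loc[g, "pvalue"] == pytest.approx(expected, abs=1e-12)

    def test_null_pmf_sums_to_one(self):
        for n1, n2 in [(3, 3), (4, 5), (7, 7)]:
            pmf = _mwu_pmf(n1, n2)
            assert pmf.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(pmf, pmf[::-1])  # symmetric null

    def test_requires_three_replicates(self):
        rng = np.random.default_rng(6)
        cm = random_count_matrix(rng, n_per_condition=2)
        with pytest.raises(CapabilityError, match="rank_sum"):
            call_degs("rank_sum", cm)


class TestLogRatioTests:
    def test_nb_wald_null_gene_has_no_signal(self):
        # constant rows => equal library sizes, so gene g0 is an exact null
        counts = pd.DataFrame(
            [[100, 100, 100, 100, 100, 100],
             [50, 50, 50, 50, 50, 50]],
            index=["g0", "g1"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        cm = CountMatrix(counts, pd.Series(
            {"a1": "A", "a2": "A", "a3": "A",
             "b1": "B", "b2": "B", "b3": "B"}))
        res = call_degs("nb_wald", cm)
        assert res.loc["g0", "log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc["g0", "pvalue"] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("method", ["nb_wald", "zlogfc"])
    def test_one_vs_one_needs_fixed_dispersion(self, method):
        cm = _two_sample_matrix([50, 10], [5, 10])
        with pytest.raises(CapabilityError):
            call_degs(method, cm)
        res = call_degs(method, cm, dispersion=0.05)
        assert len(res) == 2

    def test_negative_dispersion_rejected(self):
        cm = _two_sample_matrix([50, 10], [5, 10])
        with pytest.raises(ConfigurationError):
            call_degs("nb_wald", cm, dispersion=-1.0)


class TestCallDegs:
    def test_significance_is_padj_below_alpha(self):
        rng = np.random.default_rng(7)
        cm = random_count_matrix(rng, n_genes=50, n_per_condition=5)
        res = call_degs("zlogfc", cm, alpha=0.5)
        assert (res["significant"] == (res["padj"] < 0.5)).all()

    def test_unknown_method_rejected(self, toy_counts):
        with pytest.raises(ConfigurationError, match="unknown method"):
            call_degs("edgeR", toy_counts)

    def test_registry_exposes_four_builtins(self):
        assert set(METHODS) == {"pooled_exact", "nb_wald", "rank_sum",
                                "zlogfc"}


class TestAdaptExternal:
    @staticmethod
    def _table():
        frame = pd.DataFrame(
            {"log2fc": [2.0, 0.1], "pvalue": [1e-4, 0.1],
             "padj": [0.001, 0.2]}, index=pd.Index(["g1", "g2"],
                                                   name="gene_id"))
        return ExternalDEGTable("toolX", frame)

    def test_threshold_within_universe(self):
        ds = adapt_external(self._table(), ["g1", "g2"], alpha=0.05)
        assert ds.genes == frozenset({"g1"})
        assert ds.method_id == "toolX"

    def test_universe_gene_missing_from_table_excluded(self, caplog):
        with caplog.at_level("INFO", logger="refnof1.callers"):
            ds = adapt_external(self._table(), ["g1", "g2", "g9"],
                                alpha=0.05)
        assert "g9" not in ds.genes
        assert "absent" in caplog.text

    def test_empty_universe_gives_empty_set(self):
        assert adapt_external(self._table(), [], alpha=0.05).genes == \
            frozenset()
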