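import math

import pandas as pd
import pytest

from refnof1 import (CountMatrix, DEGSet, build_rs, evaluate_method,
                     make_holdout, precision_recall)
from refnof1.errors import BiasGuardError, CapabilityError, SizingError
from refnof1.evaluation import _predict_pair, build_region_rs
from refnof1.filtering import FilterRegion
from refnof1.io import _mean_defined
from refnof1.simulate import SimConfig, simulate

REGION = FilterRegion(5, 1.2, math.inf)
RS_METHODS = ["nb_wald", "rank_sum", "zlogfc"]


@pytest.fixture(scope="module")
def sim_counts():
    cfg = SimConfig(seed=77, n_genes=600, n_replicates=7,
                    baseline_log_mean=5.0, baseline_log_sd=1.0)
    return simulate(cfg)[0]


class TestMakeHoldout:
    def test_mcf7_style_split(self, sim_counts):
        plan = make_holdout(sim_counts, 4, 3, seed=1)
        assert len(plan.reference["A"]) == len(plan.reference["B"]) == 4
        assert len(plan.pairs) == 3
        used = set(plan.reference_samples)
        for sa, sb in plan.pairs:
            assert sim_counts.design[sa] == "A"
            assert sim_counts.design[sb] == "B"
            assert sa not in used and sb not in used

    def test_same_seed_reproduces_plan(self, sim_counts):
        assert make_holdout(sim_counts, 4, 3, seed=5) == \
            make_holdout(sim_counts, 4, 3, seed=5)

    def test_oversubscription_raises_sizing_error(self, sim_counts):
        with pytest.raises(SizingError):
            make_holdout(sim_counts, 4, 4, seed=1)


class TestPrecisionRecall:
    @staticmethod
    def _rs(positives, universe):
        sets = [DEGSet("x", "r", frozenset(positives)),
                DEGSet("y", "r", frozenset(positives))]
        return build_rs(sets, "intersection", universe=universe)

    def test_perfect_prediction(self):
        rs = self._rs({"a", "b"}, ["a", "b", "c"])
        m = precision_recall({"a", "b"}, rs)
        assert (m.precision, m.recall) == (1.0, 1.0)

    def test_counts_by_hand(self):
        rs = self._rs({"a", "b", "e"}, list("abcdef"))
        m = precision_recall({"a", "b", "c", "d"}, rs)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(2 / 3)

    def test_empty_prediction_is_undefined_precision_zero_recall(self):
        rs = self._rs({"a"}, ["a", "b"])
        m = precision_recall(set(), rs)
        assert m.precision is None
        assert m.recall == 0.0

    def test_predictions_outside_universe_dropped(self, caplog):
        rs = self._rs({"a"}, ["a", "b"])
        with caplog.at_level("INFO", logger="refnof1.evaluation"):
            m = precision_recall({"a", "zz"}, rs)
        assert m.predicted_positives == 1
        assert m.precision == 1.0

    def test_invariant_under_gene_relabeling(self):
        mapping = {g: f"X{g}" for g in "abcdef"}
        rs = self._rs({"a", "b", "e"}, list("abcdef"))
        rs2 = self._rs({mapping[g] for g in ("a", "b", "e")},
                       [mapping[g] for g in "abcdef"])
        m1 = precision_recall({"a", "c"}, rs)
        m2 = precision_recall({mapping["a"], mapping["c"]}, rs2)
        assert (m1.precision, m1.recall) == (m2.precision, m2.recall)


class TestEvaluateMethod:
    def test_report_composes_per_pair_scores(self, sim_counts):
        plan = make_holdout(sim_counts, 4, 3, seed=3)
        report = evaluate_method(sim_counts, plan, "pooled_exact",
                                 RS_METHODS, REGION, rs_rule="majority")
        # recompute by hand from the same building blocks
        ref = sim_counts.subset_samples(plan.reference_samples)
        rs = build_region_rs(ref, RS_METHODS, REGION, "majority",
                             exclude="pooled_exact")
        expected = []
        for pair in plan.pairs:
            predicted = _predict_pair(sim_counts, pair, "pooled_exact",
                                      REGION, 0.05, "total_count", 0.5, 0.05)
            expected.append(precision_recall(predicted, rs))
        assert [p.precision for p in report.pairs] == \
            [m.precision for m in expected]
        assert report.average_precision == \
            _mean_defined([m.precision for m in expected])
        assert report.average_recall == \
            _mean_defined([m.recall for m in expected])

    def test_prediction_method_in_rs_is_refused(self, sim_counts):
        plan = make_holdout(sim_counts, 4, 3, seed=3)
        with pytest.raises(BiasGuardError, match="isomorphic"):
            evaluate_method(sim_counts, plan, "nb_wald", RS_METHODS,
                            REGION)

    def test_replicate_requiring_method_rejected_for_pairs(self, sim_counts):
        plan = make_holdout(sim_counts, 4, 3, seed=3)
        with pytest.raises(CapabilityError, match="1-vs-1"):
            evaluate_method(sim_counts, plan, "rank_sum",
                            ["nb_wald", "zlogfc"], REGION)

    def test_unfiltered_mode_scores_full_pair_calls(self, sim_counts):
        plan = make_holdout(sim_counts, 4, 3, seed=3)
        filt = evaluate_method(sim_counts, plan, "pooled_exact",
                               RS_METHODS, REGION, rs_rule="majority")
        raw = evaluate_method(sim_counts, plan, "pooled_exact",
                              RS_METHODS, REGION, rs_rule="majority",
                              filter_predictions=False)
        n_filt = sum(p.predicted_positives for p in filt.pairs)
        n_raw = sum(p.predicted_positives for p in raw.pairs)
        assert n_raw >= n_filt

    def test_provenance_records_the_run(self, sim_counts):
        plan = make_holdout(sim_counts, 4, 3, seed=11)
        report = evaluate_method(sim_counts, plan, "pooled_exact",
                                 RS_METHODS, REGION, rs_rule="majority")
        prov = report.provenance
        assert prov["seed"] == 11
        assert prov["excluded_method"] == "pooled_exact"
        assert prov["region"] == REGION.region_id


def test_rs_built_from_truth_matches_truth_scoring():
    """Scoring against planted truth == scoring against an RS whose
    positives are exactly the planted truth."""
    from refnof1.simulate import truth_metrics
    cfg = SimConfig(seed=99, n_genes=300, n_replicates=5,
                    baseline_log_mean=5.0, baseline_log_sd=1.0)
    cm, truth = simulate(cfg)
    oracle_sets = [DEGSet(m, "r", truth.deg_genes) for m in ("o1", "o2")]
    rs = build_rs(oracle_sets, "intersection", universe=cm.gene_ids)
    predicted = set(list(truth.deg_genes)[:10]) | {"g000001"}
    via_rs = precision_recall(predicted, rs)
    via_truth = truth_metrics(predicted, truth)
    assert via_rs.precision == via_truth.precision
    assert via_rs.recall == via_truth.recall
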