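import itertools
from math import comb

import numpy as np
import pytest

from topicminer.curation_stats import (
    AgreementCounts,
    ConfusionCounts,
    CurationRecord,
    TriageFitError,
    cohens_kappa,
    confusion_metrics,
    fisher_enrichment,
    fit_triage_model,
    gene_set_table,
    load_curation_records,
    precision_by_strata,
    top_mentions_precision,
)


class TestConfusionMetrics:
    def test_full_table(self):
        m = confusion_metrics(ConfusionCounts(tp=8, fp=2, tn=85, fn=5))
        assert m["precision"] == pytest.approx(80.0)
        assert m["recall"] == pytest.approx(100 * 8 / 13)
        assert m["accuracy"] == pytest.approx(93.0)
        assert m["tn_rate"] == pytest.approx(100 * 85 / 87)
        p, r = m["precision"], m["recall"]
        assert m["f_score"] == pytest.approx(2 * p * r / (p + r))

    def test_absent_counts_give_none_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0))
        assert m["precision"] == pytest.approx(100.0)
        assert m["recall"] is None
        assert m["f_score"] is None
        assert m["accuracy"] is None
        assert m["tn_rate"] is None

    def test_zero_denominator_gives_none(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, fn=5))
        assert m["precision"] is None

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestCohensKappa:
    def test_worked_example(self):
        # 90 agreed of 100; marginals 60/40 and 50/50: p_e = 0.3+0.2 = 0.5
        out = cohens_kappa(AgreementCounts(before=(60, 40), after=(50, 50),
                                           agreed=90, disagreed=10))
        assert out["p_a"] == pytest.approx(0.9)
        assert out["p_e"] == pytest.approx(0.5)
        assert out["kappa"] == pytest.approx(0.8)

    def test_marginal_invariant_enforced(self):
        with pytest.raises(ValueError, match="marginals"):
            AgreementCounts(before=(60, 40), after=(50, 40), agreed=90, disagreed=10)

    def test_degenerate_marginals_raise(self):
        with pytest.raises(ZeroDivisionError):
            cohens_kappa(AgreementCounts(before=(10, 0), after=(10, 0),
                                         agreed=10, disagreed=0))

    def test_chance_level_agreement_is_zero(self):
        # p_a == p_e: kappa exactly 0
        out = cohens_kappa(AgreementCounts(before=(50, 50), after=(50, 50),
                                           agreed=50, disagreed=50))
        assert out["kappa"] == pytest.approx(0.0)


def brute_force_fisher_p(a, b, c, d):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    from scipy.stats import hypergeom

    n1, n2 = a + b, c + d
    k = a + c
    rv = hypergeom(n1 + n2, n1, k)
    support = range(max(0, k - n2), min(k, n1) + 1)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(x) for x in support
                     if rv.pmf(x) <= p_obs * (1 + 1e-12)))


class TestFisherEnrichment:
    def test_sample_odds_ratio(self):
        out = fisher_enrichment(10, 20, 5, 40)
        assert out["odds_ratio"] == pytest.approx((10 * 40) / (20 * 5))

    def test_zero_cells(self):
        assert fisher_enrichment(5, 0, 3, 4)["odds_ratio"] == np.inf
        assert np.isnan(fisher_enrichment(0, 0, 3, 4)["odds_ratio"])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(-1, 0, 0, 0)

    def test_p_matches_brute_force_on_small_tables(self):
        for a, b, c, d in itertools.product(range(0, 13, 3), repeat=4):
            if (a + b == 0) or (c + d == 0):
                continue
            out = fisher_enrichment(a, b, c, d)
            assert out["p_value"] == pytest.approx(
                brute_force_fisher_p(a, b, c, d), rel=1e-9), (a, b, c, d)

    def test_underflow_switches_p_text(self):
        out = fisher_enrichment(5000, 1000, 1000, 5000)
        assert out["p_text"] == "<2.2e-16"

    def test_cmle_present_only_for_small_tables(self):
        small = fisher_enrichment(10, 20, 5, 40)
        assert small["odds_ratio_cmle"] is not None
        big = fisher_enrichment(5000, 5000, 5000, 5000)
        assert big["odds_ratio_cmle"] is None


class TestGeneSetTable:
    def test_id_iterables(self):
        focus = [{1, 2}, {3}, {9}]          # 2 hit the set
        background = [{3}, {4}, {5}, {9}]   # 1 hits
        out = gene_set_table(focus, background, {1, 2, 9})
        assert out["table"] == (2, 1, 1, 3)
        assert out["pct_focus"] == pytest.approx(100 * 2 / 3)
        assert out["pct_background"] == pytest.approx(25.0)
        assert out["fisher"]["odds_ratio"] == pytest.approx(6.0)

    def test_mention_objects(self, bundle):
        gold = set(bundle.manifest["gold_genes"])
        out = gene_set_table(bundle.mentions, bundle.mentions, gold)
        a, b, c, d = out["table"]
        assert (a, b) == (c, d)
        assert a + b == len(bundle.mentions)
        assert out["fisher"]["odds_ratio"] == pytest.approx(1.0)

    def test_empty_side_gives_no_fisher(self):
        out = gene_set_table([], [{1}], {1})
        assert out["fisher"] is None


def rec(label, confidence, doc_count=1, sig="s"):
    return CurationRecord(sig, label, confidence, doc_count)


class TestPrecisionByStrata:
    def test_strata_partition(self):
        records = [
            rec("tp", 0.9, 3), rec("tp", 0.8, 1), rec("fp", 0.6, 1),
            rec("tp", 0.4, 2), rec("fp", 0.2, 1), rec("fp", 0.1, 1),
        ]
        out = precision_by_strata(records, confidence_cutoff=0.5)
        assert out["overall"] == pytest.approx(50.0)
        assert out["above_cutoff"] == pytest.approx(100 * 2 / 3)
        assert out["below_cutoff"] == pytest.approx(100 * 1 / 3)
        assert out["multi_doc"] == pytest.approx(100.0)
        assert out["single_doc"] == pytest.approx(25.0)

    def test_empty_stratum_is_none(self):
        out = precision_by_strata([rec("tp", 0.9, 2)])
        assert out["below_cutoff"] is None
        assert out["single_doc"] is None

    def test_no_records_rejected(self):
        with pytest.raises(ValueError):
            precision_by_strata([])

    def test_record_validation(self):
        with pytest.raises(ValueError):
            rec("maybe", 0.5)
        with pytest.raises(ValueError):
            rec("tp", 1.5)
        with pytest.raises(ValueError):
            rec("tp", 0.5, doc_count=0)


class TestLoadCurationRecords:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text(
            "signature\tlabel\tconfidence\tdoc_count\n"
            "binding(G:1,G:2)\ttp\t0.8\t3\n"
            "gene_expression(G:5)\tfp\t0.2\t1\n"
        )
        records = load_curation_records(path)
        assert len(records) == 2
        assert records[0].label == "tp" and records[0].doc_count == 3
        assert records[1].confidence == pytest.approx(0.2)


class TestTriageModel:
    def test_recovers_known_logistic(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 2000)
        p = 1 / (1 + np.exp(-(-2.0 + 8.0 * x)))
        y = rng.uniform(size=2000) < p
        records = [rec("tp" if yi else "fp", xi) for xi, yi in zip(x, y)]
        out = fit_triage_model(records)
        assert out["threshold"] == pytest.approx(0.25, abs=0.03)
        assert out["slope"] > 0

    def test_single_label_raises(self):
        with pytest.raises(TriageFitError, match="both labels"):
            fit_triage_model([rec("tp", 0.5), rec("tp", 0.6)])

    def test_complete_separation_raises(self):
        records = [rec("fp", c) for c in (0.1, 0.2, 0.3)] + \
                  [rec("tp", c) for c in (0.7, 0.8, 0.9)]
        with pytest.raises(TriageFitError, match="separated"):
            fit_triage_model(records)

    def test_non_informative_confidence_gives_no_threshold(self):
        rng = np.random.default_rng(0)
        records = [rec("tp" if rng.uniform() < 0.5 else "fp", float(c))
                   for c in rng.uniform(0, 1, 400)]
        out = fit_triage_model(records)
        assert out["threshold"] is None


class TestTopMentionsPrecision:
    def test_counts_correct_in_top_k(self):
        group = [(0.9, True), (0.8, True), (0.7, False), (0.6, True),
                 (0.5, True), (0.1, True)]
        out = top_mentions_precision([group], k=5)
        # top five by confidence contain four correct
        assert out["mean_correct"] == pytest.approx(4.0)
        assert out["n_groups"] == 1 and out["excluded"] == 0

    def test_small_groups_excluded(self):
        out = top_mentions_precision([[(0.9, True)], [(0.5, True)] * 5], k=5)
        assert out["excluded"] == 1 and out["n_groups"] == 1

    def test_totals(self):
        groups = [[(0.5, True)] * 5, [(0.5, False)] * 5]
        out = top_mentions_precision(groups, k=5)
        assert out["total_correct"] == 5
        assert out["mean_correct"] == pytest.approx(2.5)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            top_mentions_precision([], k=0)
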