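"""Gold standards, ROC/AUC, fold enrichment and confusion metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_auc
from ddinet.evaluate import (
    GoldStandard,
    binned_enrichment,
    confusion_metrics,
    fold_enrichment,
    hit_rate_by_distance,
    make_gold_standard,
    roc_auc,
    sample_gsn,
)


def pairs(n, prefix="d"):
    return [(f"{prefix}{2 * i}", f"{prefix}{2 * i + 1}") for i in range(n)]


def gold_from(pos_scores, neg_scores):
    scores = {}
    gsp, gsn = set(), set()
    for i, v in enumerate(pos_scores):
        p = (f"p{i}", f"q{i}")
        scores[p] = v
        gsp.add(p)
    for i, v in enumerate(neg_scores):
        p = (f"m{i}", f"n{i}")
        scores[p] = v
        gsn.add(p)
    gold = GoldStandard(gsp=frozenset(gsp), gsn=frozenset(gsn),
                        seed=0, multiplier=1)
    return scores, gold


class TestSampleGSN:
    def test_deterministic_for_fixed_seed(self):
        drugs = [f"d{i}" for i in range(12)]
        gsp = set(pairs(3))
        a = sample_gsn(drugs, gsp, multiplier=1, seed=42)
        b = sample_gsn(drugs, gsp, multiplier=1, seed=42)
        assert a == b
        assert a != sample_gsn(drugs, gsp, multiplier=1, seed=43)

    def test_five_times_multiplier(self):
        drugs = [f"d{i}" for i in range(30)]
        gsp = set(pairs(10))
        gsn = sample_gsn(drugs, gsp, multiplier=5, seed=0)
        assert len(gsn) == 50

    def test_never_overlaps_gsp(self):
        drugs = [f"d{i}" for i in range(8)]
        gsp = set(pairs(4))
        for seed in range(5):
            assert not (sample_gsn(drugs, gsp, multiplier=5, seed=seed)
                        & gsp)

    def test_exhausted_candidates_take_all(self):
        drugs = ["a", "b", "c"]
        gsp = {("a", "b")}
        gsn = sample_gsn(drugs, gsp, multiplier=5, seed=0)
        assert gsn == {("a", "c"), ("b", "c")}


class TestRocAuc:
    def test_interleaved_example(self):
        scores, gold = gold_from([0.9, 0.7], [0.8, 0.6])
        _, auc = roc_auc(scores, gold)
        assert auc == pytest.approx(0.75)  # 3 of 4 pos-neg pairs concordant

    def test_perfect_separation(self):
        scores, gold = gold_from([5.0, 6.0], [1.0, 2.0])
        curve, auc = roc_auc(scores, gold)
        assert auc == 1.0
        assert curve["tpr"].iloc[-1] == 1.0

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=2000)
        scores, gold = gold_from(vals[:1000], vals[1000:])
        _, auc = roc_auc(scores, gold)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_undefined_scores_rank_last(self):
        scores, gold = gold_from([1.0, None], [2.0, None])
        _, auc = roc_auc(scores, gold)
        # pos 1.0 loses to neg 2.0; None vs None ties at 1/2 ...
        assert auc == pytest.approx(brute_force_auc(
            [scores[p] for p in sorted(gold.universe)],
            [1 if p in gold.gsp else 0 for p in sorted(gold.universe)]))

    def test_single_class_rejected(self):
        scores = {("a", "b"): 1.0}
        gold = GoldStandard(gsp=frozenset({("a", "b")}), gsn=frozenset(),
                            seed=0, multiplier=1)
        with pytest.raises(ValueError):
            roc_auc(scores, gold)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        n_pos = int(rng.integers(1, n - 1))
        raw = rng.choice([-1.0, 0.0, 0.5, 1.0, 2.0, np.nan], size=n)
        vals = [None if np.isnan(v) else float(v) for v in raw]
        scores, gold = gold_from(vals[:n_pos], vals[n_pos:])
        _, auc = roc_auc(scores, gold)
        ordered = sorted(gold.universe)
        want = brute_force_auc([scores[p] for p in ordered],
                               [1 if p in gold.gsp else 0 for p in ordered])
        assert auc == pytest.approx(want, abs=1e-12)


class TestFoldEnrichment:
    @pytest.mark.parametrize("m, n, M, N, expected", [
        (5, 100, 50, 10000, 10.0),
        (50, 10000, 50, 10000, 1.0),
        (0, 100, 50, 10000, 0.0),
    ])
    def test_definitional_arithmetic(self, m, n, M, N, expected):
        assert fold_enrichment(m, n, M, N) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert fold_enrichment(3, 30, 12, 600) == pytest.approx(
            fold_enrichment(9, 90, 36, 1800))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 5, 10)


class TestBinnedEnrichment:
    def test_top_scores_all_gsp(self):
        scores = {p: float(100 - i) for i, p in enumerate(pairs(100))}
        ordered = sorted(scores, key=scores.get, reverse=True)
        gsp = set(ordered[:10])
        table = binned_enrichment(scores, gsp, bin_size=10)
        # top bin contains exactly the 10 GSPs: (10/10)/(10/100) = 10
        assert table.iloc[0]["fold_enrichment"] == pytest.approx(10.0)
        assert table.iloc[1]["fold_enrichment"] == 0.0

    def test_single_bin_is_exactly_one(self):
        scores = {p: float(i) for i, p in enumerate(pairs(20))}
        gsp = set(list(scores)[:5])
        table = binned_enrichment(scores, gsp, bin_size=1000)
        assert len(table) == 1
        assert table.iloc[0]["fold_enrichment"] == pytest.approx(1.0)

    def test_uniform_scores_near_one(self):
        rng = np.random.default_rng(5)
        ps = pairs(2000)
        scores = {p: float(v) for p, v in zip(ps, rng.random(2000))}
        gsp = set(rng.choice(len(ps), size=400, replace=False).tolist())
        gsp = {ps[i] for i in gsp}
        table = binned_enrichment(scores, gsp, bin_size=500)
        assert np.all(np.abs(table["fold_enrichment"] - 1.0) < 0.35)


class TestConfusionMetrics:
    def test_hand_built_table(self):
        gsp = frozenset(pairs(12, "p"))   # 12 positives
        gsn = frozenset(pairs(8, "n"))    # 8 negatives
        gold = GoldStandard(gsp=gsp, gsn=gsn, seed=0, multiplier=1)
        predicted = set(list(sorted(gsp))[:8]) | set(list(sorted(gsn))[:2])
        counts, acc, rec, prec = confusion_metrics(predicted, gold)
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (8, 2, 4, 6)
        assert acc == pytest.approx(0.70)
        assert rec == pytest.approx(8 / 12)
        assert prec == pytest.approx(0.8)

    def test_perfect_prediction(self):
        gsp = frozenset(pairs(5, "p"))
        gsn = frozenset(pairs(5, "n"))
        gold = GoldStandard(gsp=gsp, gsn=gsn, seed=0, multiplier=1)
        _, acc, rec, _ = confusion_metrics(set(gsp), gold)
        assert acc == 1.0 and rec == 1.0

    def test_empty_prediction(self):
        gsp = frozenset(pairs(4, "p"))
        gsn = frozenset(pairs(6, "n"))
        gold = GoldStandard(gsp=gsp, gsn=gsn, seed=0, multiplier=1)
        counts, acc, rec, prec = confusion_metrics(set(), gold)
        assert rec == 0.0
        assert acc == pytest.approx(len(gsn) / (len(gsp) + len(gsn)))
        assert prec is None

    def test_totals_consistent_with_universe(self):
        gsp = frozenset(pairs(7, "p"))
        gsn = frozenset(pairs(9, "n"))
        gold = GoldStandard(gsp=gsp, gsn=gsn, seed=0, multiplier=1)
        predicted = set(list(sorted(gsp))[:3]) | {("x", "y")}  # outside
        counts, *_ = confusion_metrics(predicted, gold)
        assert counts.TP + counts.FN == len(gsp)
        assert counts.FP + counts.TN == len(gsn)


class TestHitRateByDistance:
    def test_all_gsp_at_zero(self):
        distances = {p: 0 for p in pairs(4)}
        distances.update({p: 1 for p in pairs(6, "x")})
        gsp = set(pairs(4))
        table = hit_rate_by_distance(distances, gsp)
        row0 = table[table["distance"] == 0].iloc[0]
        assert row0["hit_rate"] == 1.0
        assert row0["coverage"] == 1.0

    def test_coverage_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(9)
        ps = pairs(300)
        distances = {p: (None if rng.random() < 0.1
                         else int(rng.integers(0, 5))) for p in ps}
        gsp = {p for p in ps if rng.random() < 0.2}
        table = hit_rate_by_distance(distances, gsp)
        cov = table[table["distance"].notna()]["coverage"].to_numpy()
        assert np.all(np.diff(cov) >= 0)
        assert cov[-1] <= 1.0

    def test_random_labels_hit_rate_near_prevalence(self):
        rng = np.random.default_rng(21)
        ps = pairs(4000)
        distances = {p: int(rng.integers(0, 4)) for p in ps}
        gsp = {p for p in ps if rng.random() < 0.25}
        table = hit_rate_by_distance(distances, gsp)
        prevalence = len(gsp) / len(ps)
        assert np.all(np.abs(table["hit_rate"] - prevalence) < 0.05)
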