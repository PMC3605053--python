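"""Likelihood-ratio fitting, lookup, combination and prediction."""

import numpy as np
import pytest

from ddinet.bayes import (
    attach_lr,
    combine_lr,
    fit_lr,
    lr_lookup,
    posterior_odds,
    predict,
    write_lr_table,
)
from ddinet.io import PairScoreRecord


def make_scores(pos_vals, neg_vals):
    scores, gsp, gsn = {}, set(), set()
    for i, v in enumerate(pos_vals):
        pair = (f"p{i}", f"q{i}")
        scores[pair] = v
        gsp.add(pair)
    for i, v in enumerate(neg_vals):
        pair = (f"n{i}", f"m{i}")
        scores[pair] = v
        gsn.add(pair)
    return scores, gsp, gsn


class TestFitLR:
    def test_perfectly_separated_two_bins(self):
        # 10 pos in the top bin, 10 neg in the bottom, pseudo = 1:
        # LR(top) = (11/12)/(1/12) = 11 with B = 2 bins (no undefined
        # scores here, but the undefined bin still counts in B)
        scores, gsp, gsn = make_scores(
            pos_vals=np.linspace(10, 11, 10), neg_vals=np.linspace(0, 1, 10))
        model = fit_lr(scores, gsp, gsn, n_bins=2, pseudo=1.0)
        # B includes the undefined bin: totals are 10 + 1*3 = 13
        top = lr_lookup(model, 10.5)
        bottom = lr_lookup(model, 0.5)
        assert top == pytest.approx((11 / 13) / (1 / 13))
        assert bottom == pytest.approx((1 / 13) / (11 / 13))

    def test_label_permutation_gives_flat_lr(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=400)
        scores, gsp, gsn = make_scores(vals[:200], vals[200:])
        model = fit_lr(scores, gsp, gsn, n_bins=4, pseudo=0.5)
        assert np.all(np.abs(model.bin_lr - 1.0) < 0.6)

    def test_empty_bin_smoothing_keeps_lr_finite(self):
        scores, gsp, gsn = make_scores([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        model = fit_lr(scores, gsp, gsn, n_bins=2, pseudo=0.5)
        assert np.all(np.isfinite(model.bin_lr))
        assert np.all(model.bin_lr > 0)

    def test_undefined_scores_get_dedicated_bin(self):
        scores, gsp, gsn = make_scores([1.0, 2.0, None, None],
                                       [1.5, 2.5, 3.0, None])
        model = fit_lr(scores, gsp, gsn, n_bins=2, pseudo=0.5)
        # 2 of 4 pos undefined vs 1 of 4 neg: undefined LR > 1
        assert lr_lookup(model, None) == model.undefined_lr
        assert model.undefined_lr > 1.0

    def test_identical_scores_single_bin_warning(self):
        scores, gsp, gsn = make_scores([5.0] * 4, [5.0] * 4)
        with pytest.warns(UserWarning, match="identical"):
            model = fit_lr(scores, gsp, gsn, n_bins=3)
        assert model.n_bins == 1
        assert model.bin_lr[0] == 1.0

    def test_prior_odds(self):
        scores, gsp, gsn = make_scores([1.0, 2.0], [0.5, 1.5, 2.5, 3.5])
        model = fit_lr(scores, gsp, gsn, n_bins=2)
        assert model.prior_odds == pytest.approx(0.5)

    def test_too_few_bins_rejected(self):
        scores, gsp, gsn = make_scores([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_lr(scores, gsp, gsn, n_bins=1)

    def test_overlapping_gold_sets_rejected(self):
        scores, gsp, gsn = make_scores([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_lr(scores, gsp, gsp, n_bins=2)

    def test_refit_is_bit_reproducible(self):
        rng = np.random.default_rng(3)
        scores, gsp, gsn = make_scores(rng.normal(size=30),
                                       rng.normal(size=30))
        m1 = fit_lr(scores, gsp, gsn)
        m2 = fit_lr(scores, gsp, gsn)
        assert np.array_equal(m1.bin_lr, m2.bin_lr)
        assert np.array_equal(m1.bin_edges, m2.bin_edges)

    def test_ratio_consistency_under_negative_distribution(self):
        """sum_bins LR(bin) P(bin|neg) = 1 + O(pseudo)."""
        rng = np.random.default_rng(11)
        scores, gsp, gsn = make_scores(rng.normal(1, 1, 300),
                                       rng.normal(0, 1, 300))
        model = fit_lr(scores, gsp, gsn, n_bins=5, pseudo=0.5)
        neg_vals = [scores[p] for p in gsn]
        idx = np.searchsorted(model.bin_edges[1:-1], neg_vals, side="right")
        p_neg = np.bincount(idx, minlength=model.n_bins) / len(neg_vals)
        assert float(np.dot(model.bin_lr, p_neg)) == pytest.approx(
            1.0, abs=0.05)


class TestLookupAndCombine:
    def fitted(self):
        scores, gsp, gsn = make_scores([1.0, 2.0, 3.0, 4.0],
                                       [0.0, 0.5, 1.5, 2.5])
        return fit_lr(scores, gsp, gsn, n_bins=2, pseudo=0.5)

    def test_clamping_outside_fitted_range(self):
        model = self.fitted()
        assert lr_lookup(model, -100.0) == model.bin_lr[0]
        assert lr_lookup(model, +100.0) == model.bin_lr[-1]

    def test_boundary_goes_to_right_open_interval(self):
        model = self.fitted()
        mid = model.bin_edges[1]
        assert lr_lookup(model, mid) == model.bin_lr[1]

    @pytest.mark.parametrize("lrs, expected", [
        ([2.0, 3.0], 6.0),
        ([], 1.0),
        ([0.5, 4.0, 0.5], 1.0),
    ])
    def test_combine(self, lrs, expected):
        assert combine_lr(lrs) == pytest.approx(expected)

    @pytest.mark.parametrize("prior, lr, expected", [
        (0.01, 100.0, 1.0),
        (0.3, 1.0, 0.3),
        (0.05, 2.0, 0.1),
    ])
    def test_posterior_odds(self, prior, lr, expected):
        assert posterior_odds(prior, lr) == pytest.approx(expected)


class TestPredict:
    def models(self):
        scores, gsp, gsn = make_scores([10.0] * 5 + [11.0] * 5,
                                       [0.0] * 5 + [1.0] * 5)
        m = fit_lr(scores, gsp, gsn, n_bins=2, pseudo=1.0)
        return m, m

    def test_both_evidences_multiply(self):
        model_s, model_p = self.models()
        rec = PairScoreRecord("a", "b", s_score=10.5, p_score=10.5)
        predicted, both = predict([rec], model_s, model_p, threshold=2.0)
        assert rec.lr_combined == pytest.approx(rec.lr_s * rec.lr_p)
        assert predicted == {("a", "b")} and both == {("a", "b")}

    def test_single_evidence_uses_that_lr_strictly(self):
        model_s, model_p = self.models()
        # exactly at the threshold: strict inequality, not predicted
        rec = PairScoreRecord("a", "b", s_score=10.5, p_score=None)
        attach_lr([rec], model_s, model_p)
        predicted, _ = predict([rec], model_s, model_p,
                               threshold=rec.lr_s)
        assert predicted == set()

    def test_no_evidence_never_predicted(self):
        model_s, model_p = self.models()
        rec = PairScoreRecord("a", "b")
        predicted, _ = predict([rec], model_s, model_p, threshold=0.0)
        assert predicted == set()
        assert rec.lr_combined is None


def test_lr_table_round_numbers(tmp_path):
    scores = {("a", "b"): 1.0, ("c", "d"): 2.0, ("e", "f"): None}
    model = fit_lr(scores, {("a", "b")}, {("c", "d"), ("e", "f")}, n_bins=2)
    path = tmp_path / "lr.tsv"
    write_lr_table(model, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "evidence\tbin_lo\tbin_hi\tlr"
    assert lines[-1].split("\t")[1:3] == ["NA", "NA"]
    assert len(lines) == model.n_bins + 2
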