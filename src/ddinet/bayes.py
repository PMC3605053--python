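"""Binned likelihood-ratio models and naive-Bayes evidence integration.

Each evidence channel (S-score, P-score) is converted into a likelihood
ratio LR(bin) = P(score bin | interacting) / P(score bin | non-interacting)
by quantile-binning the scores of gold-standard positive (GSP) and negative
(GSN) pairs.  Undefined scores go to a dedicated bin with its own LR, and
pseudo-counts keep every ratio finite.  Under the independence assumption
the per-evidence LRs multiply, and posterior odds = prior odds x combined
LR.  Because the evidence enters only through rank bins, each channel is
automatically weighted by how well it separates GSP from GSN -- an
uninformative channel contributes LR ~ 1 everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ddinet.io import PairScoreRecord, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "LRModel",
    "fit_lr",
    "lr_lookup",
    "combine_lr",
    "posterior_odds",
    "predict",
    "write_lr_table",
]

Pair = tuple[str, str]


@dataclass
class LRModel:
    """Per-evidence binned likelihood-ratio model.

    ``bin_edges`` has one more entry than ``bin_lr``; bin i covers the
    right-open interval [edge_i, edge_{i+1}), scores outside the fitted
    range clamp to the extreme bins, and undefined scores map to
    ``undefined_lr``.
    """

    evidence: str
    bin_edges: np.ndarray
    bin_lr: np.ndarray
    undefined_lr: float
    prior_odds: float
    pseudo: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_lr)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_lr = np.asarray(self.bin_lr, dtype=float)
        if len(self.bin_edges) != len(self.bin_lr) + 1:
            raise ValueError("bin_edges must have len(bin_lr) + 1 entries")
        if np.any(self.bin_lr <= 0) or self.undefined_lr <= 0:
            raise ValueError("all likelihood ratios must be positive")


def _bin_index(edges: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Right-open bin assignment with clamping to the extreme bins."""
    idx = np.searchsorted(edges[1:-1], values, side="right")
    return np.clip(idx, 0, len(edges) - 2)


def fit_lr(scores: Mapping[Pair, float | None], gsp: Iterable[Pair],
           gsn: Iterable[Pair], n_bins: int = 20, pseudo: float = 0.5,
           evidence: str = "score") -> LRModel:
    """Fit a binned LR model from gold-standard positives and negatives.

    Bin edges are quantiles of the defined scores over GSP u GSN, so every
    bin starts equally populated.  With B = number of bins (including the
    undefined bin), the per-bin ratio is

        LR(bin) = [(#pos in bin + pseudo) / (#pos + pseudo*B)]
                / [(#neg in bin + pseudo) / (#neg + pseudo*B)]

    Prior odds are |GSP| / |GSN|.  Pairs are looked up order-independently.
    """
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")
    gsp = {canonical_pair(*p) for p in gsp}
    gsn = {canonical_pair(*p) for p in gsn}
    if not gsp or not gsn:
        raise ValueError("GSP and GSN must both be non-empty")
    if gsp & gsn:
        raise ValueError("GSP and GSN overlap")
    scores = {canonical_pair(*k): v for k, v in scores.items()}

    def collect(pairs: set[Pair]) -> tuple[np.ndarray, int]:
        defined = [scores[p] for p in pairs
                   if scores.get(p) is not None]
        n_undef = len(pairs) - len(defined)
        return np.asarray(defined, dtype=float), n_undef

    pos_vals, pos_undef = collect(gsp)
    neg_vals, neg_undef = collect(gsn)
    all_vals = np.concatenate([pos_vals, neg_vals])

    if all_vals.size == 0 or np.unique(all_vals).size == 1:
        warnings.warn(f"{evidence}: all defined scores identical; "
                      "single-bin model with LR = 1", stacklevel=2)
        lo = float(all_vals[0]) if all_vals.size else 0.0
        edges = np.array([lo, lo])
        return LRModel(evidence=evidence, bin_edges=edges,
                       bin_lr=np.array([1.0]), undefined_lr=1.0,
                       prior_odds=len(gsp) / len(gsn), pseudo=pseudo)

    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(all_vals, qs))
    if len(edges) < 2:
        edges = np.array([edges[0], edges[0]])
    n_real = len(edges) - 1
    if n_real < n_bins:
        logger.info("%s: duplicate quantiles reduced bins %d -> %d",
                    evidence, n_bins, n_real)

    pos_counts = np.bincount(_bin_index(edges, pos_vals), minlength=n_real)
    neg_counts = np.bincount(_bin_index(edges, neg_vals), minlength=n_real)

    n_total_bins = n_real + 1  # the undefined bin is a bin
    pos_tot = len(gsp) + pseudo * n_total_bins
    neg_tot = len(gsn) + pseudo * n_total_bins
    with np.errstate(divide="ignore"):
        bin_lr = ((pos_counts + pseudo) / pos_tot) / (
            (neg_counts + pseudo) / neg_tot)
        undefined_lr = ((pos_undef + pseudo) / pos_tot) / (
            (neg_undef + pseudo) / neg_tot)
    if pseudo == 0 and (np.any(~np.isfinite(bin_lr)) or np.any(bin_lr == 0)
                        or not np.isfinite(undefined_lr)):
        raise ValueError("empty bin with pseudo = 0 gives a degenerate LR; "
                         "use a positive pseudo-count")
    return LRModel(evidence=evidence, bin_edges=edges, bin_lr=bin_lr,
                   undefined_lr=float(undefined_lr),
                   prior_odds=len(gsp) / len(gsn), pseudo=pseudo)


def lr_lookup(model: LRModel, score: float | None) -> float:
    """LR of the bin containing *score* (undefined bin for ``None``)."""
    if score is None:
        return model.undefined_lr
    if model.n_bins == 1:
        return float(model.bin_lr[0])
    idx = _bin_index(model.bin_edges, np.asarray([score]))[0]
    return float(model.bin_lr[idx])


def combine_lr(lrs: Sequence[float]) -> float:
    """Product of per-evidence LRs (naive-Bayes independence); empty -> 1."""
    out = 1.0
    for lr in lrs:
        if lr <= 0:
            raise ValueError("likelihood ratios must be positive")
        out *= lr
    return out


def posterior_odds(prior_odds: float, lr: float) -> float:
    """Posterior odds = prior odds x likelihood ratio."""
    if prior_odds <= 0 or lr <= 0:
        raise ValueError("prior odds and LR must be positive")
    return prior_odds * lr


def attach_lr(records: Sequence[PairScoreRecord], model_s: LRModel,
              model_p: LRModel) -> None:
    """Fill the lr_s / lr_p / lr_combined fields of score records in place.

    A pair with both evidences gets the product LR; with exactly one
    evidence, that single LR; with neither, no combined LR at all (such
    pairs are never predicted).
    """
    for rec in records:
        rec.lr_s = lr_lookup(model_s, rec.s_score) \
            if rec.s_score is not None else None
        rec.lr_p = lr_lookup(model_p, rec.p_score) \
            if rec.p_score is not None else None
        if rec.lr_s is not None and rec.lr_p is not None:
            rec.lr_combined = rec.lr_s * rec.lr_p
        elif rec.lr_s is not None:
            rec.lr_combined = rec.lr_s
        elif rec.lr_p is not None:
            rec.lr_combined = rec.lr_p
        else:
            rec.lr_combined = None


def predict(records: Sequence[PairScoreRecord], model_s: LRModel,
            model_p: LRModel, threshold: float = 2.0
            ) -> tuple[set[Pair], set[Pair]]:
    """Predict interacting pairs by thresholding the combined LR.

    Returns ``(predicted, both_evidence)``: pairs whose combined LR is
    strictly above *threshold*, and the subset of predicted pairs that had
    both evidence channels defined.
    """
    attach_lr(records, model_s, model_p)
    predicted: set[Pair] = set()
    both: set[Pair] = set()
    for rec in records:
        if rec.lr_combined is not None and rec.lr_combined > threshold:
            predicted.add(rec.pair)
            if rec.lr_s is not None and rec.lr_p is not None:
                both.add(rec.pair)
    return predicted, both


def write_lr_table(model: LRModel, path) -> None:
    """Serialize a fitted model as TSV (evidence, bin_lo, bin_hi, lr).

    The undefined bin is written with ``NA`` bounds.
    """
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("evidence\tbin_lo\tbin_hi\tlr\n")
        for i in range(model.n_bins):
            fh.write(f"{model.evidence}\t{model.bin_edges[i]:.6g}\t"
                     f"{model.bin_edges[i + 1]:.6g}\t{model.bin_lr[i]:.6g}\n")
        fh.write(f"{model.evidence}\tNA\tNA\t{model.undefined_lr:.6g}\n")
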