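"""Gold-standard construction and performance metrics.

Known interacting pairs serve as gold-standard positives (GSP); since true
negatives are unobservable, gold-standard negatives (GSN) are sampled
uniformly from the non-GSP drug pairs, either equal in size to the GSP set
or five times larger.  All threshold metrics (ROC, confusion counts) are
computed over the GSP u GSN universe.  Rank-based enrichment works over
whatever universe of scored pairs is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from ddinet.io import canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "ConfusionCounts",
    "sample_gsn",
    "make_gold_standard",
    "roc_auc",
    "fold_enrichment",
    "binned_enrichment",
    "confusion_metrics",
    "hit_rate_by_distance",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class GoldStandard:
    """GSP/GSN pair sets plus the sampling provenance."""

    gsp: frozenset[Pair]
    gsn: frozenset[Pair]
    seed: int
    multiplier: int

    def __post_init__(self):
        object.__setattr__(self, "gsp",
                           frozenset(canonical_pair(*p) for p in self.gsp))
        object.__setattr__(self, "gsn",
                           frozenset(canonical_pair(*p) for p in self.gsn))
        if self.gsp & self.gsn:
            raise ValueError("GSP and GSN overlap")

    @property
    def universe(self) -> frozenset[Pair]:
        return self.gsp | self.gsn


def sample_gsn(all_drugs: Iterable[str], gsp: Iterable[Pair],
               multiplier: int = 1, seed: int = 0) -> frozenset[Pair]:
    """Sample negatives uniformly from all non-GSP unordered drug pairs.

    Reproducible for a fixed seed.  If fewer candidate pairs exist than
    ``multiplier * |gsp|``, all of them are taken with a warning.
    """
    if multiplier not in (1, 5):
        raise ValueError("multiplier must be 1 or 5")
    gsp = {canonical_pair(*p) for p in gsp}
    drugs = sorted(set(all_drugs))
    candidates = [p for p in combinations(drugs, 2) if p not in gsp]
    want = multiplier * len(gsp)
    rng = np.random.default_rng(seed)
    if want >= len(candidates):
        if want > len(candidates):
            logger.warning("requested %d GSN pairs but only %d available; "
                           "taking all", want, len(candidates))
        return frozenset(candidates)
    idx = rng.choice(len(candidates), size=want, replace=False)
    return frozenset(candidates[i] for i in idx)


def make_gold_standard(all_drugs: Iterable[str], gsp: Iterable[Pair],
                       multiplier: int = 1, seed: int = 0) -> GoldStandard:
    """Build a :class:`GoldStandard` with a freshly sampled GSN."""
    gsp = frozenset(canonical_pair(*p) for p in gsp)
    gsn = sample_gsn(all_drugs, gsp, multiplier=multiplier, seed=seed)
    return GoldStandard(gsp=gsp, gsn=gsn, seed=seed, multiplier=multiplier)


def _score_array(scores: Mapping[Pair, float | None],
                 pairs: list[Pair]) -> np.ndarray:
    """Scores as floats with undefined values ranked below all defined."""
    scores = {canonical_pair(*k): v for k, v in scores.items()}
    vals = [scores.get(p) for p in pairs]
    defined = [v for v in vals if v is not None]
    sentinel = (min(defined) - 1.0) if defined else 0.0
    return np.array([sentinel if v is None else v for v in vals],
                    dtype=float)


def roc_auc(scores: Mapping[Pair, float | None], gold: GoldStandard
            ) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC of a score over the GSP u GSN universe.

    Undefined scores rank below all defined scores (and tie with each
    other).  The AUC equals the Mann-Whitney concordance probability with
    ties counted 1/2.  Returns a (threshold, fpr, tpr) table and the AUC.
    """
    pairs = sorted(gold.universe)
    if not gold.gsp or not gold.gsn:
        raise ValueError("need at least one positive and one negative")
    y = np.array([1 if p in gold.gsp else 0 for p in pairs])
    s = _score_array(scores, pairs)
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve, auc


def fold_enrichment(m: int, n: int, M: int, N: int) -> float:
    """Hit concentration (m/n) relative to the global rate (M/N)."""
    if n <= 0 or M <= 0 or N <= 0:
        raise ValueError("n, M and N must be positive")
    return (m / n) / (M / N)


def binned_enrichment(scores: Mapping[Pair, float | None],
                      gsp: Iterable[Pair],
                      bin_size: int = 1000) -> pd.DataFrame:
    """Fold enrichment of GSPs in rank-descending score bins.

    All scored pairs are ranked by descending score (undefined last, ties
    broken by canonical pair order) and cut into bins of *bin_size* (the
    last bin may be smaller).  Per bin: the mean of the defined scores,
    the GSP hit rate m/n and the fold enrichment (m/n)/(M/N).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    gsp = {canonical_pair(*p) for p in gsp}
    scores = {canonical_pair(*k): v for k, v in scores.items()}
    pairs = sorted(scores)
    vals = _score_array(scores, pairs)
    order = sorted(range(len(pairs)),
                   key=lambda i: (-vals[i], pairs[i]))
    N = len(pairs)
    M = sum(1 for p in pairs if p in gsp)
    rows = []
    for start in range(0, N, bin_size):
        chunk = order[start:start + bin_size]
        n = len(chunk)
        m = sum(1 for i in chunk if pairs[i] in gsp)
        defined = [scores[pairs[i]] for i in chunk
                   if scores[pairs[i]] is not None]
        mean_score = float(np.mean(defined)) if defined else np.nan
        enr = fold_enrichment(m, n, M, N) if M > 0 else np.nan
        rows.append((start // bin_size, mean_score, m, n, m / n, enr))
    return pd.DataFrame(rows, columns=["bin", "mean_score", "m", "n",
                                       "hit_rate", "fold_enrichment"])


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(predicted: Iterable[Pair], gold: GoldStandard
                      ) -> tuple[ConfusionCounts, float, float, float | None]:
    """Confusion counts, accuracy, recall and precision at a threshold.

    Counts are restricted to the GSP u GSN universe: predictions outside
    it are ignored.  Accuracy = (TP+TN)/total, recall = TP/(TP+FN),
    precision = TP/(TP+FP) (``None`` when nothing is predicted).
    """
    if not gold.gsp and not gold.gsn:
        raise ValueError("empty gold standard")
    predicted = {canonical_pair(*p) for p in predicted} & gold.universe
    tp = len(predicted & gold.gsp)
    fp = len(predicted & gold.gsn)
    fn = len(gold.gsp) - tp
    tn = len(gold.gsn) - fp
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else None
    return counts, accuracy, recall, precision


def hit_rate_by_distance(distances: Mapping[Pair, int | None],
                         gsp: Iterable[Pair]) -> pd.DataFrame:
    """GSP hit rate and cumulative coverage per minimum target distance.

    For every integer distance d: the fraction of pairs at distance d that
    are GSPs, and the cumulative fraction of all GSPs (in the supplied
    universe) found at distance <= d.  Pairs with undefined distance are
    summarized in a trailing row with distance ``NA``; they never enter
    the cumulative coverage.
    """
    gsp = {canonical_pair(*p) for p in gsp}
    total_gsp = sum(1 for p in distances if canonical_pair(*p) in gsp)
    by_d: dict[int | None, list[int]] = {}
    for pair, d in distances.items():
        hit = canonical_pair(*pair) in gsp
        cell = by_d.setdefault(d, [0, 0])
        cell[0] += int(hit)
        cell[1] += 1
    rows = []
    cum = 0
    for d in sorted(k for k in by_d if k is not None):
        m, n = by_d[d]
        cum += m
        rows.append((d, m, n, m / n, cum / total_gsp if total_gsp else np.nan))
    if None in by_d:
        m, n = by_d[None]
        rows.append((None, m, n, m / n,
                     cum / total_gsp if total_gsp else np.nan))
    return pd.DataFrame(rows, columns=["distance", "m", "n", "hit_rate",
                                       "coverage"])
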