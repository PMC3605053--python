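"""End-to-end drivers: score all drug pairs, fit LR models, evaluate.

These functions chain the individual modules exactly as the method
prescribes: weight the PPI network by cross-tissue coexpression, build each
drug's target-centered system, score every unordered drug pair (S-score,
minimum target distance, target overlap, P-score), fit per-evidence
likelihood-ratio models against a gold standard, and measure performance
(ROC/AUC, binned fold enrichment, confusion metrics at an LR threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import pandas as pd

from ddinet.bayes import LRModel, attach_lr, fit_lr, predict
from ddinet.evaluate import (
    ConfusionCounts,
    GoldStandard,
    binned_enrichment,
    confusion_metrics,
    hit_rate_by_distance,
    make_gold_standard,
    roc_auc,
)
from ddinet.io import PairScoreRecord, canonical_pair
from ddinet.network import (
    WeightedNetwork,
    _multi_source_bfs,
    background_stats,
    target_overlap,
    weight_edges,
)
from ddinet.phenotype import fit_term_weights, p_score
from ddinet.sscore import build_target_system, connection_profile, s_score

logger = logging.getLogger(__name__)

__all__ = ["score_pairs", "fit_models", "EvaluationReport", "evaluate_run"]

Pair = tuple[str, str]


def score_pairs(edges: pd.DataFrame, expr: pd.DataFrame,
                targets: Mapping[str, frozenset[str]],
                side_effects: Mapping[str, frozenset[str]] | None = None,
                all_pairs: bool = False) -> list[PairScoreRecord]:
    """Score every unordered drug pair on the coexpression-weighted network.

    By default only drugs with at least one in-network target are paired;
    with ``all_pairs`` every drug in *targets* is included and pairs
    without network evidence carry undefined S-scores and distances.
    P-scores are filled when *side_effects* is given.
    """
    net = weight_edges(edges, expr)
    mu_bg, sigma_bg = background_stats(net)
    logger.info("network: %d nodes, %d edges, background PCC %.4f +- %.4f",
                net.number_of_nodes(), net.number_of_edges(), mu_bg, sigma_bg)

    systems = {d: build_target_system(d, t, net) for d, t in targets.items()}
    in_net = {d for d, s in systems.items() if s.genes}
    dropped = sorted(set(targets) - in_net)
    if dropped:
        logger.info("%d drug(s) without in-network targets%s", len(dropped),
                    "" if all_pairs else " excluded")
    drugs = sorted(targets) if all_pairs else sorted(in_net)
    if not in_net:
        raise ValueError("no drug has a target in the network")

    # one multi-source BFS per drug instead of one per pair
    dist_from: dict[str, dict[str, int]] = {}
    in_net_targets = {d: frozenset(t for t in targets[d] if t in net.graph)
                      for d in drugs}
    for d in drugs:
        if in_net_targets[d]:
            dist_from[d] = _multi_source_bfs(net.graph, in_net_targets[d])

    weights = fit_term_weights(side_effects) if side_effects else None

    records = []
    for a, b in combinations(drugs, 2):
        a, b = canonical_pair(a, b)
        prof = connection_profile(systems[a], systems[b], net)
        s = s_score(prof, mu_bg, sigma_bg)
        if a in dist_from and in_net_targets[b]:
            d_ab = min((dist_from[a].get(t) for t in in_net_targets[b]
                        if t in dist_from[a]), default=None)
        else:
            d_ab = None
        p = p_score(a, b, side_effects, weights) \
            if side_effects is not None else None
        records.append(PairScoreRecord(
            drug_a=a, drug_b=b, s_score=s, p_score=p, min_distance=d_ab,
            overlap=target_overlap(targets[a], targets[b])))
    return records


def fit_models(records: list[PairScoreRecord], gsp: frozenset[Pair],
               gsn: frozenset[Pair], n_bins: int = 20,
               pseudo: float = 0.5) -> tuple[LRModel, LRModel]:
    """Fit the S-score and P-score LR models on a gold standard."""
    s_scores = {r.pair: r.s_score for r in records}
    p_scores = {r.pair: r.p_score for r in records}
    model_s = fit_lr(s_scores, gsp, gsn, n_bins=n_bins, pseudo=pseudo,
                     evidence="s_score")
    model_p = fit_lr(p_scores, gsp, gsn, n_bins=n_bins, pseudo=pseudo,
                     evidence="p_score")
    return model_s, model_p


@dataclass
class EvaluationReport:
    """Everything one evaluation run produces."""

    gold: GoldStandard
    model_s: LRModel
    model_p: LRModel
    auc_s: float
    auc_p: float
    auc_combined: float
    roc_s: pd.DataFrame
    roc_p: pd.DataFrame
    roc_combined: pd.DataFrame
    enrichment: pd.DataFrame
    distance_table: pd.DataFrame
    predicted: set[Pair] = field(default_factory=set)
    predicted_both: set[Pair] = field(default_factory=set)
    confusion: ConfusionCounts | None = None
    accuracy: float = 0.0
    recall: float = 0.0
    precision: float | None = None
    threshold: float = 2.0

    def summary(self) -> str:
        c = self.confusion
        lines = [
            f"gold standard: {len(self.gold.gsp)} positives, "
            f"{len(self.gold.gsn)} negatives "
            f"(multiplier {self.gold.multiplier}, seed {self.gold.seed})",
            f"AUC S-score      : {self.auc_s:.4f}",
            f"AUC P-score      : {self.auc_p:.4f}",
            f"AUC combined LR  : {self.auc_combined:.4f}",
            f"predictions at LR > {self.threshold:g}: {len(self.predicted)} "
            f"({len(self.predicted_both)} with both evidences)",
            f"confusion (universe): TP={c.TP} FP={c.FP} TN={c.TN} FN={c.FN}",
            f"accuracy  : {self.accuracy:.4f}",
            f"recall    : {self.recall:.4f}",
            "precision : " + (f"{self.precision:.4f}"
                              if self.precision is not None else "NA"),
        ]
        return "\n".join(lines) + "\n"


def evaluate_run(records: list[PairScoreRecord], gsp_pairs: frozenset[Pair],
                 seed: int = 0, gsn_multiplier: int = 1, n_bins: int = 20,
                 pseudo: float = 0.5, threshold: float = 2.0,
                 enrichment_bin_size: int = 100) -> EvaluationReport:
    """Full evaluation protocol on scored pairs against known interactions.

    The gold-standard positives are the known interacting pairs restricted
    to the scored universe; negatives are sampled (reproducibly, from
    *seed*) among the remaining scored pairs.  LR models are fitted on
    GSP u GSN and applied to all scored pairs.
    """
    universe = {r.pair for r in records}
    gsp = frozenset(canonical_pair(*p) for p in gsp_pairs) & universe
    if len(gsp) < 2:
        raise ValueError("fewer than 2 gold-standard positives were scored")
    drugs = sorted({d for r in records for d in r.pair})
    gold = make_gold_standard(drugs, gsp, multiplier=gsn_multiplier,
                              seed=seed)

    model_s, model_p = fit_models(records, gold.gsp, gold.gsn,
                                  n_bins=n_bins, pseudo=pseudo)
    attach_lr(records, model_s, model_p)

    s_scores = {r.pair: r.s_score for r in records}
    p_scores = {r.pair: r.p_score for r in records}
    combined = {r.pair: r.lr_combined for r in records}
    distances = {r.pair: r.min_distance for r in records}

    roc_s, auc_s = roc_auc(s_scores, gold)
    roc_p, auc_p = roc_auc(p_scores, gold)
    roc_c, auc_c = roc_auc(combined, gold)

    enrichment = binned_enrichment(s_scores, gold.gsp,
                                   bin_size=enrichment_bin_size)
    dist_table = hit_rate_by_distance(distances, gold.gsp)

    predicted, both = predict(records, model_s, model_p, threshold=threshold)
    counts, accuracy, recall, precision = confusion_metrics(predicted, gold)

    return EvaluationReport(
        gold=gold, model_s=model_s, model_p=model_p,
        auc_s=auc_s, auc_p=auc_p, auc_combined=auc_c,
        roc_s=roc_s, roc_p=roc_p, roc_combined=roc_c,
        enrichment=enrichment, distance_table=dist_table,
        predicted=predicted, predicted_both=both, confusion=counts,
        accuracy=accuracy, recall=recall, precision=precision,
        threshold=threshold)
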