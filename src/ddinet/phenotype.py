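"""Side-effect-profile similarity between drugs (P-score).

Two drugs that produce the same rare side effects are more likely to act on
the same physiological system than two drugs sharing only ubiquitous
effects (headache, nausea).  The P-score is therefore an inverse-frequency
weighted sum over shared side-effect terms: a term annotated to a fraction
f of all drugs contributes -log2(f), so a term present in every drug
contributes nothing and rarer terms contribute more.  Downstream evidence
integration consumes the P-score only through rank bins, so any similarity
measure that is monotone in "rare shared effects" yields the same
likelihood-ratio machinery.
"""

from __future__ import annotations

import math
from typing import Mapping

__all__ = ["fit_term_weights", "p_score"]


def fit_term_weights(side_effects: Mapping[str, frozenset[str]]
                     ) -> dict[str, float]:
    """Inverse-frequency weights for every side-effect term in the corpus.

    w(t) = -log2(f(t)) with f(t) = (# drugs annotated with t) / (# drugs).
    A term annotated to every drug gets weight 0.
    """
    if not side_effects:
        raise ValueError("side-effect table is empty")
    n_drugs = len(side_effects)
    counts: dict[str, int] = {}
    for terms in side_effects.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log2(c / n_drugs) for t, c in counts.items()}


def p_score(drug_a: str, drug_b: str,
            side_effects: Mapping[str, frozenset[str]],
            weights: Mapping[str, float]) -> float | None:
    """Weighted shared-side-effect similarity of two drugs.

    Returns ``None`` when either drug is absent from the side-effect
    table: the evidence is missing, which is not the same as two drugs
    with disjoint profiles (P = 0).  Raises ``KeyError`` for a term
    without a fitted weight.
    """
    if drug_a not in side_effects or drug_b not in side_effects:
        return None
    shared = side_effects[drug_a] & side_effects[drug_b]
    return float(sum(weights[t] for t in shared))
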