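"""Target-centered systems and the S-score.

A drug's *target-centered system* is the set of its in-network targets plus
their first-step neighbors in the PPI graph.  The S-score of a drug pair is
a one-sample t-type statistic asking whether the cross-tissue coexpression
(PCC) of the edges connecting the two systems is higher than the
network-wide background mean:

    S = (mu - mu_bg) / (sigma / sqrt(n))

where mu, sigma and n are the mean, sample SD and count of the connecting
edges' PCCs, and mu_bg is the mean PCC over all weighted edges.  If the two
systems share a gene, one artificial entry with PCC exactly 1.0 is added
per shared gene, so overlapping systems score as maximally coexpressed at
the point of contact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ddinet.io import canonical_pair
from ddinet.network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSystem",
    "ConnectionProfile",
    "build_target_system",
    "connection_profile",
    "s_score",
]


@dataclass(frozen=True)
class TargetSystem:
    """A drug's in-network targets plus their first-step neighbors."""

    drug: str
    genes: frozenset[str]


@dataclass
class ConnectionProfile:
    """PCCs of the edges connecting two target-centered systems.

    ``pcc_list`` holds one entry per physical connecting edge with a
    defined weight, plus one artificial 1.0 entry per gene shared by the
    two systems.  ``mean`` and ``sd`` (sample SD) are ``None`` when the
    list is empty; ``sd`` is 0.0 for a single entry.
    """

    pcc_list: tuple[float, ...]
    n: int = field(init=False)
    mean: float | None = field(init=False)
    sd: float | None = field(init=False)

    def __post_init__(self):
        self.n = len(self.pcc_list)
        if self.n == 0:
            self.mean = None
            self.sd = None
        else:
            arr = np.asarray(self.pcc_list, dtype=float)
            self.mean = float(arr.mean())
            self.sd = float(arr.std(ddof=1)) if self.n >= 2 else 0.0


def build_target_system(drug: str, targets: frozenset[str] | set[str],
                        net: WeightedNetwork) -> TargetSystem:
    """Expand a drug's targets to its target-centered system.

    Targets absent from the network are dropped with a logged warning; a
    drug with no in-network target yields an empty system.
    """
    in_net = {t for t in targets if t in net.graph}
    missing = set(targets) - in_net
    if missing:
        logger.info("drug %s: %d target(s) not in network: %s",
                    drug, len(missing), ", ".join(sorted(missing)[:5]))
    genes = set(in_net)
    for t in in_net:
        genes.update(net.graph.adj[t])
    return TargetSystem(drug=drug, genes=frozenset(genes))


def connection_profile(sys_a: TargetSystem, sys_b: TargetSystem,
                       net: WeightedNetwork) -> ConnectionProfile:
    """Collect the PCCs of all edges connecting two systems.

    A network edge (u, v) connects the systems when one endpoint lies in
    ``sys_a.genes`` and the other in ``sys_b.genes``; each physical edge
    contributes at most one entry even if both endpoints lie in both
    systems.  Edges without a defined weight are skipped.  One artificial
    1.0 entry is appended per shared gene.
    """
    ga, gb = sys_a.genes, sys_b.genes
    graph = net.graph
    seen: set[tuple[str, str]] = set()
    pccs: list[float] = []
    # iterate adjacency of the smaller side for speed
    small, other = (ga, gb) if len(ga) <= len(gb) else (gb, ga)
    for u in small:
        if u not in graph:
            continue
        for v, attrs in graph.adj[u].items():
            if v not in other:
                continue
            key = canonical_pair(u, v)
            if key in seen:
                continue
            seen.add(key)
            w = attrs.get("weight")
            if w is not None:
                pccs.append(float(w))
    pccs.extend(1.0 for _ in ga & gb)
    return ConnectionProfile(pcc_list=tuple(pccs))


def s_score(profile: ConnectionProfile, mu_bg: float,
            sigma_bg: float) -> float | None:
    """One-sample t-type statistic of the connection PCCs vs background.

    Returns ``None`` when no connection exists (n = 0).  When the profile
    SD is zero (in particular for n = 1) the background SD stands in, so
    single-contact pairs still receive a finite, comparable score; if the
    background SD is zero too, the score is undefined.
    """
    if profile.n == 0:
        return None
    sigma = profile.sd
    if sigma == 0.0:
        sigma = sigma_bg
    if sigma is None or sigma == 0.0:
        return None
    return (profile.mean - mu_bg) / (sigma / math.sqrt(profile.n))
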