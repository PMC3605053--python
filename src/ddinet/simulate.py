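"""Synthetic benchmark generator.

Produces the five input tables of the pipeline -- PPI edge list, gene x
tissue expression matrix, drug-target associations, drug side-effect
annotations and a known-DDI table -- with the statistical structure the
prediction method assumes: interacting drugs have targets close together in
the network (same module of a planted-partition graph), those modules are
coexpressed across tissues (shared latent tissue profile per module), and
interacting drugs share extra side-effect terms.  All randomness flows from
one integer seed through a single generator stream, so the whole benchmark
is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ddinet.io import canonical_pair

__all__ = [
    "BenchmarkConfig",
    "BenchmarkTruth",
    "default_config",
    "null_config",
    "generate_benchmark",
    "write_benchmark",
]

#: description attached to planted interacting pairs; deliberately free of
#: every classification keyword so the pairs label as PD-like
PLANTED_DESCRIPTION = ("Increased risk of adverse pharmacodynamic effects "
                       "when the two drugs are coadministered")


@dataclass(frozen=True)
class BenchmarkConfig:
    """All knobs of the generative model.

    ``rho_within`` is the expected cross-tissue expression PCC between two
    genes of the same module when ``noise_sd`` is 1 (each gene mixes the
    module's latent tissue profile with independent noise:
    x = sqrt(rho) * latent + sqrt(1 - rho) * noise_sd * eps).
    """

    n_genes: int = 300
    n_modules: int = 6
    p_within: float = 0.15
    p_between: float = 0.01
    n_tissues: int = 40
    rho_within: float = 0.7
    noise_sd: float = 1.0
    n_drugs: int = 60
    targets_per_drug: int = 3
    n_planted_pairs: int = 20
    side_effect_vocab_size: int = 150
    se_per_drug: int = 8
    se_overlap_boost: int = 4
    seed: int = 1

    def __post_init__(self):
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("need 0 <= p_between <= p_within <= 1")
        if not (0.0 <= self.rho_within < 1.0):
            raise ValueError("need 0 <= rho_within < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("n_genes", "n_modules", "n_tissues", "n_drugs",
                     "targets_per_drug", "side_effect_vocab_size",
                     "se_per_drug"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_pairs < 0 or self.se_overlap_boost < 0:
            raise ValueError("counts must be non-negative")
        if 2 * self.n_planted_pairs > self.n_drugs:
            raise ValueError("planted pairs need 2 drugs each; "
                             "2 * n_planted_pairs must be <= n_drugs")
        if self.n_tissues < 3:
            raise ValueError("need at least 3 tissues")


@dataclass(frozen=True)
class BenchmarkTruth:
    """Ground truth of a generated benchmark."""

    planted: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]
    drug_module: dict[str, int | None]


def default_config(seed: int = 1) -> BenchmarkConfig:
    """The documented default study conditions (runs in well under a minute)."""
    return BenchmarkConfig(seed=seed)


def null_config(seed: int = 1) -> BenchmarkConfig:
    """Defaults with every planted signal switched off.

    Uniform edge probability (p_within = p_between), uncorrelated
    expression and no extra shared side effects: planted labels persist
    but carry no information, so every evidence should be at chance.
    """
    cfg = default_config(seed=seed)
    return replace(cfg, p_within=cfg.p_between, rho_within=0.0,
                   se_overlap_boost=0)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_graph(rng: np.random.Generator, cfg: BenchmarkConfig,
                  module_of: np.ndarray) -> pd.DataFrame:
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    same = module_of[iu] == module_of[ju]
    p = np.where(same, cfg.p_within, cfg.p_between)
    keep = rng.random(len(iu)) < p
    genes = np.array(_gene_names(cfg.n_genes))
    return pd.DataFrame({"gene_a": genes[iu[keep]],
                         "gene_b": genes[ju[keep]]})


def _sample_expression(rng: np.random.Generator, cfg: BenchmarkConfig,
                       module_of: np.ndarray) -> pd.DataFrame:
    latent = rng.normal(size=(cfg.n_modules, cfg.n_tissues))
    noise = rng.normal(size=(cfg.n_genes, cfg.n_tissues))
    rho = cfg.rho_within
    mat = (np.sqrt(rho) * latent[module_of]
           + np.sqrt(1.0 - rho) * cfg.noise_sd * noise)
    tissues = [f"tissue_{t + 1:02d}" for t in range(cfg.n_tissues)]
    return pd.DataFrame(mat, index=pd.Index(_gene_names(cfg.n_genes),
                                            name="gene"), columns=tissues)


def generate_benchmark(config: BenchmarkConfig) -> tuple[
        pd.DataFrame, pd.DataFrame, dict[str, frozenset[str]],
        dict[str, frozenset[str]], pd.DataFrame, BenchmarkTruth]:
    """Generate (edges, expression, targets, side effects, ddis, truth).

    The first ``2 * n_planted_pairs`` drugs form the planted interacting
    pairs: both drugs of a pair draw their targets from one shared module
    (round-robin over modules).  Remaining drugs draw targets uniformly
    from all genes.  Planted pairs are recorded in the DDI table with a
    PD-like description; every other drug pair is a negative.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    module_of = np.arange(cfg.n_genes) % cfg.n_modules
    module_sizes = np.bincount(module_of, minlength=cfg.n_modules)
    if module_sizes.min() < cfg.targets_per_drug:
        raise ValueError("smallest module has fewer genes than "
                         "targets_per_drug")

    edges = _sample_graph(rng, cfg, module_of)
    expr = _sample_expression(rng, cfg, module_of)

    genes = np.array(_gene_names(cfg.n_genes))
    width = len(str(cfg.n_drugs))
    drugs = [f"D{i + 1:0{width}d}" for i in range(cfg.n_drugs)]

    targets: dict[str, frozenset[str]] = {}
    drug_module: dict[str, int | None] = {}
    planted: list[tuple[str, str]] = []
    for k in range(cfg.n_planted_pairs):
        mod = k % cfg.n_modules
        pool = genes[module_of == mod]
        d1, d2 = drugs[2 * k], drugs[2 * k + 1]
        for d in (d1, d2):
            picked = rng.choice(pool, size=cfg.targets_per_drug,
                                replace=False)
            targets[d] = frozenset(picked)
            drug_module[d] = mod
        planted.append(canonical_pair(d1, d2))
    for d in drugs[2 * cfg.n_planted_pairs:]:
        picked = rng.choice(genes, size=cfg.targets_per_drug, replace=False)
        targets[d] = frozenset(picked)
        drug_module[d] = None

    vocab = np.array([f"SE{t + 1:03d}"
                      for t in range(cfg.side_effect_vocab_size)])
    side_effects: dict[str, set[str]] = {}
    for d in drugs:
        picked = rng.choice(vocab, size=min(cfg.se_per_drug, len(vocab)),
                            replace=False)
        side_effects[d] = set(picked)
    for d1, d2 in planted:
        boost = rng.choice(vocab, size=min(cfg.se_overlap_boost, len(vocab)),
                           replace=False)
        side_effects[d1].update(boost)
        side_effects[d2].update(boost)

    ddis = pd.DataFrame(
        [(a, b, PLANTED_DESCRIPTION, "") for a, b in planted],
        columns=["drug_a", "drug_b", "description", "ddi_class"])

    all_pairs = {canonical_pair(a, b) for a, b in combinations(drugs, 2)}
    truth = BenchmarkTruth(
        planted=frozenset(planted),
        negatives=frozenset(all_pairs - set(planted)),
        drug_module=drug_module)
    se_frozen = {d: frozenset(s) for d, s in side_effects.items()}
    return edges, expr, targets, se_frozen, ddis, truth


def write_benchmark(out_dir, edges: pd.DataFrame, expr: pd.DataFrame,
                    targets: dict[str, frozenset[str]],
                    side_effects: dict[str, frozenset[str]],
                    ddis: pd.DataFrame) -> dict[str, Path]:
    """Write the five tables as TSV files readable by :mod:`ddinet.io`.

    Returns the path of each written file keyed by table name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out_dir / "network.tsv",
        "expression": out_dir / "expression.tsv",
        "targets": out_dir / "targets.tsv",
        "side_effects": out_dir / "side_effects.tsv",
        "ddis": out_dir / "ddis.tsv",
    }
    edges.to_csv(paths["network"], sep="\t", header=False, index=False)
    expr.round(6).to_csv(paths["expression"], sep="\t", float_format="%.6g")
    with open(paths["targets"], "wt", encoding="utf-8") as fh:
        for d in sorted(targets):
            for t in sorted(targets[d]):
                fh.write(f"{d}\t{t}\n")
    with open(paths["side_effects"], "wt", encoding="utf-8") as fh:
        for d in sorted(side_effects):
            for t in sorted(side_effects[d]):
                fh.write(f"{d}\t{t}\n")
    ddis.to_csv(paths["ddis"], sep="\t", header=False, index=False)
    return paths
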