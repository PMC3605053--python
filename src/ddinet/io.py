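"""Readers and writers for the flat tabular formats used throughout.

All tables are tab-separated UTF-8 text; lines starting with ``#`` are
comments and blank lines are skipped.  Every reader transparently accepts
gzip-compressed files.  These functions only parse and validate -- no
science happens here.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "PairScoreRecord",
    "canonical_pair",
    "read_edge_table",
    "read_expression_matrix",
    "read_drug_targets",
    "read_side_effects",
    "read_ddis",
    "write_pair_scores",
    "read_pair_scores",
]

#: significant digits used when writing floats; round-tripping is exact at
#: this precision
FLOAT_DIGITS = 6

PAIR_SCORE_COLUMNS = (
    "drug_a",
    "drug_b",
    "s_score",
    "p_score",
    "min_distance",
    "overlap",
    "lr_s",
    "lr_p",
    "lr_combined",
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-independent key for an unordered drug (or gene) pair."""
    return (a, b) if a <= b else (b, a)


def _open_text(path):
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _iter_rows(path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for each data line."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_edge_table(path, weighted: bool = False) -> pd.DataFrame:
    """Read an undirected edge list into a canonicalized edge table.

    Parameters
    ----------
    path
        TSV with columns ``gene_a  gene_b`` and, if *weighted*, a third
        numeric weight column.
    weighted
        Expect and parse a weight column.

    Returns
    -------
    DataFrame with columns ``gene_a``, ``gene_b`` (and ``weight``); edges
    stored with lexicographically sorted endpoints, self-loops dropped
    (count logged), duplicate undirected edges collapsed to the first
    occurrence.
    """
    rows = []
    n_self = 0
    seen: set[tuple[str, str]] = set()
    n_lines = 0
    for lineno, fields in _iter_rows(path):
        n_lines += 1
        if len(fields) < 2 or (weighted and len(fields) < 3):
            raise ParseError(f"{path}: line {lineno}: expected at least "
                             f"{3 if weighted else 2} columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(f"{path}: line {lineno}: empty gene identifier")
        if a == b:
            n_self += 1
            continue
        key = canonical_pair(a, b)
        if key in seen:
            continue
        seen.add(key)
        if weighted:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad weight "
                                 f"{fields[2]!r}") from exc
            rows.append((*key, w))
        else:
            rows.append(key)
    if n_lines == 0:
        raise ParseError(f"{path}: empty edge table")
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    cols = ["gene_a", "gene_b"] + (["weight"] if weighted else [])
    return pd.DataFrame(rows, columns=cols)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a gene x tissue expression matrix.

    First row is the header of tissue names, first column the gene id.
    Genes with any non-numeric cell are dropped with a logged warning,
    so that every retained gene has a complete tissue vector.  Ragged
    rows and duplicate gene ids are errors.
    """
    header: list[str] | None = None
    genes: list[str] = []
    vectors: list[list[float]] = []
    dropped: list[str] = []
    for lineno, fields in _iter_rows(path):
        if header is None:
            header = [f.strip() for f in fields[1:]]
            if len(header) < 3:
                raise ParseError(f"{path}: need at least 3 tissue columns, "
                                 f"got {len(header)}")
            if len(set(header)) != len(header):
                raise ParseError(f"{path}: duplicate tissue names in header")
            continue
        if len(fields) != len(header) + 1:
            raise ParseError(f"{path}: line {lineno}: expected "
                             f"{len(header) + 1} columns, got {len(fields)}")
        gene = fields[0].strip()
        if gene in genes:
            raise ParseError(f"{path}: line {lineno}: duplicate gene {gene!r}")
        try:
            vec = [float(x) for x in fields[1:]]
        except ValueError:
            dropped.append(gene)
            continue
        if any(math.isnan(v) for v in vec):
            dropped.append(gene)
            continue
        genes.append(gene)
        vectors.append(vec)
    if header is None:
        raise ParseError(f"{path}: empty expression matrix")
    if dropped:
        logger.warning("%s: dropped %d gene(s) with non-numeric cells: %s",
                       path, len(dropped), ", ".join(dropped[:10]))
    return pd.DataFrame(vectors, index=pd.Index(genes, name="gene"),
                        columns=header, dtype=float)


def _read_grouped(path, what: str) -> dict[str, frozenset[str]]:
    groups: dict[str, set[str]] = {}
    for lineno, fields in _iter_rows(path):
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        key, val = fields[0].strip(), fields[1].strip()
        if not key or not val:
            raise ParseError(f"{path}: line {lineno}: empty {what} field")
        groups.setdefault(key, set()).add(val)
    return {k: frozenset(v) for k, v in groups.items()}


def read_drug_targets(path) -> dict[str, frozenset[str]]:
    """Read drug -> target-gene associations (TSV: drug, target)."""
    return _read_grouped(path, "drug/target")


def read_side_effects(path) -> dict[str, frozenset[str]]:
    """Read drug -> side-effect-term annotations (TSV: drug, term)."""
    return _read_grouped(path, "drug/side-effect")


def read_ddis(path) -> pd.DataFrame:
    """Read a known-DDI table (TSV: drug_a, drug_b, description[, class]).

    Pairs are stored with canonical (sorted) drug order; duplicate pairs
    keep the first record.  A missing description leaves the class
    unlabeled (empty string in the ``ddi_class`` column).
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for lineno, fields in _iter_rows(path):
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected at least 2 columns")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(f"{path}: line {lineno}: empty drug identifier")
        if a == b:
            logger.warning("%s: line %d: self-pair %s dropped", path, lineno, a)
            continue
        key = canonical_pair(a, b)
        if key in seen:
            continue
        seen.add(key)
        desc = fields[2].strip() if len(fields) > 2 else ""
        cls = fields[3].strip() if len(fields) > 3 else ""
        rows.append((*key, desc, cls))
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "description",
                                       "ddi_class"])


@dataclass
class PairScoreRecord:
    """All per-pair quantities the pipeline computes.

    ``None`` marks an undefined value (evidence missing, not zero).
    """

    drug_a: str
    drug_b: str
    s_score: float | None = None
    p_score: float | None = None
    min_distance: int | None = None
    overlap: bool | None = None
    lr_s: float | None = None
    lr_p: float | None = None
    lr_combined: float | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.drug_a, self.drug_b)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, int):
        return str(value)
    return f"{value:.{FLOAT_DIGITS}g}"


def _sort_key(rec: PairScoreRecord):
    # descending combined LR, undefined last, then lexicographic pair
    lr = rec.lr_combined
    return (lr is None, -lr if lr is not None else 0.0, rec.pair)


def write_pair_scores(records: list[PairScoreRecord], path) -> None:
    """Write pair scores as TSV, sorted by descending combined LR then pair.

    Missing values are rendered ``NA``; floats use 6 significant digits.
    """
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(PAIR_SCORE_COLUMNS) + "\n")
        for rec in sorted(records, key=_sort_key):
            a, b = rec.pair
            fh.write("\t".join([
                a, b,
                _fmt(rec.s_score), _fmt(rec.p_score),
                _fmt(rec.min_distance), _fmt(rec.overlap),
                _fmt(rec.lr_s), _fmt(rec.lr_p), _fmt(rec.lr_combined),
            ]) + "\n")


def _parse_opt(text: str, kind):
    if text == "NA":
        return None
    if kind is bool:
        return text == "1"
    return kind(text)


def read_pair_scores(path) -> list[PairScoreRecord]:
    """Read back a table written by :func:`write_pair_scores`."""
    records = []
    header_seen = False
    for lineno, fields in _iter_rows(path):
        if not header_seen:
            if tuple(fields) != PAIR_SCORE_COLUMNS:
                raise ParseError(f"{path}: unexpected header {fields!r}")
            header_seen = True
            continue
        if len(fields) != len(PAIR_SCORE_COLUMNS):
            raise ParseError(f"{path}: line {lineno}: expected "
                             f"{len(PAIR_SCORE_COLUMNS)} columns")
        records.append(PairScoreRecord(
            drug_a=fields[0], drug_b=fields[1],
            s_score=_parse_opt(fields[2], float),
            p_score=_parse_opt(fields[3], float),
            min_distance=_parse_opt(fields[4], int),
            overlap=_parse_opt(fields[5], bool),
            lr_s=_parse_opt(fields[6], float),
            lr_p=_parse_opt(fields[7], float),
            lr_combined=_parse_opt(fields[8], float),
        ))
    if not header_seen:
        raise ParseError(f"{path}: empty score table")
    return records
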