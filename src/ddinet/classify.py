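"""Keyword classification of DDI description texts.

Known drug-drug interactions come with free-text clinical descriptions.
They are split into three classes by keyword rules, checked in order:
pharmaceutical (physicochemical incompatibility), pharmacokinetic (PK:
altered absorption / distribution / metabolism / excretion), and the rest,
which are treated as pharmacodynamic-like (PD-like) -- the class of
interest for network-based prediction.

Matching is by substring, case-insensitive except for keywords written in
all uppercase (e.g. "CYP"), which match case-sensitively so that the
substring does not fire inside ordinary words.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KeywordRuleSet",
    "DEFAULT_RULES",
    "classify_description",
    "classify_table",
    "read_rules",
    "write_rules",
]

PHARMACEUTICAL = "pharmaceutical"
PK = "PK"
PD_LIKE = "PD-like"


@dataclass(frozen=True)
class KeywordRuleSet:
    """Ordered keyword classes; the first class whose keyword matches wins."""

    classes: tuple[tuple[str, tuple[str, ...]], ...]
    default_class: str = PD_LIKE

    def __post_init__(self):
        for name, keywords in self.classes:
            if not keywords:
                raise ValueError(f"class {name!r} has no keywords")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.classes) + (self.default_class,)


DEFAULT_RULES = KeywordRuleSet(classes=(
    (PHARMACEUTICAL, ("physicochemical", "non-absorbable", "solution")),
    (PK, ("CYP", "absorption", "distribution", "metabolism", "excretion",
          "concentration", "level", "metabolite", "metabolized",
          "enzyme inducer", "clearance")),
))


def _matches(text: str, text_lower: str, keyword: str) -> bool:
    if keyword.isupper():
        return keyword in text
    return keyword.lower() in text_lower


def classify_description(text: str,
                         rules: KeywordRuleSet = DEFAULT_RULES) -> str:
    """Class of a single description text (total: always returns a class)."""
    text = text or ""
    text_lower = text.lower()
    for name, keywords in rules.classes:
        if any(_matches(text, text_lower, kw) for kw in keywords):
            return name
    return rules.default_class


def classify_table(ddis: pd.DataFrame,
                   rules: KeywordRuleSet = DEFAULT_RULES
                   ) -> tuple[pd.DataFrame, Counter]:
    """Label every DDI row with its class and tally per-class counts.

    Rows with a missing description get the default class with a warning.
    Returns a copy of the table with the ``ddi_class`` column filled and a
    Counter over all classes (zero counts included).
    """
    out = ddis.copy()
    desc = out["description"].fillna("") if "description" in out.columns \
        else pd.Series([""] * len(out), index=out.index)
    n_missing = int((desc.str.strip() == "").sum())
    if n_missing:
        logger.warning("%d DDI record(s) without description default to %s",
                       n_missing, rules.default_class)
    out["ddi_class"] = [classify_description(t, rules) for t in desc]
    counts = Counter({name: 0 for name in rules.class_names})
    counts.update(out["ddi_class"])
    return out, counts


def read_rules(path) -> KeywordRuleSet:
    """Read a rule config: one ``class: kw, kw, ...`` line per class.

    Class order in the file is the matching precedence; a line with no
    keywords after the colon names the default (fallback) class.
    """
    classes: list[tuple[str, tuple[str, ...]]] = []
    default = PD_LIKE
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}: malformed rule line {line!r}")
        name, _, rest = line.partition(":")
        keywords = tuple(k.strip() for k in rest.split(",") if k.strip())
        if keywords:
            classes.append((name.strip(), keywords))
        else:
            default = name.strip()
    return KeywordRuleSet(classes=tuple(classes), default_class=default)


def write_rules(rules: KeywordRuleSet, path) -> None:
    """Write a rule config readable by :func:`read_rules`."""
    lines = [f"{name}: {', '.join(kws)}" for name, kws in rules.classes]
    lines.append(f"{rules.default_class}:")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
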