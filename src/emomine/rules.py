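"""Apriori frequent-itemset mining and factor→emotion association rules.

Support is the share of posts containing an itemset; confidence the share
of antecedent posts also containing the consequent; lift the ratio of
confidence to the consequent's marginal support (>1: positive association,
≈1: independence, <1: negative association). Mining is level-wise with
downward-closure pruning: every subset of a frequent itemset is frequent,
so (k)-candidates are joins of (k−1)-frequent sets and are discarded if any
(k−1)-subset is infrequent.

Rule generation mirrors the study design: antecedents are nonempty sets of
factor items, consequents single emotion groups. Itemsets containing two or
more emotion groups therefore yield no rules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import ItemCatalog, default_catalog
from .coding import TransactionSet

__all__ = [
    "FrequentItemSet",
    "AssociationRule",
    "apriori",
    "generate_rules",
    "top_rules_by_lift",
    "rules_to_frame",
    "write_rules",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequentItemSet:
    items: frozenset[str]
    support: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: str
    support: float
    confidence: float
    lift: float

    def __str__(self) -> str:
        ante = ", ".join(sorted(self.antecedent))
        return (
            f"{{{ante}}} => {{{self.consequent}}} "
            f"(s={self.support:.3f}, c={self.confidence:.3f}, l={self.lift:.3f})"
        )


def apriori(
    transactions: TransactionSet, min_support: float
) -> list[FrequentItemSet]:
    """All itemsets with support ≥ ``min_support``, level-wise.

    Output is deterministic: sorted by itemset size, then lexicographically
    by item names. ``min_support`` must be positive — a zero threshold
    would enumerate all 2^47 subsets.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError(f"min_support must lie in (0, 1], got {min_support}")
    n = len(transactions)
    if n == 0:
        return []
    X = transactions.matrix
    names = list(transactions.items)

    result: list[FrequentItemSet] = []
    # level 1: frequent single items, kept with their indicator columns
    level: dict[tuple[str, ...], np.ndarray] = {}
    for j, name in enumerate(names):
        col = X[:, j]
        sup = col.sum() / n
        if sup >= min_support:
            level[(name,)] = col
            result.append(FrequentItemSet(frozenset((name,)), sup))

    while level:
        keys = sorted(level)
        frequent_prev = set(keys)
        nxt: dict[tuple[str, ...], np.ndarray] = {}
        # join step: two (k-1)-sets sharing their first k-2 items
        for a, b in combinations(keys, 2):
            if a[:-1] != b[:-1]:
                continue
            cand = a + (b[-1],) if a[-1] < b[-1] else b + (a[-1],)
            # prune: every (k-1)-subset must be frequent
            if any(
                cand[:i] + cand[i + 1 :] not in frequent_prev
                for i in range(len(cand))
            ):
                continue
            vec = level[a] & level[b]
            sup = vec.sum() / n
            if sup >= min_support:
                nxt[cand] = vec
                result.append(FrequentItemSet(frozenset(cand), sup))
        level = nxt

    result.sort(key=lambda fs: (len(fs.items), tuple(sorted(fs.items))))
    return result


def generate_rules(
    frequent: list[FrequentItemSet],
    min_confidence: float,
    catalog: ItemCatalog | None = None,
) -> list[AssociationRule]:
    """Factor→emotion rules from frequent itemsets.

    For every frequent itemset holding exactly one emotion group plus at
    least one factor item, emit ``factors => emotion`` when confidence
    ≥ ``min_confidence``. Lift uses the consequent's marginal support; a
    consequent never seen alone (support 0) is skipped with a log message.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    catalog = catalog or default_catalog()
    emotion_set = set(catalog.emotion_groups)
    support = {fs.items: fs.support for fs in frequent}
    rules: list[AssociationRule] = []
    for fs in frequent:
        emotions = fs.items & emotion_set
        if len(emotions) != 1 or len(fs.items) < 2:
            continue
        consequent = next(iter(emotions))
        antecedent = fs.items - emotions
        ante_sup = support[antecedent]  # guaranteed by downward closure
        conf = fs.support / ante_sup
        if conf < min_confidence:
            continue
        cons_sup = support.get(frozenset((consequent,)), 0.0)
        if cons_sup == 0.0:
            logger.warning(
                "rule %s => %s skipped: consequent support 0, lift undefined",
                sorted(antecedent),
                consequent,
            )
            continue
        rules.append(
            AssociationRule(
                antecedent=antecedent,
                consequent=consequent,
                support=fs.support,
                confidence=conf,
                lift=conf / cons_sup,
            )
        )
    group_order = {g: i for i, g in enumerate(catalog.emotion_groups)}
    rules.sort(
        key=lambda r: (
            group_order.get(r.consequent, 99),
            -r.lift,
            -r.support,
            tuple(sorted(r.antecedent)),
        )
    )
    return rules


def top_rules_by_lift(
    rules: list[AssociationRule],
    k: int = 5,
    per: str | None = None,
    catalog: ItemCatalog | None = None,
) -> list[AssociationRule]:
    """The ``k`` highest-lift rules per consequent emotion group.

    Ties break by higher support, then lexicographic antecedent. With
    ``per`` given, only that group's rules are returned; otherwise the
    per-group top-k lists are concatenated in catalog group order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    catalog = catalog or default_catalog()
    groups = [per] if per is not None else list(catalog.emotion_groups)
    out: list[AssociationRule] = []
    for g in groups:
        group_rules = sorted(
            (r for r in rules if r.consequent == g),
            key=lambda r: (-r.lift, -r.support, tuple(sorted(r.antecedent))),
        )
        out.extend(group_rules[:k])
    return out


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    """Tabular view with metrics rounded to 3 decimals."""
    return pd.DataFrame(
        [
            {
                "antecedent": "|".join(sorted(r.antecedent)),
                "consequent": r.consequent,
                "support": round(r.support, 3),
                "confidence": round(r.confidence, 3),
                "lift": round(r.lift, 3),
            }
            for r in rules
        ],
        columns=["antecedent", "consequent", "support", "confidence", "lift"],
    )


def write_rules(rules: list[AssociationRule], csv_path: str | Path) -> None:
    """CSV at 3 decimals plus a full-precision JSONL alongside."""
    csv_path = Path(csv_path)
    rules_to_frame(rules).to_csv(csv_path, index=False)
    jsonl = csv_path.with_suffix(".jsonl")
    with jsonl.open("w", encoding="utf-8") as fh:
        for r in rules:
            fh.write(
                json.dumps(
                    {
                        "antecedent": sorted(r.antecedent),
                        "consequent": r.consequent,
                        "support": r.support,
                        "confidence": r.confidence,
                        "lift": r.lift,
                    }
                )
                + "\n"
            )
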