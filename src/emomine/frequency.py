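"""Descriptive frequency tables: per-channel item counts and emotion-group
marginals.

Percentages are row percentages (share of an item's mentions falling on
each channel) or corpus percentages (share of all posts mentioning an
emotion group); both are rounded half-up to one decimal. Emotion-group
percentages may sum above 100 because posts are multi-label.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .lexicon import CHANNELS, default_catalog
from .coding import TransactionSet

__all__ = ["round_half_up", "channel_table", "emotion_frequencies"]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def channel_table(
    transactions: TransactionSet, items: list[str] | None = None
) -> pd.DataFrame:
    """Per-channel mention counts and row percentages for the given items.

    Columns: ``item, total, <ch>_n, <ch>_pct`` for each channel. An item
    never mentioned gets a zero row with percentages defined as 0.0.
    """
    catalog = default_catalog()
    if items is None:
        items = list(catalog.items)
    unknown = set(items) - set(transactions.items)
    if unknown:
        raise ValueError(f"items not in catalog: {sorted(unknown)}")
    frame = transactions.frame
    rows = []
    for item in items:
        per_channel = {
            ch: int(frame.loc[frame["channel"] == ch, item].sum()) for ch in CHANNELS
        }
        total = sum(per_channel.values())
        row: dict[str, object] = {"item": item, "total": total}
        for ch in CHANNELS:
            n = per_channel[ch]
            row[f"{ch}_n"] = n
            row[f"{ch}_pct"] = round_half_up(100.0 * n / total) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def emotion_frequencies(transactions: TransactionSet) -> pd.DataFrame:
    """Count and percentage of posts mentioning each emotion group.

    The denominator is the number of selected posts, so multi-label
    percentages can exceed 100 in total.
    """
    n_posts = len(transactions)
    if n_posts == 0:
        raise ValueError("no posts: emotion percentages undefined")
    catalog = default_catalog()
    rows = []
    for group in catalog.emotion_groups:
        count = int(transactions.frame[group].sum())
        rows.append(
            {
                "emotion_group": group,
                "count": count,
                "percent": round_half_up(100.0 * count / n_posts),
            }
        )
    return pd.DataFrame(rows)
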