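"""Inclusion/exclusion funnel and post → transaction coding.

A post enters the analysis only if it (a) mentions the cancer topic (a
generic cancer keyword or a specific cancer-type term), (b) mentions at
least one emotion term, (c) contains no stop keyword, and (d) contains no
advertising keyword. Stop-keyword posts are dropped before the emotion
count; advertising posts are subtracted afterwards, so the funnel satisfies
``n_selected = n_with_emotion - n_ad_excluded``.

Surviving posts are coded into a 47-dimensional 0/1 indicator vector with
count-once semantics: a group mentioned five times scores the same 1 as a
group mentioned once, and every distinct group mentioned in a post is
counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import CHANNELS, ItemCatalog, Lexicon, default_catalog, match_items
from .synthetic import Post

__all__ = [
    "FilterReport",
    "CodedPost",
    "TransactionSet",
    "ConsistencyError",
    "filter_posts",
    "code_posts",
]


class ConsistencyError(RuntimeError):
    """A post violated the filter contract downstream of the filter."""


@dataclass(frozen=True)
class FilterReport:
    """Counts at each stage of the selection funnel."""

    n_input: int
    n_with_emotion: int
    n_ad_excluded: int
    n_selected: int

    def __post_init__(self) -> None:
        if self.n_with_emotion > self.n_input:
            raise ValueError("n_with_emotion exceeds n_input")
        if self.n_selected != self.n_with_emotion - self.n_ad_excluded:
            raise ValueError(
                "funnel identity violated: "
                f"{self.n_selected} != {self.n_with_emotion} - {self.n_ad_excluded}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


@dataclass(frozen=True)
class CodedPost:
    id: str
    channel: str
    indicators: dict[str, int]


@dataclass
class TransactionSet:
    """Post × item binary matrix over the 47 analysis items.

    Backed by a DataFrame with ``post_id`` and ``channel`` columns followed
    by one 0/1 column per item, in catalog order.
    """

    items: tuple[str, ...]
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        expected = ["post_id", "channel", *self.items]
        if list(self.frame.columns) != expected:
            raise ValueError("TransactionSet frame columns do not match items")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, catalog: ItemCatalog | None = None):
        catalog = catalog or default_catalog()
        return cls(items=catalog.items, frame=frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def matrix(self) -> np.ndarray:
        """Boolean post × item matrix."""
        return self.frame[list(self.items)].to_numpy(dtype=bool)

    @property
    def channels(self) -> pd.Series:
        return self.frame["channel"]

    def item_counts(self) -> pd.Series:
        return self.frame[list(self.items)].sum()

    def subset(self, mask: np.ndarray) -> "TransactionSet":
        return TransactionSet(self.items, self.frame.loc[mask].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, catalog: ItemCatalog | None = None):
        catalog = catalog or default_catalog()
        frame = pd.read_csv(path, dtype={"post_id": str})
        frame[list(catalog.items)] = frame[list(catalog.items)].astype(np.int8)
        return cls(items=catalog.items, frame=frame)


def _classify(post: Post, lexicon: Lexicon):
    items, roles = match_items(post.tokens, lexicon)
    cancer_types = set(lexicon.catalog.factor_families["cancer_type"])
    on_topic = "cancer_keyword" in roles or bool(items & cancer_types)
    has_emotion = bool(items & set(lexicon.catalog.emotion_groups))
    return items, roles, on_topic, has_emotion


def filter_posts(
    posts: list[Post], lexicon: Lexicon
) -> tuple[list[Post], FilterReport]:
    """Apply the selection funnel; returns survivors and the stage counts."""
    kept: list[Post] = []
    n_with_emotion = 0
    n_ad_excluded = 0
    for post in posts:
        _, roles, on_topic, has_emotion = _classify(post, lexicon)
        if not on_topic or "stop_keyword" in roles or not has_emotion:
            continue
        n_with_emotion += 1
        if "ad_keyword" in roles:
            n_ad_excluded += 1
            continue
        kept.append(post)
    report = FilterReport(
        n_input=len(posts),
        n_with_emotion=n_with_emotion,
        n_ad_excluded=n_ad_excluded,
        n_selected=len(kept),
    )
    return kept, report


def code_posts(
    posts: list[Post], lexicon: Lexicon
) -> tuple[list[CodedPost], TransactionSet]:
    """Code filtered posts into 0/1 indicators over the 47 items.

    Raises :class:`ConsistencyError` if a post carries no emotion group —
    such posts must have been removed by :func:`filter_posts`.
    """
    catalog = lexicon.catalog
    all_items = catalog.items
    emotion_set = set(catalog.emotion_groups)
    coded: list[CodedPost] = []
    rows = np.zeros((len(posts), len(all_items)), dtype=np.int8)
    ids: list[str] = []
    channels: list[str] = []
    for i, post in enumerate(posts):
        if post.channel not in CHANNELS:
            raise ValueError(f"post {post.id}: unknown channel {post.channel!r}")
        items, _ = match_items(post.tokens, lexicon)
        if not items & emotion_set:
            raise ConsistencyError(
                f"post {post.id} reached coding with no emotion item"
            )
        indicators = {item: int(item in items) for item in all_items}
        coded.append(CodedPost(id=post.id, channel=post.channel, indicators=indicators))
        for item in items:
            if item in all_items:
                rows[i, all_items.index(item)] = 1
        ids.append(post.id)
        channels.append(post.channel)
    frame = pd.DataFrame(rows, columns=list(all_items))
    frame.insert(0, "channel", channels)
    frame.insert(0, "post_id", ids)
    return coded, TransactionSet(items=all_items, frame=frame)
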