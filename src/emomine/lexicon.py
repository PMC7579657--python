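"""Vocabulary handling: the 47-item analysis catalog and dictionary matching.

The analysis reduces every social-media post to binary indicators over 47
items: 4 multi-label emotion groups (aggregating nine ontology emotion
classes) and 43 emotion-related factor groups (gender, age bands, cancer
types, cancer stage, treatments, survivorship stages, symptom clusters).
A lexicon maps normalized surface terms — including colloquial synonyms in
any language — onto those items, or onto one of three role markers used by
the inclusion/exclusion funnel (generic cancer keywords, stop keywords,
advertising keywords).
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "CHANNELS",
    "EMOTION_GROUPS",
    "FACTOR_FAMILIES",
    "FACTOR_GROUPS",
    "EMOTION_CLASS_MAP",
    "ROLE_MARKERS",
    "ItemCatalog",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "LexiconFormatError",
    "LexiconValidationError",
    "default_catalog",
    "load_lexicon",
    "bundled_lexicon_path",
    "match_items",
    "normalize_tokens",
]

CHANNELS: tuple[str, ...] = ("blog", "cafe", "twitter", "board")

#: Four multi-label emotion groups (Jack et al. basic-emotion partition).
EMOTION_GROUPS: tuple[str, ...] = ("HG", "FAO", "SDLG", "AD")

EMOTION_GROUP_LABELS: dict[str, str] = {
    "HG": "Hope/Gratitude",
    "FAO": "Fear/Anxiety/Overwhelmed",
    "SDLG": "Sadness/Depression/Loneliness/Guilt",
    "AD": "Anger/Denial",
}

#: Nine ontology emotion classes folded into the four groups.
EMOTION_CLASS_MAP: dict[str, str] = {
    "hope": "HG",
    "gratitude": "HG",
    "anxiety": "FAO",
    "overwhelmed": "FAO",
    "depression": "SDLG",
    "loneliness": "SDLG",
    "guilt": "SDLG",
    "anger": "AD",
    "denial": "AD",
}

#: 43 factor groups partitioned into seven families (2+9+14+3+6+3+6).
FACTOR_FAMILIES: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "age": (
        "age_under_10",
        "age_10s",
        "age_20s",
        "age_30s",
        "age_40s",
        "age_50s",
        "age_60s",
        "age_70s",
        "age_over_80",
    ),
    "cancer_type": (
        "breast_cancer",
        "colon_cancer",
        "gastric_cancer",
        "leukemia",
        "lung_cancer",
        "cervical_cancer",
        "liver_cancer",
        "brain_cancer",
        "pancreatic_cancer",
        "ovarian_cancer",
        "prostatic_cancer",
        "gallbladder_cancer",
        "kidney_cancer",
        "thyroid_cancer",
    ),
    "stage": ("early_stage", "middle_stage", "terminal_stage"),
    "treatment": (
        "surgery",
        "chemotherapy",
        "radiation_therapy",
        "immunotherapy",
        "cam",
        "transplantation",
    ),
    "survival_stage": ("acute_survival", "extended_survival", "permanent_survival"),
    "symptom": (
        "fatigue_pain_fever",
        "gastrointestinal_problems",
        "hair_loss_skin_problems",
        "poor_circulation",
        "thrombocytopenia",
        "infection",
    ),
}

FACTOR_GROUPS: tuple[str, ...] = tuple(
    item for family in FACTOR_FAMILIES.values() for item in family
)

ROLE_MARKERS: tuple[str, ...] = ("cancer_keyword", "stop_keyword", "ad_keyword")


class LexiconError(ValueError):
    """Base class for lexicon problems."""


class LexiconFormatError(LexiconError):
    """The lexicon file does not have the expected columns."""


class LexiconValidationError(LexiconError):
    """The lexicon content violates a catalog constraint."""


@dataclass(frozen=True)
class ItemCatalog:
    """The fixed universe of analysis items.

    The catalog is part of the study design, not of any particular lexicon:
    4 emotion groups plus 43 factor groups = 47 items, with the nine
    ontology emotion classes mapped many-to-one onto the groups.
    """

    emotion_groups: tuple[str, ...] = EMOTION_GROUPS
    factor_groups: tuple[str, ...] = FACTOR_GROUPS
    factor_families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(FACTOR_FAMILIES)
    )
    emotion_class_map: dict[str, str] = field(
        default_factory=lambda: dict(EMOTION_CLASS_MAP)
    )

    def __post_init__(self) -> None:
        if len(self.emotion_groups) != 4:
            raise LexiconValidationError("catalog must have 4 emotion groups")
        if len(self.factor_groups) != 43:
            raise LexiconValidationError("catalog must have 43 factor groups")
        family_total = sum(len(v) for v in self.factor_families.values())
        if family_total != 43:
            raise LexiconValidationError(
                f"factor families sum to {family_total}, expected 43"
            )
        if set(self.emotion_class_map.values()) - set(self.emotion_groups):
            raise LexiconValidationError("emotion_class_map targets unknown group")
        if len(self.emotion_class_map) != 9:
            raise LexiconValidationError("emotion_class_map must cover 9 classes")

    @property
    def items(self) -> tuple[str, ...]:
        """All 47 analysis items, emotion groups first."""
        return self.emotion_groups + self.factor_groups


def default_catalog() -> ItemCatalog:
    return ItemCatalog()


@dataclass(frozen=True)
class LexiconEntry:
    """One surface term mapped to an analysis item or role marker."""

    term: str
    concept: str
    item: str

    def __post_init__(self) -> None:
        if not self.term:
            raise LexiconValidationError("empty term after normalization")


def _normalize_term(raw: str) -> str:
    return " ".join(raw.casefold().split())


def normalize_tokens(tokens: Iterable[str]) -> list[str]:
    """Casefold and whitespace-collapse tokens, dropping empties."""
    out: list[str] = []
    for tok in tokens:
        for piece in tok.casefold().split():
            out.append(piece)
    return out


class Lexicon:
    """A validated term → item mapping with O(1) phrase lookup.

    Multi-token terms are stored as token tuples; :func:`match_items` probes
    every contiguous token window whose length occurs in the lexicon.
    """

    def __init__(self, entries: Sequence[LexiconEntry], catalog: ItemCatalog):
        self.catalog = catalog
        valid_items = set(catalog.items) | set(ROLE_MARKERS)
        by_term: dict[tuple[str, ...], LexiconEntry] = {}
        offenders: list[str] = []
        deduped: list[LexiconEntry] = []
        for entry in entries:
            if entry.item not in valid_items:
                raise LexiconValidationError(
                    f"term {entry.term!r} maps to unknown item {entry.item!r}"
                )
            key = tuple(entry.term.split())
            prev = by_term.get(key)
            if prev is None:
                by_term[key] = entry
                deduped.append(entry)
            elif prev.item != entry.item:
                offenders.append(
                    f"{entry.term!r} -> {prev.item!r} and {entry.item!r}"
                )
            # identical (term, item) pair: silently deduplicated
        if offenders:
            raise LexiconValidationError(
                "ambiguous terms mapping to two items: " + "; ".join(offenders)
            )
        self.entries: tuple[LexiconEntry, ...] = tuple(deduped)
        self._by_term = by_term
        self._lengths = sorted({len(k) for k in by_term}, reverse=True)
        terms_by_item: dict[str, list[str]] = {}
        for e in self.entries:
            terms_by_item.setdefault(e.item, []).append(e.term)
        self._terms_by_item = {k: tuple(v) for k, v in terms_by_item.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def terms_for(self, item: str) -> tuple[str, ...]:
        """Surface terms attached to an item or role marker (may be empty)."""
        return self._terms_by_item.get(item, ())

    def items_touched(self) -> set[str]:
        return {e.item for e in self.entries}

    def lookup(self, window: tuple[str, ...]) -> LexiconEntry | None:
        return self._by_term.get(window)

    @property
    def window_lengths(self) -> list[int]:
        return self._lengths


def load_lexicon(path: str | Path) -> tuple[Lexicon, ItemCatalog]:
    """Read a TSV lexicon (``term<TAB>concept<TAB>item``, UTF-8).

    Item values may be any of the 47 catalog items, one of the nine emotion
    class names (folded onto their group), or a role marker
    (``cancer_keyword``/``stop_keyword``/``ad_keyword``). Duplicate
    (term, item) rows are deduplicated; a term mapped to two different
    items raises :class:`LexiconValidationError`.
    """
    path = Path(path)
    catalog = default_catalog()
    entries: list[LexiconEntry] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = set(reader.fieldnames or ())
        missing = {"term", "concept", "item"} - cols
        if missing:
            raise LexiconFormatError(
                f"{path}: missing columns {sorted(missing)} (found {sorted(cols)})"
            )
        for row in reader:
            term = _normalize_term(row["term"] or "")
            if not term:
                raise LexiconValidationError(f"{path}: blank term in row {row!r}")
            item = (row["item"] or "").strip()
            # emotion-class item values fold onto their emotion group
            item = catalog.emotion_class_map.get(item, item)
            entries.append(
                LexiconEntry(term=term, concept=(row["concept"] or "").strip(), item=item)
            )
    return Lexicon(entries, catalog), catalog


def bundled_lexicon_path() -> Path:
    """Path of the synthetic stand-in lexicon shipped with the package.

    The published cancer ontology (4,061 synonyms) is not distributable;
    this small bilingual lexicon covers all 47 items plus role markers and
    exists so the pipeline is runnable end-to-end. Any TSV with the same
    columns can be swapped in.
    """
    return Path(__file__).parent / "data" / "synthetic_lexicon.tsv"


def match_items(
    tokens: Sequence[str], lexicon: Lexicon
) -> tuple[set[str], set[str]]:
    """Dictionary-match a token sequence against the lexicon.

    Every lexicon term occurring as a contiguous token window contributes
    its item; multi-token terms therefore match without suppressing
    single-token entries inside them (set union). Repeated mentions add
    nothing beyond set membership (count-once semantics).

    Returns ``(items, roles)`` where *items* are analysis items and *roles*
    are funnel role markers (cancer/stop/ad keywords).
    """
    toks = normalize_tokens(tokens)
    items: set[str] = set()
    roles: set[str] = set()
    n = len(toks)
    for i in range(n):
        for length in lexicon.window_lengths:
            if i + length > n:
                continue
            entry = lexicon.lookup(tuple(toks[i : i + length]))
            if entry is not None:
                (roles if entry.item in ROLE_MARKERS else items).add(entry.item)
    return items, roles
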