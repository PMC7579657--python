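"""Synthetic social-media corpus with planted factor→emotion structure.

The study corpus (321,339 Korean posts about cancer) is not public, so this
module generates channel-tagged posts whose statistical structure is known
exactly: each post carries an independent Bernoulli set of the 43 factor
groups, and each of the 4 emotion groups is then drawn from a
logistic-odds model

    p_e(F) = sigma( logit(beta_e) + sum_{f in F} log(effect_e[f]) )

where ``beta_e`` is the emotion's baseline probability and ``effect_e[f]``
an odds multiplier. Posts with zero emotion groups are resampled (the
analyzed corpus contains only emotion-bearing posts) unless a contamination
fraction deliberately reinstates them; a second contamination fraction
appends advertising keywords, which the coding funnel later removes.
:func:`expected_lift` sums this generative model exactly over factor
configurations and is the closed-form oracle against which mined lifts are
checked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .lexicon import CHANNELS, EMOTION_GROUPS, FACTOR_GROUPS, Lexicon, default_catalog

__all__ = [
    "EmotionModel",
    "GeneratorConfig",
    "Post",
    "GenerationError",
    "generate_corpus",
    "expected_lift",
    "default_config",
    "write_corpus",
    "write_truth",
    "read_corpus",
]

#: Neutral tokens that never collide with lexicon terms.
DEFAULT_FILLERS: tuple[str, ...] = (
    "today",
    "really",
    "just",
    "about",
    "sharing",
    "story",
    "update",
    "everyone",
    "please",
    "while",
    "still",
    "going",
    "reading",
    "because",
    "together",
)

TWITTER_CHAR_LIMIT = 140


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EmotionModel:
    """Baseline probability and per-factor odds multipliers for one group."""

    baseline: float
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline < 1.0:
            raise ValueError(f"baseline {self.baseline} outside (0,1)")
        for f, m in self.effects.items():
            if m < 0:
                raise ValueError(f"negative odds multiplier {m} for {f}")


@dataclass
class GeneratorConfig:
    """Full description of the corpus-generating process.

    ``factor_prevalence`` values are either a single probability or a
    ``{channel: probability}`` map for channel-heterogeneous factors.
    """

    n_posts_per_channel: dict[str, int]
    factor_prevalence: dict[str, float | dict[str, float]]
    emotion_model: dict[str, EmotionModel]
    ad_fraction: float = 0.0
    no_emotion_fraction: float = 0.0
    filler_vocab: tuple[str, ...] = DEFAULT_FILLERS
    fillers_per_post: tuple[int, int] = (2, 6)  # inclusive range, longform
    seed: int = 0

    def __post_init__(self) -> None:
        catalog = default_catalog()
        for ch, n in self.n_posts_per_channel.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if n < 0:
                raise ValueError(f"negative post count for {ch}")
        for f, p in self.factor_prevalence.items():
            if f not in catalog.factor_groups:
                raise ValueError(f"unknown factor item {f!r}")
            vals = p.values() if isinstance(p, dict) else (p,)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"prevalence of {f} outside [0,1]")
        for e, model in self.emotion_model.items():
            if e not in catalog.emotion_groups:
                raise ValueError(f"unknown emotion group {e!r}")
            for f in model.effects:
                if f not in catalog.factor_groups:
                    raise ValueError(f"effect on unknown factor {f!r}")
        for frac in (self.ad_fraction, self.no_emotion_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("contamination fractions must lie in [0,1]")

    def prevalence_vector(self, channel: str) -> np.ndarray:
        """Per-factor Bernoulli probabilities for one channel (length 43)."""
        out = np.zeros(len(FACTOR_GROUPS))
        for i, f in enumerate(FACTOR_GROUPS):
            p = self.factor_prevalence.get(f, 0.0)
            out[i] = p.get(channel, 0.0) if isinstance(p, dict) else p
        return out


@dataclass(frozen=True)
class Post:
    id: str
    channel: str
    tokens: tuple[str, ...]
    truth: frozenset[str] | None = None  # planted items; tests only
    contaminant: str | None = None  # None | "ad" | "no_emotion"

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _emotion_prob_matrix(
    config: GeneratorConfig, factors: np.ndarray
) -> np.ndarray:
    """p_e(F) for each post (rows) and emotion group (columns)."""
    n = factors.shape[0]
    probs = np.empty((n, len(EMOTION_GROUPS)))
    with np.errstate(divide="ignore"):
        for j, e in enumerate(EMOTION_GROUPS):
            model = config.emotion_model.get(e)
            if model is None:
                probs[:, j] = 0.0
                continue
            log_effects = np.zeros(len(FACTOR_GROUPS))
            for f, m in model.effects.items():
                log_effects[FACTOR_GROUPS.index(f)] = np.log(m)
            logits = _logit(model.baseline) + factors @ log_effects
            probs[:, j] = 1.0 / (1.0 + np.exp(-logits))
    return probs


_MAX_RESAMPLE_ROUNDS = 1000


def _sample_channel(
    config: GeneratorConfig, channel: str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample factors, emotions and contamination flags for one channel."""
    prev = config.prevalence_vector(channel)
    no_emo = rng.random(n) < config.no_emotion_fraction
    is_ad = rng.random(n) < config.ad_fraction

    factors = rng.random((n, len(FACTOR_GROUPS))) < prev
    emotions = rng.random((n, len(EMOTION_GROUPS))) < _emotion_prob_matrix(
        config, factors
    )
    emotions[no_emo] = False  # deliberate no-emotion contaminants

    # rejection-resample (factors AND emotions jointly) until every
    # non-contaminant post carries at least one emotion group
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = ~no_emo & ~emotions.any(axis=1)
        if not bad.any():
            break
        k = int(bad.sum())
        f_new = rng.random((k, len(FACTOR_GROUPS))) < prev
        factors[bad] = f_new
        emotions[bad] = rng.random((k, len(EMOTION_GROUPS))) < _emotion_prob_matrix(
            config, f_new
        )
    else:
        raise GenerationError(
            f"channel {channel}: could not draw an emotion-bearing post in "
            f"{_MAX_RESAMPLE_ROUNDS} rounds; emotion baselines too small"
        )
    return factors, emotions, no_emo, is_ad


def _render(
    post_id: str,
    channel: str,
    planted: list[str],
    is_ad: bool,
    lexicon: Lexicon,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Pick one surface term per planted item, interleave filler tokens."""
    pieces: list[str] = []
    kw_terms = lexicon.terms_for("cancer_keyword")
    if kw_terms:
        pieces.append(kw_terms[int(rng.integers(len(kw_terms)))])
    for item in planted:
        terms = lexicon.terms_for(item)
        if not terms:
            raise GenerationError(f"lexicon has no term for planted item {item!r}")
        pieces.append(terms[int(rng.integers(len(terms)))])
    if is_ad:
        ad_terms = lexicon.terms_for("ad_keyword")
        if not ad_terms:
            raise GenerationError("ad contamination requested but no ad terms")
        pieces.append(ad_terms[int(rng.integers(len(ad_terms)))])
    rng.shuffle(pieces)

    lo, hi = config.fillers_per_post
    if channel == "twitter":
        lo, hi = 0, min(hi, 2)
    n_fill = int(rng.integers(lo, hi + 1)) if config.filler_vocab else 0
    fillers = [
        config.filler_vocab[int(rng.integers(len(config.filler_vocab)))]
        for _ in range(n_fill)
    ]
    for filler in fillers:
        pieces.insert(int(rng.integers(len(pieces) + 1)), filler)

    tokens: list[str] = []
    for piece in pieces:
        tokens.extend(piece.split())

    if channel == "twitter":
        # trim fillers (never planted terms) to honour the 140-char limit
        while len(" ".join(tokens)) > TWITTER_CHAR_LIMIT and any(
            t in config.filler_vocab for t in tokens
        ):
            for i, t in enumerate(tokens):
                if t in config.filler_vocab:
                    del tokens[i]
                    break
        if len(" ".join(tokens)) > TWITTER_CHAR_LIMIT:
            # fall back to each planted item's shortest synonym
            shortest = [
                min(lexicon.terms_for(item), key=len) for item in planted
            ]
            if kw_terms:
                shortest.append(min(kw_terms, key=len))
            if is_ad:
                shortest.append(min(lexicon.terms_for("ad_keyword"), key=len))
            rng.shuffle(shortest)
            tokens = [tok for piece in shortest for tok in piece.split()]
            if len(" ".join(tokens)) > TWITTER_CHAR_LIMIT:
                raise GenerationError(
                    f"post {post_id}: planted terms alone exceed "
                    f"{TWITTER_CHAR_LIMIT} characters"
                )
    return tuple(tokens)


def generate_corpus(config: GeneratorConfig, lexicon: Lexicon) -> list[Post]:
    """Draw the full corpus; fully reproducible from ``config.seed``.

    Channels consume independent child streams of the root seed (spawned in
    the fixed channel order), so regenerating a single channel reproduces
    its posts exactly.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(CHANNELS))
    posts: list[Post] = []
    for channel, child in zip(CHANNELS, children):
        n = config.n_posts_per_channel.get(channel, 0)
        if n == 0:
            continue
        rng = np.random.default_rng(child)
        factors, emotions, no_emo, is_ad = _sample_channel(config, channel, n, rng)
        f_idx = [np.flatnonzero(row) for row in factors]
        e_idx = [np.flatnonzero(row) for row in emotions]
        for i in range(n):
            planted = [FACTOR_GROUPS[j] for j in f_idx[i]] + [
                EMOTION_GROUPS[j] for j in e_idx[i]
            ]
            pid = f"{channel}-{i:06d}"
            tokens = _render(
                pid, channel, planted, bool(is_ad[i]), lexicon, config, rng
            )
            contaminant = (
                "no_emotion" if no_emo[i] else ("ad" if is_ad[i] else None)
            )
            posts.append(
                Post(
                    id=pid,
                    channel=channel,
                    tokens=tokens,
                    truth=frozenset(planted),
                    contaminant=contaminant,
                )
            )
    return posts


_MAX_ACTIVE_FACTORS = 20


def expected_lift(
    config: GeneratorConfig,
    antecedent: frozenset[str] | set[str],
    consequent: str,
) -> float:
    """Exact lift of ``antecedent => consequent`` under the generative model.

    Computed by enumerating all configurations of the *active* factors
    (those with any odds multiplier != 1, plus the antecedent), summing
    P(F)·p_e(F) and the keep-probability 1 − prod_g(1 − p_g(F)) that the
    zero-emotion resampling induces, and mixing channels by their post
    counts. Factors with all multipliers equal to 1 neither shift any
    emotion probability nor the keep probability, so they integrate out.

    Returns P(e | antecedent, kept) / P(e | kept) — the population value of
    the lift the mining stage measures on the filtered corpus.
    """
    catalog = default_catalog()
    if consequent not in catalog.emotion_groups:
        raise ValueError(f"consequent {consequent!r} is not an emotion group")
    antecedent = frozenset(antecedent)
    for f in antecedent:
        if f not in catalog.factor_groups:
            raise ValueError(f"antecedent item {f!r} is not a factor group")

    active = set(antecedent)
    for model in config.emotion_model.values():
        active.update(f for f, m in model.effects.items() if m != 1.0)
    active_list = sorted(active)
    if len(active_list) > _MAX_ACTIVE_FACTORS:
        raise ValueError(
            f"{len(active_list)} active factors exceed the exact-enumeration "
            f"guard of {_MAX_ACTIVE_FACTORS}"
        )

    channels = [
        (ch, n) for ch, n in config.n_posts_per_channel.items() if n > 0
    ]
    total = sum(n for _, n in channels)
    if total == 0:
        raise ValueError("no posts configured")

    models = [config.emotion_model.get(e) for e in EMOTION_GROUPS]
    num_a = den_a = num = den = 0.0
    for ch, n_ch in channels:
        w = n_ch / total
        prev = {
            f: (
                config.factor_prevalence.get(f, 0.0).get(ch, 0.0)
                if isinstance(config.factor_prevalence.get(f, 0.0), dict)
                else config.factor_prevalence.get(f, 0.0)
            )
            for f in active_list
        }
        for bits in product((0, 1), repeat=len(active_list)):
            present = {f for f, b in zip(active_list, bits) if b}
            p_config = 1.0
            for f, b in zip(active_list, bits):
                p_config *= prev[f] if b else 1.0 - prev[f]
            if p_config == 0.0:
                continue
            p_g = []
            for model in models:
                if model is None:
                    p_g.append(0.0)
                    continue
                logit = _logit(model.baseline)
                blocked = False
                for f, m in model.effects.items():
                    if f in present:
                        if m == 0.0:
                            blocked = True
                            break
                        logit += math.log(m)
                p_g.append(0.0 if blocked else 1.0 / (1.0 + math.exp(-logit)))
            keep = 1.0 - math.prod(1.0 - p for p in p_g)
            p_e = p_g[EMOTION_GROUPS.index(consequent)]
            num += w * p_config * p_e
            den += w * p_config * keep
            if antecedent <= present:
                num_a += w * p_config * p_e
                den_a += w * p_config * keep
    if den_a == 0.0 or num == 0.0:
        raise ValueError("antecedent or consequent has zero probability")
    return (num_a / den_a) / (num / den)


def default_config(n_total: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """Corpus-generating conditions emulating the study's marginals.

    Channel shares follow the reported 40.1/39.2/19.0/1.6% split; factor
    prevalences approximate the per-item mention shares of the 321,339
    analyzed posts (leukemia is channel-heterogeneous — strongly
    over-represented on Twitter); the advertising contamination of 26%
    matches the reported exclusion rate of ad posts among emotion-bearing
    posts. Emotion baselines were solved once by fixed-point iteration on
    the model's exact conditioned marginal (the same enumeration
    :func:`expected_lift` uses) so that, with the planted effects and the
    zero-emotion resampling, the population emotion marginals equal the
    reported 46.5/45.2/39.4/8.0%.
    """
    shares = {"blog": 0.401, "cafe": 0.392, "twitter": 0.190, "board": 0.016}
    n_per = {ch: int(round(n_total * s)) for ch, s in shares.items()}
    n_per["blog"] += n_total - sum(n_per.values())

    prevalence: dict[str, float | dict[str, float]] = {
        "male": 0.170,
        "female": 0.209,
        "age_under_10": 0.027,
        "age_10s": 0.020,
        "age_20s": 0.015,
        "age_30s": 0.016,
        "age_40s": 0.017,
        "age_50s": 0.018,
        "age_60s": 0.003,
        "age_70s": 0.002,
        "age_over_80": 0.002,
        "breast_cancer": 0.084,
        "colon_cancer": 0.076,
        "gastric_cancer": 0.067,
        "leukemia": {"blog": 0.042, "cafe": 0.048, "twitter": 0.160, "board": 0.030},
        "lung_cancer": 0.061,
        "cervical_cancer": 0.058,
        "liver_cancer": 0.049,
        "brain_cancer": 0.044,
        "pancreatic_cancer": 0.033,
        "ovarian_cancer": 0.031,
        "prostatic_cancer": 0.023,
        "gallbladder_cancer": 0.012,
        "kidney_cancer": 0.008,
        "thyroid_cancer": 0.002,
        "early_stage": 0.060,
        "middle_stage": 0.020,
        "terminal_stage": 0.015,
        "surgery": 0.211,
        "chemotherapy": 0.150,
        "radiation_therapy": 0.065,
        "immunotherapy": 0.060,
        "cam": 0.046,
        "transplantation": 0.010,
        "acute_survival": 0.458,
        "extended_survival": 0.093,
        "permanent_survival": 0.050,
        "fatigue_pain_fever": 0.216,
        "gastrointestinal_problems": 0.098,
        "hair_loss_skin_problems": 0.081,
        "poor_circulation": 0.010,
        "thrombocytopenia": 0.008,
        "infection": 0.020,
    }

    emotion_model = {
        "HG": EmotionModel(
            baseline=0.168622,
            effects={
                "radiation_therapy": 3.0,
                "chemotherapy": 2.2,
                "breast_cancer": 2.2,
                "surgery": 1.8,
                "acute_survival": 1.8,
                "liver_cancer": 1.8,
            },
        ),
        "FAO": EmotionModel(
            baseline=0.190798,
            effects={
                "early_stage": 2.8,
                "gastrointestinal_problems": 2.2,
                "pancreatic_cancer": 2.2,
                "fatigue_pain_fever": 1.8,
                "brain_cancer": 1.8,
                "acute_survival": 1.5,
            },
        ),
        "SDLG": EmotionModel(
            baseline=0.187957,
            effects={
                "hair_loss_skin_problems": 2.8,
                "surgery": 1.8,
                "fatigue_pain_fever": 1.8,
            },
        ),
        "AD": EmotionModel(
            baseline=0.039275,
            effects={
                "hair_loss_skin_problems": 2.0,
                "acute_survival": 1.5,
            },
        ),
    }

    return GeneratorConfig(
        n_posts_per_channel=n_per,
        factor_prevalence=prevalence,
        emotion_model=emotion_model,
        ad_fraction=0.26,
        no_emotion_fraction=0.0,
        seed=seed,
    )


def write_corpus(posts: list[Post], path: str | Path) -> None:
    """JSONL: one ``{"id", "channel", "text"}`` object per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {"id": p.id, "channel": p.channel, "text": p.text},
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_truth(posts: list[Post], path: str | Path) -> None:
    """Sibling JSONL of planted ground truth; never read by the pipeline."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "truth": sorted(p.truth or ()),
                        "contaminant": p.contaminant,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus(path: str | Path) -> list[Post]:
    posts = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            posts.append(
                Post(
                    id=str(obj["id"]),
                    channel=obj["channel"],
                    tokens=tuple(obj["text"].split()),
                )
            )
    return posts
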