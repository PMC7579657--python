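"""Generator reproducibility, contamination bookkeeping and the
closed-form lift oracle."""

import math
from itertools import product

import numpy as np
import pytest

from emomine.lexicon import EMOTION_GROUPS
from emomine.synthetic import (
    TWITTER_CHAR_LIMIT,
    EmotionModel,
    GenerationError,
    GeneratorConfig,
    default_config,
    expected_lift,
    generate_corpus,
    read_corpus,
    write_corpus,
)


def null_config(n=100, seed=7, baseline=0.5, channel="blog", **kw):
    """All effects absent: emotions independent of factors."""
    return GeneratorConfig(
        n_posts_per_channel={channel: n},
        factor_prevalence={"surgery": 0.3, "breast_cancer": 0.2},
        emotion_model={e: EmotionModel(baseline=baseline) for e in EMOTION_GROUPS},
        seed=seed,
        **kw,
    )


class TestGenerateCorpus:
    def test_deterministic_from_seed(self, lexicon):
        cfg = default_config(n_total=300, seed=11)
        a = generate_corpus(cfg, lexicon)
        b = generate_corpus(cfg, lexicon)
        assert a == b

    def test_different_seed_differs(self, lexicon):
        a = generate_corpus(default_config(n_total=300, seed=1), lexicon)
        b = generate_corpus(default_config(n_total=300, seed=2), lexicon)
        assert a != b

    def test_zero_posts_is_empty_corpus(self, lexicon):
        cfg = null_config(n=0)
        assert generate_corpus(cfg, lexicon) == []

    def test_null_model_emotion_rates(self, lexicon):
        # independent emotions at beta=0.5, conditioned on >=1 of the four:
        # P(e | kept) = 0.5 / (1 - 0.5**4) = 8/15
        cfg = null_config(n=4000, seed=7)
        posts = generate_corpus(cfg, lexicon)
        expected = 0.5 / (1 - 0.5**4)
        for e in EMOTION_GROUPS:
            rate = np.mean([e in p.truth for p in posts])
            assert rate == pytest.approx(expected, abs=0.03)

    def test_every_post_has_an_emotion_unless_contaminated(self, lexicon):
        posts = generate_corpus(null_config(n=500, seed=3), lexicon)
        assert all(p.truth & set(EMOTION_GROUPS) for p in posts)

    def test_ad_contamination_count(self, lexicon):
        cfg = null_config(n=1000, seed=5, ad_fraction=0.1)
        posts = generate_corpus(cfg, lexicon)
        ad_terms = set(lexicon.terms_for("ad_keyword"))
        n_ad = sum(
            any(t in " ".join(p.tokens) for t in ad_terms) for p in posts
        )
        assert n_ad == sum(p.contaminant == "ad" for p in posts)
        # ~100 expected; 4-sigma binomial band
        assert 60 <= n_ad <= 140

    def test_no_emotion_contaminants_have_no_emotion(self, lexicon):
        cfg = null_config(n=1000, seed=9, no_emotion_fraction=0.2)
        posts = generate_corpus(cfg, lexicon)
        flagged = [p for p in posts if p.contaminant == "no_emotion"]
        assert 140 <= len(flagged) <= 260
        assert all(not (p.truth & set(EMOTION_GROUPS)) for p in flagged)

    def test_twitter_posts_fit_140_chars(self, lexicon):
        cfg = default_config(n_total=2000, seed=13)
        posts = generate_corpus(cfg, lexicon)
        tweets = [p for p in posts if p.channel == "twitter"]
        assert tweets
        assert all(len(p.text) <= TWITTER_CHAR_LIMIT for p in tweets)

    def test_unsatisfiable_twitter_limit_names_post(self, tmp_path):
        from emomine.lexicon import load_lexicon

        long_term = "x" * 200
        path = tmp_path / "lex.tsv"
        path.write_text(
            "term\tconcept\titem\n"
            f"{long_term}\tsurgery\tsurgery\n"
            "hope\thope\tHG\n"
            "cancer\tcancer\tcancer_keyword\n",
            encoding="utf-8",
        )
        lex, _ = load_lexicon(path)
        cfg = GeneratorConfig(
            n_posts_per_channel={"twitter": 50},
            factor_prevalence={"surgery": 1.0},
            emotion_model={"HG": EmotionModel(baseline=0.9)},
            seed=0,
        )
        with pytest.raises(GenerationError, match="twitter-"):
            generate_corpus(cfg, lex)

    def test_corpus_roundtrip_jsonl(self, lexicon, tmp_path):
        posts = generate_corpus(null_config(n=50, seed=2), lexicon)
        path = tmp_path / "corpus.jsonl"
        write_corpus(posts, path)
        loaded = read_corpus(path)
        assert [(p.id, p.channel, p.tokens) for p in loaded] == [
            (p.id, p.channel, p.tokens) for p in posts
        ]


class TestConfigValidation:
    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            GeneratorConfig(
                n_posts_per_channel={"blog": 1},
                factor_prevalence={"nonexistent": 0.5},
                emotion_model={"HG": EmotionModel(baseline=0.5)},
            )

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            GeneratorConfig(
                n_posts_per_channel={"blog": 1},
                factor_prevalence={"surgery": 1.5},
                emotion_model={"HG": EmotionModel(baseline=0.5)},
            )
        with pytest.raises(ValueError):
            EmotionModel(baseline=0.5, effects={"surgery": -1.0})

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            GeneratorConfig(
                n_posts_per_channel={"myspace": 10},
                factor_prevalence={},
                emotion_model={"HG": EmotionModel(baseline=0.5)},
            )


class TestExpectedLift:
    def test_independence_gives_unit_lift(self):
        cfg = null_config()
        for e in EMOTION_GROUPS:
            assert expected_lift(cfg, {"surgery"}, e) == pytest.approx(1.0)

    def test_empty_antecedent_gives_unit_lift(self):
        cfg = default_config()
        assert expected_lift(cfg, set(), "HG") == pytest.approx(1.0)

    def test_single_factor_matches_hand_enumeration(self):
        # one planted factor (prevalence 0.5, odds x4 on HG), second group
        # independent so that conditioning on >=1 emotion is nontrivial
        cfg = GeneratorConfig(
            n_posts_per_channel={"blog": 1},
            factor_prevalence={"surgery": 0.5},
            emotion_model={
                "HG": EmotionModel(baseline=0.2, effects={"surgery": 4.0}),
                "FAO": EmotionModel(baseline=0.3),
            },
        )
        # independent enumeration over the two factor configurations
        def p_hg(present):
            odds = 0.2 / 0.8 * (4.0 if present else 1.0)
            return odds / (1 + odds)

        num_a = den_a = num = den = 0.0
        for present, p_f in ((False, 0.5), (True, 0.5)):
            keep = 1 - (1 - p_hg(present)) * (1 - 0.3)
            num += p_f * p_hg(present)
            den += p_f * keep
            if present:
                num_a += p_f * p_hg(present)
                den_a += p_f * keep
        oracle = (num_a / den_a) / (num / den)
        assert expected_lift(cfg, {"surgery"}, "HG") == pytest.approx(
            oracle, abs=1e-12
        )
        assert oracle > 1.0

    def test_channel_mixture_weights_by_post_counts(self):
        # prevalence differs by channel; hand-mix two single-channel values
        def cfg_for(channels):
            return GeneratorConfig(
                n_posts_per_channel=channels,
                factor_prevalence={"leukemia": {"blog": 0.05, "twitter": 0.4}},
                emotion_model={
                    "SDLG": EmotionModel(baseline=0.2, effects={"leukemia": 3.0}),
                    "HG": EmotionModel(baseline=0.4),
                },
            )

        mixed = expected_lift(cfg_for({"blog": 300, "twitter": 100}), {"leukemia"}, "SDLG")
        blog_only = expected_lift(cfg_for({"blog": 1}), {"leukemia"}, "SDLG")
        twitter_only = expected_lift(cfg_for({"twitter": 1}), {"leukemia"}, "SDLG")
        assert min(blog_only, twitter_only) < mixed < max(blog_only, twitter_only)

    def test_enumeration_guard(self):
        effects = {f: 2.0 for f in (
            "male", "female", "age_under_10", "age_10s", "age_20s", "age_30s",
            "age_40s", "age_50s", "age_60s", "age_70s", "age_over_80",
            "breast_cancer", "colon_cancer", "gastric_cancer", "leukemia",
            "lung_cancer", "cervical_cancer", "liver_cancer", "brain_cancer",
            "pancreatic_cancer", "ovarian_cancer",
        )}
        cfg = GeneratorConfig(
            n_posts_per_channel={"blog": 1},
            factor_prevalence={f: 0.1 for f in effects},
            emotion_model={"HG": EmotionModel(baseline=0.3, effects=effects)},
        )
        with pytest.raises(ValueError, match="active factors"):
            expected_lift(cfg, set(), "HG")

    def test_empirical_lift_approaches_oracle(self, lexicon):
        # strong planted effect should show up in the planted truth itself
        cfg = GeneratorConfig(
            n_posts_per_channel={"blog": 8000},
            factor_prevalence={"radiation_therapy": 0.2},
            emotion_model={
                "HG": EmotionModel(baseline=0.2, effects={"radiation_therapy": 8.0}),
                "FAO": EmotionModel(baseline=0.3),
            },
            seed=21,
        )
        posts = generate_corpus(cfg, lexicon)
        has_f = np.array([("radiation_therapy" in p.truth) for p in posts])
        has_e = np.array([("HG" in p.truth) for p in posts])
        lift = (has_e[has_f].mean()) / has_e.mean()
        oracle = expected_lift(cfg, {"radiation_therapy"}, "HG")
        assert oracle > 1.3
        assert lift == pytest.approx(oracle, rel=0.05)
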