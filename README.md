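# emomine

Tools for studying the public's emotions about cancer in social-media
posts. The pipeline codes each post into four multi-label **emotion
groups** — hope/gratitude (HG), fear/anxiety/overwhelmed (FAO),
sadness/depression/loneliness/guilt (SDLG), anger/denial (AD) — and 43
**emotion-related factor groups** (gender, age band, cancer type, cancer
stage, treatment, survivorship stage, symptom cluster), then asks which
factors travel with which emotions using association-rule mining and
co-occurrence network analysis.

It is written for infodemiology researchers who want a tested, rerunnable
version of this analysis. The original corpus (hundreds of thousands of
Korean posts from blogs, online cafés, Twitter and message boards) is not
public, so the package ships a synthetic corpus generator with a known
generative model: every pipeline stage can be validated against planted
ground truth and a closed-form oracle.

## The method

1. **Lexicon coding.** A term → item lexicon (a stand-in for an
   unpublished cancer ontology) maps surface tokens, including multi-token
   phrases and Korean synonyms, onto the 47 analysis items or onto role
   markers (cancer keywords, stop keywords, advertising keywords).
   Mentions are post-level 0/1: repeats count once, distinct groups all
   count.
2. **Selection funnel.** Keep a post iff it is on the cancer topic, has at
   least one emotion term, no stop keyword and no advertising keyword;
   the funnel report satisfies
   `n_selected = n_with_emotion − n_ad_excluded`.
3. **Association rules.** Apriori frequent-itemset mining over the post ×
   item matrix, then rules `F ⇒ e` with factor-only antecedents and a
   single emotion-group consequent:

   - support `s(F ⇒ e) = P(F ∪ {e})`
   - confidence `c = s(F ⇒ e) / P(F)`
   - lift `ℓ = c / P(e)` (>1 positive association, ≈1 independence)

   The top-5 rules per emotion group by lift are the headline table.
4. **Co-occurrence networks.** Posts are stratified by length (longform =
   blogs + cafés + boards vs. twitter); nodes are items with frequency and
   degree, edge weights count posts mentioning both endpoints.
5. **Synthetic corpus.** Factors are independent Bernoulli per post;
   emotion `e` is Bernoulli with
   `p_e(F) = σ(logit β_e + Σ_{f∈F} log effect_e[f])`, zero-emotion posts
   are resampled, and contaminant (ad / no-emotion) posts can be injected.
   `expected_lift` evaluates the implied population lift exactly, which is
   what makes the mining stage testable.

## Worked example

```python
import emomine as em
import emomine.frequency as fr, emomine.rules as ru, emomine.network as net

lex, _ = em.load_lexicon(em.bundled_lexicon_path())
cfg = em.default_config(n_total=20_000, seed=1)   # study-like conditions
posts = em.generate_corpus(cfg, lex)
kept, report = em.filter_posts(posts, lex)
print(report)
_, ts = em.code_posts(kept, lex)
print(fr.emotion_frequencies(ts).to_string(index=False))
```

```
FilterReport(n_input=20000, n_with_emotion=20000, n_ad_excluded=5131, n_selected=14869)
emotion_group  count  percent
           HG   6926     46.6
          FAO   6648     44.7
         SDLG   5903     39.7
           AD   1194      8.0
```

26% of the emotion-bearing posts carried an advertising keyword and were
excluded; the coded emotion marginals land on the generator's calibrated
targets (46.5/45.2/39.4/8.0%). Mining the rules and checking one planted
effect against the closed-form oracle:

```python
frequent = ru.apriori(ts, min_support=0.01)
rules = ru.generate_rules(frequent, min_confidence=0.1)
print(ru.rules_to_frame(ru.top_rules_by_lift(rules, k=5)).head(5).to_string(index=False))
print("expected lift:", round(em.expected_lift(cfg, {"radiation_therapy"}, "HG"), 3))
```

```
                         antecedent consequent  support  confidence  lift
         breast_cancer|chemotherapy         HG    0.012       0.765 1.643
          radiation_therapy|surgery         HG    0.014       0.730 1.567
   acute_survival|radiation_therapy         HG    0.028       0.728 1.563
acute_survival|chemotherapy|surgery         HG    0.014       0.720 1.546
              breast_cancer|surgery         HG    0.014       0.685 1.472
expected lift: 1.493
```

The highest-lift hope/gratitude rules are built from the treatments and
cancer types the generator links to HG, and the mined single-factor lift
for radiation therapy sits at its analytic expectation. The same
transaction matrix feeds the networks:

```python
longform = net.build_network(ts, "longform")
print(net.top_nodes(longform, 0.5).head(5).to_string(index=False))
```

```
              item  frequency  percent  degree
    acute_survival       5972     49.5      46
                HG       5610     46.5      46
               FAO       5425     45.0      46
              SDLG       4755     39.5      46
fatigue_pain_fever       3000     24.9      46
```

A `emomine` console script exposes the stages (`generate`, `code`,
`frequencies`, `rules`, `network`, `all`); `emomine all config.yaml
--seed 2` runs everything from a YAML config and writes CSV/GraphML
artifacts plus a JSON manifest.

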