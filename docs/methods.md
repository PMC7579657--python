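# Methods

## Analysis items and lexicon

The unit of analysis is the post. Each post is reduced to 47 binary
indicators: 4 emotion groups and 43 factor groups partitioned as gender
(2), age bands (9), cancer types (14), cancer stage (3), treatments (6),
survivorship stages after Mullan's model (3) and symptom clusters (6).
Nine ontology emotion classes fold many-to-one onto the groups: {hope,
gratitude} → HG, {anxiety, overwhelmed} → FAO, {depression, loneliness,
guilt} → SDLG, {anger, denial} → AD. This catalog is fixed; the lexicon
that maps surface terms onto it is an input.

The shipped lexicon (`data/synthetic_lexicon.tsv`) is a small bilingual
stand-in: the ontology it emulates (4,061 synonyms) is not publicly
distributable. Every analysis item has at least one term, plus generic
cancer keywords and stop/advertising keywords for the funnel. Any TSV
with `term / concept / item` columns can replace it; all correctness
properties are lexicon-parametric.

Matching is token-based: tokens are case-folded and
whitespace-collapsed, and every lexicon term occurring as a contiguous
token window matches. Multi-token phrases do not suppress shorter entries
inside them (set union), repeats add nothing (count-once), and no
stemming or morphological analysis is attempted — the synthetic corpus
controls its own tokens, so morphology is out of scope. Whether the
original platform search was substring- or token-based is not documented;
token matching was chosen as the cleaner semantics for a generated
corpus.

## Selection funnel

Order of exclusions: topic requirement and stop-keyword removal first,
then the emotion requirement, then advertising exclusion. This makes the
reported counts obey `n_selected = n_with_emotion − n_ad_excluded`, the
identity the published funnel (1,854,497 → 434,299 → −112,960 → 321,339)
satisfies. Stop keywords remove the whole post, not just the match; the
source description is ambiguous here and post-level removal is the
stricter reading. Demographic items (gender, age) are coded from term
mentions exactly like any other factor — no author attributes are
inferred.

## Generative model of the synthetic corpus

For each post: channel fixed by block, factor set `F` drawn as
independent Bernoulli(π_f) (optionally per channel), and each emotion
group `e` drawn Bernoulli with

    p_e(F) = σ( logit β_e + Σ_{f∈F} log m_{e,f} )

with baseline `β_e ∈ (0,1)` and odds multipliers `m_{e,f} ≥ 0`. A
logistic link is the smallest model that makes lift a free, analytically
tractable parameter. Posts with zero emotion groups are resampled
(factors and emotions jointly), because the analyzed corpus contains only
emotion-bearing posts; a `no_emotion_fraction` knob reinstates them to
exercise the filter, and an `ad_fraction` knob appends advertising terms
to otherwise ordinary posts. Planted items are rendered as randomly
chosen lexicon synonyms interleaved with neutral filler tokens; Twitter
posts are kept within 140 characters by trimming fillers, then by falling
back to each item's shortest synonym, and only error if genuinely
unsatisfiable. One root seed drives per-channel child streams
(`numpy` `SeedSequence.spawn` in fixed channel order), so a single
channel regenerates identically.

`expected_lift` computes the population lift of any rule exactly by
enumerating configurations of the *active* factors (those with any
multiplier ≠ 1, plus the antecedent; factors with all multipliers 1
integrate out), including the conditioning that zero-emotion resampling
induces: P(F | kept) ∝ P(F)·(1 − Π_g (1 − p_g(F))). Ignoring this
conditioning would bias the oracle away from what mining measures on the
filtered corpus. Enumeration refuses more than 20 active factors
(exponential guard). With all multipliers 1 the conditioning cancels and
every lift is exactly 1.

### Default conditions

The defaults describe a 20,000-post corpus shaped like the study corpus:

- channel shares 40.1 / 39.2 / 19.0 / 1.6% (blogs / cafés / Twitter /
  boards);
- factor prevalences set to the per-item mention shares of the 321,339
  analyzed posts (e.g. female 0.209, acute survivorship 0.458, surgery
  0.211, fatigue/pain/fever 0.216); leukemia is channel-heterogeneous
  (0.16 on Twitter vs ≈0.04–0.05 elsewhere), reproducing its reported
  Twitter skew;
- advertising contamination 0.26, the reported share of ad posts among
  emotion-bearing posts; no-emotion contamination 0 by default;
- planted odds multipliers linking treatments/acute survivorship/breast
  and liver cancer to HG, early stage/GI problems/pancreatic and brain
  cancer/fatigue to FAO, hair-skin problems/surgery/fatigue to SDLG and
  hair-skin problems/acute survivorship to AD — the direction and rough
  strength of the associations the study reports, at moderate sizes
  (1.5–3);
- emotion baselines β = (0.1686, 0.1908, 0.1880, 0.0393), solved once by
  fixed-point iteration on the model's exact conditioned marginal so that
  the population emotion marginals equal the reported 46.5 / 45.2 / 39.4
  / 8.0% under the default effects and prevalences.

What the generator does **not** emulate: real (Korean) text and
morphology, temporal dynamics, author/user structure and cross-posting,
correlated factors (comorbidity, gender × cancer-type dependence), and
channel-specific emotion expression. Passing tests therefore demonstrate
that the pipeline measures the model it is pointed at, not that the
published corpus-specific rule tables would reproduce.

## Mining and networks

Apriori is level-wise with downward-closure pruning; candidate
(k)-itemsets join (k−1)-sets sharing a (k−2)-prefix and are discarded if
any (k−1)-subset is infrequent. `min_support` must be positive (a zero
threshold would enumerate 2^47 sets). Output order is deterministic
(size, then lexicographic), as is every ranking in the package, so runs
diff cleanly. Rule antecedents are restricted to factor items and
consequents to single emotion groups, matching the published rule space;
mixed-gender antecedents like {male, female} are permitted — they follow
from post-level set semantics (a post mentioning both). Default
thresholds `min_support = 0.01`, `min_confidence = 0.1` are the smallest
consistent with the published rules (all reported supports ≥ 0.010, the
lowest reported confidence 0.107); both are configurable. Metrics are
kept at full precision and rounded to 3 decimals only on export. Top-k
selection per group breaks lift ties by higher support, then
lexicographic antecedent. Mining runs on the full corpus (the published
rule table is unstratified).

Networks are built per length stratum (longform vs Twitter). Edge weight
counts posts containing both endpoints — post-level count-once semantics
carried through — so Σ weights = Σ_p C(m_p, 2) exactly, a conservation
law the tests assert. "Top 50% of nodes" means ⌈0.5 × 47⌉ = 24 nodes
ranked by frequency (tie-break degree, then identifier); node
percentages use the stratum's post count as denominator, which is why
multi-label shares can exceed 50%.

## Numerical choices and degenerate inputs

- Percentages round half-up to one decimal (`decimal.Decimal`), matching
  the convention of the published tables; banker's rounding would differ
  on exact .x5 boundaries.
- Empty corpus: filtering returns a zero report; Apriori on empty
  transactions returns no itemsets; emotion percentages on zero posts
  are an error (undefined denominator).
- A consequent with zero marginal support would make lift undefined; the
  rule is skipped and logged (unreachable when the consequent is part of
  a frequent itemset, kept as a guard).
- A post reaching the coding stage without an emotion item is an
  internal-consistency error, not silently coded — it means the filter
  contract was violated.
- Lexicon validation fails loudly: missing columns, a term mapped to two
  different items (offenders listed), unknown items, blank terms.

## Problem sizes

Unit and property tests run on corpora of ≤ 4,000 posts. Parameter
recovery uses 20,000 posts with 200 bootstrap resamples (mined lift of
each planted single-factor rule within 3 bootstrap SEs of
`expected_lift`); null calibration uses 50,000 posts and requires ≥ 95%
of single-factor lifts within ±0.1 of 1. Oracle equivalence checks
Apriori against brute-force subset enumeration on ~150 randomized corpora
of up to 15 items. These sizes give stable statistics while keeping the
full suite around a quarter of a minute on one CPU.

## Known limitations

- The stand-in lexicon is tiny; real-corpus recall/precision of the
  dictionary matcher is untested and out of scope.
- Factors are generated independently, so mined multi-factor antecedents
  on synthetic data reflect the logistic model's induced correlations
  only, not realistic co-mention structure.
- No statistical significance testing of rules or of channel differences
  is provided (none is part of the method being implemented).
- Network analysis stops at frequency/degree/edge weight; no layout or
  further centrality measures.
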