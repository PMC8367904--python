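# Methods

This note documents the statistical machinery behind `stylesalience`: the
feature schema, the classifier and its training procedure, the validation
designs, the longitudinal analysis, the synthetic-data generator used for
testing, and the numerical conventions. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## 1. Problem and assumptions

Given posts from two *intersecting* social groups (a person can belong to
both — e.g. parent and feminist), the package trains a binary classifier
that maps a document's linguistic style to the probability that one of the
two identities was salient while writing. The key assumptions:

* **Style, not topic.** Salience expresses itself in *how* a text is
  written (function words, pronoun choices, tense, punctuation, sentence
  length), which travels across topics and audiences; topical vocabulary
  does not, and is excluded.
* **Relative measure.** The classifier places texts on a continuum between
  the two trained identities. The midpoint is ambiguous (both or neither
  salient), scores are meaningless when a third identity dominates the
  data, and a falling probability for identity A cannot be distinguished
  from a rising salience of identity B. Downstream analyses should use
  changes over time and group differences, never absolute values per
  person.
* **Forum as proxy.** Training labels are forum memberships, a noisy proxy
  for salience. The validation ladder (below) is what licenses the
  salience interpretation.

## 2. The 44-feature style schema

The canonical vector has 44 named features, fixed in order
(`stylesalience.schema.FEATURE_NAMES`):

* **structural (2):** `wps` = words / sentences; `sixltr` = % words with
  ≥ 6 letters (apostrophes not counted as letters);
* **word categories (31), % of words:** `funct`, the personal-pronoun
  subclasses `i, we, you, shehe, they`, `ipron`, `article`, `preps`,
  `auxverb`, `adverb`, `conj`, `verb`, `past`, `present`, `future`,
  `quant`, `number`, `time`, `posemo`, `negemo`, `swear`, `negation`,
  `assent`, `insight`, `cause`, `discrep`, `tentat`, `incl`, `excl`,
  `nonflu`;
* **punctuation classes (11), % of words:** `period`, `comma`, `colon`,
  `semic`, `qmark`, `exclam`, `dash`, `quote`, `apostro`, `parenth`,
  `otherp` (these may exceed 100 on punctuation-heavy text).

The count of 44 and the membership of the list are a reconstruction:
closed-vocabulary tools in this tradition publish partial inventories, so
the schema here was assembled from the standard grammatical and
psychological style categories plus the punctuation classes, resolving
hierarchical redundancy by keeping the higher-order category (`negemo`)
and dropping its sparse subcategories (anxiety/anger/sadness), which are
too low-frequency in short posts to estimate reliably. External feature
tables computed with other tools are accepted through
`features.validate_schema` with a configurable alias map, so users are not
tied to the packaged dictionary.

**Tokenisation.** Words are maximal alphabetic runs, lowercased, with
internal apostrophes kept (`don't` is one word *and* increments
`apostro`). Sentences are runs of `. ! ? …`, minimum one for word-bearing
text. Single quotes are always tallied as apostrophes (the two are not
reliably distinguishable); characters in other Unicode punctuation
categories land in `otherp`; symbols and emoji are ignored (an emoji-only
post has zero words and is removed by cleaning).

**Dictionary.** The packaged dictionary (`stylesalience.lexicon`) is an
open, compact word list per category — lowercase literals plus trailing
`*` prefix wildcards — adequate for the synthetic corpora and for
demonstration. It is deliberately not a substitute for a professionally
curated dictionary on real data; a converter for the common `.dic` layout
is provided for users who own one. Topical categories are rejected at
construction unless explicitly overridden.

## 3. Corpus handling

* Cleaning removes posts whose **entire trimmed text** matches an
  administrative pattern (e.g. platform-withdrawal notices), posts by
  bot-matching user ids, and wordless posts. Matching the whole text
  (rather than substrings) keeps genuine posts that quote an admin notice.
  Cleaning is idempotent.
* Quoted text inside replies is not stripped: the full post text is
  analysed as-is. (Forum quoting conventions are too heterogeneous to
  parse reliably; users who need this should pre-process.)
* The word-count cutoff analysis retrains the ensemble at each candidate
  minimum length and tabulates in-subset ("training") and out-of-bag
  ("test") AUC against retention. The default recommendation removes the
  lower quartile of the word-count distribution — keeping the most
  informative 75% of posts — with Q1 computed by the median-unbiased
  (Hyndman–Fan type 8) convention and rounded up when fractional. An
  alternative rule (best test AUC subject to a retention floor) is
  selectable.
* Exports are anonymised by default: 44 features, label, word count and a
  salted SHA-256 hash of the user id — never raw text or raw user ids,
  which search engines can trace back to authors.

## 4. Ensemble training

`TrainingConfig` defaults mirror the protocol's reference settings:
20 bootstrap subsets of 100,000 posts, balanced (half per label), posts
under 25 words excluded. At desk scale the same machinery runs with
smaller subsets (the tests and the acceptance script use ~10,000-post
corpora with subsets of 5,000); `subset_size` shrinks automatically with
a warning when a corpus cannot supply half the subset per label.

Per subset: draw without replacement (a post may recur across subsets,
never within one), z-standardize all 44 features **on that subset**, fit
an unpenalized maximum-likelihood logistic regression (lbfgs, tolerance
1e-8, 1000 iterations). Standardization per subset (rather than globally)
keeps members exchangeable bootstrap replicates; each member stores its
own means/SDs and applies them at prediction time. Zero-variance features
in a subset are dropped from that member (coefficient 0) rather than
failing. No regularization by default because the coefficients are
interpreted; an optional L2 strength (`l2_C`) exists for perfectly
separable toy data where the MLE diverges.

Subsets are drawn by the corpus's *label order*, not by which label is
declared positive, so swapping `positive_label` provably maps every
probability p → 1 − p and negates every coefficient (up to optimizer
tolerance); this is covered by a test.

**Evaluation conventions.** Training AUC = member on its own subset; test
AUC = member out-of-bag (posts outside its subset). The protocol's
"training/test" split is not otherwise specified; out-of-bag is the
reconstruction used throughout, and the cutoff curve reports both.

Models serialize to versioned JSON (schema id, members with coefficients
and standardization constants, config, seed) and are portable across
platforms.

## 5. Validation designs

* **ROC/AUC.** AUC = P(score⁺ > score⁻) + ½ P(tie), computed by the
  rank-based routine and cross-checked in the tests against an exhaustive
  pairwise-comparison oracle (criterion: exact agreement with ties, up to
  n = 200).
* **Asymptotic uncertainty.** Hanley–McNeil (1982) SE by default — the
  convention behind "asymptotic 95% CI" columns in this literature —
  DeLong (1988) by flag; CIs truncated to [0, 1].
* **Within-participant CV.** Each round draws one random post per label
  for every dual-membership user and scores the ensemble-mean probability
  (per-member AUCs are additionally reported). Rounds use dedicated
  random streams derived from `(seed, round)`, so adding rounds never
  changes earlier ones. Default 20 rounds.
* **Standard errors of a CV mean.** The SE across rounds understates
  uncertainty because every round reuses the same users; the SE across
  members understates it because every member scores the same posts. The
  reported report therefore carries `se_rounds`, `se_members` *and*
  `se_auc` (the Hanley–McNeil SE at the design's evaluation size, which
  captures the shared sampling noise), and the 95% CI uses
  √(se_rounds² + se_auc²). Calibration tests ("AUC within 2 SE of 0.5")
  use this combined SE.
* **Cross-platform test.** Identical mechanics on a corpus from a held-out
  platform, cleaned and cutoff-filtered with the training rules.
* **Experimental evaluation.** Per-topic AUC with asymptotic SE and 95%
  CI over documents whose salience condition was manipulated; topics with
  a single class are skipped and reported.
* **Confusion matrices** at probability threshold 0.5; ties predict the
  positive class (documented convention).
* **Sample-size planning.** Smallest total N for which the z-test of
  AUC = target against 0.5 reaches the requested power, under an explicit
  variance model (Hanley–McNeil exponential approximation by default,
  Obuchowski's binormal variance by flag) and explicit sidedness, both
  echoed in the result. Published calculators differ in exactly these
  choices, which is why none of them is hard-coded; a Monte-Carlo power
  simulation in the tests confirms the analytic model at the returned N.

## 6. Longitudinal trajectories

Posts are binned into calendar periods relative to a per-user anchor
event: period 1 is the anchor's calendar month, period k starts
(k−1) months later. Users qualify with at least one post anywhere in the
window; full coverage is not required. Per user-period the posts are
**concatenated into one document**, featurised once and scored once —
aggregation before extraction stabilises short-post noise and is scale
invariant (duplicating a text changes nothing); averaging per-post
probabilities is available as an option (`method="mean"`).

Group comparison at a period: Welch's unequal-variance t with
Welch–Satterthwaite df, two-sided p, and Cohen's d with the pooled SD.
If a group has zero variance the d is flagged; identical constant groups
return t = d = 0. Trajectory plots show group means ± 1 SE per period.

## 7. The synthetic-corpus generator

The generator exists so every stage — tokenisation, dictionary matching,
cleaning, cutoffs, training, all validation designs, trajectories — can
be exercised end to end without any external data. It emits real token
streams from a deterministic pseudo-word vocabulary (≈1,240 category
words, 40 per category with 15% carrying a second category, plus 800
category-free filler words) with a matching `CategoryDictionary`.

Per-token emission logits are: base rate (default −3.4 against filler at
0, i.e. ≈1.6% per category, ≈50% filler) + identity effect + stable
per-user normal effect (SD 0.4) + optional platform shift. Sentence
lengths are normal (mean 12 words, SD 4, shiftable) and terminators are
`!` with configurable log-odds (base ≈15%), `?` with probability 0.05,
else `.` — so `wps` and `exclam` can carry signal. Post lengths are
lognormal (median 40 words, σ = 0.6), placing the lower word-count
quartile near the canonical 25-word cutoff.

The default identity contrast mirrors an informal/positive versus
intellectual/negative pattern: ±0.8 log-odds on ten word categories
(`posemo`, `incl`, `nonflu`, `assent`, `shehe` toward the first identity;
`negemo`, `article`, `cause`, `insight`, `swear` toward the second), −0.8
on `!`-termination and +3 words per sentence toward the second. At the
default post length this yields out-of-bag AUCs in the low .9s and
within-user AUCs slightly below — strong but imperfect separation, the
regime the protocol targets.

Scenario presets (`scenario_library()`):

| preset | structure |
|---|---|
| `study1_between` | two forums, ~1,100 single- plus 160 dual-membership users, ≈10,000 posts |
| `null` | identical shape, zero identity effect |
| `study2_confounded` | zero identity effect, but user traits (±1.2 log-odds pattern) aligned with the home forum of single-membership users |
| `study3_platform` | signal intact; the venue dampens the contrast on half the signal categories (±0.5), shifts some base rates, and hosts shorter posts (median 28) |
| `study4_experiment` | 43 dual-identity users, salience manipulated between subjects, one ≥25-word document per user per topic (3 topics); style signal topic-independent by construction |
| `study5_drift` | 25 tagged + 60 control users over 4 monthly periods; the tagged group's identity-effect multiplier declines 1.0 → 0.75 → 0.5 → 0.25, controls stay at 1.0 |

A design note on the platform scenario: a purely additive, class-symmetric
base-rate shift moves both classes' features equally and therefore leaves
a rank-based AUC essentially unchanged — it is *not* a mechanism by which
accuracy degrades. The preset instead perturbs the identity contrast
itself and shortens posts, the two mechanisms that genuinely make
classifiers travel imperfectly across venues; the additive base-rate
shift remains available (`platform_shift`) for distribution-shift
experiments.

**What the generator does not emulate.** Real prose (word order is
exchangeable within a sentence), topic structure, burstiness and
word-level Zipfian reuse, demographic covariates, dictionary coverage
gaps, spelling variation, or time-varying platform norms. Passing tests
therefore demonstrate that the *machinery* is correct and that the
designs detect or reject effects under controlled conditions — they do
not certify accuracy figures on real corpora, whose effect sizes and
noise structure differ.

## 8. Numerical conventions and degenerate inputs

* Quantiles: median-unbiased interpolation everywhere a quantile is taken.
* Probabilities always in [0, 1]; ensemble mean preserves this.
* Confusion-matrix ties at threshold → positive.
* Zero-word documents: rejected at extraction with a pointer to cleaning.
* Single-member ensembles: coefficient SEs reported as unavailable.
* Single-round CV: `se_rounds` unavailable, `se_auc` still reported.
* Empty out-of-bag sets (subset = whole corpus): OOB AUC unavailable.
* All stochastic procedures take integer seeds; per-round/per-subset
  streams are derived as `(seed, index)` so partial reruns are stable.

## 9. Known limitations

* The packaged dictionary is small; real-data deployments should supply a
  curated dictionary or externally computed feature tables.
* Binary by construction: no multiclass identities, no absolute salience.
* The 44-feature schema is one defensible reconstruction of a partially
  published inventory; results on real data will depend on the dictionary
  far more than on the schema's exact membership.
* English-oriented tokenisation (apostrophe handling, sentence
  terminators); no lemmatisation or multilingual support.
* Desk-scale defaults are intentionally modest; scaling `subset_size` and
  corpus sizes up is purely a matter of compute.
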