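# Methods

This note documents the models, the construction rules, the numerical
choices and the limitations of `aglab`.  It is the package's own
account of its science; every number quoted here is computed by the
test suite or the example scripts.

## Grammars and the structure inventory

Each of the four grammars is a small context-free rewrite system over
nonterminals {S, NP, VP (or VP1/VP2), CP} and terminal classes
{N, V, R}, with verbs subcategorised into intransitive V1 and
transitive V2 (the surface class string collapses both to V; the
derivation tree keeps them distinct).  All four grammars are
subject-initial (`S → NP VP…`); the variants differ in whether CP
attaches right (`NP → N CP`) or left (`NP → CP N`) of its head noun,
and in whether a CP nested inside a CP sits at the edge of its host
(tail embedding) or interrupts it (centre embedding).  Two of the
variants need a dedicated embedded verb phrase `VP2 → V1 | NP V2` to
realise the embedded clause's word order; those have five rules, the
other two have four.

A token's **layer** is 1 + the number of CP ancestors in its
derivation.  Enumeration caps derivations at three layers and at most
two CP constituents; for these grammars that cap is provably
equivalent (the test suite checks it by brute force) to capping the
sentence length at nine words.  Either cap yields exactly 18 distinct
class sequences per grammar — 2 one-layer, 10 two-layer (6 with one
CP, 4 with two sibling CPs), 6 three-layer (nested CP chains) — and
the layer annotation of each sequence is unique, which the enumerator
asserts.

Note one symmetry that holds and one that does not: the CP-content
sets of left- and right-branching grammars of the same embedding type
are exact token reversals of each other, but whole-sentence mirror
symmetry fails for 2 of the 18 structures per pair, because the main
clause is subject-initial in every variant.  Tests assert the former.

**Parsing** is an independent span-recursion (CYK-style with
memoisation over `(symbol, span, layer)`), not a lookup into the
enumerated set; the two routes are checked against each other
exhaustively over all 3^L class strings, L ≤ 9, for all four grammars.

## Stimulus construction

* **Old/new split.** Both one-layer structures are always old (too
  few structure types to spare); the ten 2-layer and six 3-layer
  structures are split half-half by the seeded generator.
* **Training corpus.** Old structures are instantiated with uniform
  random words per class position — ×8 (one-layer), ×16 (two-layer),
  ×24 (three-layer) — giving 16 + 80 + 72 = 168 sentences, distinct as
  word sequences (collisions are resampled; distinctness across
  structures is automatic because word identity determines class).
* **Layer violations.** A violation rewrites, in place, the direct
  tokens of exactly one *constituent* — the main clause, or a single
  CP — using a fixed substitution table, leaving every other token
  untouched.  The table for main-clause contents is shared by all
  variants ("N V N" → "V N N" or "N R V"; "N V" → "R V" or "V N").
  Embedded-clause entries are variant-specific: the centre-left
  entries ("V N R" → "V V R" or "N R V"; "V R" → "R V" or "N R") are
  the reference; centre-right uses their token reversals; tail-left
  applies the same two edit operations (noun→verb substitution and
  one-step rotation) to its own content "N V R"; tail-right mirrors
  tail-left.  Every substitution is verified ungrammatical by the
  parser at build time — an assertion, not a rejection sampler.
  The violation set comprises 6 one-layer items (the four distinct
  violated forms plus one seed-chosen duplicate per structure), 20
  two-layer items (each structure violated once per layer) and 18
  three-layer items (once per layer): 44 in total.
* **Locality.** A violation is *nonlocal* when the violated
  constituent's tokens are non-contiguous, i.e. intermitted by
  correctly embedded material.  A layer realised by two sibling CPs is
  *not* nonlocal when one (contiguous) CP is rewritten.  Under this
  rule the per-condition nonlocal trial counts are 14 (centre-left),
  18 (centre-right), 8 (tail-left) and 12 (tail-right) — asserted in
  the tests.
* **Random-ungrammatical items** permute the template's class multiset
  (keeping class frequencies matched) until the result neither equals
  the template nor parses: 3 per one-layer structure and 1 per deeper
  structure, 22 in total.
* **Test pairs.** Each of the 66 ungrammatical items is paired with a
  fresh instantiation of its own template structure.  Length matching
  is then exact by construction, and the old/new composition falls out
  arithmetically: 12 one-layer + 15 two-layer-old + 12 three-layer-old
  = 39 old-grammatical, and 15 + 12 = 27 new-grammatical items.
* **Control corpus.** 168 random-ungrammatical sentences blocked per
  structure exactly like the training corpus, so lengths match.

## Participant model

Choice is logistic in the pair's feature differences:
`P(choose grammatical | inclusion) = σ(w0 + w·Δx)` with `Δx` the
grammatical-minus-ungrammatical values of the chunk/repetition
predictor set and `w0` the nonlocal sensitivity (the dummy codes local
= 1, so the intercept carries the nonlocal effect).  Exclusion
reverses the knowledge-driven choice with probability `c ∈ [0, 1]`
(conscious control); `c = 0` makes exclusion identical to inclusion
(purely unconscious knowledge), `c = 1` fully reverses it.  Confidence
is `round(50 + 50·tanh(g·|evidence|))` with gain `g = 0.5` by default;
only the guess (= 50) vs confident (> 50) split is analysed, so the
saturating form is a convenience, not a claim.

Presets:

* `grammar-learner` — population means equal to the reported per-unit
  group coefficients (intercept 0.150, word chunk 0.004, class chunk
  0.002, local 0.163, global repetition 0.032/−0.004, local repetition
  0.170/−0.002), SDs back-computed from the reported group t values
  (`sd = |m|·√80 / t`), and `c = 0.1` (reproducing a small
  inclusion–exclusion gap).  Caveat: the printed SDs include
  estimation noise, so treating them as pure between-participant
  heterogeneity overstates individual differences; this preset serves
  qualitative study emulation (trained > control, unconscious-
  knowledge signatures), not parameter recovery.
* `recovery` — the correctly specified generative model used to
  validate the inference machinery: each weight sized so one feature
  SD moves the evidence by ≈ 0.3 (at the printed per-unit scale,
  several sparse predictors saturate their few informative trials,
  leaving those coefficients only boundedly identified — a property
  of the effect-size regime, not of the estimator), heterogeneity
  CV = 0.5, `c = 0`.
* `chunk-learner` — a mis-specified surface-chunk learner, and
  `control` — all-zero weights.

## Predictors

* **Chunk strength**: summed training-corpus token frequency of the
  item's bigrams and trigrams over sequences padded with one start and
  one end symbol (two *distinct* pads, so edge positions act as
  anchors), at word and class level.  Counts are raw (no
  normalisation), matching per-unit coefficient scales.
* **Repetition structure**: the adjacent code (`AABBCC → 10101`) and
  the global first-occurrence-rank code (`AABBCC → 112233`;
  `ABABC`/`BCBCD → 12123`, invariant under relabelling — a property
  test).  The predictor is the number of training sentences sharing
  the item's code, per kind and level.
* **Gapped bigrams**: ordered token pairs at exactly 2 or 3
  intervening tokens, counted over unpadded sequences (edges are
  already carried by the padded n-grams).
* The **chunk-rep** predictor set (7 features + intercept) and the
  **gapped** set (4 features + local/nonlocal control + intercept) are
  fit separately; a joint regression is unstable at 132 trials.

## Inference

Exclusion responses are scored as grammatical-choice throughout.  Per
participant, the 132 pooled choices are regressed on the features by
**Firth's bias-reduced logistic regression** (Jeffreys-prior
penalisation, Fisher scoring on unit-norm-scaled columns, damped
steps).  Firth was chosen over a weakly ridge-penalised MLE because
several predictors are informative on only 15–22 of the 66 pairs, and
at that effective sample size the MLE's away-from-zero bias is large
enough to break group-level CI coverage (observed 80% for one
coefficient over 200 replicates; 92.5–96.5% for all coefficients with
Firth).  A ridge-penalised fit (`method="ridge"`, λ = 1e-3 on slopes,
intercept unpenalised, λ escalated ×10 on optimiser failure) is
retained and is the one validated against a brute-force grid-search
MLE oracle.  Constant feature columns are dropped with a NaN
coefficient, not an error.

Group inference is a one-sample t test per coefficient over
participants (df = n − 1, dz = mean/SD; the degenerate all-zero case
reports t = 0, p = 1).  The 2×2 mixed ANOVA (pingouin) reports F, df,
p and partial eta squared, and is checked against the F = t² identity
for a pure between-group contrast.  Hochberg's step-up correction
wraps `statsmodels` (`simes-hochberg`) and is checked against a direct
implementation of the step-up rule.  The five awareness contrasts
(inclusion vs exclusion; trained exclusion vs control; guess-trial
accuracy vs control; confident vs guess; the confident-vs-guess
difference of inclusion−exclusion) use participant-level pooling, and
participants lacking a confidence bin are excluded from the contrasts
that need it.

The **Bayes factor** for a normal estimate under a half-normal
prediction integrates `N(mean; θ, se)` against `HalfNormal(sd)` by
adaptive quadrature after substituting θ = sd·u (making the integrand
O(1) for any scale ratio, with break points at the likelihood peak and
width); it matches the closed-form Gaussian result to < 1e-6 relative
error, equals 1/√2 at (0, 1, 1), tends to 1 as sd → 0 and to 0 as
sd → ∞.  The prior SD is interpreted on whatever scale the estimate is
on (percentage points for accuracy effects).

## Parameter recovery and calibration

`recovery_experiment` holds one stimulus design fixed, draws fresh
participant groups per replicate, simulates both phases, fits every
participant and records the group mean and 95% CI per coefficient.
At the sizes used by the acceptance suite (n = 80 participants, 200
replicates, `recovery` preset) all coefficients show coverage inside
[90%, 98%] and the intercept's bias is below 10% of its generating
value.  Zero-weight groups sit at accuracy .500 within Monte-Carlo
error and the group test's type-I rate is nominal.

## What the synthetic data do and do not show

The generator emulates the *design* — group sizes, trial structure,
stimulus statistics — and a *known* choice process.  Passing tests
therefore demonstrate that the pipeline constructs the stimuli exactly
as specified and that the inference stack is calibrated and can
recover known sensitivities under correct specification.  They do not
reproduce the human cell means (raw data are not available), do not
model learning dynamics during training, reaction times, order
effects, or any principled confidence process, and real participants'
choice processes are surely not logistic in exactly these features.
The per-condition human effect sizes are matched only qualitatively
(trained > control; tail > centre embedding is a property of the
stimuli's nonlocal trial counts, not separately modelled).

## Problem sizes

Default study runs use 20 trained + 20 control participants per
condition (the experimental scale); examples scale some runs to 10–40
participants, and the recovery harness uses one condition at n = 80
with 200 replicates.
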