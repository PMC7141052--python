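# Methods

This note documents the models implemented in `gazeparse`, the choices
made where the design was genuinely open, and what the synthetic studies
do and do not show.

## Transition system

The parser is unlabeled arc-eager with four transitions. The virtual root
(index 0) sits at the bottom of the stack from initialization, and
RIGHT-ARC from the root is legal; consequently exactly two transitions
(SHIFT, RIGHT-ARC) are legal at the first word of every sentence.
LEFT-ARC takes its head from the buffer front and therefore requires a
nonempty buffer, a non-root stack top, and a headless stack top; REDUCE
requires a headed stack top. States are immutable and carry the stack,
the buffer position (1-based; n+1 when exhausted), the arc set, the
transition history, and the accumulated log-probability.

The training oracle is the standard eager one: attach when the gold arc
joins stack top and buffer front, REDUCE when the stack top is finished
and buried material still links to the buffer front, otherwise SHIFT.
Non-projective sentences are skipped with a count (no
pseudo-projectivization); the synthetic grammar never produces them.
Oracle correctness is verified by exhaustive enumeration of every
projective single-root tree up to length 5 (replay must reproduce the
gold arc set exactly).

At the end of a sentence, the REDUCE closure is run to termination so
parses can be flagged complete or incomplete, but it is assigned no word
index: a sentence of n words yields exactly n surprisal values.

## Transition model

A multinomial logistic (MaxEnt) classifier with L2 regularization
(scikit-learn `LogisticRegression`, lbfgs; inverse strength `l2_c` = 1.0,
tolerance 1e-6, max 500 iterations — all config keys, since nothing
pins them down externally). Features are binary template instantiations;
absent context instantiates an explicit `<null>` value so templates are
never silently dropped. The rich template set covers FORM / LEMMA /
POSTAG / CPOSTAG / morphological features (with gender, number and
person excluded — they hurt accuracy on this kind of data) / chunk id of
Stack[0], Stack[1] and Input[0], plus POS of head(Stack[0]), of the
linear predecessor of Stack[0], and of the leftmost dependent of
Input[0], and three merge templates pairing stack-top and buffer-front
columns. A simple POSTAG-merge-only set is available as
`--features simple`. No template reads past the buffer front, keeping
extraction strictly incremental (property-tested).

At parse time the classifier's distribution is masked to the legal
transitions and renormalized. This makes every branching of a live state
a proper probability distribution, so before pruning the states at a
word index always carry total mass 1, and surprisal measures only the
mass removed by the beam (and, at k=1, the mass of unchosen chains).
Unknown features contribute zero weight, the standard MaxEnt behaviour.

## Beam search and surprisal

Word-synchronous beam: from the states that have consumed word i, apply
all legal transitions, closing over the non-consuming LEFT-ARC/REDUCE
(chains terminate because both strictly pop the stack), keep the k most
probable states that have consumed word i+1. Ties at the beam boundary
break on (probability, then lexicographic transition history) for
reproducibility. Prefix probabilities use log-sum-exp; surprisal is the
natural log ratio s_i = ln(α_{i−1}/α_i) — the natural log is forced by
the worked example the implementation reproduces (ln(0.9985/0.3134) =
1.1587; log₂ or log₁₀ would miss it by far). α is cumulative: no
re-normalization across words after pruning. Values within one ulp of
zero are clamped to 0 so the invariant s_i ≥ 0 survives float round-off.

SHIFT is always legal while the buffer is nonempty, so states can only
die in the end-of-sentence closure; during the word sweep mass is lost
to pruning alone. Hence with the beam disabled the prefix probability
stays exactly 1 and surprisal 0 at every word — a property the tests use
as a mass-conservation check, alongside the telescoping identity
Σ s_i = −ln α_n which holds in every configuration. The default beam is
k = 10, with a sweep command over {1, 2, 3, 4, 5, 10, 15, 20, 25}.

If every state dies (possible in principle at sentence end with an
adversarial model), surprisal from that word on is reported as +inf and
the sentence flagged; the analysis stage excludes such sentences.

## Memory metrics

**Storage cost.** SC(i) = number of distinct positions h > i that are
the gold head of at least one word at position ≤ i. This is an
algorithmic proxy for hand annotation of "predicted upcoming heads"; it
yields 1 at the first case-marked argument of a head-final clause,
stays constant as further arguments accumulate, and drops to 0 at the
verb. It may diverge from hand annotation on coordination or ellipsis,
which the toy grammar does not produce.

**Integration cost.** IC(w) = Σ over gold dependencies whose rightmost
member is w of the number of discourse-referent words strictly between
the two members. Discourse referents default to coarse POS {N, V}
(configurable). Arcs from the virtual root are excluded — root
attachment is not a retrieval at an integration site.

**Retrieval cost.** Cue-based retrieval in the ACT-R family. Chunks are
created when a word is pushed (the virtual root is encoded at time 0).
Activation A = B + W·S with B = ln Σ_j (now − t_j)^(−d) over the chunk's
creation and retrieval times, and S = S_max − ln(fan) for the single
part-of-speech cue, fan counting all chunks in memory sharing the POS.
Defaults: S_max = 1.5, W = 1, decay d = 0.5 (the framework's canonical
value; nothing in the implemented model pins it), latency factor
F = 1.0 s — **F is an assumption**: the latency equation
T = F·e^(−A) is the standard form in the cue-based retrieval literature
and F is a config key. Productions cost 50 ms; arc formation costs two
productions plus a retrieval of the stack-resident arc member (the
buffer front is current input, not retrieved); SHIFT costs one
production; REDUCE costs one production and no retrieval; reading a word
costs 1 ms, attached per word rather than per parser step. The clock
advances through all of these, and retrieval timestamps are appended at
retrieval completion. Costs are attributed to the word at the buffer
front when the transition fires; the end-of-sentence closure is
attributed to no word. Per-word costs across the beam are the
probability-weighted mean over the surviving states at that word (the
aggregation rule is not externally fixed; weighting by state probability
is the natural choice consistent with beam-wide prefix probabilities).
The predictor table reports both the total per-word cost and its pure
retrieval-latency component; the retrieval analysis excludes words whose
latency component is zero, since no retrieval effect is possible there.

## Gaze measures

FPRT sums fixations on a word from its first fixation — provided no word
to its right was fixated earlier in the trial (first-pass entry "from
the left"; trial-initial mid-sentence landings therefore deny first-pass
status to the words they skipped) — until the first fixation on any
other word. Re-fixations after leaving never re-open the first pass.
RPD sums *all* fixations (including returns to the word itself) from the
word's first fixation until the gaze first lands right of it, extending
to the end of the trial if that never happens; it is 0 for words without
a first pass. TFT sums all fixations on the word. These definitions are
cross-checked against an independently written event-replay oracle on
arbitrary generated sequences.

## Regression pipeline

Rows with 0 ms on the chosen measure are removed (skipped words,
about a quarter of the data under the default generator), the dependent
is natural-log transformed, and every predictor is centered and scaled
to unit variance *on the analyzed rows*. Models are linear mixed models
with crossed varying intercepts and varying slopes for subjects and
items (sentences), no intercept-slope correlations, fitted by REML.

Fitting is delegated to lme4 through `Rscript` — the reference
implementation for crossed random effects and far faster here than
pure-Python equivalents. A statsmodels variance-component backend
(random intercepts only) serves as an independent cross-check in the
test suite; the two agree on the crossed-intercept model to numerical
tolerance. The lme4 optimizer runs with `calc.derivs=FALSE` and
`xtol_abs = ftol_abs = 1e-4`, which reproduces tightly-converged
estimates and standard errors to ~1e-5 — far below the 3-decimal
reporting precision — at a fraction of the cost; replicated fits of the
same design warm-start from the previous solution's variance parameters.
If the full random-slope structure fails to converge, slopes are pruned
in reverse predictor order and the pruning is recorded on the result.
Boundary (singular) fits count as converged. Significance convention:
|t| ≥ 2.

## Synthetic data

The toy grammar is head-final with postposed case clitics: 1–3 argument
NPs (optionally with genitive modifiers and adjectives), an optional
adverb, a verb, an optional auxiliary. Case clitics attach to the
preceding nominal, arguments to the verb, genitives and adjectives to
the following noun. Locative NPs followed by another noun modify that
noun with probability 0.35 — genuine attachment ambiguity, without which
the trained model would be near-deterministic and prefix probabilities
degenerate. All trees are projective and single-rooted; morphology
(case, TAM, chunk, gender) is populated so the rich templates are
exercised. Word-level predictors (syllables, complexity, uni-/bigram
log-frequency) are deterministic functions of the lexicon standing in
for externally computed values.

Reading times: per measure, log-duration = intercept + Σ β·(scaled
predictor) + subject intercept + item intercept + per-predictor
subject/item slopes + Gaussian noise, exponentiated to ms; 25% of words
are skipped (0 ms on all three measures at once, which preserves
FPRT ≤ TFT and FPRT ≤ RPD). Random effects and residuals are shared
across the three measures — a slow reader is slow on every measure —
which keeps each marginal measure exactly log-linear while guaranteeing
the ordering invariants (a max() guard covers extreme tails). Default
magnitudes are typical of log reading times in naturalistic corpora:
intercepts 5.50/5.65/5.62 (≈ 245–285 ms), residual sd 0.30, subject
intercept sd 0.10, item sd 0.05, slope sds 0.01, a strong syllable-length
effect (≈ 0.11), facilitatory frequency effects, and small sentence-level
effects (storage, integration, surprisal ≈ 0.003–0.019).

What passing the simulation studies shows: the pipeline recovers known
coefficients with calibrated uncertainty *when the generating model is
the assumed model*. Real eye-tracking data violate that in ways the
generator deliberately omits (no saccade dynamics, no spillover, no
correlated skipping, no non-Gaussian tails), so these studies validate
the machinery, not the psycholinguistic claims one might test with it.

Fixation sequences are constructed from measure triples, not the other
way around. Feasibility follows from the measure definitions: every
re-reading millisecond (TFT−FPRT) must be spent inside the regression
window of a first-passed word at or to its right, every regression
millisecond (RPD−FPRT) must be covered by re-reading supply at or to its
left, the two totals must balance exactly within a trial, a regression
needs an earlier word to land on, and no re-read word may follow the
last first-passed word. The constructor is greedy (nearest earlier
supply first, own re-reading last) and raises on infeasible triples;
round trips are verified against measures computed from independently
generated random reading records. Note that reading times produced by
the regression generator are three independent linear models and are
generally *not* jointly fixation-feasible; the fixation constructor is
for building raw-log fixtures, not for inverting simulated regressions.

## Study sizes

The simulation studies run at 30 subjects × 150 items (≈ 28,000 word
tokens per replication, ≈ 21,000 after skip removal), 50 replications
for the recovery and null studies and 20 for the dissociation study,
beam width 10 for predictor tables — sizes chosen to mirror a typical
single-experiment eye-tracking corpus while keeping a full acceptance
run in the minutes range on one CPU.

## Known limitations

* Unlabeled parsing only; no non-projective transitions; no
  phrase-structure surprisal.
* The latency factor F and decay d of the retrieval model are
  assumptions (flagged above), so retrieval costs are meaningful up to
  monotone transformation rather than as absolute milliseconds.
* Storage cost is a gold-tree proxy for hand annotation.
* The statsmodels cross-check backend cannot fit random slopes.
* Surprisal magnitudes on the toy grammar are small (the grammar is
  simple); the regression studies therefore inject effects at the
  scaled-predictor level rather than relying on raw magnitudes.
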