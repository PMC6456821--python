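# Methods

## The problem and the model

`motimsg` implements a situation-based motivational message system for
e-mental-health therapy of post-traumatic stress disorder (PTSD), in which
a virtual agent addresses the patient between exposure sessions.  The
patient's *situation* is the pair

- **PCL trend** — the direction of the summed brief PTSD-Checklist score
  across sessions: `dropping` (improving), `stable`, or `rising`
  (worsening), and
- **initial trust** — the patient's self-rated belief in a good therapy
  outcome: `low`, `medium`, or `high`,

giving 9 situations.  A statement database holds short motivational
statements grouped into a two-level *statement-type* forest (e.g. the
super-type `note_pcl` with subtypes `note_pcl_dropping/stable/rising`),
together with three per-situation tables:

- a **probability table** `p(type | situation)` — how likely an expert
  therapist is to use a statement of that type in that situation,
- a **length table** — the target number of statements per message (the
  rounded mean length of expert answers; 3 or 4 in the default table), and
- an **order table** — presentation ranks (note-the-situation first, then
  empathy, giving perspective, tackling things together; general
  motivation near the end, only the future after it).

### Composition algorithm

For a situation, the generator (`motimsg.generate`):

1. reads the target length;
2. includes every type with `p > .5` (threshold configurable).  A
   mandatory super-type resolves to all of its subtypes above the
   threshold, or — if none — to exactly one subtype drawn by *weighted
   randomized selection*: the probabilities are laid out as consecutive
   intervals on `[0, sum)` and a single uniform draw picks the interval;
3. fills the remaining slots one by one with the same weighted draw over
   all still-eligible positive-probability leaves;
4. draws one stored statement uniformly per selected leaf and sorts the
   result by rank (ties broken by database declaration order).

De-duplication blocks a selected leaf, its siblings, and its super, so a
message never notes two different trends or motivates twice from the same
family.  Two edge policies are deliberate: if the mandatory set alone
exceeds the target length (impossible with the default table, possible
with user tables) all mandatory types are kept and a warning is logged,
because inclusion above the threshold is unconditional; if the eligible
pool empties before the target is reached the message is emitted short
with a warning rather than padded from zero-probability types, which
experts never used in that situation.  Whether the statement picked
within a type should be uniform or probability-weighted is not fixed by
the design; uniform is used.

All randomness flows through one explicit `numpy.random.Generator`; a
fixed integer seed reproduces a message bit for bit.

## Deriving the tables from a coded expert corpus

`motimsg.corpus` rebuilds the tables from a corpus of coded expert
answers (expert id, situation, ordered statements with leaf types).
Free-text splitting and categorization are human judgment and out of
computational scope; the corpus format requires pre-coded statements.

- **Occurrence coding**: binary answer x type matrix; a super-type column
  is the OR of its leaves.
- **Rare-type filter**: types with fewer than 10 coded statement
  *instances* are dropped; the retained fraction of instances is
  reported.
- **Per-type model**: a random-intercept binomial logistic regression —
  expert intercepts `b_e ~ N(0, sigma^2)` on the log-odds scale, and a
  *saturated* 3x3 trend-by-trust cell-means fixed part, so the fitted
  probabilities are invariant to contrast coding.  The marginal
  likelihood is computed with 25-node Gauss–Hermite quadrature and
  maximized (L-BFGS-B with analytic gradients) over the nine cell logits
  and `log sigma`; this matches `lme4::glmer(..., nAGQ=25)` to four
  decimals on test data.  Reported probabilities are population-level
  predictions (random intercept at zero).  Non-convergent or separated
  fits (any |cell logit| ≥ 10) fall back to pooled cell proportions and
  are flagged.
- **Length table**: per-situation mean statement count, rounded half-up
  (`floor(x + .5)`; "rounded" alone does not fix the convention, so it is
  documented here).
- **Statement retention**: statements survive only if their leaf type or
  its super exceeds probability .05 in at least one situation.
- **Reliability**: unweighted Cohen's kappa (marginal-product expected
  agreement) for double coding; likelihood-ratio tests
  (`2 * delta loglik` against the chi-square upper tail) for nested model
  comparisons.

Whether the source regressions ran at super or leaf level is not stated;
`derive_probability_table(..., level=...)` exposes `leaf`, `super`, and
`both` (default).

## Evaluation-study machinery

`motimsg.study` covers the statistics of a 3 (message type: personalized /
general / none, between subjects) x 3 (trend) x 3 (trust, both within
subjects) evaluation, with change scores on bounded −10..10 analog scales:

- **A priori power**: `anova_power_n` scans total N upward and returns the
  first N whose one-way fixed-effects ANOVA power (noncentrality
  `f^2 * N`, df `k−1`, `N−k`) reaches the target.  By default only
  balanced totals (multiples of k) are considered, the allocation a
  G*Power-style calculation assumes; for 3 groups, `f = .25`,
  alpha `.05`, power `.90` this gives N = 207 (achieved power .9022).
  An unbalanced scan is available and returns 206 for the same inputs.
- **Deviation from zero**: classical one-sample t; **scale reliability**:
  Cronbach's alpha from the item covariance identity.
- **Model ladder**: M0..M7 linear mixed models with a random participant
  intercept, fit by **maximum likelihood (not REML)** so the
  likelihood-ratio tests on fixed effects are valid.  Terms enter in the
  order message type, trend, trust, trust x trend, message x trend,
  message x trust, three-way; each comparison's df is that of the added
  terms (2, 2, 2, 4, 4, 4, 8 with treatment contrasts).  Fits use
  `statsmodels` MixedLM; a step that fails to improve the likelihood
  numerically is clamped to a zero statistic and flagged.
- **Post hoc**: refits on each two-level subset of a factor with the same
  random-intercept model, reporting Wald estimate/interval/p.  No
  multiplicity correction is applied by default (none is prescribed); a
  Bonferroni flag exists.

## Synthetic data: what it emulates and what it does not

The published statement list and probability table are not distributed
with the package, so `motimsg.simulate` provides synthetic stand-ins with
known ground truth (all marked as such):

- **Default database** (`make_default_database`, also bundled as
  `data/default_database.json`): 18 types (15 leaves), 45 statements
  authored for this package.  It encodes every constraint the message
  model states: at (rising, low) `motivation`, `give_perspective` and
  `note_pcl` exceed .5, `note_pcl_rising` exceeds .5 while no motivation
  subtype does; `note_trust` has only low/high subtypes; lengths are 3 at
  (dropping, high), (dropping, medium), (stable, high) and 4 elsewhere;
  in every situation 2–3 types are mandatory, leaving at least one
  weighted slot.  Two free choices: leaf probabilities per situation sum
  approximately to the target length (the balance an answer of that
  length implies — this also keeps the simulator's length forcing nearly
  unbiased), and `future` has probability 0 at (rising, low) so that the
  reference situation always closes on the motivation family, matching
  the documented example structure.
- **Expert corpus** (`simulate_expert_corpus`): the generative mirror of
  the per-type GLMM — one normal intercept per expert, independent
  Bernoulli inclusion per leaf and answer, 2 answers per situation by
  default.  Answer lengths are then forced to the true length table
  (trim lowest-probability inclusions first, pad by weighted draws) so
  the length table is exactly recoverable.  The forcing mildly distorts
  marginal type frequencies; with the default table the end-to-end mean
  absolute error of the recovered probabilities settles around 0.045 at
  200 experts (the residual is the forcing bias, not estimation noise).
  Real expert answers have correlated type usage within an answer and
  free-text variability that this independence model does not emulate,
  so recovery results bound estimation behavior, not coding quality.
- **User study** (`simulate_user_study`): additive condition/trend/trust
  (+ optional interaction) effects, participant intercepts, correlated
  motivation/trust residuals, truncation (not resampling) at ±10 —
  mirroring a bounded analog scale.  Default noise (participant SD 1.5,
  residual SD 2.5) is illustrative: no raw-scale effect sizes are
  published to copy, and these values give a +2-point between-subject
  effect at 60 participants an expected first-step LRT power of ≈0.97
  by the noncentral-chi-square calculation, a sensible regime for
  calibration experiments.  Responder bias and order effects are not
  modeled.

## Numerical choices and problem sizes

- Inclusion threshold .5 and retention threshold .05 are parameters
  everywhere they appear.
- Trend classification uses the OLS slope of score on session with a
  ±0.5 points/session stable band (the label definitions are verbal in
  the source; the slope rule is this package's operationalization) —
  shift-invariant by construction.
- Brief-PCL items default to a 1–5 ordinal scale (configurable); the
  screening rule is: at least one item of each pair (2,3), (6,7),
  (16,17) rated ≥ 3.
- GLMM probabilities are clipped to (1e-6, 1 − 1e-6); `sigma < 1e-3` is
  reported as the boundary value 0.
- Calibration experiments in the test suite use 200 replicates at 60
  participants (ladder type-I error and power) and 20 replicates across
  expert-corpus sizes {25, 50, 100, 200}; these sizes give Monte-Carlo
  error comfortably inside the asserted bands while keeping the suite
  quick.

## Known limitations

- The bundled database is a constructed stand-in: message *content*
  quality claims cannot be transferred to it.
- The corpus simulator's per-leaf independence understates the negative
  dependence that fixed-length expert answers induce; the length-forcing
  step reintroduces some of it, which is exactly the source of the
  small residual recovery bias noted above.
- `posthoc_pairwise` refits subsets rather than using joint contrasts;
  with strong imbalance the two approaches can differ.
- The trend classifier assumes linear drift; non-monotone symptom
  trajectories are summarized by their OLS slope only.
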