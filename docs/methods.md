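# Methods

## Model family

The core model is tabular Q-learning over two actions with softmax choice.
Pre-choice values `Q_L, Q_R` start at 0/0 at every session start and are
*not* reset at block transitions: transitions are uncued, so the agent (like
the animal) carries its values across them. The initialization is
configurable (`q_init`, e.g. 0.5/0.5) but 0/0 is the default everywhere.

Update (chosen action only):

    R = 1:  Q ← (1 − α_pos) Q + α_pos − γ_win
    R = 0:  Q ← (1 − α_neg) Q − γ_lose

Choice: `P_L = 1 / (1 + exp(−β (Q_L − Q_R) + b))`. The sign convention is
kept exactly as written: *positive* b lowers P_L. `ParamSet.left_bias`
exposes `−b` for interpretation as a left-favoring bias. The logistic is
evaluated in its numerically stable branch form, so extreme `β·ΔQ`
saturates to 0/1 without overflow.

The six variants are a nested family (1 ⊂ 2 ⊂ {3, 4} ⊂ 5 ⊂ 6) defined by
which of (α_pos, α_neg, β, b, γ_win, γ_lose, ε, ρ) are free; constraints
are enforced (`ModelSpec.validate_params`), so a ParamSet that sets a
pinned parameter is rejected rather than silently accepted.

**Uncertainty exploration (model 6).** Each action carries an accumulator
U that grows by ε for every trial the action goes unchosen and resets to 0
when chosen; the softmax argument gains `ρ (U_L − U_R)`. This is one
concrete, testable member of the uncertainty-bonus family, implemented
behind the model-variant interface so an alternative formulation can be
substituted without touching the likelihood machinery.

**Likelihood.** Per-trial choice probabilities are floored at 1e−12 before
the log, which keeps likelihoods finite and bit-reproducible for
near-deterministic parameter corners. The sequential replay is a numba-
compiled scalar loop (`_kernels.replay`); the test suite checks it against
a plain-Python per-trial recomputation to 1e−10 on randomized
(session, parameters, model) triples for all six variants.

## Fitting

Per animal × drug condition, all sessions are pooled (values re-initialize
at session boundaries, so the pooled log-likelihood is the sum of
per-session terms) and −log L is minimized with L-BFGS-B from 20
Latin-hypercube start points under box bounds α ∈ [0, 1], β ∈ [0, 50],
b, γ ∈ [−5, 5], ε ∈ [0, 5], ρ ∈ [−10, 10]. Learning rates are fitted on
their natural scale (no logit transform) so estimates compare directly
across conditions. Fits are deterministic given the restart seed;
parameters within 0.1% of a bound are flagged. AIC = 2k + 2·nll and
BIC = k·ln(n_trials) + 2·nll are both reported; model comparison flags any
nested log-likelihood violation as an optimization failure and refits with
doubled restarts.

Degenerate data (e.g. an animal that chose one side on every trial) push
β and/or b to a bound; the fit still returns, with the boundary flags set.
For a β = 0 generator α is unidentifiable — the suite asserts only the
chance-level likelihood there, never α recovery.

## Synthetic cohorts

The generator emulates the within-subject pharmacology design:

* **TAB task**: 4 blocks per session, lengths drawn uniformly from
  {35, 40, 45, 50}; 72%/12% reward probabilities, first block's side
  random, swapped at each transition. (Realized block sizes in real data
  average below the uniform mean, suggesting unmodeled session truncation;
  the generator deliberately draws uniformly and does not match that.)
* **Reversal task**: 5 stages, 60-trial sessions (90 in stage 5), correct
  choice rewarded with probability 1, across-session reversals from stage
  3, within-session reversals taking effect at trial 31 (stage 4) and
  trials 31 & 61 (stage 5). Control animals are generated as a third
  treatment (eGFP-CNO) with a null effect map.
* **Cohort**: 20 D1R + 19 D2R animals, 10 CNO + 10 DMSO sessions each on
  alternating days, first-day drug counterbalanced. Baseline parameters
  per animal are drawn once — α ~ U(0.45, 0.75), β ~ U(2, 4), typical of
  fitted rodent dynamic-foraging values — and the CNO condition multiplies
  β by 0.6 (D1R) or both learning rates by 0.5 (D2R).
* **Durations**: log-normal per trial (median ≈ 5 s, log-SD 0.25) with a
  session-level random effect (SD 0.20 on the log scale) and a ×1.1
  multiplicative CNO slowing. This yields right-skewed session means with
  occasional outliers, so the 3-SD exclusion and the CNO/DMSO
  duration-matching stages operate on realistic material; a much larger
  whole-distribution shift would make mean-matching by tail deletion
  impossible at any reasonable removal budget.

All randomness flows through `numpy.random.SeedSequence` spawning, so a
cohort is bit-reproducible from (config, seed) across runs.

What the generator does *not* emulate: motivation/satiety drifts,
inter-trial-interval dynamics, shaping sessions, session truncation, or
any within-session parameter drift. Passing tests therefore validate the
*machinery* (simulation → fitting → segmentation → inference) and the
internal consistency of the double-dissociation logic, not the biological
claims themselves.

## Preprocessing

* **Outlier exclusion**: single pass; a session is dropped when its mean
  trial duration exceeds its population mean + 3 sample SDs, populations
  defined by (line, treatment) for TAB (never pooled). Populations smaller
  than 2 warn and are left untouched; a zero-SD population drops nothing
  (strict inequality).
* **Duration matching**: repeatedly removes the longest remaining CNO
  session or the shortest remaining DMSO session — whichever removal most
  reduces the group-mean gap — until the gap is within tolerance (default
  0.5 s) or the budget (default 20% of sessions) is exhausted. Every
  removal is logged and the log replays to the matched sets exactly. The
  stopping rule (tolerance + budget) is this package's choice; only the
  tails-to-trim are externally specified.

## State segmentation and metrics

Per block, the high-side-choice indicator is smoothed with a 7-trial
moving average. Alignment is configurable (`centered` default, `trailing`
available) because the original alignment is unstated; centered smoothing
avoids a systematic lag in the detected dynamic-state end. Windows shrink
at block edges and never cross block boundaries. With M the block maximum
of the smoothed series, the dynamic state runs from block start until the
series first *strictly* exceeds 0.70 M, the steady state from the first
trial strictly exceeding 0.90 M to block end; strictness makes the
M = 0 block entirely dynamic and the at-ceiling block entirely steady.

P(WS)/P(LS) condition on the *actual* previous trial (stay/switch is
defined by consecutive behavior), even when that trial falls outside the
requested state window; predecessors never cross session boundaries. Zero-
denominator metrics are NaN — distinct from 0 — and excluded from animal-
level averages. The animal is the statistical unit throughout: session
proportions are averaged within animal before any test.

Fitted-value profiles replay each animal's fitted parameters on its own
sessions and use blocks 2–4 only (block 1 starts from the initialization,
not from a transition), aligning Q_high/Q_low to the first 15 post- and
last 10 pre-transition trials, truncated at block edges, plus
dynamic/steady-state means.

## Group statistics

The 2 × 2 mixed ANOVA is computed in closed form via the sum/difference-
score decomposition (exact for two within levels; classical weighted-means
sums of squares, so balanced results match textbook formulas and
unbalanced results match pingouin, which the tests verify to 1e−9). The
closed form makes the permutation control — 8 ANOVAs × 100 permutations,
pseudo-lines drawn without replacement preserving the 20/19 group sizes —
essentially free. The 2 × 3 between-groups ANOVA uses statsmodels OLS with
Type-II sums of squares (robust to mildly unbalanced cells). Bonferroni
post-hoc families are the simple-effect contrasts actually tested per
measure (CNO vs DMSO within each line → m = 2, paired by animal);
corrected p = min(1, m·p). Degenerate inputs (zero error variance) return
NaN F-values rather than raising. Significance is 0.05 two-tailed
throughout.

## Validation design and known limitations

The acceptance study (five seeded full-size cohorts) verifies that the
planted effects are recovered: the line × drug interaction on fitted β
localizes to line 1 and on fitted α to line 2 (interaction plus post-hocs,
≥ 4 of 5 cohorts), truth-vs-fit correlations exceed 0.9, and the
transition-aligned Q_high trace climbs more slowly — and its first-15-trial
mean is lower — under CNO in the reduced-α line only, with late-block
values matched across conditions.

Two behavioral signatures reported for real animals are **not** reproduced
by the pure model-1 generator, and the corresponding acceptance checks are
expected to fail; this is a property of the generating model, not an
implementation defect:

* **Steady-state P(LS)** *rises*, not falls, when β is reduced. In the
  moderate-α regime the post-loss value ranking still favors the high
  side, so a sharper softmax *stays* after losses; lowering β moves switch
  probability toward 0.5 from below. A lose-switch drop requires either
  explicit switching tendencies (γ_lose > 0) in the generator or learning
  rates high enough that a single loss inverts the value ranking.
* **Dynamic-state P(R)** shows no reliable drop when α is halved, because
  the dynamic window is defined by each condition's own smoothed-P(H)
  crossing: a slower learner gets a proportionally longer window with the
  same relative choice profile, self-normalizing the comparison. (In real
  animals dynamic-window lengths were nearly identical across conditions,
  so their comparison was not self-normalized this way.) The
  transition-aligned early-trial window, which fixes the comparison window
  across conditions, does show the expected slowing.

Both windows (state-masked and transition-aligned) are computed and
returned, so either convention can be used explicitly.

Other limitations: no hierarchical/Bayesian estimation, no standard errors
or profile confidence intervals, no cross-validated model selection, and
the model-6 exploration rule is a stand-in contract rather than a claim
about any particular published formulation.

## Problem sizes

Defaults used by the test suite and acceptance study: recovery at 50
agents × 10 sessions (~155 trials each); five cohorts of 39 animals × 20
sessions; 100-permutation control; 500-replicate null calibration of the
ANOVA engine. These sizes give stable Monte-Carlo margins (binomial SEs an
order of magnitude below the tested effects) while keeping a full
validation run to a few minutes on one CPU.
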