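# Methods

## Game model

A board is a 9 × 9 grid (1-based (column, row) coordinates), two player
squares and 1–8 discs valued 1–5. Scoring is per disc: identical
assignments pay the agreed player the disc's value; differing assignments
fine both players `penalty_fraction × value` (default 0.2). Penalties are
signed deductions, so session totals may be negative; no floor is applied.
The payoff identity `payoff₁ + payoff₂ = agreed − 2·penalty·disagreed`
holds exactly and is property-tested.

The default square placement is r₁ = (2, 5), r₂ = (8, 5). This choice is
what makes the focal-point-prominence (FPP) ratio span exactly [1, 7] over
the 79 legal cells: the cell (1, 5) has distances 1 and 7, and the central
column x = 5 is equidistant. The geometry is configurable; the FPP range
then changes accordingly.

**Equidistant discs.** The closeness rule is undefined for a disc
equidistant from both squares. Rather than tie-breaking silently,
`closeness_solution` raises, and all generators reject-and-resample such
positions (on the default geometry this is the x = 5 column). Equidistance
is detected on integer squared distances, never on floats, and the
exact-half test for strategic position compares `2·points` with the board
total in integer arithmetic.

## Features

Per-disc FPP is aggregated to a board-level X₁ by arithmetic mean
(default) or max; the measure is defined per disc, and the mean was chosen
as the smooth, scale-free option. Both strategies are exposed because the
right aggregation for multi-disc boards is genuinely open; for one-disc
boards they coincide. ERP (X₂) and strategic position (X₃) derive from the
focal split; X₄, X₅ are raw board totals (trees are scale-invariant, so no
normalization is applied); X₆ is the SVO angle in degrees, consumed as
given (slider-instrument scoring is out of scope).

## Behavioral model

`P_FP` comes from a bagging ensemble of depth-bounded CART trees
(scikit-learn `BaggingClassifier` over `DecisionTreeClassifier`):
same-size bootstrap resamples, admissible grid 1–300 trees × depth 1–50.
The predicted probability is the mean over trees of each tree's leaf
class-1 frequency — smoother than a hard-vote fraction, which matters
because the adaptive policy thresholds this probability against a uniform
draw. Hyperparameters are selected by 5-fold cross-validated accuracy at a
0.5 threshold; folds are a seeded uniform shuffle without stratification;
ties go to fewer trees, then smaller depth (parsimony). Cross-validated
held-out accuracy is the reported figure of merit (rather than
refit-on-all accuracy). Single-class training data yields a constant
model; this keeps degenerate synthetic configurations well-defined.

## Agents

Cooperative ≡ closeness solution; greedy ≡ all discs to self (its payoff
is ≥ the opponent's on every board, with equality iff the opponent
concedes nothing). The dichotomous agent cooperates iff the opponent's SVO
is **strictly** above 22.5°; the boundary case plays greedy. The adaptive
agent plays focal iff `P_FP > X` with `X ~ U[0, 1]`; ties (`P_FP ≤ X`) go
to greedy. Draws are independent across games within a session. The
closed-form evaluator
`E = P_FP·profit_focal + (1 − P_FP)·profit_greedy` is affine in `P_FP` and
is verified against a 10,000-draw Monte Carlo within 3 standard errors.

## Synthetic world

No human data ships with the package, so a synthetic world stands in for
the two cohorts. What it does and does not emulate:

* **Population.** 93 players (41 blue / 52 orange; the training cohort is
  38 players on 10 random boards each → 380 observations). SVO angles are
  an equal-weight two-component normal mixture, individualistic
  5° ± 8 and prosocial 32° ± 6, straddling the 22.5° convention. Real SVO
  distributions are not published for these cohorts; the mixture shape is
  a package choice, config-exposed.
* **Choice model.** P(focal) is logistic in the six features:
  `logit P = b0 + b_svo(svo − 22.5) + b_fpp(fpp − 2) + b_pos·pos +
  b_erp(erp − 0.5)` with defaults b0 = −0.3, b_svo = 0.05, b_fpp = 1.8,
  b_pos = 1.0, b_erp = 3.0. Focal play rises with prosociality and with
  board salience; dominant positions and larger expected shares also favor
  it.
* **Non-focal behavior.** A non-focal player assigns each disc to their
  own square independently with probability `self_bias` (default 0.5 —
  uncoordinated ad-hoc play; 1.0 would be perfect greed). This default is
  load-bearing: if non-focal opponents were *perfectly* greedy, the
  cooperative policy would weakly dominate every other policy pointwise
  (vs a focal opponent it earns `own` against greedy's `own − 0.2·opp`;
  vs a greedy opponent `−0.2·own` against greedy's `−0.2·total`), and no
  adaptive or greedy policy could ever beat it on average. Real non-focal
  humans are not perfectly greedy, and modeling them as noisy makes the
  strategic trade-off the agents are designed around actually exist in
  the synthetic world.

The default coefficients were fixed by a closed-form expected-payoff
analysis of the tournament design (the per-board expected profits of all
four policies are linear in P(focal), so policy orderings can be computed
without simulation) to place the synthetic world in the regime where
personality and board structure are both informative and the adaptive
policy's mixture is profitable. They were frozen before the empirical
checks and are exposed in `ChoiceModelConfig` for sensitivity analyses.
Passing tests therefore show internal consistency of model, agents and
tournament on a plausible synthetic world — not that these effect sizes
hold for human players.

## Evaluation set

The 10-board tournament set must give each player a 4 dominant / 4 weak /
2 equal position mix and exactly 52 points under mutual focal play. The
seeded search: (1) rejection-sample random boards until four are dominant
for P1; (2) greedily nudge disc values (±1 within 1–5, preserving
dominance) until the remainder 52 − Σtotals is attainable; (3) mirror the
four boards across the vertical midline — with mirror-symmetric square
placement this swaps roles exactly, yielding the four weak boards and
making the two players' totals automatically equal; (4) construct two
mirror-symmetric "equal" boards from value-matched cell pairs to absorb
the remainder; (5) shuffle the ten boards. The search is budgeted
(`max_iter` candidate draws, default 20,000; a zero budget raises
immediately) and reports its best residual on failure. Typical runtime is
well under a second.

## Tournaments

Opponent behavior is frozen per (opponent, board) before any agent plays,
from a stream keyed by (seed, opponent index) only — every policy faces
byte-identical opponents, so between-policy differences are attributable
to policy. The agent replaces each side in turn (blue vs the 52 orange
players, orange vs the 41 blue). The adaptive agent's session score is its
closed-form expected total against the frozen opponent assignments, which
removes draw noise from policy comparisons; realized totals are recorded
alongside. The synthetic human-vs-human baseline, when wanted, is
all-vs-all rather than randomly paired.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.Generator` with explicit
  integer seeds; no global state.
* Equidistance and exact-half tests use integer arithmetic (see above).
* Quartiles use numpy's linear interpolation.
* Problem sizes in the test suite: 10,000-draw Monte Carlo checks for
  binomial and payoff-mixture properties (3σ bounds), n = 2000 for
  calibration (binned MAE < 0.1), 380-row study-shaped datasets for CV
  shape checks, and small tree grids for hyperparameter-selection tests.

## Known limitations

* Non-focal play is a single-parameter Bernoulli disc allocation;
  systematic partial strategies (e.g. value-ordered concessions) are not
  modeled.
* The choice model is logistic and additive in the six features; real
  decision processes need not be.
* No learning or reciprocity across games (one-shot by design); no >2
  players, non-square grids, or penalty-size sweeps (the penalty is a
  config parameter only).
* The confusion tables of the original human-cohort model are reproduced
  only as arithmetic identities on their printed counts; the underlying
  human data is not deposited, so those accuracies are not recomputable
  from scratch.
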