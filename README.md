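# bargaining-table

Tools for studying **divergent-interest tacit coordination**: the
Bargaining Table game, a behavioral model of focal-point play driven by
Social Value Orientation (SVO), and a stochastic adaptive agent that uses
that model to decide when to cooperate and when to play selfishly.

## The game

Two players face a 9 × 9 grid with one blue square (player 1), one orange
square (player 2) and 1–8 discs worth 1–5 points each. Without
communicating, each player assigns *every* disc to one of the two squares.
A disc pays its value to a player only when **both** assignments agree on
that player; on a disagreement both players lose a penalty of 20 % of the
disc's value. The natural focal (Schelling) point is the *closeness rule*:
give each disc to the nearer square.

For a disc *d* and squares *r₁*, *r₂*, focal-point prominence is

```
FPP(d) = max(D(r1, d), D(r2, d)) / min(D(r1, d), D(r2, d))
```

with `D` the Euclidean distance; FPP = 1 means no focality, and on the
default geometry the attainable range over legal cells is exactly [1, 7].
Six predictors — board FPP, the player's expected revenue proportion under
mutual focal play (ERP), strategic position (+1/0/−1), total points, disc
count and the player's SVO angle — feed a bootstrap-aggregated ensemble of
depth-bounded decision trees whose output is `P_FP`, the probability that
the player implements the focal solution.

The **adaptive agent** predicts the opponent's `P_FP`, draws
`X ~ U[0, 1]`, and plays the focal solution iff `P_FP > X`, otherwise the
greedy (all-discs-to-self) solution. Its long-run payoff per board is the
mixture `P_FP · profit_focal + (1 − P_FP) · profit_greedy`. It is compared
against always-cooperative, always-greedy, and *dichotomous* (cooperate
iff the opponent's SVO > 22.5°) policies in round-robin tournaments over a
constrained 10-board evaluation set against a synthetic 93-player
population (41 blue, 52 orange).

## Worked example

```
$ bargaining-table generate-eval-set --seed 0 --out eval.json
wrote evaluation set to eval.json (focal totals: 52/52)

$ bargaining-table evaluate-agents --seed 0 --out results.csv
cooperative  mean session score    34.49
greedy       mean session score    36.58
dichotomous  mean session score    36.78
adaptive     mean session score    38.27
wrote 372 session rows to results.csv
```

The first command builds the 10-board evaluation set: each player is
dominant on 4 boards, weak on 4 and equal on 2, and mutual focal play
yields exactly 52 points to each side. The second runs all four policies
against the same frozen synthetic opponents (a paired design: identical
opponent behavior for every policy) and prints each policy's mean
accumulated payoff per 10-board session. The adaptive agent's score is its
closed-form expected total; here it tops cooperative, greedy and
dichotomous play, because it cooperates against players and boards where
coordination is likely and defects where it is not.

`bargaining-table simulate-players` and `train-model` expose the
synthetic-cohort generator (38 players × 10 random boards → 380 labeled
observations) and the ensemble fit, and `report` summarizes a results CSV.

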