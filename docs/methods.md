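# Methods

## The model

The stage game is a one-shot public goods game with punishment. A group
of N players, each endowed with E monetary units (MU), contributes
c_i ∈ [0, E]; the pool is multiplied by r and shared equally, so each
contributed MU returns r/N per capita. The social-dilemma condition
1 < r < N is enforced at construction. In the punishment stage, a player
with propensity α spends α·max(c_i − c_j, 0) MU on each group mate who
contributed strictly less; the target loses e times that amount (e > 1).
Punishment of equal or higher contributors is excluded — "anomalous
punishment of cooperators" is outside the linear norm the model studies.

P&L and relative fitness:

    π_i = −c_i + (r/N)·Σ_k c_k − e·Σ_{j≠i} α_j·(c_j − c_i)⁺ − Σ_{j≠i} α_i·(c_i − c_j)⁺
    u_i = Σ_{j≠i} (π_i − π_j)

u is zero-sum within the group by construction; both identities are
checked on random profiles in the test suite. Contributions are
real-valued in the theory modules (the optimization calculus presumes a
continuum); integer rounding is a synthetic-data option. Punishment
expenditures are not capped by the remaining endowment in the theory
modules — the closed forms are exact without a cap — while the generator
offers an optional cap.

A lone deviator shifting her contribution by dc against a homogeneous
norm (everyone sharing α) changes her relative fitness piecewise
linearly:

    dc < 0:  (N−1)·|dc|·(1 − α((N−1)e − 1))
    dc > 0: −(N−1)·dc·(1 + α(N−1−e))

The downward branch flips sign at the bifurcation propensity
α_b = 1/((N−1)e − 1). Both branches are validated against brute-force
payoff evaluation on explicit profiles.

## Beliefs and expected utility

An agent holds a first-order belief Q over another member's
contribution. The canonical representation is a discrete atom grid
(lab contributions are integer MU); survival S̄(c) = P(X > c) uses the
strict inequality, and the median is the smallest support value with
CDF ≥ 1/2 (deterministic, order-independent tie-break). Continuous
uniform and truncated-normal families are provided because the
closed-form propensity results presume a smooth survival function; the
uniform family has closed-form partial expectations and serves as the
oracle in the α\*(S̄) equivalence tests.

Expected utility of contributing c under the common norm α is the
belief-expectation of relative fitness; with t₊(c) = E(X−c)⁺,
t₋(c) = E(c−X)⁺ and D = E(X−Y)⁺ for independent X, Y ~ Q:

    U(c) = (N−1)[ −c + EX − eα(N−1)t₊ − α(N−1)t₋ + eαt₋ + αt₊ + (e+1)α(N−2)D ]

The D term is independent of c; it is included in reported utility
values and provably never moves the argmax (asserted in tests, and
exposed as a switch). Setting dU/dc = 0 at a contribution with survival
S̄ gives

    α\*(S̄) = 1 / [ S̄(N−2)(e+1) + e − N + 1 ]

with α\*(1) = α_b and α\*(1/2) = α_c = 2/(N(e−1)), the coordination
optimum — the unique α making deviation losses symmetric in ±dc. When
the denominator is non-positive (possible for e < N−1 and small S̄) no
finite propensity stabilizes that contribution and the function raises
rather than returning a number.

The contribution optimizer is derivative-free — a coarse grid (step
E/400) plus bounded golden-section refinement — because grid-belief
utilities are piecewise linear with kinks at atoms. The reported FOC
residual is zero whenever the numeric left/right derivatives bracket
zero (the sub-differential contains 0, the correct optimality
certificate at a kink); tolerance 1e−6 MU/MU otherwise. Boundary optima
are flagged, not errors.

## Replicator dynamics

The population is a frequency measure ν over a grid of strategies
(dc, α). Strategy payoff is the lone-deviator kernel above, evaluated
against a *fixed* norm: the frequency-weighted median of the initial
contribution marginal. This is the Black's-theorem coordination point —
with efficient punishment the best reply is the believed median, and
beliefs do not update in the one-shot strong-mixing setting, so the
norm is frozen at the start of a run. A deviator below the norm is
punished at the population-mean propensity; one above it spends at her
own. Success is σ(s) = u(s) − ū; the ν-weighted mean success is exactly
zero.

Integration is explicit Euler on normalized frequencies,
ν ← ν(1 + dt·σ), renormalized each step, with a guard that raises a
step-size error before any frequency can turn negative (dt must stay
below 1/max|σ|). Mutation, when enabled, diffuses 1% of the mass per
step through a Gaussian kernel on the dc grid, column-renormalized so
mass reflects off the grid bounds; the kernel is a deterministic
convolution, so trajectories are reproducible without a seed (the seed
argument is accepted for interface stability).

The viability floor — the smallest sustainable mean contribution given
a per-period subsistence cost c_m — is c_floor = c_m/(r−1), the
homogeneous contribution whose net payoff covers c_m; an alternative
reading N·c_m/r is selectable. The grid is constructed on
[c_floor, E], which implements the floor as a reflecting lower bound.

Regimes: for α ≤ α_b (boundary inclusive: coordination needs the strict
inequality) the attractor is the floor; above α_b it is the initial
median — verified by simulation, including a skewed-start check that
the attractor is the median, not the mean. The acceptance scan uses a
400-point α grid on [0, 0.3] and a 400-point contribution grid with 800
Euler steps at dt = 0.01 (t = 8): the modal-strategy classification is
sharp because the floor strategy has the strictly highest payoff for
every α below the threshold and the median strategy for every α above
it, so the simulated switch brackets 0.125 to one grid step.

## Preferences and invasion

The selfish predicate (own P&L did not decrease) and the DIA predicate
(negation of the two dislike cases) are parameter-free. Their implied
propensity ranges come from the explicit one-deviator transition:
selfish agents tolerate punishment only up to
(1 − r/N)/((N−1)e) < α_b; DIA cooperators facing a lone defector are
satisfied exactly for α > α_b. "Average utility of the remaining group
members" is the arithmetic mean of their P&L, consistent with the
pairwise-sum fitness structure.

The invasion analysis puts n_s selfish agents (norm contribution,
propensity α_s, default 0) and n_d DIA agents (propensity α_d, default
the coordination optimum of the whole population) into one mixed game
of size n_s + n_d with cross-group punishment. The DIA contribution
deviates by ±δ from the selfish norm, negatively with probability p.
Per-capita P&L differences (pool returns cancel):

    D(−) = δ(1 − α_s(e·n_s − n_d))      D(+) = δ(−1 + α_d(e·n_d − n_s))

validated against explicit payoff-engine evaluation on the mixed
profile. Expected success is p·D(−) + (1−p)·D(+), and
p_min = max(0, −D(+)/(D(−) − D(+))) when D(−) > D(+); p_min returns 0
when D(+) ≥ 0, a no-invasion signal when both branches lose, and raises
on the degenerate D(−) = D(+). The takeover Monte Carlo is a
birth–death process: one conversion per period toward the group with
strictly higher per-capita P&L, ties converting nobody (neutral drift
deliberately unresolved), DIA propensity re-derived from the (fixed)
total population size, absorption when a group is extinct; replicates
unabsorbed after 100 000 periods count as failures.

## Estimation pipeline

Each punishment record with positive deviation d = c_punisher − c_target
yields a realization α̂ = expenditure/d; zero-expenditure pairs with
positive deviation are genuine decisions and count as 0 (a sensitivity
switch excludes them); non-positive deviations are excluded and logged
row by row. Estimates pool across sessions and treatments by default.

The median's SE comes from b_outer bootstrap resamples; the bootstrap-t
interval studentizes each outer median by a nested SE from b_inner
resamples (default) or a delete-one jackknife. The documented defaults
are b_outer = 10 000, b_inner = 200; the test and acceptance runs use
b_outer = 400, b_inner = 40, which the coverage study shows is already
well calibrated (≥ 90% empirical coverage at the 95% level over 200
repetitions). The jackknife pivot is offered for comparison but is
known to be unstable for medians (near-zero jackknife SEs inflate the
pivot); only its contract is tested. Degenerate (constant) samples give
SE 0 and a point interval.

The stationarity check is a two-sample KS test of period-1 realizations
against the full sample, exactly mirroring the empirical procedure —
including the fact that period 1 is contained in the full sample. That
overlap shrinks the statistic by the factor (1 − q) (q the period-1
mass share) while the critical value shrinks less, and MU discreteness
adds ties, so the test is structurally conservative: the measured
type-I error across 200 seeds sits well below the 5% nominal rate, and
the calibration check asserts it never exceeds 10%. scipy's
`ks_2samp` (plain ECDF sup-distance, asymptotic p-value) is used as the
field-standard implementation.

The punishment curve bins positive deviations (default width 1 MU),
reporting per-bin mean expenditure, SE (missing below 2 records) and
count — empty bins are reported, not dropped — plus the
origin-constrained least-squares slope Σds/Σd², unbiased under
symmetric noise.

## Synthetic data

The generator emulates the lab designs the estimation pipeline targets:
groups of 4, endowment 20 MU, per-capita return 0.4 (r = 1.6),
punishment efficiency 3, stranger (uniform re-randomized groups each
period; the "no repeated partners" refinement is not modeled) or
partner treatment, 6–10 periods typical (defaults: 24 subjects, 10
periods). Contributions are i.i.d. truncated normal, mean 10, sd 5 on
[0, 20], rounded to integer MU — a stand-in for unpublished empirical
contribution distributions. Punishment follows the linear norm with
slope alpha_true (default 0.25, the coordination optimum of the default
game) plus additive N(0, σ) noise, σ = 0.5 MU, clamped at zero (an
optional cap and a multiplicative-lognormal noise model exist). The
clamp censors only values below zero — all below the true slope — so
the realization *median* stays exactly alpha_true as long as less than
half the mass is censored; this is why median recovery is unbiased
under the default noise.

What the generator does not emulate: conditional cooperation, learning
and contribution dynamics over periods (realizations are i.i.d. across
periods by construction — stationarity holds exactly, which is what the
KS calibration study needs), punishment of cooperators, and the first
cited experiment's payoff-dependent punishment efficiency (approximated
by the constant factor 3). Passing tests therefore show the pipeline
recovers the norm when the linear-punishment model is true; they cannot
show the model is true of real subjects.

## Problem sizes and numerical choices

Simulation sizes in the shipped tests are chosen to make each check
statistically decisive at interactive runtimes: 100–200 random
configurations for closed-form/oracle equivalences (tolerances 1e−6
analytic, 1e−9 algebraic identities), 400×400 grids for the bifurcation
scan, 200 repetitions × ~1100 pairwise observations for the coverage
study, 200 seeds for KS calibration, 500 replicates for the takeover
probability. All randomness flows through explicit integer seeds;
reruns are bit-identical.

## Known limitations

* The replicator module evolves contributions at a fixed punishment
  propensity (or propensities frozen on the grid); full two-trait
  co-evolution with per-agent birth/death bookkeeping is out of scope.
* The invasion closed forms assume both groups internally homogeneous
  and exactly one mixed game per period; group-size weighting of
  success and a selfish propensity at its upper bound are exposed as
  parameters rather than fixed.
* The bootstrap-t interval is clamped to contain the sample median,
  which the raw pivot does not guarantee in pathological resamples.
* Beliefs are exogenous: no updating across periods, no higher-order
  beliefs.
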