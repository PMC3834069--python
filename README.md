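# pggpunish

Evolutionary expected-utility analysis of public goods games (PGG) with
altruistic punishment: why do people in one-shot lab games pay to punish
free-riders, and why at the specific rate they do?

The package is for researchers in evolutionary game theory and
experimental economics who want a tested, reusable implementation of the
full analysis chain:

* the stage game — N players with endowment E contribute c_i ∈ [0, E],
  the pool is multiplied by r (< N, > 1) and shared; punishers spend
  α·(c_i − c_j) MU on each group mate contributing less, inflicting
  e-fold harm;
* relative fitness u_i = Σ_{j≠i}(π_i − π_j), exactly zero-sum per group;
* subjective expected utility over first-order beliefs about others'
  contributions, with the closed-form optimal punishment propensity
  α\*(S̄) = 1 / [S̄(N−2)(e+1) + e − N + 1], where S̄ is the believed
  survival probability P(X > c);
* the two organizing propensities: the **bifurcation**
  α_b = 1/((N−1)e − 1) = α\*(1), below which defection pays, and the
  **coordination optimum** α_c = 2/(N(e−1)) = α\*(1/2), the unique rate
  making up- and downward deviation losses symmetric, which sustains
  coordination on the believed **median** contribution (Black's theorem);
* replicator dynamics on a (Δc, α) strategy grid with a viability floor
  c_m/(r−1) and mutation, reproducing the defection/coordination
  bifurcation numerically;
* selfish vs disadvantageous-inequity-averse (DIA) satisfaction
  predicates and the propensity ranges they imply
  (selfish: α ≤ (1 − r/N)/((N−1)e), strictly below the bifurcation;
  DIA: α > α_b);
* two-group invasion analysis (DIA punishers vs selfish non-punishers):
  branch successes D(±), the minimum deviation probability
  p_min = −D(+)/(D(−) − D(+)), and a birth–death takeover Monte Carlo;
* an estimation pipeline recovering the propensity to punish from
  experiment records — each pairwise interaction with positive deviation
  d gives a realization α̂ = expenditure/d — with the sample median,
  bootstrap-t confidence intervals, a period-1-vs-all KS stationarity
  check and the binned punishment curve;
* a synthetic experiment generator (stranger/partner treatments, 20 MU
  endowment, per-capita return 0.4, e ≈ 3) so the whole pipeline is
  testable without lab data.

## Worked example

```python
import pggpunish as pg

cfg = pg.GameConfig(N=4, r=1.6, e=3.0, E=20.0)      # the standard lab game
print(pg.alpha_thresholds(cfg))                      # (0.125, 0.25)

# three cooperators, one defector, everyone punishing at the optimum
res = pg.payoffs(pg.Profile([20, 20, 20, 0], [0.25] * 4), cfg)
print(res.pl)        # [ -1.  -1.  -1. -21.]
print(res.fitness)   # [ 20.  20.  20. -60.]

# closed loop on synthetic data: generate, estimate, compare to theory
spec = pg.SyntheticSpec(n_subjects=40, periods=20, alpha_true=0.25, seed=12)
report = pg.run_pipeline(spec, b_outer=400, b_inner=40)
print(round(report["alpha_median"], 3))              # 0.25
print(round(report["alpha_coordination"], 3))        # 0.25
print(report["regime_of_median"])                    # coordination
```

The bifurcation/coordination pair (0.125, 0.25) says: in a 4-player game
with punishment efficiency 3, punishing less than 0.125 MU per MU of
negative deviation leaves free-riding profitable, while 0.25 — the rate
the estimation pipeline recovers from data generated at that norm — makes
deviations in either direction equally costly and stabilizes cooperation
at the group's believed median contribution.

The same analyses are available from the shell:

```bash
pgg thresholds --config game.yaml
pgg synth --out-dir data/ --seed 3
pgg estimate --contributions data/contributions.csv --punishments data/punishments.csv
pgg invade --config game8.yaml --n-selfish 4 --n-dia 4 --p-neg 0.5
```

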