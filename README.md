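# cheatcycles

Simulator and analysis toolkit for cheat–cooperator eco-evolutionary
dynamics. Two strains — a cooperator growing logistically and a cheat whose
growth rate is rescaled by a benefit coefficient `h` and by two sigmoid
modifiers (one increasing with cooperator *density*, weight `a`; one with
cooperator *frequency*, weight `b`) — are simulated in three settings:

1. **Chemostat** (`scenario1`): one uninterrupted growth phase. With equal
   between-strain regulation every state on `N_co + N_ch = K` is stationary,
   so dynamics always reach an equilibrium cheat proportion.
2. **Serial passage** (`scenario2`): growth for `Tgrow` time units followed by
   instantaneous dilution of both strains by `D`, repeated for many cycles.
   With strong density dependence (`a ≈ 1`) the cheat proportion settles into
   a stable *within-cycle* oscillation; frequency dependence alone never
   oscillates. The summary statistic is the stabilized amplitude
   (max − min cheat proportion after a burn-in).
3. **Stochastic metapopulation** (`scenario3`): `M` subpopulations grow
   deterministically, then are partially mixed by `round(F·M)` random pairwise
   pooling events and passed through a bottleneck, with counts kept as
   integers (binomial sampling by default). Demographic stochasticity plus
   density dependence produces noisy *cross-cycle* oscillations that attenuate
   as `M`, `K`, or `F` grow.

The analysis stack quantifies periodicity with per-period harmonic regression
(OLS sine/cosine fit, delta-method 95% CIs, peak period) and with the DFT
amplitude of the mean-centered per-cycle series, plus grid sweeps over
`(a, b)` with replicate averaging.

## Parameter defaults

Defaults (`r=1, K=10, alpha=1, h=4.5, s_d=20/K, t_d=K/5, s_f=10, t_f=0.5,
D=10, Tgrow=10`; metapopulation `M=50, K_sub=40, F=2`) are repository
calibrations chosen so the focal density-dependence-only setting sits inside
the oscillating regime: within-cycle amplitude ≈ 0.23, cross-cycle
quasi-period 10–20 growth cycles, and mean cheat relative fitness between
1 and 1.5. The density threshold `t_d` must lie between the post-bottleneck
density `K/D` and `K` for selection on cheats to switch sign within a growth
phase; every default is overridable via config file or CLI flag.

## CLI

```bash
cheatcycles scenario1 --a 1 --b 0 --duration 100 --out runs/s1
cheatcycles scenario2 --a 1 --b 0 --d 10 --tgrow 10 --cycles 200 --out runs/s2
cheatcycles scenario3 --a 1 --b 0 --m 50 --f 2 --cycles 200 --seed 1 --out runs/s3
cheatcycles sweep --scenario 3 --a-grid 0:1:6 --b-grid 0:1:6 --replicates 10 --out runs/sweep
cheatcycles analyze --input runs/s3/cycles.csv --column global_p_cheat \
    --method harmonic --periods 2:75 --out runs/fit.csv
```

Every run writes tidy CSV output plus a JSON sidecar with the full parameter
set and seed, so it can be reproduced exactly. A YAML config can replace the
flags (`--config run.yaml`); flags win on conflict. Minimal config example:
`{scenario: 2, a: 1, b: 0}`.

## Package layout

| module | contents |
| --- | --- |
| `cheatcycles.core_model` | modifiers, derivatives, ODE integration, vector field |
| `cheatcycles.serial_passage` | dilution bottlenecks, cycle records, stabilized amplitude |
| `cheatcycles.metapopulation` | subpopulation growth, pairwise mixing, integerization, relative fitness |
| `cheatcycles.analysis` | harmonic regression, DFT amplitude, grid sweeps |
| `cheatcycles.fixtures` | synthetic sinusoid / logistic series for testing |
| `cheatcycles.config`, `cheatcycles.io`, `cheatcycles.cli` | YAML/JSON config, CSV output, command line |
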