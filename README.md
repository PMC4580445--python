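# nichesim

Stochastic simulation of breast cancer stem cell (BCSC) niche dynamics:
a mass-action reaction-network model of the cytokine/receptor signaling
that regulates the switch between mesenchymal (EMT-like, quiescent) and
epithelial (MET-like, proliferative) stem-cell states, plus the tools that
turn it into quantitative results — an exact Gillespie simulator, a
step-anticipation tau-leaping (SAL) engine, two-state Markov-chain rate
estimation, a carcinogenesis hierarchy with Gompertz growth fitting, and
in-silico inhibition screens.

## What's inside

| module                    | contents                                                        |
|---------------------------|-----------------------------------------------------------------|
| `nichesim.network`        | species/reaction/network types, mass-action propensities, conserved-moiety detection, YAML/JSON/SBML-style XML round-trip |
| `nichesim.niche`          | the built-in 32-species, 37-channel BCSC niche model            |
| `nichesim.sal`            | exact SSA, SAL tau-leaping, hybrid stepper, vectorized ensembles, mean-field (RRE) integrator |
| `nichesim.transitions`    | two-state EMT/MET chain: equilibria from marker fractions, detailed-balance completion, exponential rate fitting |
| `nichesim.carcinogenesis` | BCSC → progenitor → terminal-cell hierarchy with a time-varying division schedule |
| `nichesim.gompertz`       | Gompertz law evaluation and nonlinear least-squares fitting      |
| `nichesim.screen`         | inhibition targets, single/pairwise screens, extinction frequencies, rankings, sensitivity sweeps |
| `nichesim.synthetic`      | seeded synthetic-data generators and small fixture networks with closed-form moments |
| `nichesim.cli`            | `nichesim` command-line interface                                |

Modeling assumptions, parameter provenance, and numerical methods are
documented in [docs/methods.md](docs/methods.md).

## Quickstart

Estimate transition rates from marker equilibria:

```python
from nichesim import complete_rates, equilibrium_from_marker_fractions

eq = equilibrium_from_marker_fractions(0.008, 0.003)
print(round(eq.pi_emt, 2))            # 0.73 — mesenchymal-state occupancy

rates = complete_rates(eq, lambda_met=0.08)
print(round(rates.lambda_emt, 3))     # 0.213 /day via detailed balance
```

Simulate the niche and screen inhibitions:

```python
from nichesim import (LeapSettings, build_niche_model, rank_combinations,
                      run_screen)

net = build_niche_model()
result = run_screen(net, mode="pairwise", horizon_days=1000.0, reps=100,
                    seed=0)
for row in rank_combinations(result)[:3]:
    print(row["condition"], row["extinction_total"])
# HER2+IL6 ranks first, with nonzero total-BCSC extinction by day 1000
```

Run the 12-year carcinogenesis ensemble and fit the growth law:

```python
from nichesim import build_growth_model, fit_gompertz, simulate_growth

model = build_growth_model()
summary = simulate_growth(model, years=12.0, reps=24, seed=1234)
fit = fit_gompertz(summary.times, summary.total().mean(axis=0))
print(f"c = {fit.params.c_decay:.5f}/day, R^2 = {fit.r_squared:.3f}")
# c = 0.00148/day, R^2 = 0.996, asymptote ~1.3e9 cells
```

The same workflows are available from the command line:

```bash
nichesim simulate --reps 100 --t-final 1000 --seed 0 --output runs/baseline
nichesim screen --mode pairwise --reps 100 --seed 0 --out-dir runs/screen
nichesim simulate-growth --years 12 --reps 24 --seed 0 --output runs/growth
nichesim make-synthetic --generator marker-series \
    --params '{"rate": 0.08, "n": 20}' --seed 0 --out data/marker.csv
```

## Testing

```bash
pytest tests -q
```

The suite covers worked examples with hand-derived values, closed-form
oracles on fixture networks (linear birth–death moments, dimerization
moiety conservation, two-state occupancies), seeded property-based tests,
and statistical equivalence of the leaping engine against the exact SSA.
`tests/test_acceptance.py` holds the release criteria, including
large-ensemble (n = 1000) oracle-equivalence checks and the qualitative
inhibition-screen orderings at 100 replicates.

One acceptance criterion is currently red by design honesty rather than
silently re-tolerated: the Gompertz decay parameter fitted to the
12-year carcinogenesis ensemble comes out ≈ 0.00148/day against a
0.00133/day reference with a pre-registered ±10% tolerance. See
[docs/methods.md](docs/methods.md) §3 for the structural analysis.

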