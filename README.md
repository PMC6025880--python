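# amvoi — value of information for adaptive resource management

`amvoi` answers a question managers of natural resources ask constantly and
rarely get answered: *is more monitoring or experimentation worth it?* It
implements optimal **active and passive adaptive management** for systems
whose dynamics are structurally uncertain — a finite Markov decision
process with `K` rival transition models `P_k(x'|x,a)` and a Bayesian
belief `q` over them — and prices information against the management
objective itself:

- **EVPI** (expected value of perfect information):
  `Σ_k q(k) V_k[x] − V[x,q]` — the most that resolving model uncertainty
  could ever be worth;
- **EVSI** (expected value of sample information) of an external datum `z`
  with model-specific law `P_k(z)`, by preposterior analysis:
  `Σ_z P̄(z|q) V[x, q'(z)] − V[x,q]`;
- the **marginal value of monitoring frequency**: optimal policies when the
  state is observed only every `m` years (out-year actions committed at the
  last observation), and the per-state gain or loss
  `V[x,q] − V̄[x,q,a*]` from observing annually instead.

Values are computed by stochastic dynamic programming over (state × belief)
with the belief simplex discretized on a regular lattice and barycentric
interpolation; beliefs update by Bayes' rule inside the backup (active
mode), so the solver prices learning itself. A forward Monte-Carlo
simulator replays solved policies under a chosen "true" model for
policy and monitoring-scheme comparison.

The package is written for quantitative ecologists and decision analysts;
the shipped example mirrors prescribed-fire management of Florida scrub for
scrub-jay habitat (five scrub height/openness classes, do-nothing vs
routine vs intensive burn, and a null model saying the intensive burn is
not worth its extra cost). The published transition estimates are not
redistributable, so the packaged fixture is a clearly-labelled synthetic
stand-in with the same structure; see `docs/methods.md`.

## Worked example

```python
import amvoi

problem, signal, period = amvoi.load_scrubjay_synthetic()
grid = amvoi.build_belief_grid(2, 0.01)

report = amvoi.monitoring_report(problem, grid, [0.0, 0.5, 1.0], period=2)
print(report.round(2).to_string(index=False))

evpi = amvoi.evpi_surface(problem, grid, as_percent=True)
print("max EVPI as % of value:", round(evpi.evpi_percent.max(), 3))
```

```
 state   q  annual_action  annual_value  outyear_action  outyear_value  evsi
     1 0.0              1        392.43               1         392.42  0.00
     2 0.0              3        391.87               1         392.32 -0.45
     3 0.0              1        393.95               1         393.14  0.80
     4 0.0              3        392.22               1         392.41 -0.20
     5 0.0              3        391.85               1         392.30 -0.45
     1 0.5              1        308.61               1         308.57  0.05
     2 0.5              3        307.96               1         308.37 -0.40
     3 0.5              1        310.14               1         309.39  0.75
     4 0.5              3        308.33               3         308.22  0.11
     5 0.5              3        307.89               3         308.30 -0.40
     1 1.0              1        226.41               2         226.32  0.09
     2 1.0              2        225.65               2         225.86 -0.21
     3 1.0              2        227.99               2         227.21  0.79
     4 1.0              2        226.04               2         226.00  0.04
     5 1.0              2        225.46               2         225.67 -0.21
max EVPI as % of value: 0.384
```

Each row is one (scrub state, null-model probability `q`) pair: states are
1 short-open … 5 tall-mix, actions 1 do-nothing / 2 routine burn /
3 intensive burn. `annual_value` is the optimal 2000-year cumulative
return with annual monitoring; `outyear_value` is the averaged value
attainable in a year the state goes unobserved under biennial monitoring,
and `evsi` (their difference) is the marginal value of observing that
year — note it is *negative* for several states: skipping an observation
sometimes costs nothing because an average of optima can exceed the
optimum of the particular state realized. The intensive burn (action 3)
appears only for the fire-resistant classes (2, 4, 5) and never once the
null model is certain (`q = 1`), and eliminating model uncertainty
entirely would improve the objective by at most 0.38% — monitoring design,
not model discrimination, is where the value lies in this system. (These
numbers come from the synthetic fixture and are illustrative of the
method, not of the real system.)

A command-line interface wraps the same calls:

```sh
amvoi validate   --problem scrub.yaml
amvoi solve      --problem scrub.yaml --mode active --grid-step 0.01 --out out/
amvoi voi        --problem scrub.yaml --out out/
amvoi monitoring --problem scrub.yaml --period 2 --out out/
amvoi simulate   --problem scrub.yaml --true-model 1 --replicates 100 --out out/
amvoi make-scenario --kind scrubjay-synthetic --out scrub.yaml
```

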