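# beebloom

Dynamics of a wind-stressed blooming-plant / honeybee / honey-production
model.

The package implements a three-compartment ODE in which plant density
`p`, honeybee density `h`, and the standing amount of honey `n` are
coupled by a Beddington–DeAngelis mutualism that wind attenuates:

```
dp/dt = r1 p (1 - p/k1) + alpha1 h p / D - gamma1 p
dh/dt = r2 h (1 - h/k2) + alpha2 h p / D - gamma2 h
dn/dt = alpha3 h / (1 + w + c h) - beta n h - gamma3 n
D     = 1 + w + a h + b p
```

The wind level `w` inflates both interaction denominators, so a single
wind-efficiency factor `1/(1+w)` (equal to 1 in still air) scales the
pollination benefit to plants, the nutrient gain of bees, and honey
production.  Honey is slaved to the populations: it does not feed back
into the first two equations, so the core dynamics are planar.

The package provides:

- **model core** — vector field, analytic Jacobian, a rigorous
  attracting box, and validated parameter handling with a shipped
  baseline parameter set (`beebloom.params.baseline_params()`);
- **equilibria** — closed-form boundary points (extinction, plants-only,
  bees-only with and without honey) and a multi-start nullcline solver
  for the coexistence point, plus a transcription of a circulating cubic
  closed form kept as a cross-check only;
- **stability** — eigenvalue classification, the named sufficient
  inequalities, Lyapunov-based global-stability conditions with an
  empirical descent check, and the closed-form bounds/persistence
  floors (with an honest caveat: see `docs/methods.md`);
- **bifurcation** — transcritical detection by det(J) bisection with
  Sotomayor nondegeneracy scalars, and Hopf machinery that correctly
  reports that no Hopf point exists for this model (see
  `docs/methods.md`);
- **dynamics** — stiff-capable trajectory integration, attractor
  classification (point / cycle / aperiodic / boundary-collapse), and
  parameter sweeps;
- **sensitivity** — Latin-hypercube PRCC of the coexistence coordinates
  against all fifteen parameters;
- a `beebloom` CLI wrapping all of the above.

## Worked example

Write the shipped baseline parameters to a file and explore the model:

```sh
python -c "
from beebloom.params import baseline_params, save_params
save_params(baseline_params(), 'baseline.params')
"
beebloom equilibria --params baseline.params
```

```
S1: (p=0, h=0, n=0) exists=True residual=0
S2: (p=9.28571, h=0, n=0) exists=True residual=4.44e-16
S3: (p=0, h=5, n=0) exists=False residual=0.0123
S4: (p=0, h=5, n=1.27934) exists=True residual=5.55e-17
S5: (p=11.0829, h=11.4783, n=1.40736) exists=True residual=3.89e-16
```

Note `S3` (bees with zero honey): it is reported but flagged
non-existing, because with a positive honey-production rate the honey
equation is strictly positive at `n = 0`; the genuine bees-only
equilibrium is `S4`.

```sh
beebloom stability --params baseline.params --point S5
```

```
S5: stable node | eigen-real-parts=-0.01982, -0.3014, -0.6807
```

```sh
beebloom bifurcate --params baseline.params --param r2 --range 0.001 0.2 --type tb
```

```
transcritical at r2=0.03 (S1)
```

The extinction point changes stability exactly at `r2 = gamma2 = 0.03`
(and, tracking the plant-only point over `r1`, at `r1 = gamma1 = 0.04`).

```sh
beebloom simulate --params baseline.params --init 1,1,1 --tend 5000
```

```
attractor: point; final state (p=11.0829, h=11.4783, n=1.40736)
```

The same pipeline is available from Python:

```python
from beebloom import baseline_params, rhs
from beebloom.equilibria import find_coexistence

theta = baseline_params()
eq = find_coexistence(theta, seed=0)[0]
print(eq.state)        # [11.08288515 11.47830327  1.4073645 ]
print(max(abs(rhs(eq.state, theta))))  # ~4e-16
```

Other subcommands: `sweep` (simulate-and-classify over a parameter
grid, CSV export), `prcc` (sensitivity coefficients, CSV export).  All
commands accept `--seed` and `--log-level`; every random draw in the
package flows from the single user-supplied seed.

## Tests

```sh
python -m pytest -q tests/
```

The suite contains unit, property, and acceptance tests.  Two
acceptance tests fail by design, documenting claims that are not true
of the model as written down (no Hopf bifurcation exists anywhere in
parameter space, and the closed-form bounds box is not invariant under
the flow); `docs/methods.md` gives the analysis.
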