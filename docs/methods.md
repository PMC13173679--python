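# Methods

This note records the model, the numerical choices, and the analytical
findings behind the package, including two places where widely quoted
closed-form claims about this model do not hold and the package
deliberately reports the honest result instead.

## Model

State `(p, h, n)`: blooming-plant density, honeybee density, standing
honey.  With `D = 1 + w + a h + b p`:

```
dp/dt = r1 p (1 - p/k1) + alpha1 h p / D - gamma1 p
dh/dt = r2 h (1 - h/k2) + alpha2 h p / D - gamma2 h
dn/dt = alpha3 h / (1 + w + c h) - beta n h - gamma3 n
```

The mutualism is of Beddington–DeAngelis type; the wind level `w`
enters additively in both interaction denominators, which is equivalent
to scaling the interactions by the wind-efficiency factor
`theta(w) = 1/(1+w)` with `theta(0) = 1`.  Honey does not feed back
into the populations, so the `(p, h)` subsystem is planar and the third
Jacobian column is `(0, 0, -beta h - gamma3)`.

Baseline parameter set (shipped as `beebloom/data/baseline.params`):
`r1=0.56, k1=10, alpha1=0.04, w=3, a=0.02, b=0.03, gamma1=0.04,
r2=0.18, k2=6, alpha2=0.08, gamma2=0.03, alpha3=0.01, beta=0.00157,
gamma3=0.0018, c=0.01`.

## Equilibria

Boundary points are closed-form.  A subtlety: the bees-only point with
zero honey, `S3 = (0, h2, 0)` with `h2 = k2 (r2-gamma2)/r2`, is *not* a
fixed point whenever `alpha3 h2 > 0` — the honey equation is strictly
positive at `n = 0`.  The package reports it with `exists=False` and a
note; the genuine bees-only equilibrium is `S4 = (0, h2, n3)` with
`n3 = alpha3 h2 / ((1+w+c h2)(beta h2 + gamma3))`.

The coexistence point `S5` is found by multi-start 2-D root finding on
the per-capita nullcline system (seeded Halton starts over the rigorous
attracting box plus the decoupled logistic corner; `scipy` hybrid
Powell, merge tolerance 1e-6, acceptance residual 1e-9).  At the
baseline: `S5 = (11.082885, 11.478303, 1.407365)`.

A cubic resultant for the coexistence plant coordinate circulates in
closed form; its intermediate constants are dimensionally inconsistent
as usually printed.  The package transcribes it as a cross-check
(`coexistence_cubic`, `cross_validate_cubic`) and reports agreement or
disagreement, but never uses it as the authority; at the baseline it
disagrees with the verified nullcline root, confirming the
transcription defect.

## Boundedness: why there are two boxes

The often-quoted bounds `pm = sqrt((r1 + alpha1 k2 - gamma1) k1 / r1)`
(≈ 3.684 at baseline) and the analogous `hm`, `nm` are implemented
verbatim in `stability.compute_bounds` — but they are *not* honoured by
the flow.  Two defects in the usual derivation: a comparison ODE linear
in `p` is treated as if it produced a square-root bound, and the bee
density is capped at its bare carrying capacity `k2` although mutualism
pushes it higher.  Empirically the baseline attractor
(`p ≈ 11.08 > pm ≈ 3.68`) sits far outside the box.

`model.attracting_box` instead uses the interference saturation of the
response (`alpha1 h / D ≤ alpha1/a`, `alpha2 p / D ≤ alpha2/b`), which
yields genuine logistic comparison bounds; the resulting box
(≈ `(45.0, 93.9, 105.6)` at baseline) is verified to be forward
invariant by property tests and is used as the search and sampling
domain throughout.  The acceptance test asserting the closed-form box
is left failing on purpose.

## Stability

`classify_local` uses eigenvalues of the analytic Jacobian
(nonhyperbolicity tolerance 1e-10) and also reports the printed named
sufficient inequalities per point.  Global sufficient conditions are
evaluated literally, with state-dependent expressions required to hold
at every node of a dense grid over the bounding box; the Lyapunov
descent checker samples the box and reports the fraction of states with
`dE/dt < 0` (equal to 1.0 under parameter sets satisfying the
conditions, e.g. heavy depletion `gamma1 = gamma2 = 0.5` with weak
growth and coupling).

## Bifurcations

Transcritical points are detected by bisecting sign changes of
`det(J)` along a parameter for a closed-form-tracked boundary
equilibrium (Brent, xtol 1e-12), then verified by a numeric Sotomayor
test: with right/left null vectors `v`, `t` of the Jacobian, the
scalars `s1 = <t, F_mu>`, `s2 = <t, (dJ/dmu) v>`,
`s3 = <t, D2F(v, v)>` must satisfy `s1 = 0`, `s2 != 0`, `s3 != 0`.
Parameter derivatives and `D2F` are central differences (step
`1e-4 (1 + |x|)` for the second difference, balancing truncation
against rounding at the 1e-6 verification tolerance).  The right null
vector is normalized so that its component in the equation containing
the bifurcation parameter equals one — `s3` is quadratic in `v`, so a
unit-norm choice would not reproduce the standard values
`s3 = -2 r2*/k2` at the extinction point and `-2 r1*/k1` at the
plant-only point.  Crossings whose tracked state leaves the nonnegative
octant (zero eigenvalues of the extended algebraic branch, not of a
model equilibrium) are filtered out by default.

Verified thresholds at baseline: `r2* = gamma2 = 0.03` (extinction
point) and `r1* = gamma1 = 0.04` (plant-only point), with
`s1 = 0, s2 = 1` and `s3 = -0.01 / -0.008` respectively.

### No Hopf bifurcation exists

Substituting the equilibrium conditions into the interior `(p, h)`
Jacobian block gives

```
a11 = -r1 p4 / k1 - alpha1 b p4 h4 / D^2  < 0
a22 = -r2 h4 / k2 - alpha2 a p4 h4 / D^2  < 0
```

at *every* interior equilibrium, for *all* admissible parameter values.
The block trace is therefore strictly negative and a conjugate
eigenvalue pair can never reach the imaginary axis; the boundary
equilibria have triangular Jacobians with real eigenvalues.  Hence no
Hopf bifurcation — and no bifurcating limit cycle or downstream chaotic
regime — exists anywhere in parameter space for this system.  The
widely quoted critical-wind quadratic for a Hopf point treats
`(p4, h4)` as constants independent of `w`, which is where that
derivation breaks.  The package implements the quadratic
(`hopf_closed_form`), a fixed-point refinement that re-solves the
equilibrium at each candidate (`refine_hopf`), and a robust
complex-pair sweep (`sweep_hopf`); all of them correctly come back
empty, and the corresponding acceptance test is left failing on
purpose.

## Dynamics

`simulate` wraps LSODA at `rtol 1e-8 / atol 1e-10` (the slowest
baseline rate, `gamma3 = 0.0018`, relaxes on a ~500-time-unit scale, so
the default horizon is 5000 with 5000 output samples).  Components that
dip below zero by solver error are clamped in the report only; an
excursion below `-10 atol` is an error.  `classify_attractor` discards
the first half of the record, calls a flat tail a point attractor (or
boundary collapse below the extinction tolerance 1e-5), and otherwise
analyses quadratic-interpolated peaks of the most strongly oscillating
variable: near-equal peak heights (relative spread < 1e-3) make a
cycle, anything else is aperiodic.

Regime exchange around the verified thresholds is demonstrated with the
partner species held below its own persistence threshold (e.g. plants
with `gamma1 > r1` while sweeping `r2` through `gamma2`): otherwise the
mutualistic term rescues the focal species and masks the flip.

## Sensitivity

PRCC: Latin-hypercube samples (scipy `qmc`, n = 1000 by default) over
±25 % ranges around the baseline, pushed through the coexistence
solver; ranks (average ties) are partialled on all other parameters by
least-squares regression and the residuals correlated.  Draws with no
coexistence point are dropped *and counted* (silent dropping would bias
the coefficients).  At the baseline the wind level `w` has negative
PRCC against all three outputs.

## Problem sizes and runtimes

Everything is desk-scale: the full test suite runs in a few seconds on
one CPU; the acceptance script (`scripts/acceptance.py`) in about a
second; a 1000-sample PRCC in a few seconds.

## Limitations

- The printed-bounds box and the Hopf closed form are kept only as
  faithful transcriptions with their defects documented above.
- The attractor classifier is heuristic (peak analysis), adequate for
  the point/cycle/collapse distinctions exercised here, not a substitute
  for Floquet or Lyapunov-exponent analysis.
- PRCC ranges are a documented convention (±25 %), not fitted to data.
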