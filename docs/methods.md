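# Methods

This document records the mathematical model, the numerical choices made in
implementing it, and the known limitations of those choices. It is written so
that every number the package produces can be traced to a definition here.

## 1. Model

Three state variables describe an individual's stress dynamics:

* `X` — perceived psychological stress,
* `Y` — symptoms of stress-related ill-health,
* `Z` — social support currently in use, drawn from a total pool `S0`
  (the unused reserve is `S0 − Z`).

The vector field is an Oregonator-like kinetic scheme:

```
f1 = k1·A + (k2·B − k6)·X + k3·Y − k4·X·Z − k5·X²
f2 = k6·X − k7·Y
f3 = k8·(S0 − Z)·Y − β·k4·X·Z − k9·Z
```

with environmental stress `A(t) = A0 + ρ·sin(ω·t)`. `B` is the *kindling*
parameter (existing stress amplifies the response to new stressors), `β` the
fraction of support consumed per unit of buffered stress, and `ρ, ω` the
amplitude and angular frequency of periodic environmental forcing.

The reference calibration (`fracstress.TABLE1`) is

| k1 | k2 | k3 | k4 | k5 | k6 | k7 | k8 | k9 | A0 | S0 | β |
|----|----|----|----|----|----|----|----|----|----|----|---|
| 1 | 1 | 0.01 | 2 | 0.3 | 0.01 | 0.01 | 0.1 | 0.01 | 1 | 10 | 0.5 |

with `B = 2.2` as the default kindling level. The chaotic reference regime
adds `ρ = 11`, `ω = 1.5` and fractional order `q = 0.99`.

In the fractional variant each time derivative is a Caputo derivative of
order `q ∈ (0, 1]`; the classical model is recovered at `q = 1`. The order is
interpreted as a memory parameter: smaller `q` weights the system's history
more heavily.

## 2. Equilibria and fractional stability

For the unforced system (`ρ = 0`), `f2 = 0` forces `Y* = (k6/k7)·X*` and
`f3 = 0` gives `Z*` as a rational function of `X*`; substituting into
`f1 = 0` and clearing denominators leaves a cubic in `X*`. Its real roots
seed a Newton-type refinement of the full three-dimensional root problem
(`scipy.optimize.root`, tolerance 1e-14). Refinement is mandatory: the
support-depleted branch (large negative `Z*`) is ill-conditioned, with `Z*`
varying steeply in `X*`, so the cubic's roots alone are not trustworthy
beyond about two decimals there.

At `B = 2.2` the three stationary states are, to three decimals,

* `E1 = (2.584, 2.584, 0.906)` — all positive,
* `E2 = (−0.009, −0.009, −54.81)` — support-depleted, ill-conditioned in `Z`,
* `E3 = (−1.311, −1.311, 0.915)` — negative stress branch.

Stability of a commensurate fractional linearization follows the Matignon
criterion: asymptotically stable iff every eigenvalue λ of the Jacobian
satisfies `|arg λ| > q·π/2`. Eigenvalues within 1e-9 of the sector boundary
are classified marginal and reported as unstable. For kindling `B ≥ 1.2`
the non-contracting eigenvalues of the all-positive state are positive
reals, so the state is unstable at *every* fractional order. At the low end
of the range the picture is order-dependent: at `B = 1.0` the pair is
complex (`0.049 ± 0.057i`, argument `0.276π`), making the state
Matignon-stable for `q < 0.55` and unstable above; classically (`q = 1`)
the state is unstable across the whole range `B ∈ [1, 2.2]`.

## 3. Fractional integrator

The Caputo initial value problem is integrated with the
Adams–Bashforth–Moulton predictor–corrector scheme (the standard
product-rectangle predictor / product-trapezoidal corrector discretization
of the equivalent Volterra integral equation), with per-component orders.
Its convergence order is `min(2, 1 + q)`; the implementation reproduces
empirical slopes 1.56 at `q = 0.5` and 2.01 at `q = 1` on a scalar linear
benchmark, and matches `E_q(−t^q)` (independent Mittag-Leffler series
oracle) to about 1e-7 at `h = 1e-3`. At `q = 1` it agrees with an adaptive
classical integrator to better than 1e-3 over ten time units of the chaotic
regime. A direct Gauss–Jacobi quadrature of the Caputo derivative is
provided as a second independent oracle.

Full-memory cost is O(N²). The inner history sums run in a compiled kernel
with component-major contiguous buffers; a 100 000-step full-memory run
takes tens of seconds on one CPU.

**Short memory is rejected for this model.** The usual short-memory
principle (truncating the history window) is unsound for orders near 1: the
Volterra kernel `(t−s)^{q−1}` at `q = 0.99` is essentially flat, so the
dropped history carries order-one weight. Empirically, a 1000-step horizon
at `h = 0.01` makes the chaotic-regime run diverge near `t ≈ 45` while the
full-memory run stays bounded. The `memory_horizon` option is retained in
the API (it is meaningful at small `q`), but every long-horizon workload in
this package — Lyapunov estimation, scans, headline results — uses full
memory.

Divergence handling: any state component exceeding 1e8 truncates the
trajectory and sets a `diverged` flag rather than raising, because sweeps
over small `q` legitimately contain unbounded solutions.

## 4. Lyapunov spectrum and dimensions

The spectrum is estimated by the Benettin–Wolf procedure on the variational
equations: the base trajectory is integrated first, then an orthonormal
tangent frame is propagated through `D^q M = J(x(t))·M` and re-orthonormalized
by QR factorization every 10 steps, accumulating `log |diag R|` after a
100-time-unit transient. A Caputo tangent flow carries memory that is
incompatible with restarting directions at each renormalization; the frame's
fractional history is therefore reset at every QR event (each
inter-renormalization block is a fresh short fractional IVP). This restart
is the standard compromise in fractional Benettin–Wolf implementations and
is exact at `q = 1`.

Reference settings: `h = 0.01`, `t_total = 1000`, transient 100, full
memory, initial state (1, 1, 1). At the chaotic reference regime this yields
approximately

```
LE1 ≈ +0.025    LE2 ≈ −0.06    LE3 ≈ −8.4
```

i.e. *weak* chaos: one weakly expanding direction atop strong dissipation.
Cross-checks supporting these magnitudes:

* a classical (`q = 1`) Benettin implementation on an adaptive integrator
  gives LE1 in 0.02–0.08 and LE3 in −9…−12 for the same model;
* direct two-trajectory separation at `q = 0.99` grows at ≈ 0.05 per time
  unit after a long laminar episode, consistent with LE1 ≲ 0.05.

Because the system is non-autonomous (periodic forcing) there is no exact
zero exponent in the three-dimensional tangent space; the middle exponent
is only near-neutral.

Two attractor-dimension conventions are implemented: the standard
Kaplan–Yorke interpolation `j + (ΣLE_1..j)/|LE_{j+1}|`, and a variant
`3 − LE1/|LE3|` relating the expansion rate to the strongest contraction.
From the estimated spectrum the variant evaluates to ≈ 2.997.

## 5. Complexity metrics

Two scale-invariant spectral statistics classify regimes, both computed on a
post-transient window of the `X` series (first half of the run discarded,
remainder linearly resampled to `N = 4096` points, mean removed):

* **Spectral entropy (SE)** — Shannon entropy of the one-sided relative
  power spectral density (`k = 0 … N/2 − 1`, Nyquist bin excluded),
  normalized by `ln(N/2)` to [0, 1].
* **C0 complexity** — bins of the full two-sided spectrum whose power does
  not strictly exceed `r` times the mean one-sided power are zeroed; the
  inverse transform of the kept bins is the "regular" part, and C0 is the
  energy fraction of the residual. `r = 1` is the default; C0 is
  nondecreasing in `r`.

The discrimination thresholds are SE > 0.4 and C0 > 0.12, applied
conjunctively by `classify_regime`. At the reference settings the chaotic
regime gives SE ≈ 0.437 and the periodic regime (`ω = 1`) SE ≈ 0.266, so the
SE threshold separates them cleanly. The C0 value of the faithful chaotic
series is ≈ 0.068 at `r = 1` — *below* the 0.12 threshold; crossing it at
these dynamics would require `r ≥ 5` (measured C0 at r = 0.5/1/2/5/10:
0.045/0.068/0.097/0.142/0.177). Consequently the conjunctive label almost
never fires at `q = 0.99`, and regime statements in the test suite are
anchored on the SE signature where the conjunctive rule would be vacuous.
The one faithful grid point that crosses both thresholds in the coarse
`(B, q)` scan is `q = 1.0, B = 2.25` (SE 0.632, C0 0.129).

## 6. Scans

Bifurcation scans integrate once per grid point and record the set of
distinct `X` values at strict local maxima after discarding the first half
of the run; metric scans record SE, C0 or LE1 per point. Axes: `q`, `B`,
`ρ`, `ω`, `Y0`, `Z0`. Defaults: `h = 0.02`, `t_end = 1000`, full memory,
initial state (1, 1, 1) (the system is multistable, so the IC is recorded in
every grid). The horizon cannot be shortened: the chaotic signature at
`q = 0.99` only develops after several hundred time units. The coarser step
was validated against `h = 0.01` at reference points.

Peak deduplication uses resolution 1e-2. The resolution is matched to the
algebraic settling of fractional transients: peak heights of a settling
periodic orbit still drift by a few times 1e-3 over a 1000-unit window
(Caputo relaxation is power-law, not exponential), so a much finer
resolution would report a limit cycle as dozens of spurious distinct peaks.
At 1e-2 the construct behaves as intended: limit cycles collapse to a
handful of values (1–6 across `q = 0.85–0.97`), chaotic attractors retain
85–95.

Observed coarse-scan structure at the reference calibration:

* `ω`-scan (resolution 0.05, `ρ = 11`, `q = 0.99`): SE > 0.4 only on the
  contiguous window {1.50, 1.55};
* `ρ`-scan (resolution 1, `ω = 1.5`): SE ≤ 0.36 for all `ρ ≤ 10`;
* `q`-scan over [0.8, 1.0]: few-peak windows for `q ≲ 0.96`, many-peak
  windows at `q ≥ 0.98`;
* `q`-scan over [0.3, 0.7]: points either diverge (`q ≲ 0.4`) or settle
  into bounded narrowband (quasi)periodic motion (SE ≤ 0.35);
* `Y0`-scan over [0, 50]: the broadband SE > 0.4 signature is confined to
  `Y0 ≲ 2.5`;
* initial conditions (1, 1, 1) vs (1, 10, 1) land on opposite sides of the
  SE threshold — a multistability witness.

## 7. Limitations

* The tangent-history restart at QR events (Section 4) is an approximation
  away from `q = 1`; its effect was bounded empirically by comparing
  renormalization intervals and step sizes.
* Lyapunov exponents of this weakly chaotic attractor converge slowly; the
  leading exponent is small (≈ 0.02–0.03) and sensitive at the second
  decimal to horizon and step choices. The contracting exponent is robustly
  in the −8 to −9 range at `h ∈ [0.005, 0.02]`.
* The conjunctive SE/C0 chaos label is conservative at `r = 1` for this
  system: C0 rarely exceeds 0.12 even in regimes with a positive leading
  exponent and broadband spectra.
* Scan grids are deliberately coarse (desk-scale); fine structure such as
  narrow periodic windows inside the chaotic band is not resolved.
* Equilibrium reporting assumes the unforced system; with forcing the
  stationary states become periodic orbits and the linearization is
  evaluated at the unforced fixed points.
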