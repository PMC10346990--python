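# Methods

## The binding model

ssisfit implements the single-set-of-identical-sites (SSIS, Langmuir)
isotherm for a macroion with `N` independent, identical sites:
`theta = Kb*[A] / (1 + Kb*[A])`, with the free-ligand concentration tied to
the known total by mass balance, `[A]_tot = [A] + N*theta*[M]`. The model
assumes the sites are non-interacting and equivalent (no cooperativity, no
explicit competition term for the monovalent background — the background
enters only through the fitted effective `Kb`), activities equal
concentrations, and each injection reaches equilibrium before the next.

Substituting the mass balance into the isotherm gives

```
Kb*N*[M]*theta^2 - (1 + Kb*[A]_tot + Kb*N*[M])*theta + Kb*[A]_tot = 0
```

whose physical root is the smaller of the two (the larger always exceeds 1).
It is evaluated as `theta = c/q` with `q = (-b + sqrt(b^2 - 4ac))/2`
(`b` is always negative), which avoids the catastrophic cancellation the
naive quadratic formula suffers at low Wiseman `c = Kb*N*[M]`; the systems
this package targets sit at `c ≈ 0.6–1.7`. Degenerate inputs are handled
exactly: `[A]_tot = 0` gives `theta = 0`, `[M] = 0` collapses to the bare
isotherm. The closed form is verified in the test suite against bisection
on the fixed-point residual over `Kb ∈ [10, 1e7] 1/M` and `c ∈ [0.01, 1000]`
(10⁴ grid points, agreement to 1e-10; mass balance to 1e-12 relative).

## Injection bookkeeping

The calorimeter is a fixed-volume perfusion cell: each injection `dV`
expels an equal volume of (partially mixed) cell liquid. We adopt the
standard vendor convention that the expelled liquid carries the average of
the pre- and post-injection composition, giving with cumulative injected
volume `DV`:

```
[M]_i     = [M]_0   * (1 - DV/2V0) / (1 + DV/2V0)
[A]_tot,i = c_syr * (DV/V0) / (1 + DV/2V0)
```

The per-injection heat applies the same mid-point displacement correction
on the heat side, `dQ'_i = Q'_i + (dV_i/V0)*(Q'_i + Q'_{i-1})/2 - Q'_{i-1}`
with `Q'_0 = 0`, so concentration and heat bookkeeping use one consistent
approximation. The cumulative-heat average is taken over the *model*
cumulative heats on both terms of the correction. Injection indexing is
1-based.

Internal units are SI throughout (mol/L, L, K, J); enthalpies are carried
in kJ/mol and converted where heats are formed; bench units (mM, uL, mL,
degrees C, ucal) are converted at the I/O boundary (1 cal = 4.184 J).

## Preprocessing

`integrate_peaks` assigns each injection the window `[t_i, t_i + spacing)`.
The baseline under a window is the straight line through two nodes: the
median power over the final 10% of the preceding window and of the current
window (robust to peak tails); the integral of baseline-subtracted power is
taken by the trapezoid rule. Upward power excursions integrate to positive
(endothermic) heats. A schedule-level `initial_delay` (default 60 s) gives
the first injection a preceding quiescent segment; without one the first
window's own tail level is used flat. Instrument-response deconvolution and
automatic peak detection are out of scope — injection times come from the
schedule. `subtract_dilution` is exact elementwise subtraction with
quadrature-combined sigmas and refuses mismatched injection counts.

## Fitting

`fit_ssis` minimizes the sum of squared residuals between measured and
model per-injection heats, in absolute joules (so the large early peaks
carry proportionate weight; `weight_by_sigma=True` switches to 1/sigma
weights). Optimization is MINPACK Levenberg–Marquardt (via lmfit) over
`(N, ln Kb, dH)`: the log parameterization enforces `Kb > 0` and
conditions the search; `N` is box-constrained positive. Tolerances are
`xtol = ftol = 1e-12` with up to 2000 residual evaluations; if the first
start fails, three log-spaced `Kb` restarts (1e2, 1e4, 1e6) are tried and
the best SSR accepted. Initial guesses: `dH0` from the mean of the first
three normalized heats divided by an assumed 0.8 initial bound fraction;
`N0` from the molar ratio where the normalized heat crosses half its
initial value (floored at 1; the final molar ratio if no crossing);
`Kb0 = 1e3 1/M`.

Uncertainties are asymptotic: the residual-variance-scaled inverse
Gauss–Newton Hessian on `(N, ln Kb, dH)`, propagated to the natural scale
by the Jacobian `diag(1, Kb, 1)`; `sigma(dG) = R*T*sigma(Kb)/Kb`. These are
linearized estimates and understate uncertainty when the isotherm is
shallow.

Diagnostics: the Wiseman `c = Kb*N*[M]_0` at the fitted optimum, a check
for an inflection of the model isotherm inside the measured molar-ratio
range, and a `low_confidence` flag (any relative standard error above 50%,
or `c < 0.5`). All are warnings (`FitDiagnosticWarning`), never silent
failures and never exceptions: shuffled or degenerate data return a result
with diagnostics. This mirrors the experimental failure mode at elevated
ionic strength, where the measured enthalpy collapses and the SSIS
parameters become unidentifiable.

## Buffer accounting

`ionic_strength` computes `I = I_buffer + 1/2 * sum(c_i * z_i^2)` with the
organic buffer counted at its nominal concentration as a 1:1 electrolyte —
the convention under which all five reference compositions close exactly
(10 + 3*c_MX2 + c_NaCl). A Henderson–Hasselbalch mode that scales the
buffer term by its ionization fraction (~0.5 for MOPS at pH = pKa = 7.2) is
available but is not the reference convention. The macroion's own
counterions are excluded. Activity coefficients are out of scope.

## Synthetic data

The generator emulates a VP-ITC-style experiment: 35 injections of 8 uL
into 1.43 mL at 303.15 K with 300 s spacing, at the five reference designs
(titrant 5.0–15.2 mM, macroion 0.020–0.064 mM, ionic strengths 16.5 and
21.5 mM) paired with their published-scale SSIS truths (N = 4.5–7.9,
Kb = 4.1–6.5e3 1/M, dH = +6.8–10.1 kJ/mol). Defaults are those conditions;
the Monte-Carlo noise level used in validation is Gaussian with s.d. 2% of
the largest heat, a realistic signal-to-noise for ucal-scale peaks.

* `simulate_heats`: forward model plus iid Gaussian noise (absolute or
  fraction-of-max), truth retained on the result.
* `simulate_dilution`: geometric decay `magnitude * decay^(i-1)` plus noise.
* `simulate_thermogram`: each heat becomes an exponentially modified
  Gaussian pulse (Gaussian rise sigma = width/4, exponential tail
  tau = width, default width 20 s, 1 Hz sampling) on a linear drift
  baseline with optional white power noise. The pulse is truncated where
  its tail reaches 90% of the window and its amplitude normalized so the
  *discretely sampled* trapezoid area equals the requested heat; with zero
  noise and zero drift, peak integration therefore recovers the heats to
  machine precision, making the zero-noise full-pipeline round trip exact
  rather than approximate. The exact pulse shape is immaterial to area
  recovery.

All generators are pure functions of their arguments and a seed.

What the generator does *not* emulate: finite mixing/response kinetics,
thermal feedback, baseline steps or drift nonlinearity, first-injection
backlash (exposed only as a `discard_first` fitting flag), and any
systematic (non-Gaussian) error. Passing recovery tests therefore
demonstrates correctness of the estimator under the stated noise model, not
robustness to instrument artifacts in real traces.

## Validation problem sizes

The test suite and the acceptance script use the 35-injection reference
designs directly; the Monte-Carlo study uses 100 replicates at 2%-of-max
noise (observed there: mean-N bias ≈ +0.1 sites, mean-Kb error ≈ 2%). The
occupancy oracle grid is 10⁴ points. These sizes keep the whole validation
under a few seconds on one core while leaving the Monte-Carlo means stable
to well within the tolerances asserted.

## Known limitations

* A single effective `Kb` absorbs the monovalent-ion competition; the model
  cannot separate divalent binding from monovalent release, and the count
  of displaced monovalent ions is not an output.
* At `c < ~0.5` the parameters are only weakly identified; the fitter flags
  this but cannot repair it — that is a property of the experiment design.
* Asymptotic standard errors; no bootstrap or posterior sampling.
* CSV/YAML only; instrument-vendor binary formats are not read.
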