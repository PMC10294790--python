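# Methods

This note records the modelling assumptions, calibration anchors, numerical
choices and known limitations behind the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Plant model and exact propagation

The two-state plant (oral compartment x1, FT4 output x2) is linear and
time-invariant between events. Dosing is impulsive (one tablet per day) and
the TSH drive is held piecewise constant per hour (zero-order hold), so each
step has a closed-form solution: x1 decays as exp(-kexc t); x2 combines its
own decay, the constant-forcing term (vmax TSH/(km+TSH))/ksec (1-exp(-ksec t))
and the two-exponential cross term from x1. `simulate_plant` propagates these
forms exactly (via `scipy.signal.lfilter` on uniform grids, a per-interval
loop otherwise); tests compare it against an adaptive Runge-Kutta oracle at
1e-6 relative. A constant-rate infusion variant exists but is non-default —
impulsive dosing is what motivates the impulse-invariant discretization.
Reported samples at dose times are post-impulse.

Fixed rates: kexc = 0.26 1/h (nominal oral elimination; the robustness
analysis spans 0.16-0.36), ksec = ln 2/(9.5 d) ≈ 3.04e-3 1/h from the
midpoint of the 9-10 day T4 half-life in hypothyroid patients. Fitted
constants (nominal set): kreac = 7.25 "ppm", km = 9.504e3 umol,
vmax = 2.19e-4 umol/h.

Unit scheme. Doses are ug at every interface and convert to umol via the
LT4 molar mass 776.87 g/mol, times bioavailability, before entering x1.
"ppm" for kreac is ambiguous; the package treats the printed number as a raw
multiplicative factor by default, with a configurable literal 1e-6
interpretation (`ppm_interpretation: micro`). The choice only rescales x2's
internal units and cancels out of every calibrated, dimensionless or
closed-loop quantity.

## Identification

J(p) = sum of squared FT4 residuals over an hourly record, minimized over
p = (kreac, km, vmax) with kexc, ksec fixed. The search is Nelder-Mead in
log space (positivity for free) with a quadratic penalty above the upper
bounds (default 10x nominal — "realistic" bounds are otherwise unspecified)
and 3 seeded restarts from jittered copies of the best point, the standard
cure for premature simplex collapse. The model output is initialized at the
record's first FT4 sample.

Identifiability. The endogenous term enters as vmax TSH/(km+TSH). If TSH is
constant — or small compared with km — only the lump vmax/(km+TSH) is
determined; `identify` rejects constant-TSH records outright. The default
synthetic identification record therefore combines the three-month dose
staircase (50/80/110 ug/day) with a smooth TSH sweep spanning a range
commensurate with km (0.6 km ± oscillations on 30-day and 7-day periods),
which drives the Michaelis term through its nonlinear range. On that
noiseless record the optimum is unique and Nelder-Mead recovers all three
parameters to well below 0.1% from inits perturbed by x0.5-x2.

## Discretization and controller synthesis

Impulse-invariant discretization at Td = 672 h (28 days; 30 days available
via config) gives G(z) = A p1 z/(z^2 - p2 z + q1 q2) with
A = kreac/(ksec - kexc), q1 = exp(-ksec Td), q2 = exp(-kexc Td). At this
sampling time q1 q2 < 1e-69, far below the 1e-6 neglect threshold, so the
reduced first-order form A p1/(z - p2) is used; for short Td the full form
is retained with a warning and the design path refuses it. Note the signs:
ksec < kexc makes A and p1 both negative, the effective gain A p1 positive.

The rate-limiter block is linear: Kr(z) = kr/(z-1) under unity feedback,
i.e. Krz(z) = kr/(z - Delta), Delta = 1 - kr, a first-order lag with unit
DC gain. kr = 0.5 by default: the dimensionless smoothing gain of the
cascade, not the clinical step bound — a linear lag cannot hard-bound
increments, so the literal 12.5-25 ug per-visit limit is enforced by the
dose shaper instead (below).

Pole placement solves a(z)v(z) + b(z) mu0 = (z - z0)^3 for the monic
first-order controller by direct coefficient matching
(a0 = w2 - v1, b1 = (w1 - v0 - a0 v1)/mu0, b0 = (w0 - a0 v0)/mu0); the
identity is re-verified to 1e-10 after every design. z0 = -0.01 (triple):
poles near 0 react deadbeat-fast, poles near ±1 overshoot and lose
robustness. A numerical caveat frozen into the tests: recovering a *triple*
root from exact cubic coefficients is conditioned as eps^(1/3) ≈ 6e-6, so
root-space assertions use 1e-5 while the identity itself is held to 1e-10.

## Robust stability

The closed-loop characteristic cubic a(z)v(z) + b(z)mu(z) is re-evaluated
along the kexc interval (ksec and the fitted constants held nominal,
mirroring the single-parameter family; the interval is read as 1/h).
Schur stability of the whole family follows from the four Jury-Pavlidis
conditions: one Schur anchor plus nonvanishing of p(1,q), p(-1,q) and
det(X(q)-Y(q)) along the interval. X and Y are the (n-1)-square
leading/trailing coefficient matrices; for a cubic,
det(X-Y) = a3(a3-a1) + a0(a2-a0), used as a closed-form cross-check.
The continuous conditions are evaluated on a dense grid (default 1001
points) with sign-change monitoring; "nonzero" means
|value| > 1e-12 (1 + max coefficient). Roots for the anchor and for
brute-force cross-validation come from companion-matrix eigenvalues.

## The closed dosing loop

Block order per visit: measure -> controller R(z) -> linear smoothing lag
Krz(z) -> hard rate clip (± max_step about the previous dose) -> quantizer
(nearest 12.5 ug multiple, exact ties rounded down) -> saturator
([0, 200] ug) -> hold daily until the next visit. The smoothing lag is part
of the loop, not only of the synthesis model: without it the controller's
alternating mode (denominator root near -0.66) can sustain a one-quantum
limit cycle just below the band for low references.

Steady-state rule: when the measured FT4 lies inside [9.2, 16] ng/L and the
reference did not change since the last visit, the previous dose is held
verbatim. A non-integrating linear loop with quantization would otherwise
chatter; the hold implements the clinical requirement that a euthyroid
patient's prescription stays constant. A consequence worth knowing: the
loop regulates *into the band*, not onto the reference value — titration
freezes at band entry, so the steady FT4 sits near the lower band edge when
titrating upward regardless of the exact reference, and a reference change
inside the band moves the dose by at most one quantum before the hold
re-engages.

Visits are perfectly periodic. Therapy starts from dose 0 and zero
controller state after a one-day run-in, so the first prescription is one
12.5 ug tablet; a run may instead continue an established regimen
(`initial_dose`), which a patient measuring in band keeps unchanged. The
visit measurement is the mean of the preceding 24 h of hourly FT4 (one
circadian period, so the ripple averages out).

Controller units. The controller is designed in the plant's native units;
at the loop boundary measured FT4 (ng/L) is divided by the display scale
and the command is converted to ug/day by molar mass over nominal
bioavailability. With these conversions the loop's static gain is high:
while the patient is out of band the shaped dose moves by the full
per-visit step toward the command, which yields exactly the titration
staircase the prescription rules describe, and the band hold provides the
stable steady state. The linear small-signal loop is not the operating
regime and is deliberately not relied on.

## Virtual patient and cohort

The virtual patient wraps the plant core with the externally relevant
behaviours of a treated Hashimoto patient; it is not a physiological
whole-axis simulator. Hourly, it applies the daily dose impulse (scaled by
bioavailability), advances the exact one-hour propagation, multiplies the
displayed FT4 by the circadian ripple 1 + a sin(2 pi t/24 + phase)
(a = 0.05 default), and updates TSH = tsh_max h^n/(h^n + FT4^n)
(tsh_max = 100 mU/L, h = 6 ng/L, n = 4 — monotone decreasing, ~4 mU/L when
euthyroid at 13 ng/L, saturated near 100 when untreated) which feeds the
endogenous drive at the next step (one-hour lag keeps each step exact).
Patients start at their untreated FT4/TSH fixed point, solved at reset —
a chronic hypothyroid patient presents at equilibrium, and x2's two-week
time constant would otherwise leak a spurious ramp into the first visits.

Two calibration anchors fix the display units, chosen once and frozen:

1. Dose anchor: the nominal patient on 100 ug/day settles at 13 ng/L FT4.
   The scale follows in closed form from the period-averaged steady state
   (mean x1 = D/(24 kexc), mean x2 = kreac mean-x1/ksec).
2. Endogenous anchor: a *normal* gland (residual fraction 1) under maximal
   TSH stimulation produces the same 13 ng/L. With the 17% residual
   fraction of the modelled patients this puts untreated FT4 near
   2.2 ng/L — overt hypothyroidism — and, because therapy suppresses TSH,
   the residual contribution shrinks below 0.5 ng/L once the patient is
   in band.

Cohort sampling (deterministic per (master seed, index) via
`numpy.random.default_rng([seed, i])`): kexc ~ U(0.16, 0.36) 1/h;
half-life ~ U(9, 10) days; kreac, vmax, km log-normal with median at the
nominal values and 30% CV; bioavailability ~ U(0.64, 0.83); circadian phase
~ U(0, 2 pi). All patients share the nominal-design controller. The summary
reports monthly cross-patient mean/std of FT4 (24-h mean at month end) and
of the prescribed dose, with population std (so n = 1 gives 0), plus
per-patient endpoints; individual failures are recorded, not fatal.

Problem sizes: the default cohort is 50 patients x 12 monthly visits of
hourly simulation (~8.4e3 steps each), the refractory run 24 visits, the
identification record 90 days hourly — the whole acceptance script runs in
a few seconds on one CPU.

What the surrogate does not capture: T3/LT3 dynamics, TSH kinetics beyond a
static Hill response, antibody effects, meal- or adherence-driven
absorption variability, and visit-interval irregularity. Passing tests
demonstrate that the dosing algorithm satisfies its prescription-rule
guarantees and regulates this documented class of virtual patients; they
are not evidence about real patients or about any external simulator.
A known cohort-level consequence of the sampling ranges: a few percent of
draws combine low gain and low bioavailability so that their maintenance
dose exceeds what 12 monthly visits of +12.5 ug can reach (150 ug/day);
such patients are still titrated safely and converge in later visits, but
are not yet euthyroid at month 12.
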