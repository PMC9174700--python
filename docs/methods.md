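# Methods

## Scope and model structure

`flashodh` quantifies pulsed ultra-high-dose-rate (FLASH) sparing from
oxygen effects alone.  The chain is:

1. a damage-response model mapping pO2 (Torr) to complex-DNA-lesion yield
   per Gy;
2. a depletion model mapping delivered dose (or in-pulse time) to
   instantaneous pO2;
3. the oxygen dose histogram (ODH) — dose binned by the pO2 at which it was
   deposited — with an algebra (addition, scaling) that composes pulse
   trains;
4. reduction to a sparing factor `F = M_D / M_D0` and a survival
   correction `SF_corr = 1 − (1 − SF_meas)·F`;
5. voxelised application over co-registered dose/oxygen grids.

Biological mechanisms (repair kinetics, immune effects, genomic differences
between tumour and normal tissue) are deliberately out of scope: the package
asks how much of the observed FLASH phenomenology oxygen physics alone can
carry.

## Damage response

The oxygen-fixation site population is treated as a saturable
ligand-receptor system, giving the rational response
`F(x) = (C1·x + C2)/(x + C3)` per Gy.  Defaults `C1 = 8.334`,
`C2 = 15.99`, `C3 = 5.67` are the 2 MeV electron fit; in the clinical
photon/electron energy range the oxygen effect is nearly energy independent,
so this single set serves as the package default.  Units are fixed at Torr
and lesions·cell⁻¹·Gbp⁻¹·Gy⁻¹; a helper converts percent O2 to Torr with
100% = 760 Torr (so the common 20% lab atmosphere is 152 Torr).  The
saturation form is dimensionless-scaled and its concentration-like units are
absorbed into the energy-dependent damage scale `a(y)`; the rational form
fixes units unambiguously, which is why it is the canonical interface.

Energy-tabulated coefficients `a(y)`, `b(y)` are interpolated
piecewise-linearly with no extrapolation — no functional form in energy is
assumed, so queries outside the table are errors rather than guesses.

Fitting (`fit_response_params`) is bounded nonlinear least squares
(`scipy.optimize.curve_fit`, all parameters positive) initialised from the
data: asymptote ← max yield, floor ← median-pO2 × min yield, half-saturation
← median pO2.  This is robust for saturation shapes.  A fit with
`C1·C3 ≈ C2` (no oxygen dependence) is flagged `flat` in the diagnostics;
constant-yield data either converge to that boundary or raise a `FitError`.

## Depletion models

**Linear (constant rate).**  `pO2(d) = max(pO2₀ − R·d, 0)` with R in
Torr/Gy.  Conventional-dose-rate measurements give R between 0.21–0.22 and
0.42 Torr/Gy; effective values fitted to pulsed UHDR cell survival are much
steeper, ~15.0 Torr/Gy (15.5 in an alternative calibration — both ship as
named presets, neither privileged).  The trajectory is represented exactly
by breakpoints at dose 0, the hypoxia onset `pO2₀/R` (when reached) and the
total dose.

**Second order (binding kinetics).**  Oxygen binds to radiation-induced
species at rate λ (per Torr-equivalent per ns); a dose D creates G·D of
species.  The concentration solves `dx/dt = −λ·x·(x + G·D − x₀)` with the
standard closed form.  Numerical choices: the exponent-sign split keeps the
evaluated exponential decaying (no overflow at large t), and within
`|G·D − x₀| < 1e-9·max(G·D, x₀)` the analytic equal-rate limit
`x₀/(1 + λ·x₀·t)` replaces the 0/0-prone general form.  The closed form is
validated against tight-tolerance Runge–Kutta integration to ≤ 1e-6 Torr,
including the singular point.  Mapping to the dose domain assumes a constant
in-pulse dose rate (rectangular pulse) and samples the curve at 256 points
by default; depletion between identical samples is piecewise-linearised.

## ODH construction and algebra

Bins are left-closed right-open `[lo, hi)` on pO2 with the lowest edge at
exactly 0 (fully hypoxic dose occupies the first bin); default bin width
0.1 Torr.  Dose is integrated exactly over each piecewise-linear trajectory
segment: within a segment the dose per unit pO2 is constant, so each bin
receives its pO2 overlap times that density; constant segments deposit into
the single containing bin.  Conservation (Σ bin doses = delivered dose) is
then exact up to float rounding for every construction path.

Addition rebins both operands to the union of their edge grids with
mass-preserving reassignment (piecewise-constant density within source
bins); it is commutative and associative to rounding.  Downstream damage
evaluation uses the bin midpoint, which is second-order accurate in the bin
width; convergence to the exact trajectory integral is tested against
adaptive quadrature and the closed form below.

Pulse trains: with full re-oxygenation the single-pulse ODH is scaled by the
pulse count (this exact invariance is what makes "dose per pulse = mean rate
/ pulse repetition frequency" a sufficient statistic for train sparing).
With none/partial re-oxygenation, pulse i+1 starts at
`o2_end + f·(pO2₀ − o2_end)` and histograms are added; `f = 0` on the linear
model reproduces one continuous trajectory exactly.  What fraction of
re-oxygenation occurred in historical double-pulse experiments (2.5 ms gap)
is not established; full re-oxygenation is the documented default and
`partial(f)` is provided uncalibrated.

Instantaneous dose rate is carried in cGy/ns (1 cGy/ns = 1e7 Gy/s); pulse
lengths in ns, periods in ms at the boundary.

## Sparing and the closed-form integral

For the linear model the trajectory damage integral has the closed form

    M_D = (1/R)·[C1·(x₀ − x_end) − (C1·C3 − C2)·ln((x₀+C3)/(x_end+C3))]
          + max(D − x₀/R, 0)·C2/C3,      x_end = max(x₀ − R·D, 0).

This is the exact bin-width → 0 limit of the binned path; the two are held
to ≤ 0.1% of each other (and of adaptive quadrature) at 0.01 Torr bins in
the acceptance suite.  The experiment pipelines and the voxel engine
evaluate sparing through this closed form — exact and vectorisable — while
histogram construction remains the general path for arbitrary trajectories
and partial re-oxygenation.

Sparing framings: the primary report is the ratio `F ≤ 1`; `1 − F` (relative
sparing) and `1/F` (used against behavioural response data, which increase
with sparing) are exposed as derived properties.

The asymptotics are useful anchors: `F → F_resp(0)/F_resp(pO2₀)` as dose
grows (approach rate O(pO2₀/(R·D)), so the asymptote is only reached within
0.5% at 10⁴ Gy for the steep UHDR depletion rate; at 0.42 Torr/Gy and
152 Torr it is still ~6% away), and `F = 1` exactly with no depletion.  At
small doses lower initial pO2 spares more; at large doses the ordering
reverses, so any two initial levels have a unique crossover dose, found by
bracketed bisection (`brentq`, 1e-6 Gy).  The crossover location depends
strongly on the (unstated, scenario-specific) depletion rate and is treated
as an output, not a calibration target.

## Exact rank statistics

Spearman's rho uses the `1 − 6·Σd²/(n(n²−1))` shortcut on tie-free data and
the product-moment correlation of average ranks otherwise.  The exact null
distribution of Σd² over all n! permutations is computed by a bitmask
dynamic program (states = subsets of assigned ranks × running Σd²), exact in
integer counts up to n = 10 and cross-checked against naive factorial
enumeration for n ≤ 7.  A two-sided level α maps to the one-sided α/2 upper
tail, matching the convention of the published critical-value tables: the
critical rho is the smallest attainable value whose exact upper-tail
probability is ≤ α/2 (at n = 10, α = 0.01 this is Σd² = 34, rho_c ≈ 0.7939,
i.e. 0.794 at 3 decimals).  When even rho = 1 fails the level (n ≤ 4ish),
an explicit "unattainable" result carries the minimum achievable tail
probability 1/n!.  With tied data the tie-free null is used as a documented
approximation.  No asymptotic approximation is provided beyond n = 10.

## Experiment pipelines

**Cell survival (single vs double pulse).**  Defaults: 152 Torr initial
oxygenation, 15.0 Torr/Gy effective depletion, 1.2 µs pulses.  Single-pulse
records get the sparing factor at their dose; double-pulse records are two
half-dose ODHs with full re-oxygenation added together — by additivity their
sparing equals the single-pulse value at half the dose — and their measured
survival is corrected by `SF_corr = 1 − (1 − SF_meas)·F`.  Single-pulse
records pass through uncorrected: the correction's purpose is to map
double-pulse data onto single-pulse behaviour.

**Dose-rate sweep.**  Defaults: 10 Gy total, 100 Hz PRF, 20 Torr, linear
depletion at 15.0 Torr/Gy.  Per arm, dose per pulse = mean rate / PRF; the
single-pulse arm delivers the full 10 Gy in one 1.8 µs pulse and is plotted
at the conventional 1000 Gy/s position.  Inverse sparing `1/F` is
rank-correlated against the supplied responses with the exact test above.
Reproducing the historically reported correlation coefficient itself is not
claimed — it requires the original behavioural response values, which are
not bundled.

## Synthetic data

No public dataset accompanies the recreated experiments, so seeded
generators produce all pipeline inputs; they emulate structure, not
biological realism.

* `gen_response_table`: exact rational-response values on a pO2 grid plus
  relative Gaussian noise.  Default grid {0, 2, 5, 10, 20, 76, 152} Torr.
* `gen_town_survival`: single-pulse "truth" is linear-quadratic survival on
  the sparing-effective dose `D·F₁(D)` with generic mammalian-cell fixture
  parameters α = 0.3 Gy⁻¹, β = 0.03 Gy⁻² (a round-trip-testing convention —
  the formalism corrects measured survival and assumes no survival model).
  Double-pulse measurements are derived by algebraically inverting the
  survival correction, so the pipeline provably restores the single-pulse
  curve.  The inversion `SF_meas = 1 − (1 − SF_true)/F₂` has no valid
  solution once `1 − SF_true > F₂`; on the default 0.5–45 Gy ladder with the
  default LQ parameters this occurs above ≈ 9 Gy, and such records are
  flagged `infeasible` (measured fraction clamped to 0) rather than silently
  adjusted.  Round-trip tests assert exact restoration on the feasible
  range and noise-bounded restoration under 5% lognormal measurement noise.
* `gen_recognition_sweep`: the nine historical mean dose rates
  (0.1–500 Gy/s) plus the single-pulse arm; responses are
  `baseline + slope·(1/F) + noise` with the physics-path F, defaults
  baseline 0.5, slope 0.2, noise sd 0.02 (recognition-ratio scale).  With
  zero noise the correlation is exactly 1; with realistic noise the
  sub-threshold arms (near-identical F) rank randomly, which is the same
  behaviour that keeps real sweeps below perfect concordance.
* `gen_phantom`: uniform-background dose/oxygen volumes with spherical
  region overrides and optional seeded dose jitter.

All generators are pure functions of their arguments including the seed
(NumPy `default_rng`).

## Voxel engine

Grids are plain 3-D arrays with per-axis mm spacing, exchanged as NIfTI
(nibabel, diagonal affine) or long-format CSV with 0-based indices.  The
per-voxel path uses the closed-form linear integral vectorised over the
whole volume for full/no re-oxygenation (a 64³ phantom evaluates in
milliseconds); partial re-oxygenation or second-order kinetics fall back to
histogram composition over the unique (dose, pO2) pairs present, which is
exact and fast for piecewise-constant phantoms.  Zero-dose voxels get
sparing 1 and damage 0 by convention.  Per-voxel energy spectra are reduced
to the single effective energy of the default response (justified by the
flat electron/photon energy dependence); the spectrum-weighting hook exists
on the scalar API but is not exercised by the voxel default.  The summary's
hypoxic-dose fraction is the share of physical dose delivered beyond each
voxel's hypoxia-onset dose (linear model only).

## Problem sizes and test design

The shipped suites run on deliberately small inputs chosen to make every
check exact or oracle-backed: trajectories with ≤ 300 samples, histograms
with ≤ 0.01 Torr bins over ≤ 152 Torr, 64³ voxel grids, 100-seed noise
ensembles, and full 10! permutation counts via the DP (sub-second).  The
independent oracles are adaptive quadrature (damage integrals),
Runge–Kutta integration (second-order kinetics), naive factorial
enumeration (rank null, n ≤ 7) and hand-derived closed forms.

## Known limitations

* Oxygen depletion is spatially homogeneous within a histogram; pockets of
  local hypoxia around damage sites are representable only through the
  histogram abstraction itself, not resolved.
* The linear depletion rate at UHDR is an *effective* parameter fitted to
  survival data, an order of magnitude above radiolytic-chemistry
  measurements; the package treats it as configuration, not physics.
* The tie-free permutation null is used even when ranks are tied.
* No proton/ion spectral weighting is bundled: the energy-flat
  approximation covers photons and electrons; heavier particles would need
  energy-resolved coefficient tables via the provided hooks.
* No dose calculation, DICOM-RT, or planning-system integration; grids in,
  grids out.
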