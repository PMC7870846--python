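# Methods

This note documents the models implemented in `mfapkit`, the assumptions
behind them, the defaults that matter, and the numerical choices that were
genuinely open.

## Binding equilibria

**Single-site isotherm.** Chromophore titrations are modeled as
`f(L) = f_min + (f_max − f_min)·Lⁿ/(Lⁿ + K_dⁿ)` with the Hill exponent n
fixed at 1 (one binding pocket per barrel). A free-n mode exists purely as
a diagnostic: Ca²⁺-responsive variants are expected to show n ≈ 1, meaning
a single Ca²⁺ site is thermodynamically coupled to the chromophore pocket.
Fitting conventions:

- Blanks are subtracted per concentration; technical replicates are
  averaged *before* fitting (the means are the fit targets; replicate s.d.
  is retained for reporting, not used as weights).
- Means are min–max normalized for conditioning; fitted plateaus are
  rescaled back to the RFU scale of the maximum mean.
- Positivity of `K_d` is enforced by fitting `log K_d`; its standard
  deviation comes from the fit covariance via the delta method
  (`sd(K_d) = K_d · sd(log K_d)`).
- Initialization: `K_d` at the geometric mean of the nonzero tested
  concentrations, `f_max` at the maximum mean, `f_min` at the
  zero-condition mean.
- If the fitted `K_d` exceeds the largest tested concentration the result
  is flagged `is_lower_bound` and reported as `≥ K_d` — a titration that
  never plateaus cannot localize the constant, only bound it.
- Flat titrations (range below a configurable fraction of the signal
  scale) raise instead of returning an arbitrary constant.

Units are µM internally everywhere; molar values are converted at I/O
boundaries.

**Exact bimolecular binding.** For A + B ⇌ AB at totals A₀, B₀ the complex
is the root of a quadratic. We evaluate it in the conjugate form
`C = 2·A₀·B₀ / (S + √(S² − 4·A₀·B₀))` with `S = A₀ + B₀ + K_d`, which
avoids the catastrophic cancellation of the textbook
`0.5·(S − √…)` expression when `K_d ≪ A₀ + B₀`; mass-action residuals stay
below 10⁻⁹ relative across the tested parameter space. The excess-binder
approximation `P/(P + K_d)` is an upper bound on the exact bound fraction
and converges to it as the tracked species becomes trace.

**Allosteric cycle.** A sensor with one chromophore site and one analyte
site has four states (apo, chromophore-bound, analyte-bound, doubly
bound). The cycle is parameterized by `K_d⁻` (chromophore K_d of the
analyte-free sensor), `K_d⁺` (analyte-bound), and the analyte K_d of the
apo sensor; the fourth constant follows from cycle closure
`K_d⁻ · K_d^analyte,holo = K_d⁺ · K_d^analyte,apo`, which therefore holds
to machine precision by construction. State fractions are Boltzmann
weights in the free-ligand approximation; an exact mode solves the two
ligand-conservation equations by nested Brent root-finding for cases where
the sensor is not trace. Fluorescence is a brightness-weighted sum over
the two chromophore-bound states; the weights default to equal because
nothing in the characterization distinguishes whether analyte binding
changes bound-state brightness or only affinity.

**Labeling rule and dynamic range.** The fluorescence fold-change between
zero and saturating analyte at chromophore concentration c (equal
brightness weights) is `(c + K_d⁻)/(c + K_d⁺) − 1`: it approaches the
coupling factor minus one as c → 0 and vanishes as c saturates both
states. Labeling at the geometric mean `√(K_d⁺·K_d⁻)` trades dynamic range
against absolute signal (hence photostability and detection sensitivity),
which is why that concentration is the recommended label point.

**Competition.** Two ligands sharing one receptor reduce to a single
monotone scalar equation in free receptor,
`r + Σᵢ Lᵢ·r/(K_i + r) = R_total`, solved by Brent bisection on
`[0, R_total]`. Tests verify it against an independent nested-bisection
oracle formulated in the free-ligand variables.

## Split-fragment complementation

The fluorescent complex between a titrant fusion and a partner fusion is
the exact bimolecular solution, with two conventions:

- Only the folded fraction `p_folded` of the partner fusion is competent
  to complement, so the effective partner concentration is
  `p_folded · partner_total`.
- The normalizing theoretical maximum is the same bimolecular expression
  evaluated at a saturating titrant concentration, kept at the literal
  10.0 M convention (a normalization device, not a physical condition).

The folded partner concentration is used consistently in both the titration
curve and its normalization anchor. This makes the normalized model reach 1
at saturation — matching data that are min–max normalized to their own
plateau — and places the information about `p_folded` in the position of
the stoichiometric breakpoint (the curve rises linearly and plateaus at
titrant ≈ `p_folded · partner_total` when the composite K_d is tiny).
Normalizing by the maximum at the *total* partner concentration instead
would cap the model at `p_folded` < 1 and contradict plateau-normalized
data; with a composite K_d of ~10⁻¹³ M the choice is otherwise
inconsequential.

The composite constant multiplies the two interface constants,
`K_d^comp = K_d^binder · K_d^fragments`, equivalent to Gibbs-energy
additivity `ΔG_total = ΔG_binder + ΔG_fragments` with `ΔG = RT ln K_d` at
298.15 K. `K_d^comp` is held fixed while `p_folded` is fitted (logit
parameterization keeps it in (0, 1]; a joint fit is out of scope).

Kinetics are empirical monophasic relaxations
`y(t) = plateau + (start − plateau)·e^(−kt)` fitted to ΔF/F₀ series with
F₀ = the first measurement (so the first fold-change point is exactly 0).
Initialization: start = first point, plateau = last point, k = 3/span.
Only endpoint equilibria are modeled for competition; rates come solely
from the empirical fit.

## Ratiometric pH sensing

The calibration is a three-parameter logistic
`F_ratio = A / (1 + e^(∓k(pH − pH₀)))` where the ratio is emission from
the redshifted excitation peak over the blueshifted one, computed on
background-subtracted, unnormalized intensities (per-channel background
subtraction happens before any ratio). One parameterization with a signed
steepness covers both increasing (mFAP_pH-like) and decreasing (pHRed,
pHluorin2-like) sensors; the stored constants mirror the printed forms
exactly (amplitude, positive steepness magnitude, midpoint, direction).
Direction is auto-detected from the Spearman rank correlation when not
given. Inversion is closed-form,
`pH = pH₀ ∓ (1/k)·ln(A/F_ratio − 1)`, the exact inverse of evaluation on
(0, A).

Calibration points in the ambiguous region where the empirical ratio
reverses direction (one ratio ↔ two pH values) are excluded before
fitting: pairs of points that violate the monotone trend by more than 5%
of the data range count as conflicts, and the most-conflicted points are
removed greedily until the retained set is monotone within tolerance. This
drops an isolated reversal while keeping its well-behaved neighbors.

## Photophysics and photobleaching

Beer's law `ε = A/(b·c)`; relative quantum yield against a reference
standard
`ϕ_c = ϕ_r · (1 − 10^−A_r)/(1 − 10^−A_c) · (∫F_c/∫F_r) · (n_c²/n_r²)`
with emission integrals by trapezoid quadrature on a shared wavelength
grid; absolute quantum yield as emitted-over-absorbed photon flux, with a
physicality warning above 1. Brightness is ε·ϕ, reported at 3 significant
figures; % bound at one decimal; these rounding conventions apply to
report fields only, never to stored values. The tabulated % bound values
are reproduced with the exact bimolecular mode (protein and chromophore
totals both matter at the 10⁻⁰·⁵ precision of the tables); the
excess-protein approximation is the default for quick bookkeeping and
differs only in the one borderline row.

Photobleach series are frame-wise pixel sums normalized to frame 1
(saturated pixels — at the detector maximum `2^bits − 1`, default 12-bit —
are excluded upstream), fitted to `F = h + (1 − h)·e^(−kt)` with `h ∈
(0, 1]` via a logit parameterization. Time runs in frames by default
(k in frame⁻¹), convertible to seconds through the frame period
(default 1.13 s at the ~0.885 Hz acquisition rate). Photostability between
probes is the ratio of their `h` plateaus. A constant series short-circuits
to h = 1, k = 0.

## Live-cell time courses

ROI traces carry a matched proximal background ROI, subtracted
elementwise. The baseline F₀ is the mean over the 1 s window immediately
preceding the stimulation frame (5 frames at 5 Hz), so the pre-stimulus
ΔF/F₀ has mean ≈ 0 by construction. The peak response is the maximum
|ΔF/F₀| strictly after the stimulation frame (first occurrence on ties);
cohorts are summarized as mean ± s.d. over ROIs. Sustained baseline shifts
(e.g. SERCA-pump inhibition) are quantified as post/pre window-mean
differences, not a mechanistic model.

Cardiomyocyte lag analysis detects peaks in a fluorescence trace and a
contraction-proxy trace (any proxy is accepted), pairs them by
nearest-cycle matching, and reports per-cycle
`lag = t(peak fluorescence) − t(peak contraction)` as mean ± s.d. in ms —
antisymmetric under swapping the traces. The peak finder uses local maxima
with a minimum separation (default 0.3 s) and a prominence threshold
(default 20% of the trace range); both are configurable since peak-finding
conventions vary between labs.

## Synthetic data

Generators are pure functions of (parameters, seed) with no global random
state, emitting bitwise-reproducible tables in the same CSV schemas the
fitting modules read. Defaults mirror the assay designs the analyses
assume: √10 serial dilutions (10–11 steps plus a zero condition), 8
technical replicates for chromophore titrations and 3 for pH sweeps,
kinetic sampling every 12–30 s, 200-frame bleach series at ~0.885 Hz, and
5 Hz ROI cohorts with a stimulation frame and background channels.

The noise law is multiplicative Gaussian with CV 5% plus an optional
additive floor — chosen because replicate scatter in plate-reader data is
predominantly proportional to signal, while no explicit noise model is
available to copy. What the generators deliberately do **not** emulate:
instrument drift, spectral crosstalk, pipetting bias, well-position
effects, photobleaching during titration reads, or segmentation error in
ROI traces. Passing recovery tests therefore demonstrate estimator
correctness and statistical efficiency under idealized i.i.d. noise, not
robustness to structured artifacts in real recordings.

## Problem sizes and tolerances

Recovery suites use 50 seeded datasets per scenario at 5% CV (median
relative error ≤ 15% asserted, ≤ 10⁻⁶ noiseless); solver-equivalence
suites use 100 random systems against 200-iteration bisection oracles
(agreement within 10⁻⁶); the pH evaluate/invert round trip is checked to
10⁻⁹ over 100-point grids. These sizes give stable medians while keeping
the default suite quick on a laptop. Degenerate inputs (flat titrations,
constant kinetic traces, zero denominators, out-of-range ratios) raise
typed errors rather than returning arbitrary parameters.

## Known limitations

- Chromophore-exchange kinetics (on/off rates), global multi-curve fits
  and Bayesian posteriors are out of scope; uncertainties are
  least-squares covariances.
- The ternary model assumes one analyte site coupled to one chromophore
  site; multi-site cooperativity (Hill n > 1) is fit-diagnosable but not
  mechanistically modeled.
- Competition modeling is equilibrium-only; approach-to-equilibrium in
  displacement assays is described by the empirical monophasic fit.
- ROI geometry, image segmentation and motion tracking are upstream of
  this package: inputs are per-ROI scalar traces.
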