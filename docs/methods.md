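# Methods

`serobind` packages the quantitative analyses used to characterize how a
histone-tail modification changes binding to a reader domain — here the
Taf3 PHD finger reading H3K4-methylated tails with and without glutamine-5
serotonylation.  Four measurement chains are implemented end to end:
isothermal titration calorimetry (ITC), affinity-ratio statistics,
two-state NMR line-shape analysis, chemical-shift-perturbation (CSP)
statistics, and NOE distance-restraint calibration.  A synthetic-data
module generates inputs with the statistical structure each fitter
assumes, so the whole pipeline is testable without any deposited data.

## ITC: one set of sites

The forward model is the Wiseman isotherm for `n` identical independent
sites.  After injection *i*, with dilution-corrected cell protein `M_i`
and cumulative ligand `X_i` (each injection of `dV` scales cell contents
by `1 − dV/V0` and adds ligand at `syringe_conc · dV/V0`), writing
`r = X/(nM)` and `k = K_D/(nM)`:

    Q_i = (n · M_i · ΔH · V0 / 2) · [1 + r + k − sqrt((1 + r + k)² − 4r)]
    ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2 + q_dil

The second term corrects for liquid displaced from the active volume; the
constant `q_dil` absorbs the dilution heat instead of subtracting a blank
titration.  `one_site_heat` agrees with a brute-force mass-balance solver
to better than 10⁻⁶ relative over wide random parameter draws (tested).

Fitting (`fit_one_site`) is bounded nonlinear least squares in
(n, log₁₀K_D, ΔH, q_dil); standard errors come from the Gauss–Newton
curvature at the optimum scaled by the residual variance.  Both floating
and fixed `n` are supported (`fix_n`), as is discarding leading
injections (`skip_first`); defaults float `n` and keep all injections.
The default protocol is 29 × 10 µl of 300 µM peptide into 30 µM protein
at 20 °C in a 1.4 ml cell (a typical active volume for this calorimeter
class).  Units are SI internally, µcal/µM at the file boundary.

Thermodynamic decomposition uses ΔG = RT ln K_D (K_D in mol/L) and
TΔS = ΔH − ΔG.

## Affinity-ratio statistic

For two fitted affinities `K_D,A ± s_A` and `K_D,B ± s_B` the ratio
`ρ = K_D,A / K_D,B` carries the first-order (delta-method) standard error
`s_ρ = ρ·sqrt((s_A/K_D,A)² + (s_B/K_D,B)²)` under uncorrelated errors,
and `z = (ρ − 1)/s_ρ` is tested two-sided at 99 % confidence
(z_crit = 2.5758, strict inequality).  This linear-scale propagation, with
the null at ρ = 1, is the convention that reproduces the published ratio
table to its printed precision; a log-scale variant is available
(`log_scale=True`) but is not the default.  Zero-SE corner cases are
reported explicitly (`degenerate` flag) rather than silently.

Published Z-scores were evidently computed from unrounded fit results, so
recomputation from the rounded, printed K_D ± SE pairs reproduces them
only to about ±0.3; ratios reproduce to ±0.02 and all significance calls
exactly.  The tests assert at those tolerances.

## Two-state exchange line shapes

A resonance exchanging between free and bound environments evolves, in
each spectral dimension, under `L = iΩ − R + K` with
`K = [[−k_fb, k_off], [k_fb, −k_off]]` and `k_fb = k_off · p_b/p_f`; the
populations come from the 1:1 binding quadratic at the sample's total
concentrations.  The modelled experiment is an HSQC with a 1.2 ms
zz-filter (exchange-only evolution: magnetization is longitudinal, so no
shift or transverse relaxation acts; longitudinal relaxation during this
short delay is neglected) and 0.6 ms of indirect-dimension evolution at
both t1 edges.  Processing applies exponential line broadening (10 Hz
direct / 15 Hz indirect), halves the first time-domain point, zero-fills
to a power of two (factor 2) and Fourier transforms; a first-order phase
correction in the indirect dimension compensates the linear phase roll
the edge delays impose, as in real processing.

All propagators are 2×2, so each residue's signal is a sum of four
complex exponentials.  Matrix exponentials are evaluated by closed-form
eigendecomposition of the 2×2 generator; the simulator matches a
brute-force ODE integration of the evolution equations to 10⁻⁶ relative
(tested).  The fitter evaluates the discrete Fourier transform of the
apodized, truncated exponentials analytically (finite geometric series)
only inside per-residue rectangular regions (default half-width five
linewidths around the free and bound positions; overlapping regions are
rejected), which makes the joint fit cheap enough for bootstrap and
profile searches.

The joint titration fit shares `k_off` and `K_D` (inside an optional box
restraint, e.g. 100–400 nM when prior affinity knowledge warrants it)
across all spectra and residues, with per-residue free/bound shifts, one
R2 per residue per dimension per state, a per-residue amplitude, a
per-spectrum amplitude (first spectrum anchored at 1), and one global
ligand-concentration scale factor compensating concentration errors.
Free-shift starting values are sub-grid (parabolic) apo peak positions;
bound shifts start at the end-point spectrum maxima; `k_off` from a
coarse 1-D scan with analytic amplitude rescaling; `K_D` at the centre of
its box.  The optimizer is bounded trust-region least squares with
numerical derivatives, followed by a tightly-converged polish — the
profile-based confidence search below compares sums of squares at ~10⁻⁵
relative precision, so the reference optimum must be solid.

Uncertainties:

* **Bootstrap SE** (default 100 replicas): residual resampling — fit
  residuals pooled over all regions are resampled with replacement onto
  the fitted surface and each replica refit warm-started.  Residual
  resampling preserves the fixed titration design.
* **95 % confidence limits**: grid search fixing `k_off`, refitting all
  other parameters (warm-started from the neighbouring grid point), with
  the threshold `SSR ≤ SSR_min · (1 + F(1, N−p; 0.95)/(N−p))` — the
  one-fixed-parameter profile convention.  Endpoints are interpolated
  linearly in `sqrt(SSR − SSR_min)` versus log k_off, which is exact for
  a locally quadratic profile and therefore insensitive to grid spacing.
  Intervals still open at a grid edge are flagged.  The relative SSR
  increase at the threshold depends on N−p; for desk-scale region fits it
  is of order 10⁻⁴–10⁻², smaller than for fits over a few spectra at full
  resolution.

Default acquisition for synthetic studies: 900 MHz ¹H frequency, 3 ppm ×
26 ppm windows, 256 × 128 complex points.  These are deliberately modest
grids — enough to resolve the free/bound peaks and transfer features —
so that the recovery grid (3 × 3 in k_off × K_D), the 20-replicate
coverage study and the bootstrap all run on one CPU in minutes.  At
spectral SNR 50 the median k_off recovery error across the grid is a few
percent and the F-grid intervals cover truth at close to their nominal
95 %.

## CSP statistics

Composite CSP: `sqrt(ΔδH² + (ΔδN/6.5)²)` in ¹H-equivalent ppm (¹⁵N
down-weighted by 6.5).  To isolate a modification-specific effect that is
shared across methylation states, shifts are first averaged per residue
across the unmodified-state complexes and across the modified-state
complexes (residues missing from some states are averaged over the
available ones, with coverage recorded), and the CSP is computed between
the two averages.  The detection threshold is the mean + 1 SD of the 50 %
smallest CSPs (⌊n/2⌋ values, ties at the cut broken by residue id; sample
SD with ddof = 1 — the population/sample choice is configurable since the
convention is not dictated by the procedure).  Flagging uses strict
inequality with a 10⁻⁹ relative guard so values equal to the threshold up
to floating-point rounding are not flagged.  Peak intensities are
normalized by anchoring a reference residue (a flexible C-terminal
residue unaffected by binding) to 1 in every spectrum; ratios between
modified and unmodified complexes exclude overlapped or missing residues
with the reason recorded.

## NOE calibration

Assigned peaks with s/n strictly above 8 are kept; reciprocal
observations of the same unordered proton pair are averaged; peaks to the
two protons of a diastereotopic methylene collapse into one ambiguous
restraint carrying the higher intensity.  Distances follow the
isolated-spin-pair relation `I = C·r⁻⁶` with the single constant `C`
anchored so the strongest peak maps to 2.1 Å; raw distances beyond 7.1 Å
are capped there and flagged.  The anchor convention is a package choice
(only the calibrated range is dictated by the procedure); a least-squares
calibration against reference distances can replace it.  Bounds are
lower = 1.8 Å (van der Waals contact, a community default) and
upper = target, with no extra tolerance.  Output dialects: XPLOR/CNS
`assign` statements (d/minus/plus convention, ambiguous sides as
`(name A or name B)` selections) and TSV; both round-trip through the
bundled readers.  Spin-diffusion-suspect NOEs are not detected
automatically — judging them requires comparing mixing times — but an
explicit exclusion list is supported by simply removing peaks before
calibration.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (truth, seed).  Noise is additive
i.i.d. Gaussian on the observable (heats, spectral intensities), except
NOESY intensities which carry multiplicative fractional noise with s/n
reported against a configurable constant noise floor.  The titration
design reproduces the study conditions: 0.19 mM labelled protein observed
at 0 %, 50 % and 150 % peptide; ITC follows the default protocol above;
exchange rates of tens to hundreds s⁻¹; binding shift changes ≤ 0.3 ppm
(¹H) and ≤ 3 ppm (¹⁵N).  The spectral noise level of real data is not
fixed by the study description, so it is a free parameter; studies here
use SNR 50 as a realistic cryoprobe-era figure.

The shift-table generator gives every unspiked residue a composite CSP of
*exactly* `background_scale` (only the direction in the (δH, δN) plane is
random) and every spiked residue exactly `spike_size`.  This makes the
trimmed-null detector's behaviour on generated tables deterministic —
with a continuous background-magnitude distribution, a mean + 1 SD
threshold over the lower half necessarily sits below the background
maximum and some background residues would be flagged, as indeed happens
with real data.  Passing the round-trip test therefore shows the
threshold arithmetic and bookkeeping are right, not that the detector has
perfect specificity on real spectra.

Not emulated: pulse-sequence artefacts, solvent signals, ¹³C dimensions,
peak-overlap pathologies, baseline drifts in ITC, and spin diffusion in
NOESY.  Conclusions from passing tests are about the estimators under the
stated noise model, not about robustness to those effects.

## Numerical choices and degenerate inputs

* Bound fractions use the numerically safe root of the binding quadratic;
  `p_b` is clipped to `[0, 1 − 10⁻⁹]` so the fully-bound limit never
  divides by zero (the vanishing state's component then decays
  instantly, which is the correct physics).
* Degenerate 2×2 eigensystems (coincident eigenvalues) are perturbed by
  10⁻⁹; with distinct free/bound shifts this path is never exercised in
  practice.
* The total-intensity invariance of exchange (integrated spectrum
  independent of k_off at fixed populations/relaxation/apodization) holds
  exactly only with the t1 edge delays disabled, because those delays
  give the two states k_off-dependent phases at detection; the invariant
  is tested at `t1_edge_delay = 0`.
* ITC fits parameterize K_D on a log scale with bounds 10⁻¹²–10⁻² M;
  non-convergence is reported via the `converged` flag, never silently.

## Known limitations

Three-state or induced-fit exchange, R1/ZZ-exchange experiments,
multi-site ITC models, automated peak picking, and docking are out of
scope.  The published k_off values themselves (48.8/16.8 and 207/71 s⁻¹)
are not reproducible without the underlying raw spectra; synthetic
recovery studies at matching rate scales stand in for them, and the
pipeline confirms the derived quantity that *is* computable from the
published numbers — the ~2.9-fold slowdown of dissociation upon
serotonylation.
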