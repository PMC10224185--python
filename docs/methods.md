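# Methods

## Spin simulation

Spectra are computed in the frequency domain from per-metabolite spin
systems (chemical shifts δ in ppm, scalar couplings *J* in Hz; shipped
in `src/benchnmr/data/metabolites.yaml` for the 19-metabolite fecal
panel, the internal standards TSP and formate, and succinate/taurine).
Shifts printed in the source study are marked `source: study` in that
file; the remainder are standard aqueous pH-7 reference values and are
flagged as such.

Two simulation routes exist:

* **First order** (`first_order_peaks`): each group of *n* equivalent
  protons resonates at its shift and is split by every coupled partner
  group of *m* spins into *m+1* lines with binomial intensities spaced
  *J/ν₀* ppm; splittings from distinct partners convolve. Valid when
  |Δν| ≫ J; used for systems larger than the Hamiltonian cap and as
  the default in cohort synthesis, where speed matters.
* **Exact** (`full_hamiltonian_peaks`): equivalent protons are expanded
  into explicit spins-1/2 sharing one shift (intra-group *J* is
  unobservable for magnetically equivalent nuclei and set to zero), the
  isotropic Hamiltonian *H = Σ νᵢIzᵢ + Σ Jᵢⱼ Iᵢ·Iⱼ* (Hz) is
  diagonalized, and single-quantum transition intensities are
  |⟨f|I₋|i⟩|² under equal high-temperature populations, normalized so
  total intensity equals the proton count. The state space is 2ⁿ,
  capped at n = 8; larger systems (glucose-with-anomers, isoleucine,
  leucine, phenylalanine) fall back to first order via `peaks_auto`.
  In strong coupling a handful of vanishingly weak combination
  transitions have a higher-M eigenstate below the lower-M one; they
  are folded to |ΔE|, which keeps intensity conservation exact.

Intensities are carried in proton equivalents, so weighting a peak list
by a concentration in mM makes a multiplet's rendered area equal
(concentration × proton count) in arbitrary units — this encodes the
field invariance of *J* and of integrated intensity.

The multiplet-envelope helper uses the convention multiplicity × J/ν₀
(e.g. a 7.70 Hz triplet occupies 3×7.70/60 = 0.385 ppm at 60 MHz), not
the peak-to-peak span (n−1)×J/ν₀; the extra spacing approximates the
linewidth skirt of the outer lines. Both conventions appear in the
literature; this package standardizes on the former and documents the
difference here.

**Rendering.** Lines are summed as area-normalized pseudo-Voigt
profiles (η·Gaussian + (1−η)·Lorentzian, default η = 0.1), plus an
optional polynomial baseline and seeded i.i.d. Gaussian noise in the
frequency domain. Default FWHM: 1.4 Hz at 60 MHz, 1.0 Hz at 800 MHz —
the linewidths of the two instrument classes are not published for this
assay, so these were chosen once to reproduce the qualitative
congestion of low-field spectra and are not revisited. Default grids:
32 768 points at 60 MHz and 65 536 at ≥ 400 MHz (matching the
acquisition time-domain sizes), spanning −0.5 to 10 ppm so the TSP
reference singlet at 0.0 ppm is fully covered. Time-domain noise
correlation is not modeled; the pipeline consumes frequency-domain
spectra, and the FID path exists for the apodization/transform
round trip.

## Cohort generator

The generator emulates the study design: two groups × 3 subjects ×
days 0–5 (36 samples per field), with fixed internal standards (TSP
0.5 mM, formate 1 mM). Per-sample concentrations are lognormal draws
(CV 20 %, guaranteeing positivity) around baseline × fold(group, day).
Baselines are phenomenological SCFA-dominated fecal-water values
(acetate 10 mM, butyrate/propionate 3 mM, …); they are free parameters
of `data/cohort_defaults.yaml`, not measured values. The treated-group
fold ramps linearly from 1 starting at day 2 to its day-5 target:
acetate ×2.5, succinate/glucose/taurine ×1.3 (up); butyrate ×0.5;
propionate, the branched-chain amino acids, alanine, aspartate,
glycerol, threonine ×0.7 (down). Directions follow the
discriminating-bin interpretation of the study; magnitudes are
explicitly synthetic. The acetate magnitude was fixed by a design-time
power analysis: with n = 3 per group and CV 20 %, a one-sided Welch
test at day 5 has power 0.88 at fold 2.0 but 0.96 at fold 2.5, and the
generator's purpose is to reproduce the study's day-5 significance as a
typical outcome, not a coin flip. A small chemical-shift jitter
(SD 0.003 ppm) per sample exercises the referencing step; per-spectrum
noise is max-signal/SNR with SNR 500. An unassigned fecal-matrix
background hump is off by default.

What passing tests on this generator do **not** show: robustness to
real-matrix backgrounds, solvent-suppression artifacts, pH-dependent
shift drift between samples, or metabolites outside the panel. The
generator's spectra are exactly the model the fitters assume, up to
noise and jitter, so recovery errors here are lower bounds on real
data.

## Processing chain

FIDs are multiplied by exp(−π·lb·t) (lb = 0.2 Hz, so lb adds directly
to the Lorentzian FWHM) and Fourier transformed. Automated phasing
minimizes the summed squared negative real intensity over (φ0, φ1) with
a multi-start Nelder–Mead; the original workflow phased manually, and a
manual (φ0, φ1) override is retained, with automated runs flagged in
metadata. Baseline correction fits a polynomial (default degree 3) by
iterative reweighting that zeroes points above fit + 2σ of the
negative-side residuals. Referencing locates the TSP maximum within
±0.3 ppm of 0 (requiring ≥ 5× the noise floor), refines it to sub-pixel
precision with a 3-point parabola — at 800 MHz one grid step is an
appreciable fraction of the linewidth — and shifts the axis so it sits
at 0.000 ppm exactly. Normalization divides by the TSP integral over
±0.05 ppm; normalized spectra carry a flag that binning enforces.

For **quantification** the internal-standard area is instead taken from
a lineshape fit of the TSP singlet (`normalize_by_tsp_fit`): the shape
(FWHM, η) is pre-defined once on the pooled TSP signal of the series or
cohort, after which only the amplitude is fitted per spectrum — a
matched filter. A fixed ±0.05 ppm window sum is noise-dominated at high
field, where the singlet is ~40× narrower than the window, and a fit
with free shape parameters suffers an η–area ambiguity at modest SNR;
the fixed-shape amplitude fit avoids both. The untargeted binning
branch keeps the simpler window rule, whose systematic tail loss is
common to all samples and harmless after scaling.

## Binning

Bins are half-open [left, left + 0.04) ppm tiled from 0; values are
trapezoidal integrals computed from the cumulative integral, so the
retained bins plus the excluded region account for the total area
exactly. The water window 4.5–5.0 ppm does not align with 0.04-ppm
edges; a bin is dropped when its **center** lies in the window, which
removes exactly the 13 bins [4.48, 4.52) … [4.96, 5.00) (centers
4.50–4.98), leaving 237 of 250. An "any-overlap" rule is available.
Only uniform-width binning is supported.

## Chemometrics

Scaling: Pareto divides centered columns by √sd, UV by sd (ddof = 1);
zero-variance columns are centered only and reported. PCA is the SVD of
the scaled matrix; explained fractions are eigenvalue ratios. OPLS-DA
encodes the two classes as centered ±1 and alternates: find the PLS
weight w ∝ Xᵀy, extract a component orthogonal to it from the loading,
deflate X, repeat for n_ortho components (default 1), then fit one
predictive component on the deflated X. R²X counts predictive plus
orthogonal X-variance; R²Y is the fit of y by the predictive component;
Q² = 1 − PRESS/SS from k-fold cross-validation (default 7-fold,
venetian-blind fold assignment by sample index, deterministic). The
predictive component is oriented so the treated-class mean score is
positive, making S-line signs reproducible (positive covariance =
higher in treated). VIP for the single predictive component is
√p·|w|/‖w‖, so ΣVIP² = p exactly. The days-2–5 subset is the default
for PCA/OPLS-DA (the day-2 boundary is inclusive; both subsets are
selectable). Model validity is checked by label permutation: the true
Q² should exceed ≥ 95 of 100 permuted-label Q² values.

## Quantification

* *Region integration*: trapezoidal integral of a fixed window
  (1.80–2.04 ppm at 60 MHz — wide enough for the broadened singlet plus
  shoulders — and 1.90–1.94 ppm at 800 MHz).
* *Generalized-Lorentzian fit*: the named vendor lineshape has no
  published formula; it is implemented as a pseudo-Voigt with free
  mixing η, plus an optional kurtosis exponent (off by default), and
  documented as an interpretation. The window model is the target peak
  + up to 2 nuisance peaks + a local linear baseline, solved by
  trust-region least squares with an analytic Jacobian, explicit
  parameter scaling, ftol 10⁻¹⁰ and a 500-iteration cap (reaching the
  cap is valid termination; only solver failure raises). Nuisance peaks
  initialize on residual maxima; component widths are bounded to
  [⅓, 4]× the initial linewidth (every component is a resonance line —
  broad blobs belong to the baseline, whose offset is bounded by the
  window-edge signal level so it cannot trade area with the peak).
  Components stacked within 0.7 FWHM of the target are summed: they are
  unresolvable splits of one physical line.
* *Template fit*: per-metabolite reference multiplets rendered at 1 mM
  at the spectrum's field with the TSP-calibrated lineshape, divided by
  the fitted TSP area of a 0.5 mM TSP rendering (the same normalization
  the samples receive), then non-negative least squares; amplitudes are
  mM. Templates are interpolated onto each sample's referenced axis.
  An ill-conditioned template matrix triggers a condition-number
  warning.

Responses convert to mM through a calibration line fit by OLS on a
simulated 2–20 mM sodium-acetate series in triplicate (noise fixed at
top-level-max/500 across levels), which cancels each method's own
systematic window/tail bias. Agreement against a designated reference
(template fitting on the 800 MHz spectra, or ground truth when only one
field is simulated) is summarized by paired differences with a
t-distribution 95 % CI (n is small), MAE, and per-sample absolute
percentage error. Group comparisons use Welch's unequal-variance t-test
(Satterthwaite df; the day-5 comparison is one-sided because the
hypothesis is directional) and one-way ANOVA with Tukey's HSD, α = 0.05.

## Numerical choices and problem sizes

Repeated-cohort properties (the 50-seed replicate study in the tests
and `analysis/05_replicate_study.py`) synthesize 60 MHz spectra on
4 096-point grids and calibrate on 8 192-point grids: at 0.04-ppm bins
and 1.4 Hz linewidths this oversamples every feature (≈ 9 points per
FWHM) while keeping a full 50-replicate study under a few minutes.
Single-study analyses use 4 096/32 768 points (60/800 MHz); the
simulator's own defaults remain 32 768/65 536. 800 MHz quantification
requires ≥ 4 points per FWHM, i.e. ≥ 32 768 points over 10.5 ppm.

Degenerate inputs are rejected loudly: empty FIDs, non-monotone axes,
single-row scaling, classes with < 2 members, calibrations with < 3
distinct levels or zero response variance, regions outside the axis,
referencing without a TSP peak above 5× noise.

## Known limitations

* First-order simulation is used for cohort synthesis by default;
  strong-coupling distortions are exact only through `peaks_auto`/
  `full_hamiltonian_peaks` for systems of ≤ 8 spins.
* The metabolite library is a single-anomer, simplified-coupling
  description; it reproduces footprints and overlap structure, not
  literature-exact fine structure.
* Quantification is internal-standard based throughout; absolute
  traceability (ERETIC/PULCON) is out of scope.
* Real fecal-extract backgrounds, solvent suppression artifacts and
  vendor raw formats (Bruker/Magritek directories) are unsupported;
  spectra enter as JCAMP-DX or two-column CSV.
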