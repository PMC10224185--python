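# benchnmr

Benchtop (60 MHz) versus high-field (800 MHz) ¹H NMR metabolomics of
fecal extracts, as a fully simulated, tested pipeline.

Cryogen-free benchtop NMR spectrometers make metabolomics cheap and
portable, but at 60 MHz chemical-shift separations (in Hz) shrink to the
order of the scalar couplings *J*, so multiplets broaden (an *n*-line
multiplet occupies *n·J/ν₀* ppm) and overlap. This package asks,
end-to-end and with known ground truth, what that costs: it simulates
field-dependent spectra of a 19-metabolite fecal panel (plus internal
standards TSP and formate) for a two-group cohort — healthy controls vs
a colitis-model ("DSS") group of 3 subjects each, sampled on days 0–5 —
then runs the standard untargeted and targeted analyses on both fields'
data:

* **Spin simulation** — first-order (binomial) multiplets, or exact
  diagonalization of the isotropic spin Hamiltonian
  *H = Σᵢ νᵢ Iz⁽ⁱ⁾ + Σᵢ<ⱼ Jᵢⱼ Iᵢ·Iⱼ* for systems of ≤ 8 spins, so strong
  coupling (AB-type roof effects) at 60 MHz is exact; pseudo-Voigt
  rendering with noise and baseline.
* **Processing** — exponential apodization (0.2 Hz) + FT, automated or
  manual phase correction, iteratively reweighted polynomial baseline,
  chemical-shift referencing to TSP at 0.0 ppm and normalization to the
  TSP peak area.
* **Binning** — 0.04-ppm integrals over 0–10 ppm, residual-water window
  4.5–5.0 ppm excluded.
* **Chemometrics, from scratch** — Pareto/UV scaling, PCA, and
  two-class OPLS-DA (one predictive + *n* orthogonal components) with
  R²X/R²Y/Q² (7-fold venetian-blind CV), VIP scores and the S-line
  (covariance/correlation of each bin with the predictive score).
* **Quantification** — acetate by three internal-standard strategies:
  window integration, generalized-Lorentzian (pseudo-Voigt) peak
  deconvolution with nuisance peaks, and non-negative template fitting
  with the lineshape pre-defined by the TSP signal; 2–20 mM calibration
  curves; paired-difference agreement statistics (mean, SD, SE, t-based
  95 % CI, MAE, absolute percentage error); Welch and ANOVA/Tukey group
  comparisons.

Because every sample is synthetic, recovered concentrations and
discriminant patterns can be scored against exact ground truth — which
is the point: the pipeline demonstrates *why* region integration fails
at 60 MHz (neighboring multiplets invade the acetate window) and that
lineshape deconvolution repairs most of the damage.

## Worked example

The numbered scripts under `analysis/` run the study in order; all
randomness flows from `--seed`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_process_and_bin.py --seed 1
python analysis/03_multivariate.py   --seed 1
python analysis/04_quantify_acetate.py --seed 1
python analysis/05_replicate_study.py --seed 1 --n-runs 50
```

Script 03 prints, for seed 1:

```
   60 MHz: PC1/PC2 = 63.8%/8.4%; OPLS-DA R2X=0.707 R2Y=0.747 Q2=0.394
          separated from day 3: True; S-line signs ok: True; top VIP bins (ppm): [1.9, 1.94, 0.9, 1.98, 1.86]
  800 MHz: PC1/PC2 = 64.1%/4.8%; OPLS-DA R2X=0.669 R2Y=0.906 Q2=0.524
          separated from day 3: True; S-line signs ok: True; top VIP bins (ppm): [1.9, 1.94, 0.9, 2.18, 0.94]
```

i.e. on both fields the treated group separates completely from day 3
along the predictive score, and the top discriminating bins are the
acetate singlet (1.9 ppm, increased) and the butyrate/branched-chain
region (0.9 ppm, decreased). Script 04 prints the calibration curves
(r² ≥ 0.9995 for all three methods) and the agreement of each 60 MHz
method with the reference (template fitting on the 800 MHz spectra):

```
region   vs reference (template fit @800): MAE=1.155 mM, 95% CI of diff (+0.941, +1.266), APE=11.0%
gl       vs reference (template fit @800): MAE=0.379 mM, 95% CI of diff (-0.492, -0.234), APE=2.7%
library  vs reference (template fit @800): MAE=0.219 mM, 95% CI of diff (-0.303, -0.042), APE=1.3%
day-5 acetate, treated > control (one-sided Welch): t=5.11, df=2.19, p=0.0150
```

— region integration carries an order-of-magnitude larger error than
either curve-fitting strategy, and the day-5 group difference is
significant. Script 05 repeats the whole study on 50 seeds and prints
the reproduction rates (50/50 separation, 1.2 % mean GL recovery error,
49/50 day-5 significance for seed 1).

The same stages are available as a CLI (`benchnmr simulate-cohort`,
`process`, `bin`, `pca`, `oplsda`, `calibrate`, `quantify`, `run-all`)
and as library functions (`benchnmr.workflow`). Spectra read and write
as JCAMP-DX (XYDATA, AFFN or SQZ/DIF/DUP) and two-column CSV.

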