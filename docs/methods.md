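# Methods

`nirqc` implements the complete chemometrics workflow behind a non-invasive
(through-vial) near-infrared quality-control system for Lanqin oral solution
(LOS), a five-herb TCM formulation: four quality indicators — the ANTI-NO
anti-inflammatory endpoint and the marker analytes epigoitrin, geniposide and
baicalin — are calibrated against absorbance spectra over 10,000–4000 cm⁻¹
(1557 points) by partial least squares regression after pretreatment and
wavenumber selection. Because the original 101-batch dataset was never
deposited, the package pairs the workflow with a synthetic generator that
reproduces the statistical structure every stage assumes; all stochastic
claims in the test suite are therefore claims about that generator, not about
laboratory data.

## The calibration workflow

For one indicator and one acquisition system:

1. **External holdout.** ⌈10%⌉ of samples (11 of 101) are drawn at random
   and set aside; they touch no modelling stage.
2. **SPXY division.** The remaining samples are split 3:1
   (67/23 for n = 90; half-down rounding of 0.75·n) by the joint x–y
   distance d(i,j) = dx(i,j)/max dx + dy(i,j)/max dy, with dx Euclidean on
   the spectra and dy = |yᵢ − yⱼ| on the indicator being modelled. Selection
   is Kennard–Stone max–min seeded with the maximal-distance pair; ties
   break toward the lowest row index, so splits are deterministic. Each
   indicator gets its own division. The division runs on raw spectra: it
   precedes pretreatment choice, and the criterion that would pick a
   pretreatment does not exist yet at this stage.
3. **Pretreatment scan.** raw, unit-vector normalization (min–max available
   behind `norm_kind`), SNV, Savitzky–Golay smoothing (window 11, order 2,
   derivative 0), and MSC. MSC's reference spectrum is the calibration mean,
   frozen before prediction/validation rows are transformed. Each candidate
   is scored by the leave-one-out RMSECV of a global PLSR (LVs chosen on the
   same curve); minimum wins, ties to fewer LVs.
4. **Wavenumber selection.** SIPLS (exhaustive best union of m of k
   contiguous intervals; first `n mod k` intervals one point longer), CARS
   (Monte-Carlo row subsampling, exponential enforced elimination from p
   down to exactly 2 variables, |coefficient|-weighted reweighted sampling),
   and random frog (reversible-jump subset walk whose visit frequencies
   become selection probabilities; final subset is the best top-j cut).
   Selector-internal CV is 5-fold for speed (switchable to leave-one-out);
   the three winners are then re-scored on a common footing by leave-one-out
   RMSECV, and the best subset wins (ties: fewer LVs, then fewer variables).
5. **Final model and metrics.** PLSR refit on the selected subset;
   Rc/RMSEC/RSEC on calibration, Rp/RMSEP/RSEP/RPD on prediction, and
   Rv/RMSEV/RSEV plus a Wilcoxon rank-sum p on the external validation set.

PLS1 is a NIPALS decomposition of the mean-centered blocks (no autoscaling —
standard for absorbance spectra). For a single response each component is
closed-form, and the compacted regression vector is accumulated incrementally
so one decomposition yields the coefficient path for every LV count up to
`max_lvs` (default 15); that is what makes leave-one-out selection affordable
at n ≈ 67, p ≈ 1557. Deflation that exhausts X'y (squared norm ≤ 1e-12) ends
the path early and later counts repeat the last attainable coefficient
vector; an exactly constant response yields the zero-coefficient mean
predictor with a warning rather than an error.

## Metric conventions

Fixed by recomputing the published external-validation tables from their
printed per-sample pairs (every cell reproduces to printed precision):

* R = √(max(0, 1 − SSres/SStot)) — the residual-based coefficient, **not**
  Pearson's r (the two disagree by 0.015 on one published column, and only
  the residual form matches all printed cells); clamped at 0 when a model is
  worse than the mean.
* RSE = 100·√(SSres/Σy²) (residual norm over reference norm, percent).
* RMSE = √(SSres/n).
* RPD = sd(prediction-set reference, n−1)/RMSEP, pass flag at 3. The
  published RPD cells are not exactly consistent with any tested convention
  (printed sd/RMSEP gives 5.03 where 4.95 is printed), so RPD is reported
  but never asserted as an equality.
* Wilcoxon rank-sum via the Mann–Whitney U (exact when both n ≤ 20 and no
  ties; otherwise normal approximation with tie and continuity corrections);
  the statistic is reported as the rank sum of the first sample.
* Distance correlation is the standard double-centered dCov/dVar ratio with
  an add-one-smoothed permutation p; it is implemented directly (about 30
  lines) and cross-checked against a from-definition double loop in the
  tests.

ANTI-NO is stored as a fraction everywhere; report layers may print percent.

## The synthetic generator

`SyntheticConfig` defaults are the study conditions: 35 undiluted batches
with analyte concentrations uniform over the reported ranges
(epigoitrin 0.02546–0.0702, geniposide 2.388–7.413, baicalin
0.9230–3.131 mg/mL), plus 66 diluted samples whose concentrations are a
random undiluted parent's divided by a factor cycled through
{1.25, 1.67, 2.5, 5} (the real dilution schedule is unpublished). Spectra
are Beer–Lambert mixtures of Gaussian-band component profiles — water
(O–H first overtone near 6900 cm⁻¹, combination band near 5150 cm⁻¹),
the three analytes (six bands each, widths 60–300 cm⁻¹, placed in their
assignment regions), and a lumped "matrix" component for the several hundred
unresolved constituents — plus a degree-2 random baseline (±0.03 AU),
per-sample multiplicative scatter (sd 2%), and white noise (sd 0.002 AU).
The through-vial spectrum scales the mixture by the 12 mm/4 mm path ratio
(3) and adds a smooth per-vial glass curve (amplitude 0.1 AU, 10% vial-to-
vial coefficient spread); the empty-vial spectrum is that curve plus noise.
Scatter and baseline draws are shared between the two liquid measurements of
a sample, so the degenerate config (noise = vial = baseline = 0,
path ratio = 1) makes the modes exactly equal.

Bioactivity is simulated through the Griess assay itself: per batch,
NO concentrations Cm ~ N(45, 2) µM (model group) and Cc ~ N(8, 1) µM
(control) are drawn, the drug group is Cd = Cm − (Cm − Cc)·f + ε with
ε ~ N(0, 0.5 µM), f = logistic(10·epigoitrin + 0.18·geniposide +
0.36·baicalin + 0.7·matrix − 1.2 + latent), latent ~ N(0, 0.08), and
ANTI-NO = (Cm − Cd)/(Cm − Cc). The logistic keeps undiluted activity in a
narrow band (≈0.69–0.92, bracketing the reported 0.7555–0.8897) while the
concentrations vary ~3-fold, ties activity to every component at once, and
lets the strongest dilutions reach ≈0.33 as the reported calibration range
does. The weights were chosen once from that range calculus and are
configurable.

What the generator does **not** emulate: instrument line shape and
resolution effects, wavelength-dependent pathlength, temperature shifts,
detector nonlinearity, analyte–analyte spectral interactions, and any real
covariance between analyte concentrations across batches beyond the shared
dilution factor. Passing recovery tests therefore show the algorithms work
under the assumed signal model, not that real LOS spectra carry enough
information — the published validation tables are the only real-data anchor,
and only their metric arithmetic is reproducible.

One measured gap: the representativeness property of SPXY (calibration
ranges bracketing prediction ranges) holds in ~91% of seeded synthetic runs
aggregated over indicators (99% for ANTI-NO, ~75% for baicalin on raw
spectra) rather than essentially always as the real study observed, because
the minor analytes' y-extremes are less spectrally salient than scatter in
the synthetic mixtures. The property test asserts an 85% floor plus strict
superiority over a random split of the same size (~57%).

## Problem sizes and numerical choices

* Orchestrated-search defaults are sized so a four-indicator search on one
  system runs in ~20 s: SIPLS scans k = 18 with m ∈ {2, 3}; CARS 50 runs at
  80% row sampling; random frog 300 iterations (the standalone selector
  default is 1000), q₀ = 0.1p, θ = 0.3, ω = 3, η = 0.1. All are config.
* Stochastic test properties use 10–20 seeds; selector recovery uses the
  100 × 200 planted design with five informative variables at 5× noise sd.
* CV folds are contiguous and deterministic; cv = n is leave-one-out.
* The CARS retention schedule is computed in the algebraically equivalent
  power form (p/2)^((1−i)/(N−1)) with an epsilon-guarded ceiling so the
  endpoint identities (start at p, end at 2) are exact in floating point.
* Grid uniformity is validated at relative tolerance 1e-6; CSV round-trips
  are lossless (17 significant digits out, round-trip parsing in).
* All randomness flows from a single top-level seed (NumPy `SeedSequence`
  spawning); identical seed ⇒ byte-identical reports, asserted in tests.

## Known limitations

* The published optimal-model table (variable counts, LV counts, Rc/Rp
  cells) depends on the never-deposited spectra and is not reproducible;
  it is carried as descriptive context only.
* SIPLS guarantees "subset no worse than full spectrum" only when the
  scanned combinations include m = k; fixed small m offers no such bound.
* The through-vial system is modelled on raw through-vial spectra; the
  empty-vial difference spectrum is available (`subtract_vial`) as a
  variant but is not part of the default search.
* Proprietary instrument formats (SPC, TQ Analyst projects, JCAMP-DX) are
  out of scope; I/O is CSV only.
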