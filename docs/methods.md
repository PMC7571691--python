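# Methods

This note documents the models, estimators and numerical choices behind
`dcm-phenolink`, and what the synthetic-data generators do and do not
emulate.

## Sarcomere length and packing density (`dcm_phenolink.spd`)

**Model.** A striated cardiomyocyte immunostained for alpha-actinin shows
z-disc bands spaced by the sarcomere length SL (physiologically 1.3–3.0
µm). The 2D Fourier power spectrum of a 200×200 px region of interest
(ROI) concentrates this periodicity into peaks at multiples of the
fundamental spatial frequency f₀ = 1/SL along the striation normal. The 1D
radial profile Γ(f) of a 30° spectral wedge centred on that orientation is
fitted with

```
Γ(f; ζ) = a0·exp(−f/b0) + Σ_{k=1,2} a_k·exp(−(f − k·f0)² / b_k),
ζ = {a0, b0, a1, b1, a2, b2, f0}
```

an aperiodic exponential decay plus Gaussian peaks at the first two
harmonics. Then SL = 1/f₀ and the sarcomere packing density

```
SPD = ∫ Γ_p df / ∫ Γ df  ∈ [0, 1]
```

is the periodic share of spectral power — a brightness-invariant measure
of striation organization. For peaks far from zero frequency the integrals
have closed forms ∫Γ_ap = a0·b0 and ∫Γ_p = Σ a_k√(π·b_k), which the
quadrature implementation reproduces to 1e-6 relative whenever
f₀ ≥ 5·√(max(b1,b2)/2).

**Numerical choices.**

- ROI is mean-subtracted and tapered with a 2D Hann window before the FFT
  (a flag disables the window; Parseval checks run unwindowed). Windowing
  suppresses edge leakage that otherwise inflates the aperiodic term.
- With no ROI given, the highest-variance 200×200 window on a 50-px grid
  is used; striated regions have high local variance.
- Orientation = argmax of a 1°-binned angular power histogram restricted
  to the 0.3–0.8 cycles/µm radial band (where the fundamental of a 1.3–3
  µm lattice lies); ties break to the smallest angle. The estimate is
  flagged low-confidence when less than one third of band power falls in
  the ±15° wedge (an isotropic spectrum puts 1/6 there).
- Profile = mean power per radial bin (bin width = the ROI's spectral
  resolution, 1/(200·pixel size)) over the wedge; angles are computed
  mod 180°, which folds the two Hermitian-symmetric wedge halves together.
  DC and f < 0.05 cycles/µm are excluded.
- The fit runs in linear power with nonnegativity bounds, f₀ confined to
  [1/3.0, 1/1.3] cycles/µm, multistart from the top-3 smoothed in-band
  local maxima (a0/b0 from a log-linear fit to off-peak bins, b1 = b2 =
  0.01 initially); lowest residual wins, ties to smaller f₀.
- SPD integrates the fitted model by adaptive quadrature; `analyze_image`
  uses the image Nyquist frequency as the upper limit, `sarcomere_metrics`
  defaults to the half-line (the model decays, so the difference is
  negligible and covered by the closed-form cross-check).

## Calcium-transient kinetics (`dcm_phenolink.calcium`)

Paced ratiometric (F340/F380) traces are split into one-period windows
anchored at stimulus times (or detected upstrokes). Per beat:

- **Baseline** = median of the diastolic region — the pre-upstroke segment
  when the window carries one, else the trailing quarter of the window.
  The median is unbiased under symmetric noise, unlike a low-percentile
  statistic; when the trailing region is used, the residual decay still
  present there is estimated from the fitted exponential and removed in up
  to three refinement iterations.
- **Amplitude** = parabolic-vertex peak (on a 3-sample median-smoothed
  copy) minus baseline: unbiased for a smooth extremum and much less
  sensitive to single noise excursions than a raw maximum.
- **Decay**: t50/t90 are interpolated recovery times; tau comes from a
  monoexponential least-squares fit from t50/3 after the peak (the
  ~80%-amplitude point; the first post-peak samples still carry upstroke
  shape and would inflate tau) down to 90% recovery, with the asymptote
  pinned to the measured baseline and the rate bounded within 8× of
  ln2/t50. The free three-parameter fit admits near-linear degenerate
  optima on noisy segments; the pinned, bounded form removes them. Both
  deviations from the naive "fit from the peak with free offset" are
  required to keep amplitude and tau unbiased within 5% at 20 dB SNR,
  which simulation confirms.
- **Per cell**: median across beats per metric with per-metric counts;
  beats whose fit failed still contribute model-free metrics.

## Contractility and EHT force (`dcm_phenolink.contractility`)

**Block matching.** Frames are tiled into 16-px blocks; per consecutive
frame pair each block takes the integer displacement (within ±8 px)
maximizing normalized cross-correlation. Candidates are scanned in order
of increasing magnitude (then raster order) and only a strictly better
score replaces the incumbent, so ties resolve to the smallest
displacement — a property the naive reference implementation in the test
suite mirrors exactly. Blocks with sub-threshold texture variance or
without any in-frame candidate window are invalid; matches on the search
boundary carry a saturation flag (magnitude is then a lower bound only).
The mean displacement magnitude over valid blocks times the frame rate
gives the speed trace; a quadratic Savitzky–Golay filter (5 pairs)
suppresses integer-quantization noise without flattening velocity peaks,
and contraction/relaxation peak pairs define beats.

**EHT force.** A tissue bending a cylindrical elastic post with tip
deflection d exerts F = 3π·d·E·r⁴/(4L³) (tip-loaded cantilever; defaults
E = 1.7 MPa, r = 0.5 mm, L = 10 mm — with d = 0.1 mm this gives
2.5035×10⁻⁵ N). Per contraction cycle the rest position is the minimum
over the quarter-interval preceding the peak, which tracks slow baseline
drift to within ~1% for drifts up to ~40% of the peak amplitude over a
recording.

## Linkage, homozygosity mapping, variant filter (`dcm_phenolink.linkage`)

**Likelihood.** Classic parametric two-point linkage: biallelic disease
locus (frequency q, penetrance triple for 0/1/2 disease alleles) and one
multi-allelic marker at recombination fraction θ. Founders draw phased
two-locus genotypes from Hardy-Weinberg/linkage-equilibrium priors; a
child's gamete takes both alleles from one parental haplotype with
probability (1−θ)/2 each, or recombines with probability θ/2 per phase.
The exact likelihood is computed by variable elimination over phased
per-individual states — a generalization of Elston-Stewart peeling that is
exact on looped (consanguineous) pedigrees without loop-breaking. Feasible
states are pre-filtered by observed marker genotypes and zero-penetrance
phenotype combinations; a configurable bound (10⁷ states) guards factor
sizes. Marker allele frequencies default to uniform over the alleles
observed in the family — an explicit founder-prior assumption that matters
when founders are untyped. Defaults mirror the conventional recessive
model: penetrance (0, 0, 0.99), q = 0.001 (0.01 as the published
alternative), θ grid {0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4}.

Lod(θ) = log₁₀ L(θ) − log₁₀ L(0.5); θ̂ is the grid argmax. Multipoint Lod
scores are out of scope.

**Shared ROH.** Maximal runs where every affected member is homozygous for
the same allele (a homozygosity-by-descent proxy; a flag relaxes to
per-individual homozygosity), with runs shorter than 4 cM dropped —
equality at the threshold is kept, a measure-zero distinction on a
continuous map. Surviving runs are annotated with unaffected members who
share the homozygous haplotype across the span (exclusion evidence).

**Variant filter.** A candidate survives when it lies in the interval, is
homozygous-alt in every affected (a missing genotype fails — segregation
unconfirmed), not homozygous-alt in any unaffected, and its population
frequency (≤0.01) and healthy-homozygote count (≤0) pass — missing
annotations mean "not reported" and pass, mirroring how an absent database
entry is treated in practice. Rejections log the first failing rule in
that fixed order.

## Synthetic data (`dcm_phenolink.synth`)

The generators define the study conditions for every test:

- **Images** (default 512×512 px at 0.1 µm/px; tests use 256×256, the ROI
  is 200×200 regardless): Gaussian-profile striation bands (sd =
  period/6, so a genuine second harmonic exists) at a set period (~1.8 µm)
  and orientation cover an `organized_fraction` of the field, delineated
  by a thresholded smooth random field (24-px correlation length, small
  relative to the ROI so any window samples ≈ the global fraction). The
  rest carries isotropic punctate blobs with a log-uniform radius mixture
  (0.10–0.60 µm) at matched mean intensity; a radius mixture gives the
  smoothly decaying spectrum of real punctate staining, where a single
  size would leave a sharp spectral shoulder that masquerades as a peak.
  Additive Gaussian noise last.
- **Calcium traces** (50 Hz, 0.5 Hz pacing): per beat a saturating rise
  times exponential decay, normalized to unit peak so the requested amplitude
  is exact; ground-truth tau is the generator's decay constant. Tails of
  successive beats overlap by <1% of amplitude at the default constants.
- **Videos** (75 fps, 10 s): a static texture warped by a global
  raised-cosine displacement pulse train; ground truth stores per-frame
  displacement and the implied speed trace, and flags displacements that
  exceed the conventional search radius.
- **Gene drop**: forward simulation of the two-locus model above, with
  phased ground truth retained. The θ-recovery study uses a 22-member
  three-generation multiplex family (q = 0.25, full penetrance, 8-allele
  equifrequent marker) with replicates ascertained to ≥4 affected —
  phenotype-based ascertainment, which does not bias θ̂.
- **Variant tables**: one planted causal variant (homozygous-alt in
  affected, heterozygous obligate carriers, unreported frequency 0) among
  decoys that each violate at least one filter rule by construction.
  Positions are integers on a 10⁻⁴ cM scale; `interval_scaled` gives the
  matching filter interval.

**What passing tests do not show.** The generators emulate idealized
versions of the raw data: no photobleaching, cell segmentation errors,
focus drift, motion artefacts other than rigid translation, genotyping
error, allele dropout, or population stratification. Passing therefore
demonstrates correctness of the estimators under their stated models and
exactness of the likelihood machinery, not robustness to every real-world
artefact. Published group differences (organization, calcium kinetics,
force) depend on raw data that are not deposited and are not reproduction
targets; the pipeline instead verifies that differences of the reported
kind are detectable at the reported group sizes.

## Problem sizes and runtime

Default verification sizes: 100 parameter sets for the SPD closed form;
50 images per period at 4 periods (SL recovery); 6 levels × 20 images
(monotonicity); 50 traces + 30/30 cells (calcium); full 17×17 shift sweep
against the naive matcher (block matching); 200 random pedigrees ≤ 10
members including first-cousin loops against brute-force enumeration; 200
linked and 100 unlinked gene-drop replicates (θ̂ and null Lod); 10 ROH
panels. These are desk-scale study conditions chosen to keep Monte-Carlo
error comfortably inside the asserted tolerances.
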