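# dcm-phenolink

Gene mapping and iPSC-cardiomyocyte phenotyping for autosomal-recessive
dilated cardiomyopathy (DCM) studies.

Validating a recessive DCM variant in a consanguineous family takes two
chains of computation. The **mapping chain** locates the locus: two-point
Lod scores from exact pedigree likelihoods under a recessive model, shared
runs of homozygosity (ROH) across affected members, and a recessive filter
that reduces the exome candidates inside the linkage interval to the
segregating, database-absent variant. The **phenotyping chain** quantifies
the cellular consequences in engineered iPSC-derived cardiomyocytes:
sarcomere organization from 2D Fourier spectra, calcium-transient kinetics
from paced Fura-2 ratio traces, monolayer contractility from
block-matching motion analysis, and contractile force of engineered heart
tissues (EHTs) from elastic post deflection. `dcm-phenolink` implements
both chains as a tested library with a CLI, plus synthetic-data generators
that emit every input with known ground truth.

## The statistics at the core

**Sarcomere packing density (SPD).** The 1D profile Γ(f) of a 30° wedge of
the ROI power spectrum is fitted with an aperiodic + two-harmonic model

    Γ(f) = a₀e^(−f/b₀) + Σ_{k=1,2} a_k exp(−(f − k f₀)²/b_k),

giving the sarcomere length SL = 1/f₀ and SPD = ∫Γ_p/∫Γ ∈ [0, 1], the
fraction of spectral power in the periodic (sarcomeric) component.

**Calcium kinetics.** Per paced beat: baseline, amplitude (peak −
baseline), time to peak, monoexponential decay constant τ, and t50/t90
recovery times; cells are summarized by medians across beats.

**Contractility.** Block matching assigns each 16-px block the integer
displacement (±8 px) maximizing normalized cross-correlation between
consecutive frames; beat rate and peak contraction/relaxation velocities
come from the mean speed trace. EHT force follows the tip-loaded
cantilever relation F = 3π·d·E·r⁴/(4L³) (E = 1.7 MPa, r = 0.5 mm,
L = 10 mm by default).

**Linkage.** Lod(θ) = log₁₀ L(θ) − log₁₀ L(0.5), with L the exact joint
likelihood of phenotypes and marker genotypes computed by variable
elimination (generalized Elston–Stewart peeling, exact on consanguinity
loops) under a recessive model — penetrance (0, 0, 0.99), disease-allele
frequency 0.001 or 0.01, θ grid {0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4}.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
import numpy as np
from dcm_phenolink.synth import ImageSpec, generate_sarcomere_image
from dcm_phenolink.spd import analyze_image
from dcm_phenolink.linkage import VariantRecord, filter_variants

img = generate_sarcomere_image(ImageSpec(size_px=(256, 256), period_um=1.8,
                                         orientation_deg=30.0, seed=1))
metrics, qc = analyze_image(img)
print(f"SL = {metrics.SL_um:.3f} um, SPD = {metrics.SPD:.3f}, "
      f"orientation = {qc['orientation_deg']:.0f} deg")

aff, unaff = ["III3", "III5", "III6"], ["II4"]
gts = {a: "1/1" for a in aff} | {"II4": "0/1"}
candidates = [
    VariantRecord("chr2", 220037393, "a", "g", "C2orf24", gts, pop_af=0.99),
    VariantRecord("chr2", 220250147, "a", "g", "DNPEP", gts, pop_af=1.0),
    VariantRecord("chr2", 220343876, "g", "a", "SPEG", gts),
    VariantRecord("chr2", 225721677, "c", "t", "DOCK10", gts,
                  pop_af=0.0072, n_healthy_homozygotes=9),
]
survivors, audit = filter_variants(candidates, ("chr2", 218_317_008, 227_728_735),
                                   aff, unaff)
print([v.gene for v in survivors])
print({a.variant.gene: a.failed_rule for a in audit if not a.passed})
```

prints

```
SL = 1.777 um, SPD = 0.996, orientation = 30 deg
['SPEG']
{'C2orf24': 'pop_af', 'DNPEP': 'pop_af', 'DOCK10': 'healthy_hom'}
```

— the synthetic 1.8 µm lattice is recovered within 1.3% with essentially
all spectral power periodic, and of the four candidate variants in the
mapped chr2 interval only the SPEG missense variant (absent from
population databases, no healthy homozygotes) survives the recessive
filter.

The same operations are available from the shell, e.g.

```bash
dcm-phenolink simulate image --seed 1 --out cell.tif
dcm-phenolink spd cell.tif --out metrics.csv
dcm-phenolink map lod --ped family --out lod.csv
dcm-phenolink map filter-variants candidates.tsv --ped family \
    --interval chr2:218317008-227728735 --out survivors.tsv
```

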