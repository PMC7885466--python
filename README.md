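# clonedrop

Quantitative analysis of droplet digital PCR (ddPCR) data for tumour
genetics: absolute allele quantification from droplet counts,
copy-number-corrected mutant cell fractions, deconvolution of bulk
samples into healthy tissue plus nested clones, clonal/subclonal event
ordering, and DNA-vs-RNA allelic-balance testing. It is aimed at
molecular-pathology and cancer-genomics groups who run duplex/multiplex
ddPCR assays (e.g. a FAM-labelled mutant probe against a HEX-labelled
wild-type probe on a QX200) and want to go from classified droplet
counts to a clonal-evolution readout, including on low-quality FFPE
input where sequencing depth is limiting.

## The model

**Poisson quantification.** A reaction is partitioned into ~20,000
droplets; a target present at mean occupancy λ copies/droplet leaves a
droplet negative with probability e^(−λ), so from the positive fraction
p̂ the concentration is

    λ̂ = −ln(1 − p̂),     Var(λ̂) ≈ (e^λ̂ − 1)/n.

Double-positive droplets contain both targets of a duplex and count
toward both channels. The mutant allele fraction is
MAF = λ_mut/(λ_mut + λ_wt), and a locus copy number against a
germline-diploid reference is CN = 2·λ_target/λ_ref (delta-method CIs
throughout).

**Cell fractions and clones.** A bulk sample is modelled as a mixture of
healthy cells and a chain of nested clones (germline → clone I →
clone II), each with integer allele copy numbers per locus. A
single-copy loss in a fraction L of cells gives CN = 2 − L; a gain in G
gives CN = 2 + G. The copy-number-corrected mutant cell fraction is

    MCF = 2·MAF                 (diploid heterozygous)
    MCF = MAF·(2 − L)           (wild-type allele lost in L)
    MCF = MAF·(2 + G) − G       (mutant allele gained in G)

Bulk measurements are linear in the mixing proportions **w**, so
`deconvolve` solves the forward model by weighted least squares on the
simplex (exact when determined, seeded parametric bootstrap for CIs),
and `order_events` groups events by pairwise two-proportion z-tests into
clonal vs subclonal sets. Allele-specific expression is tested by
comparing the RNA allele fraction against the DNA fraction (or against a
proportional-expression null when the copy-number state is known).

## Worked example

Tumour sample with MAF 55% and a single-copy loss of the wild-type
allele in 67% of cells (measured at the mutation locus):

```python
from clonedrop import (AlleleFractionEstimate, AberrantFractionEstimate,
                       Observation, loh_chain_model, mutant_cell_fraction,
                       deconvolve)

model = loh_chain_model()                       # germline -> mut/wt -> mut/-
maf   = AlleleFractionEstimate(0.55, (0.54, 0.56))
loss  = AberrantFractionEstimate(0.67, (0.65, 0.69),
                                 "single_copy_loss", "CYSLTR2")

mcf = mutant_cell_fraction(maf, model, loss)
print(f"mutant cell fraction: {mcf.fraction:.4f}")

res = deconvolve(model, [
    Observation("cell_fraction", "CYSLTR2", 0.74, (0.72, 0.76), allele="mut"),
    Observation("aberrant_fraction", "CYSLTR2", 0.67, (0.65, 0.69),
                alteration="single_copy_loss"),
], seed=1)
for pid, w in zip(res.population_ids, res.proportions):
    print(f"{pid}: {round(100 * w)}%")
```

prints

```
mutant cell fraction: 0.7315
healthy: 26%
cloneI: 7%
cloneII: 67%
```

i.e. 73% of all cells carry the mutation; the sample decomposes into 26%
healthy cells, a 7% clone that acquired the mutation, and a nested 67%
clone that additionally lost the wild-type allele (the subclonal event).

The same analysis runs end-to-end from files via the CLI
(`clonedrop simulate | quantify | cnv | deconvolve | ase | pipeline`);
`clonedrop pipeline wells.csv --panel panel.json --model model.json`
produces a JSON report plus a human-readable summary, and
`clonedrop simulate config.yaml` generates synthetic wells with known
ground truth for validation.

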