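# famnorm

Reference-free pre-processing and evaluation for Infinium 450k-style DNA
methylation array data in **familial designs** — cohorts of related
individuals with no case/control or tumour/normal reference group.

Most 450k pre-processing pipelines assume two contrasting sample groups.
Family studies have none: the biology of interest *is* the inter-individual
(and inherited) variation, so a normalisation step that flattens it is as
harmful as a batch effect that masquerades as it. `famnorm` packages the
pieces needed to choose a pre-processing strategy for such data:

* **Transforms and QC** — β = M/(M + U + 100), the base-2 logit M value
  m = log₂(β/(1−β)), detection-p / bead-count / sex-chromosome probe
  filters, and flag-only sample QC.
* **Seven normalisation methods** — quantile normalisation, stratified
  (by genomic region) quantile normalisation, SWAN, BMIQ, noob
  (normal-exponential out-of-band background correction), dasen, and
  control-probe functional normalisation — each a scikit-learn-style
  transformer with a fitted-parameter record.
* **ComBat** — parametric empirical-Bayes location/scale batch adjustment
  of M values (matches Bioconductor `sva::ComBat` to ~1e-5).
* **Eight evaluation metrics** — β density summaries and type I/II KS
  distance, classical MDS, batch/family ANOVA on PC1, replicate median
  absolute differences, the imprinted-region dispersion DMRSE, hierarchical
  cluster agreement with batch (ARI), kinship-adjusted meQTL association
  (LMM residuals + per-SNP regression, Bonferroni over a 2-Mb window), and
  the age-EWAS inflation factor λ = median(obs −log₁₀p)/median(exp −log₁₀p).
* **A synthetic-data generator** — familial pedigrees, three batches with
  replicate pairs split across them, two probe chemistries with a
  compressed type II distribution, 227 hemi-methylated imprinted probes,
  a planted cis-meQTL and epigenome-wide age drift, with full ground truth
  for recovery testing.
* **A pipeline CLI** — `famnorm pipeline` runs QC once, every
  normalisation branch with and without ComBat, all metrics, and a
  cross-method ranking report.

## Worked example

```python
import numpy as np
from famnorm import SimulationConfig, simulate_dataset, norm_stratified_qn
from famnorm.normalize import combat_dataset
from famnorm.qc import run_qc
from famnorm.metrics import pc_anova, dmrse, replicate_mad, ibs_kinship, meqtl_association
from famnorm.datatypes import BetaMatrix

dataset, truth = simulate_dataset(SimulationConfig(), seed=7)
qc_ds, report = run_qc(dataset)
corrected = combat_dataset(norm_stratified_qn(qc_ds))

for label, ds in [("raw", qc_ds), ("stratified QN + ComBat", corrected)]:
    p = pc_anova(BetaMatrix(ds.beta), ds.samples.batch)
    mad = np.mean(list(replicate_mad(ds.mvalues(), ds.samples.replicate_groups()).values()))
    err = dmrse(BetaMatrix(ds.beta), ds.annotation.is_idmr.to_numpy())
    print(f"{label:>22}: batch-PC1 ANOVA p = {p:.3g}, replicate MAD = {mad:.3f}, DMRSE = {err:.5f}")

kinship = ibs_kinship(truth.background_genotypes)
_, min_p = meqtl_association(corrected.mvalues().loc[truth.meqtl_probe], truth.genotypes, kinship)
print(f"planted meQTL, Bonferroni-adjusted p after correction: {min_p:.3g}")
```

prints

```
                   raw: batch-PC1 ANOVA p = 1.27e-71, replicate MAD = 0.364, DMRSE = 0.00091
stratified QN + ComBat: batch-PC1 ANOVA p = 1, replicate MAD = 0.157, DMRSE = 0.00035
planted meQTL, Bonferroni-adjusted p after correction: 7.7e-08
```

Read: the raw data cluster overwhelmingly by processing batch (ANOVA of
batch on the first principal component, p ≈ 1e-71); after stratified
quantile normalisation and ComBat the batch signal is gone (p ≈ 1), the
technical replicates agree twice as well (median absolute M-value
difference 0.364 → 0.157), the dispersion at imprinted regions — which
should sit at β = 0.5 in everyone — drops by ~60 %, and the planted
genotype–methylation association is still detected at Bonferroni-adjusted
p ≈ 8e-8: the technical bias went, the biology stayed.

The same comparison across all fifteen branches (raw + 7 methods ×
±ComBat):

```bash
famnorm pipeline --simulate --seed 7 --out results/
# results/report.json, results/ranking.tsv
```

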