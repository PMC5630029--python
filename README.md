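# mycflux

Analysis toolkit for acute transcription-factor activation time courses,
built around three linked questions about MYC-style regulators:

1. **Who gets induced, who gets repressed?** The *binding share* of a
   promoter — its fraction of the total factor signal bound genome-wide —
   changes upon activation, and the sign of that change predicts the
   transcriptional response.  The package computes shares, the
   *share-neutral threshold* (the per-gene log2 binding change equal to the
   global log2 change in total binding), local-regression trends, and ROC
   discrimination of induced vs repressed genes.
2. **Which kinetic step changed?** From exonic/intronic signal in total and
   metabolically labeled (nascent) RNA-seq, the two-compartment model

       dP/dt = k1(t) − k2(t)·P          dM/dt = k2(t)·P − k3(t)·M

   yields time-resolved synthesis (k1), processing (k2) and degradation
   (k3) rates per gene, with likelihood-ratio calls of which rates vary.
3. **Which step of the RNAPII cycle changed?** RNAPII ChIP-seq densities in
   promoter (Pr), gene-body (Gb) and TES (Te) windows follow a compartment
   chain

       dPr/dt = p1 − p2·Pr    dGb/dt = p2·Pr − p3·Gb    dTe/dt = p3·Gb − p4·Te

   with p1 the net promoter flux (polymerase/h, may turn negative), p2 the
   pause-release rate, p3 the elongation rate (k1/Gb) and p4 the TES
   release rate.  The package infers p1–p4 per gene cluster, attributes
   explained variance to single parameters, and predicts the effect of
   freezing any one step at its untreated level.

A synthetic-data generator produces whole cohorts (binding, RNAPII
densities, RNA tables) with known ground truth, so every inference stage is
testable without external data.

## Worked example

```python
import mycflux as mf

gt = mf.generate_ground_truth(n_genes=1000, seed=1)
chip = mf.simulate_chip_tables(gt, mf.NoiseModel(cv=0.2), n_replicates=3)
myc = mf.replicate_average(mf.normalize(chip["MYC"], 1.0))
b0, b1 = myc.values[:, 0, 0], myc.values[:, -1, 0]

delta_star = mf.share_neutral_threshold(b0, b1, 1.0)
tab = mf.share_table(b0, b1, 1.0)
roc = mf.roc_induced_vs_repressed(tab["delta"], gt.classes,
                                  neutral_threshold=delta_star)
```

Running `python examples/share_analysis.py` (the same computation) prints:

```
share-neutral threshold delta* = 1.580 log2 (global binding gain 2.99x)
genes gaining share: 220 / 1000
AUC, binding change as induced-vs-repressed predictor: 1.000
Youden-optimal threshold 1.600; J at delta* = 1.000 (max 1.000)
```

The total amount of bound factor rose ~3-fold, so only promoters whose own
binding grew by more than `delta* = log2(3)` gained share; those are the
induced genes, and the neutral threshold lands at the ROC operating point
with the best sensitivity/specificity trade-off.

The other `examples/` scripts walk through cohort simulation
(`simulate_cohort.py`), per-gene kinetic-rate fitting
(`rna_rate_fitting.py`), RNAPII parameter inference and variance
attribution (`polii_inference.py`), and response clustering with PCA
(`response_clustering.py`).

A thin CLI mirrors the stages for shell use:

```bash
mycflux simulate --n-genes 300 --seed 0 --outdir cohort/
mycflux share --myc cohort/MYC.tsv --expr cohort/total_exon.tsv
mycflux rna-rates --total-exon cohort/total_exon.tsv --total-intron cohort/total_intron.tsv \
    --nascent-exon cohort/nascent_exon.tsv --nascent-intron cohort/nascent_intron.tsv
```

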