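# cernet

**ceRNA network inference and qPCR statistics for tumor expression cohorts.**

`cernet` is a toolkit for nominating oncogenic long non-coding RNAs
(lncRNAs) and reconstructing their competing-endogenous-RNA (ceRNA)
circuitry when only tumor samples are available — the situation of most
TCGA cohorts, which lack matched normals.  It implements, end to end:

* **Decoy-gene screening** — candidate lncRNAs are selected by
  opposite-sign expression correlation with two anchor genes of known
  dysregulation (an upregulated oncogene and a downregulated tumor
  suppressor, e.g. *MET* and *BAP1* in uveal melanoma).
* **Sponge-triplet inference** — for each candidate lncRNA, miRNAs it may
  sequester are ranked by negative correlation plus multiple seed sites
  with favorable hybridization energy; target mRNAs are then the
  intersection of an *anticorrelation branch* (r(miRNA, mRNA) < 0 and
  r(lncRNA, mRNA) > 0, both significant) and a *complementarity branch*
  (≥ 2 seed sites in the 3′-UTR).  An accepted lncRNA–miRNA–mRNA triplet
  satisfies all six evidence conditions and is scored by
  |r_lnc,mi| · |r_lnc,m| · |r_mi,m|.
* **miRNA-protector masking** — sliding-window lncRNA:3′-UTR interaction
  energy profiles (nearest-neighbor duplex DP), minimum-free-energy region
  calling, and overlap of those regions with predicted miRNA sites.
* **TFBS regulator ranking** — TF binding sites in a strand-aware promoter
  window, ranked by expression correlation with the lncRNA.
* **qPCR statistics** — signed 2^−ΔΔCt fold changes (a ratio of 0.75 is
  reported as −1.33), normality-driven test selection (Shapiro–Wilk →
  F-test → Student/Welch t / Mann–Whitney; ANOVA / Kruskal–Wallis),
  ΔCt correlations, nuclear/cytoplasmic fractionation percentages, and the
  ≥ 75% silencing-efficiency replicate filter.

Because real cohorts of this kind are not redistributable, the package
ships a **synthetic-data module** that generates expression cohorts with
planted sponge triplets at exact target correlations, sequences with
implanted seed-complementary sites, qPCR plates with known fold changes,
and TFBS BED tracks — all with recorded ground truth, so the whole pipeline
is testable against known answers.

## Worked example

```python
from cernet import CohortSpec, QpcrDesign, simulate_qpcr, fold_change
from cernet.pipeline import run_synthetic_pipeline

res = run_synthetic_pipeline(CohortSpec(seed=3))
c = res.candidates[0]
print(f"top candidate {c.id}: r_up={c.r_decoy_up:.2f}, r_down={c.r_decoy_down:.2f}")
t = res.triplets[0]
print(f"top triplet: {t.lnc_id} -| {t.mirna_id} -| {t.mrna_id}  score={t.score:.3f}")
print(f"precision={res.precision:.2f}, recall={res.recall:.2f}")

ds = simulate_qpcr(QpcrDesign(n_per_group=41), {"LNC0000": 33.3},
                   ct_noise_sd=0.2, seed=3)
fc = fold_change(ds, "tumor", "normal")
print(f"fold change: {fc.fold_change_signed:.1f} (p={fc.p:.2g}, {fc.test_used})")
```

prints

```
top candidate LNC0001: r_up=0.85, r_down=-0.85
top triplet: LNC0001 -| MIR0001 -| MRNA0001  score=0.292
precision=1.00, recall=1.00
fold change: 33.6 (p=1.4e-112, student_t)
```

The screen recovers all five planted oncogene-like lncRNAs (positive
correlation with the upregulated decoy, negative with the downregulated
one), the network stage recovers every planted triplet with no false
positives at this seed, and a simulated 41-pair tumor/normal plate
generated at a true fold change of 33.3 is estimated at 33.6 under
replicate noise of 0.2 Ct.

The same stages are available from the shell:

```sh
cernet simulate --outdir demo --seed 1
cernet screen   --matrix demo/expression.tsv --decoy-up MET --decoy-down BAP1
cernet network  --lnc LNC0000 --matrix demo/expression.tsv \
                --lnc-fasta demo/lncRNA.fa --mirnas demo/miRNA.fa --utrs demo/utr.fa
cernet protector --lnc demo/lncRNA.fa --utrs demo/utr.fa --mirnas demo/miRNA.fa
cernet qpcr     --cts demo/ct.tsv --group1 tumor --group2 normal
cernet tfscan   --bed demo/tfbs.bed --tss-table tss.tsv \
                --matrix demo/expression.tsv --lnc LNC0000
```

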