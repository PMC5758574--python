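# twindiff

Differential gene expression in **discordant monozygotic twin pairs**, across
multiple phenotypes at once.

Monozygotic co-twins are genetically identical, so when one twin is affected
by a phenotype (a disease, obesity, high physical activity, ...) and the other
is not, the within-pair expression difference isolates non-inherited —
environmental or phenotype-driven — contributions. Individual twin studies are
small (typically 10–44 pairs) and sit on different microarray platforms, which
measure each gene with several probes on platform-specific intensity scales.
`twindiff` implements the full integrative analysis for a collection of such
studies, together with a synthetic-cohort generator that provides ground truth
for every stage.

## The method

For each study *s* and probe *k*, with within-pair differences
*d\_i = x\_affected,i − x\_unaffected,i* over complete pairs:

* **Paired t statistic** — mean difference *m = d̄*, *se = sd(d)/√n*,
  *t = m/se*, two-sided p with *n − 1* df.
* **Probe→gene summarization** — a gene's probe estimates are pooled by
  fixed-effect inverse-variance meta-analysis:
  *w\_j = 1/se\_j²*, *μ̂ = Σw\_j m\_j / Σw\_j*, *se(μ̂) = (Σw\_j)^{−1/2}*, with a
  Wald z p-value; genes are also ranked by |μ̂| within the study.
* **Per-study significance** — Benjamini–Hochberg FDR *q < 0.05* **and**
  |μ̂| strictly above τ₉₅, the 95th percentile of |mean difference| over that
  study's genes (both gates, to keep small noisy cohorts from flooding the
  calls).
* **Cross-phenotype comparison** — pairwise significant-gene overlap as a
  percentage of co-measured genes, and Spearman correlation of the two
  studies' gene-level differences.
* **Cross-phenotype meta-analysis** — per gene, DerSimonian–Laird
  random-effects pooling across studies with Cochran's *Q*, the moment
  estimate τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), heterogeneity p-value
  *QEp* from the χ²\_{k−1} tail, and *I² = max(0, (Q − (k−1))/Q)·100*.
  A gene is **overall significant** when its BH-adjusted meta p < 0.05, its
  |pooled estimate| exceeds the 95th-percentile threshold of pooled
  estimates, and it was measured in more than one study.
* **Sex stratification** — monozygotic twins share sex, so the identical
  pipeline re-runs per sex on the pair subsets of the sex-labelled studies,
  with thresholds recomputed inside each stratum.

Everything operates on platform-native intensity units; no log transform is
applied anywhere.

## Worked example

Run the default seven-study synthetic cohort (pair counts 10–44, a
25,154-gene universe, 1–4 probes per measured gene, sex labels in the CFS,
MDD and OB studies):

```sh
cat > pipeline.yaml <<'YAML'
out_dir: twin_run
seed: 1
simulation:
  seed: 1
YAML
twindiff run --config pipeline.yaml --summary
```

which prints:

```
studies analyzed: 7
  CFS: 592 significant genes
  IAR_invitro: 370 significant genes
  IQ: 306 significant genes
  MDD: 430 significant genes
  OB: 345 significant genes
  PA: 362 significant genes
  UC: 407 significant genes
genes meta-analyzed: 25154
overall significant (q<0.05, |est|>tau95, k>1): 727
heterogeneous (QEp FDR<0.05): 389
male stratum: 469 overall significant (CFS, MDD, OB)
female stratum: 407 overall significant (CFS, MDD, OB)
cross-sex overlap: 250 gene(s)
```

Per-study counts are the genes clearing both the FDR and the τ₉₅ effect-size
gate; "overall significant" genes additionally needed measurement in at least
two studies; "heterogeneous" genes have FDR-adjusted *QEp* < 0.05, i.e.
evidence that their effect truly differs between phenotypes. `twin_run/`
holds every intermediate table (per-probe statistics, per-gene estimates with
q-values and ranks, overlap/Spearman matrices, the meta-analysis long table,
an I² ECDF table) plus `manifest.json` with a checksum per output — rerunning
with the same seed reproduces every file byte-for-byte.

The same stages are available individually (`twindiff simulate / probes /
genes / select / integrate / stratify`) and as library functions
(`twindiff.study_probe_table`, `twindiff.summarize_study`,
`twindiff.dl_meta`, ...) for use on your own TSV matrices; see
`docs/methods.md` for file formats and modelling details.

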