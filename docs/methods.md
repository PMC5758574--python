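# Methods

## Study design and model

The unit of analysis is the discordant monozygotic (MZ) twin pair: one
affected and one unaffected co-twin. Because MZ twins share their genome and
much of their rearing environment, the within-pair difference
*d = x_affected − x_unaffected* cancels additive genetic and shared-pair
effects; its expectation is the phenotype-associated expression shift for
that gene in that study, and its variance is twice the individual residual
variance.

A cohort is a set of studies, each on its own microarray platform. Platforms
differ in which genes they measure (partially overlapping gene universes),
how many probes interrogate each gene (typically 1–4) and in intensity
scale. All analysis is done on platform-native intensity units — reported
differences such as "105 units" only make sense untransformed, so the
pipeline never log-transforms; any variance-stabilising transform is the
caller's decision before the data enter the pipeline.

The analysis stack is:

1. **Paired t per probe** (`paired`). Complete-pair analysis with pairwise
   deletion: a missing value in either twin removes that pair for that probe
   only. Two-sided p-values on *n − 1* df. Probes with fewer than 3 complete
   pairs (`insufficient_pairs`) or zero difference variance
   (`zero_variance`, infinite inverse-variance weight) are flagged and
   excluded downstream; their mean difference is still reported.
2. **Fixed-effect probe→gene pooling** (`genes`). Inverse-variance weights
   over a gene's `ok` probes. The common-effect assumption is justified by
   the design: probe offsets are additive on the intensity scale and cancel
   in within-pair differences, so all probes of a gene estimate the same
   quantity. Probes of one gene share samples and are therefore positively
   correlated; naive pooling ignores this, which makes gene-level SEs
   somewhat anti-conservative. This matches the summarization technique the
   pipeline implements and is flagged here as a known property, not a bug.
   Probes annotated to several gene symbols contribute to every mapped gene.
   Genes whose probes are all flagged or unmapped are omitted from that
   study's table.
3. **Two-gate significance** (`significance`). BH FDR within each study over
   exactly the genes summarized there, plus the effect-size gate
   |μ̂| > τ₉₅ where τ₉₅ is the 95th percentile of |μ̂| in that study. Both
   inequalities are strict. The effect gate caps the per-study call rate at
   ~5% of genes and suppresses statistically significant but minuscule
   differences; note that filtering BH rejections by effect size does not
   itself preserve the FDR guarantee — with well-separated true effects the
   false-discovery proportion stays near the nominal level (measured by the
   calibration experiments), but it is not a theorem.
4. **Cross-phenotype integration** (`integrate`). Overlap percentage
   100·|SigA ∩ SigB| / |MeasA ∩ MeasB| for every unordered study pair
   including self-pairs (the diagonal is the study's own significant
   fraction); Spearman correlation (average ranks on ties, two-sided
   t-approximation p) of gene-level mean differences over co-measured genes,
   reported unadjusted. Per gene, DerSimonian–Laird random-effects pooling
   across the studies measuring it, with Q, moment τ² (truncated at 0), I²,
   and the χ² heterogeneity p-value QEp; Wald z test for the pooled mean (no
   Knapp–Hartung adjustment, matching the standard implementation of the
   technique). BH is applied across all genes to the meta p-values
   (`q_value`) and, separately, to the QEp values (`QEp_fdr`).
5. **Overall selection.** Overall-significant genes satisfy q < 0.05,
   |pooled estimate| > the 95th percentile of |pooled estimates| over all
   meta-analyzed genes, and k > 1. Genes measured once are retained in the
   table with the degenerate conventions Q = 0, τ² = 0, I² = 0, QEp = 1 —
   this keeps the gene table total-ordered and BH well-defined — but are
   barred from overall selection. The reference distribution for the overall
   effect threshold is configurable (`overall_threshold_reference`):
   `meta` (default) uses the per-gene pooled estimates; `per_study` pools
   the per-study |mean difference| values instead. The field convention for
   the overall analysis does not pin this down; the default is the
   distribution the selection actually acts on.
6. **Sex stratification** (`stratify`). Sex is a pair-level attribute (MZ
   twins share sex; a conflicting label is a load-time error). Each labelled
   study is restricted to pairs of the requested sex (dropped if fewer than
   `min_pairs` remain) and the identical pipeline re-runs, recomputing
   effect-size thresholds within the stratum rather than inheriting pooled
   thresholds. The cross-sex comparison intersects the two overall
   significant sets; no sex-by-effect interaction test is performed.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| `fdr_alpha` | 0.05 | — | BH gate, per study and overall |
| `effect_percentile` | 95 | percentile | effect-size gate reference |
| `percentile_definition` | linear (type 7) | — | interpolation at position (n−1)·q; the dominant default in scientific software |
| `min_pairs` | 3 | pairs | fewest complete pairs yielding a probe statistic |
| `min_pairs_study` | 10 | pairs | studies below this draw a fidelity warning (small-cohort exclusion rule) but are still analyzed |
| `rank_mode` | `abs_desc` | — | gene ranking by \|μ̂\| descending, ties broken by symbol; signed variants available |

## The synthetic cohort generator

`simulate` draws, for study *s*, gene *g*, probe *k*, pair *i*:

    value = baseline_g + probe_offset_k + pair_effect_i
            + [affected]·δ_{g,s} + ε,   ε ~ N(0, noise_sd²)
    δ_{g,s} ~ N(μ_g, τ²) for affected genes, 0 otherwise
    μ_g ~ N(0, effect_mean_sd²) for the affected fraction

Defaults mirror the reference seven-study design: pair counts
(10, 44, 10, 17, 11, 28, 13), a 25,154-gene universe with per-study platform
coverage 74–91% (independent random panels), 1–4 probes per gene, 5%
affected genes, and sex labels only in CFS, MDD and OB. Intensity-scale
defaults (baseline 500 ± 100, noise 50, pair effect 50, probe offset 20,
effect scale 30, between-study τ 10) put typical per-study gene SEs at
roughly 10–30 units so that effects span the detectable range, in line with
reported mean differences of tens to hundreds of platform units. One seeded
generator drives every draw; a (config, seed) pair reproduces the cohort
bitwise.

What the generator deliberately does **not** emulate: intensity-dependent
noise (no MA-plot structure), batch effects beyond additive probe offsets,
correlated probes beyond the shared true effect, non-normal heavy-tailed
expression noise, and informative missingness (`missing_rate` knocks out
values completely at random). Tests passing on this generator therefore
validate the estimators and the pipeline plumbing under the model's own
assumptions; they do not certify behaviour under real-platform artefacts.

## Numerical and I/O choices

* Within-pair difference variance is 2·noise_sd² by construction, which the
  SE-based oracles use exactly.
* The vectorized per-gene meta-analysis computes Q via the
  Σw·m² − (Σw·m)²/Σw identity with truncation at 0; the scalar `dl_meta`
  uses the two-pass Σw(m−μ̂)² form. They agree to ~1e-8 relative, and the
  scalar form is the reference.
* τ² truncation: the DL moment estimate is clipped at 0 (the canonical
  definition, as in the standard R implementation); some libraries report
  the untruncated moment, which explains I²'s spike at exactly 0 under
  homogeneity — about half of null genes land there with k = 7, an expected
  estimator property, not a defect.
* TSV is the only dialect (UTF-8, tab, `.` decimal); missing values read as
  empty or `NA`, written as `NA`; floats rendered at 6 significant digits;
  result rows sorted by gene then study. Multi-gene annotation cells use the
  `///` delimiter with surrounding whitespace stripped; an empty symbol
  leaves the probe unmapped.
* Pair lists are sorted by pair ID at load, so metadata row order never
  affects results. Pairs missing a member are dropped with a warning; a pair
  with two affected members, duplicate probe IDs, or zero valid pairs are
  hard errors naming file and line.
* When the pipeline simulates, it writes the cohort TSVs and reads them back
  before analysis, so an orchestrated run and a by-hand chain of stage CLIs
  see byte-identical inputs and produce byte-identical intermediates.
* Single-probe genes get the normal-approximation p (z = m/se) rather than
  the probe's t-based p, so every gene-level p comes from one reference
  distribution; the difference vanishes as pair counts grow.

## Problem sizes used in validation

The test-suite and the acceptance script size their experiments as: ≥ 2,000
null probes for type-I calibration; 20 replicate 2,000-gene studies for the
false-discovery proportion; 500 replicate genes at k = 7 for τ² recovery and
the I² null spike; 20 replicate two-study null cohorts at 5,000 co-measured
genes for the cross-phenotype null structure; and the full seven-study
reference-scale cohort (~20,000 genes/study, 1–4 probes per gene), run
twice, for determinism.

## Known limitations

* No moderated (limma-style) variance shrinkage; with 10 pairs the per-probe
  variance estimate is noisy and the paired t correspondingly blunt.
* No correction for probe-probe correlation within a gene (see above).
* No batch correction; the pipeline analyzes the matrices it is given.
* The effect-size gate is a heuristic power/precision trade-off; FDR control
  after the gate is empirical, not guaranteed.
* GEO/ArrayExpress/dbGaP native formats are not parsed — conversion to the
  TSV triple is the caller's job.
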