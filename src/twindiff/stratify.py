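"""Sex-stratified re-analysis of the sex-labelled studies.

Sex may modulate expression differences between discordant co-twins. Because
monozygotic twins share sex, stratification acts at the pair level: each
sex-labelled study is restricted to pairs of the requested sex and the
identical pipeline is re-run on the restriction — paired statistics, gene
summarization, per-study significance (with effect-size thresholds recomputed
within the stratified run, not inherited from the pooled run), then the
cross-study random-effects meta-analysis and overall selection. Studies with
too few pairs of that sex are dropped from the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import AnalysisError
from .genes import summarize_study
from .integrate import meta_analyze_genes, overall_selection
from .paired import study_probe_table
from .significance import select_significant
from .types import ExpressionStudy, SignificanceResult

logger = logging.getLogger(__name__)


@dataclass
class StratifiedRun:
    """Results of one sex-specific pipeline run."""

    sex: str
    studies_used: list[str]
    gene_tables: dict[str, pd.DataFrame]
    significance: dict[str, SignificanceResult]
    meta: pd.DataFrame
    overall_significant: frozenset[str]
    heterogeneous: frozenset[str]
    threshold_meta: float
    pair_counts: dict[str, int] = field(default_factory=dict)


def restrict_to_sex(study: ExpressionStudy, sex: str,
                    min_pairs: int = 3) -> ExpressionStudy | None:
    """The study restricted to pairs of ``sex``; None if unlabelled or too few."""
    if study.sex is None:
        return None
    keep = [p for p in study.pairs if study.sex.get(p.pair_id) == sex]
    if len(keep) < min_pairs:
        return None
    return study.subset_pairs(keep)


def stratified_analysis(cohort: list[ExpressionStudy], sex: str,
                        alpha_fdr: float = 0.05,
                        effect_percentile: float = 95.0,
                        min_pairs: int = 3) -> StratifiedRun:
    """Run the full pipeline on the ``sex`` stratum of the labelled studies."""
    if sex not in ("male", "female"):
        raise AnalysisError(f"sex must be male/female, got {sex!r}")
    gene_tables: dict[str, pd.DataFrame] = {}
    significance: dict[str, SignificanceResult] = {}
    used, counts = [], {}
    for study in cohort:
        sub = restrict_to_sex(study, sex, min_pairs=min_pairs)
        if sub is None:
            if study.sex is not None:
                logger.info("study %s: < %d %s pairs, dropped from %s run",
                            study.study_id, min_pairs, sex, sex)
            continue
        probes = study_probe_table(sub, min_pairs=min_pairs)
        genes = summarize_study(probes, sub.annotation, sub.study_id, sub.phenotype)
        genes, sig = select_significant(genes, alpha_fdr=alpha_fdr,
                                        effect_percentile=effect_percentile)
        gene_tables[sub.study_id] = genes
        significance[sub.study_id] = sig
        used.append(sub.study_id)
        counts[sub.study_id] = sub.n_pairs
    if not used:
        raise AnalysisError(f"no study qualifies for the {sex}-specific analysis")
    meta = meta_analyze_genes(gene_tables)
    selected, het, tau95 = overall_selection(meta, alpha=alpha_fdr,
                                             effect_percentile=effect_percentile)
    return StratifiedRun(sex=sex, studies_used=used, gene_tables=gene_tables,
                         significance=significance, meta=meta,
                         overall_significant=selected, heterogeneous=het,
                         threshold_meta=tau95, pair_counts=counts)


def cross_sex_overlap(run_m: StratifiedRun, run_f: StratifiedRun
                      ) -> tuple[int, int, frozenset[str]]:
    """(|male set|, |female set|, intersection) of overall-significant genes."""
    inter = run_m.overall_significant & run_f.overall_significant
    return len(run_m.overall_significant), len(run_f.overall_significant), inter
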