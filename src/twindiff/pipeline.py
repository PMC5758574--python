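"""End-to-end orchestration: simulate/load → per-study → integrate → stratify.

``run_pipeline`` drives the whole workflow from one :class:`PipelineConfig`,
writes every intermediate table as TSV, and finishes with a JSON manifest
carrying a SHA-256 checksum per output — identical config + seed must
reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tdio
from .errors import ConfigError, TwindiffError
from .genes import summarize_study
from .integrate import meta_analyze_genes, overall_selection, pairwise_tables
from .paired import study_probe_table
from .significance import select_significant
from .simulate import SimulationConfig, emit_cohort_files, simulate_cohort
from .stratify import cross_sex_overlap, stratified_analysis
from .types import ExpressionStudy

logger = logging.getLogger(__name__)

#: Studies smaller than this trigger a fidelity warning (the reference design
#: excluded cohorts with fewer than 10 pairs) but are still analyzed.
RECOMMENDED_MIN_PAIRS_STUDY = 10


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults reproduce the standard thresholds
    (FDR 0.05, 95th-percentile effect gate, ≥3 complete pairs per probe)."""

    out_dir: str = "twindiff_run"
    studies: list[dict] = field(default_factory=list)  # matrix/metadata/annotation paths
    simulation: SimulationConfig | None = None
    fdr_alpha: float = 0.05
    effect_percentile: float = 95.0
    percentile_definition: str = "linear"
    rank_mode: str = "abs_desc"
    overall_threshold_reference: str = "meta"
    min_pairs: int = 3
    min_pairs_study: int = RECOMMENDED_MIN_PAIRS_STUDY
    stratify_by_sex: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if isinstance(sim.get("pairs_per_study"), list):
                sim["pairs_per_study"] = tuple(sim["pairs_per_study"])
            for key in ("phenotypes", "platform_coverage", "probes_per_gene",
                        "sex_labelled_studies"):
                if isinstance(sim.get(key), list):
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_cohort(config: PipelineConfig) -> list[ExpressionStudy]:
    if config.simulation is not None and config.studies:
        raise ConfigError("give either simulation parameters or study files, not both")
    if config.simulation is not None:
        # Materialize the cohort to TSV and read it back, so the orchestrated
        # run and a by-hand chain of stage CLIs see byte-identical inputs.
        cohort, truth = simulate_cohort(config.simulation, seed=config.seed)
        cohort_dir = Path(config.out_dir) / "cohort"
        emit_cohort_files(cohort, cohort_dir, truth=truth)
        reread = []
        for study in cohort:
            loaded, _ = tdio.read_expression(
                cohort_dir / f"{study.study_id}_matrix.tsv",
                cohort_dir / f"{study.study_id}_metadata.tsv",
                cohort_dir / f"{study.study_id}_annotation.tsv",
                study_id=study.study_id, phenotype=study.phenotype)
            reread.append(loaded)
        return reread
    if not config.studies:
        raise ConfigError("no input: neither simulation parameters nor study files")
    cohort = []
    for entry in config.studies:
        study, report = tdio.read_expression(
            entry["matrix"], entry["metadata"], entry["annotation"],
            study_id=entry.get("study_id"), phenotype=entry.get("phenotype", ""))
        logger.info("loaded %s: %d pairs, %d probes (%d unmapped)", report.study_id,
                    report.n_pairs, report.n_probes, report.n_unmapped_probes)
        cohort.append(study)
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write all tables, return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        cohort = _load_cohort(config)
        for study in cohort:
            if study.n_pairs < config.min_pairs_study:
                logger.warning("study %s has %d pairs (< recommended %d)",
                               study.study_id, study.n_pairs, config.min_pairs_study)

        stage = "per-study"
        gene_tables, sig_results, universes = {}, {}, {}
        for study in cohort:
            probes = study_probe_table(study, min_pairs=config.min_pairs)
            tdio.write_results(probes, out / f"{study.study_id}_probes.tsv")
            genes = summarize_study(probes, study.annotation, study.study_id,
                                    study.phenotype, rank_mode=config.rank_mode)
            genes, sig = select_significant(
                genes, alpha_fdr=config.fdr_alpha,
                effect_percentile=config.effect_percentile,
                percentile_interpolation=config.percentile_definition)
            tdio.write_results(
                genes.assign(significant=genes["gene"].isin(sig.significant_genes)),
                out / f"{study.study_id}_genes.tsv")
            gene_tables[study.study_id] = genes
            sig_results[study.study_id] = sig
            universes[study.study_id] = frozenset(genes["gene"])

        thresholds = pd.DataFrame(
            [{"study_id": s, "n_tested": r.n_tested, "threshold_95": r.threshold_95,
              "n_significant": len(r.significant_genes)}
             for s, r in sorted(sig_results.items())])
        tdio.write_results(thresholds, out / "study_thresholds.tsv")

        stage = "integrate"
        meta = None
        overall, het, tau95_meta = frozenset(), frozenset(), float("nan")
        if len(cohort) >= 2:
            pairwise = pairwise_tables(gene_tables, sig_results, universes)
            tdio.write_results(
                pairwise[["phenotype_a", "phenotype_b", "n_measured_both",
                          "n_sig_both", "overlap_pct"]], out / "pairwise_overlap.tsv")
            tdio.write_results(
                pairwise[["phenotype_a", "phenotype_b", "n_measured_both",
                          "spearman_rho", "spearman_p"]], out / "pairwise_spearman.tsv")
        meta = meta_analyze_genes(gene_tables)
        per_study_abs = pd.concat(gene_tables.values())["mean_diff"].abs().to_numpy()
        overall, het, tau95_meta = overall_selection(
            meta, alpha=config.fdr_alpha, effect_percentile=config.effect_percentile,
            threshold_reference=config.overall_threshold_reference,
            per_study_abs_diffs=per_study_abs)
        meta = meta.assign(overall_significant=meta["gene"].isin(overall))
        tdio.write_results(meta, out / "meta_genes.tsv")
        ecdf = meta[["gene", "I2"]].sort_values(["I2", "gene"]).reset_index(drop=True)
        ecdf["ecdf"] = (ecdf.index + 1) / len(ecdf)
        tdio.write_results(ecdf[["I2", "ecdf", "gene"]], out / "ecdf_i2.tsv")

        stage = "stratify"
        strat_summary = {}
        if config.stratify_by_sex and any(s.sex for s in cohort):
            runs = {}
            for sex in ("male", "female"):
                try:
                    run = stratified_analysis(
                        cohort, sex, alpha_fdr=config.fdr_alpha,
                        effect_percentile=config.effect_percentile,
                        min_pairs=config.min_pairs)
                except TwindiffError as exc:
                    logger.warning("%s stratum skipped: %s", sex, exc)
                    continue
                runs[sex] = run
                tdio.write_results(run.meta, out / f"meta_genes_{sex}.tsv")
                strat_summary[sex] = {
                    "studies_used": run.studies_used,
                    "overall_significant": len(run.overall_significant)}
            if len(runs) == 2:
                n_m, n_f, inter = cross_sex_overlap(runs["male"], runs["female"])
                strat_summary["cross_sex"] = {
                    "n_male": n_m, "n_female": n_f,
                    "n_intersection": len(inter), "intersection": sorted(inter)}

        stage = "manifest"
        outputs = sorted(p.name for p in out.glob("*.tsv"))
        manifest = {
            "seed": config.seed,
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
            "outputs": {name: _sha256(out / name) for name in outputs},
            "summary": {
                "n_studies": len(cohort),
                "per_study_significant": {s: len(r.significant_genes)
                                          for s, r in sorted(sig_results.items())},
                "n_genes_meta": int(len(meta)),
                "overall_significant": len(overall),
                "overall_significant_genes": sorted(overall),
                "heterogeneous": len(het),
                "threshold_95_meta": tau95_meta,
                "stratified": strat_summary,
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except TwindiffError as exc:
        raise TwindiffError(f"pipeline stage {stage!r} failed: {exc}") from exc


def summarize_manifest(manifest: dict) -> str:
    """Human-readable run summary."""
    s = manifest["summary"]
    lines = [f"studies analyzed: {s['n_studies']}"]
    for sid, n in s["per_study_significant"].items():
        lines.append(f"  {sid}: {n} significant genes")
    lines.append(f"genes meta-analyzed: {s['n_genes_meta']}")
    lines.append(f"overall significant (q<0.05, |est|>tau95, k>1): {s['overall_significant']}")
    lines.append(f"heterogeneous (QEp FDR<0.05): {s['heterogeneous']}")
    for sex, info in s.get("stratified", {}).items():
        if sex == "cross_sex":
            lines.append(f"cross-sex overlap: {info['n_intersection']} gene(s)")
        else:
            lines.append(f"{sex} stratum: {info['overall_significant']} overall significant "
                         f"({', '.join(info['studies_used'])})")
    return "\n".join(lines)
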