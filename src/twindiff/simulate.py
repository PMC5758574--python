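"""Synthetic multi-study discordant-twin cohorts with known ground truth.

The generator mirrors the assumptions of the downstream analysis. For study
``s``, gene ``g`` measured there, probe ``k`` of that gene, pair ``i`` and
twin ``t``:

    value = baseline_g + probe_offset_k + pair_effect_i
            + [t is affected] · δ_{g,s} + ε,        ε ~ N(0, noise_sd²)

with δ_{g,s} ~ N(μ_g, τ²) for affected genes and δ_{g,s} = 0 for null genes.
Effects are additive on the intensity scale (platform-native units; no log
transform anywhere in the pipeline). Baselines, probe offsets and the shared
pair effect all cancel in within-pair differences, so the difference for one
probe is distributed N(δ_{g,s}, 2·noise_sd²) — the paired design removes
inherited and shared-environment variation by construction, and all probes of
a gene share a common true effect, matching the fixed-effect summarization
model.

Each study measures an independent random subset of the gene universe
(``platform_coverage``), with 1–4 probes per measured gene by default; sex is
assigned per pair (monozygotic twins share sex) in the studies configured as
sex-labelled. Every draw comes from one seeded generator, so a (config, seed)
pair reproduces the cohort exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, TwindiffError
from .reference import GENE_UNIVERSE_SIZE, REFERENCE_STUDIES
from .types import ExpressionStudy, TwinPair

_REF_PAIRS = tuple(s.n_pairs for s in REFERENCE_STUDIES)
_REF_PHENOTYPES = tuple(s.phenotype for s in REFERENCE_STUDIES)
_REF_COVERAGE = tuple(s.n_genes / GENE_UNIVERSE_SIZE for s in REFERENCE_STUDIES)
_REF_SEX = tuple(i for i, s in enumerate(REFERENCE_STUDIES) if s.sex_labelled)


@dataclass
class SimulationConfig:
    """Cohort-generator parameters.

    Defaults reproduce the reference seven-study design: 10–44 pairs per
    study, a 25,154-gene universe with per-study platform coverage between
    ~74% and ~91%, 1–4 probes per measured gene, and sex labels only in the
    CFS, MDD and OB studies. Intensity-scale parameters (all in platform
    units): 5% of genes carry a true effect with per-gene mean effect
    μ_g ~ N(0, effect_mean_sd²), between-study effect SD ``tau``, residual
    twin noise ``noise_sd``, shared-pair effect SD ``pair_effect_sd`` and
    additive per-probe offset SD ``probe_offset_sd``.
    """

    n_studies: int = len(REFERENCE_STUDIES)
    pairs_per_study: tuple[int, ...] = _REF_PAIRS
    phenotypes: tuple[str, ...] = _REF_PHENOTYPES
    n_genes_universe: int = GENE_UNIVERSE_SIZE
    platform_coverage: tuple[float, ...] | float = _REF_COVERAGE
    probes_per_gene: tuple[int, int] = (1, 4)  # uniform integer range, inclusive
    frac_affected_genes: float = 0.05
    effect_mean_sd: float = 30.0
    tau: float = 10.0
    noise_sd: float = 50.0
    pair_effect_sd: float = 50.0
    probe_offset_sd: float = 20.0
    baseline_mean: float = 500.0
    baseline_sd: float = 100.0
    missing_rate: float = 0.0
    sex_labelled_studies: tuple[int, ...] | None = None  # None: reference default
    seed: int = 0

    def __post_init__(self):
        if self.sex_labelled_studies is None:
            self.sex_labelled_studies = (
                _REF_SEX if self.n_studies == len(REFERENCE_STUDIES) else ())
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        if len(self.pairs_per_study) != self.n_studies:
            raise ConfigError("pairs_per_study length must equal n_studies")
        if any(n < 3 for n in self.pairs_per_study):
            raise ConfigError("every study needs >= 3 twin pairs")
        if len(self.phenotypes) != self.n_studies:
            raise ConfigError("phenotypes length must equal n_studies")
        cov = self.coverage_per_study()
        if any(not (0 < c <= 1) for c in cov):
            raise ConfigError("platform_coverage must lie in (0, 1]")
        for name in ("tau", "noise_sd", "pair_effect_sd", "probe_offset_sd",
                     "effect_mean_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("frac_affected_genes", "missing_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError("probes_per_gene must be an increasing range with min >= 1")
        if any(not (0 <= i < self.n_studies) for i in self.sex_labelled_studies):
            raise ConfigError("sex_labelled_studies indices out of range")

    def coverage_per_study(self) -> tuple[float, ...]:
        if isinstance(self.platform_coverage, (int, float)):
            return (float(self.platform_coverage),) * self.n_studies
        if len(self.platform_coverage) != self.n_studies:
            raise ConfigError("platform_coverage list length must equal n_studies")
        return tuple(float(c) for c in self.platform_coverage)


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated cohort.

    ``genes`` has one row per universe gene (gene, affected, mu); ``deltas``
    one row per (study, measured gene) with the realized effect δ_{g,s};
    ``probe_maps`` gives each study's probe → gene map.
    """

    genes: pd.DataFrame
    deltas: pd.DataFrame
    probe_maps: dict[str, dict[str, str]]
    tau: float
    seed: int

    def true_effect(self, study_id: str, gene: str) -> float:
        d = self.deltas
        row = d[(d["study_id"] == study_id) & (d["gene"] == gene)]
        return float(row["delta"].iloc[0]) if len(row) else 0.0


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None,
                    ) -> tuple[list[ExpressionStudy], SimulationTruth]:
    """Draw a multi-study cohort and its ground truth from one seeded RNG."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    G = config.n_genes_universe
    gene_ids = np.array([f"G{i:05d}" for i in range(G)])

    n_aff = int(round(config.frac_affected_genes * G))
    affected_idx = rng.choice(G, size=n_aff, replace=False)
    affected = np.zeros(G, dtype=bool)
    affected[affected_idx] = True
    mu = np.zeros(G)
    mu[affected] = rng.normal(0.0, config.effect_mean_sd, size=n_aff)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)

    coverage = config.coverage_per_study()
    lo, hi = config.probes_per_gene
    studies: list[ExpressionStudy] = []
    delta_rows = []
    probe_maps: dict[str, dict[str, str]] = {}

    for s in range(config.n_studies):
        sid = config.phenotypes[s]
        n_pairs = config.pairs_per_study[s]
        panel = np.sort(rng.choice(G, size=int(round(coverage[s] * G)), replace=False))
        n_probes_per_gene = rng.integers(lo, hi + 1, size=len(panel))
        gene_of_probe = np.repeat(panel, n_probes_per_gene)  # universe index per probe
        n_probes = len(gene_of_probe)
        probe_ids = [f"{sid}_probe{j:06d}" for j in range(n_probes)]
        probe_maps[sid] = {pid: gene_ids[gi] for pid, gi in zip(probe_ids, gene_of_probe)}

        delta_g = np.zeros(len(panel))
        aff_panel = affected[panel]
        if config.tau > 0:
            delta_g[aff_panel] = rng.normal(mu[panel][aff_panel], config.tau)
        else:
            delta_g[aff_panel] = mu[panel][aff_panel]
        delta_rows.append(pd.DataFrame({
            "study_id": sid, "gene": gene_ids[panel], "delta": delta_g}))
        delta_of_probe = np.repeat(delta_g, n_probes_per_gene)

        probe_offset = rng.normal(0.0, config.probe_offset_sd, size=n_probes)
        pair_effect = rng.normal(0.0, config.pair_effect_sd, size=n_pairs)
        noise = rng.normal(0.0, config.noise_sd, size=(n_probes, 2 * n_pairs))

        # columns: pair0-affected, pair0-unaffected, pair1-affected, ...
        values = (baseline[gene_of_probe][:, None] + probe_offset[:, None]
                  + np.repeat(pair_effect, 2)[None, :] + noise)
        values[:, 0::2] += delta_of_probe[:, None]
        if config.missing_rate > 0:
            values[rng.random(values.shape) < config.missing_rate] = np.nan

        sample_ids, pairs = [], []
        for i in range(n_pairs):
            a, u = f"{sid}_pair{i:03d}_aff", f"{sid}_pair{i:03d}_unaff"
            sample_ids += [a, u]
            pairs.append(TwinPair(f"{sid}_pair{i:03d}", a, u))
        sex = None
        if s in config.sex_labelled_studies:
            draws = rng.random(n_pairs) < 0.5
            sex = {p.pair_id: ("female" if d else "male") for p, d in zip(pairs, draws)}

        studies.append(ExpressionStudy(
            study_id=sid, phenotype=sid, probe_ids=probe_ids, sample_ids=sample_ids,
            values=values, pairs=pairs, sex=sex,
            annotation={pid: frozenset({g}) for pid, g in probe_maps[sid].items()}))

    truth = SimulationTruth(
        genes=pd.DataFrame({"gene": gene_ids, "affected": affected, "mu": mu}),
        deltas=pd.concat(delta_rows, ignore_index=True),
        probe_maps=probe_maps, tau=config.tau, seed=config.seed)
    return studies, truth


def emit_cohort_files(cohort: list[ExpressionStudy], directory,
                      truth: SimulationTruth | None = None,
                      seed: int | None = None) -> dict:
    """Write one (matrix, metadata, annotation) TSV triple per study.

    Also writes the ground-truth table when given, plus ``manifest.json``
    listing every file and the seed. Returns the manifest dict.
    """
    if not cohort:
        raise TwindiffError("emit_cohort_files: empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for study in cohort:
        base = directory / study.study_id
        mat = pd.DataFrame(study.values, columns=study.sample_ids)
        mat.insert(0, "probe_id", study.probe_ids)
        mat.to_csv(f"{base}_matrix.tsv", sep="\t", index=False,
                   float_format="%.6g", na_rep="NA")
        rows = []
        for p in study.pairs:
            sx = (study.sex or {}).get(p.pair_id, "")
            rows.append((p.affected, p.pair_id, "affected", sx))
            rows.append((p.unaffected, p.pair_id, "unaffected", sx))
        meta = pd.DataFrame(rows, columns=["sample_id", "pair_id", "status", "sex"])
        if study.sex is None:
            meta = meta.drop(columns=["sex"])
        meta.to_csv(f"{base}_metadata.tsv", sep="\t", index=False)
        ann = pd.DataFrame({
            "probe_id": study.probe_ids,
            "gene_symbol": [" /// ".join(sorted(study.annotation.get(p, ())))
                            for p in study.probe_ids]})
        ann.to_csv(f"{base}_annotation.tsv", sep="\t", index=False)
        files += [f"{study.study_id}_matrix.tsv", f"{study.study_id}_metadata.tsv",
                  f"{study.study_id}_annotation.tsv"]
    if truth is not None:
        truth.deltas.merge(truth.genes, on="gene").to_csv(
            directory / "truth.tsv", sep="\t", index=False, float_format="%.6g")
        files.append("truth.tsv")
        if seed is None:
            seed = truth.seed
    manifest = {"seed": seed, "n_studies": len(cohort), "files": files}
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
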