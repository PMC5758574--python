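"""Core data containers for discordant-twin expression analysis.

The central object is :class:`ExpressionStudy`: one study's probe-level
expression matrix together with its discordant twin-pair design (which sample
is the affected twin, which the unaffected co-twin), optional per-pair sex
labels, and the platform's probe-to-gene annotation. Downstream statistics are
carried in plain :class:`pandas.DataFrame` tables whose column schemas are the
module constants ``PROBE_COLUMNS``, ``GENE_COLUMNS`` and ``META_COLUMNS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError

#: Columns of a per-probe paired-statistics table (one row per probe).
PROBE_COLUMNS = ["probe_id", "n_pairs", "mean_diff", "se", "t_stat", "df", "p_value", "flag"]

#: Columns of a per-study gene-level table (one row per gene).
GENE_COLUMNS = ["gene", "study_id", "phenotype", "n_probes", "mean_diff", "se",
                "z_stat", "p_value", "q_value", "abs_rank"]

#: Columns of the cross-study per-gene random-effects meta-analysis table.
META_COLUMNS = ["gene", "k", "re_estimate", "re_se", "z", "p_value", "q_value",
                "tau2", "Q", "Q_df", "QEp", "QEp_fdr", "I2"]

FLAG_OK = "ok"
FLAG_ZERO_VARIANCE = "zero_variance"
FLAG_INSUFFICIENT_PAIRS = "insufficient_pairs"


@dataclass(frozen=True)
class TwinPair:
    """One discordant monozygotic twin pair."""

    pair_id: str
    affected: str
    unaffected: str


@dataclass
class ProbeStat:
    """Paired-difference statistic for a single probe (affected − unaffected)."""

    probe_id: str
    n_pairs: int
    mean_diff: float
    se: float
    t_stat: float | None
    df: int | None
    p_value: float | None
    flag: str = FLAG_OK


@dataclass
class SignificanceResult:
    """A study's significant-gene call: BH FDR gate plus effect-size gate.

    ``threshold_95`` is the per-phenotype effect-size threshold — the 95th
    percentile of |mean difference| over all genes summarized in the study.
    Membership requires ``q_value < alpha_fdr`` AND ``|mean_diff| > threshold_95``
    (both strict).
    """

    study_id: str
    threshold_95: float
    significant_genes: frozenset[str]
    n_tested: int
    alpha_fdr: float = 0.05
    effect_percentile: float = 95.0


@dataclass(frozen=True)
class PairwiseComparison:
    """Cross-phenotype comparison of two studies' gene signatures."""

    phenotype_a: str
    phenotype_b: str
    n_measured_both: int
    n_sig_both: int
    overlap_pct: float | None
    spearman_rho: float | None
    spearman_p: float | None


@dataclass
class LoadReport:
    """What happened while reading one study from disk."""

    study_id: str
    n_pairs: int
    n_probes: int
    n_unmapped_probes: int
    dropped_pairs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ExpressionStudy:
    """One study: probe × sample intensities plus the discordant-pair design.

    Parameters
    ----------
    study_id, phenotype
        Identifier and phenotype label of the study.
    probe_ids, sample_ids
        Row and column labels of ``values`` (order is meaningful and preserved).
    values
        Probe × sample matrix of platform-native intensities; ``NaN`` marks a
        missing measurement.
    pairs
        The discordant twin pairs; each sample may belong to at most one pair.
    sex
        Optional map ``pair_id -> {"male", "female"}``. Monozygotic twins share
        sex, so it is a pair-level attribute.
    annotation
        Map ``probe_id -> frozenset of gene symbols``. Probes absent from the
        map (or mapped to an empty set) are *unmapped* and are excluded from
        gene-level summarization.
    """

    study_id: str
    phenotype: str
    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    pairs: list[TwinPair]
    sex: dict[str, str] | None = None
    annotation: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DesignError(
                f"study {self.study_id}: values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise DesignError(f"study {self.study_id}: duplicate probe IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DesignError(f"study {self.study_id}: duplicate sample IDs")
        if len(self.pairs) < 1:
            raise DesignError(f"study {self.study_id}: no twin pairs")
        pair_ids = [p.pair_id for p in self.pairs]
        if len(set(pair_ids)) != len(pair_ids):
            raise DesignError(f"study {self.study_id}: duplicated pair_id")
        members = [s for p in self.pairs for s in (p.affected, p.unaffected)]
        if len(set(members)) != len(members):
            raise DesignError(f"study {self.study_id}: a sample appears in more than one pair slot")
        known = set(self.sample_ids)
        missing = [s for s in members if s not in known]
        if missing:
            raise DesignError(f"study {self.study_id}: pair members not in sample list: {missing}")
        if self.sex is not None:
            bad = {v for v in self.sex.values()} - {"male", "female"}
            if bad:
                raise DesignError(f"study {self.study_id}: invalid sex labels {sorted(bad)}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def unmapped_probes(self) -> list[str]:
        """Probes with no (non-empty) gene annotation."""
        return [p for p in self.probe_ids if not self.annotation.get(p)]

    def measured_genes(self) -> frozenset[str]:
        """All gene symbols interrogated by at least one probe of this study."""
        genes: set[str] = set()
        for p in self.probe_ids:
            genes |= self.annotation.get(p, frozenset())
        return frozenset(genes)

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of (affected, unaffected) samples, pair order."""
        col = {s: j for j, s in enumerate(self.sample_ids)}
        aff = np.array([col[p.affected] for p in self.pairs], dtype=int)
        unaff = np.array([col[p.unaffected] for p in self.pairs], dtype=int)
        return aff, unaff

    def subset_pairs(self, keep: list[TwinPair], suffix: str = "") -> "ExpressionStudy":
        """A copy of the study restricted to ``keep`` pairs (samples and sex pruned)."""
        if not keep:
            raise DesignError(f"study {self.study_id}: pair subset is empty")
        keep_samples = [s for p in keep for s in (p.affected, p.unaffected)]
        keep_set = set(keep_samples)
        cols = [j for j, s in enumerate(self.sample_ids) if s in keep_set]
        sex = None
        if self.sex is not None:
            sex = {p.pair_id: self.sex[p.pair_id] for p in keep if p.pair_id in self.sex}
        return ExpressionStudy(
            study_id=self.study_id + suffix,
            phenotype=self.phenotype,
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[j] for j in cols],
            values=self.values[:, cols],
            pairs=list(keep),
            sex=sex,
            annotation=dict(self.annotation),
        )
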