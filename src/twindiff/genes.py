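"""Probe-to-gene summarization by fixed-effect inverse-variance meta-analysis.

Microarray platforms interrogate most genes with several probes, each on its
own measurement scale. Rather than reporting probe-level differences, each
gene's probe estimates are pooled under a common-effect model with
inverse-variance weights w_j = 1/se_j²:

    pooled_mean = Σ w_j m_j / Σ w_j,   pooled_se = 1/sqrt(Σ w_j),
    z = pooled_mean / pooled_se,       p = two-sided normal tail.

Probes annotated to several genes contribute to every mapped gene; probes
flagged at the paired-statistics stage (zero variance, too few pairs) and
unmapped probes are excluded. Genes are additionally ranked within the study
by |pooled mean difference| (1 = largest), a scale-free summary that eases
comparison across platforms with different intensity units.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .types import FLAG_OK, GENE_COLUMNS

logger = logging.getLogger(__name__)


def fixed_effect_pool(estimates: Sequence[tuple[float, float]]
                      ) -> tuple[float, float, float, float]:
    """Pool (mean, se) estimates under the fixed-effect model.

    Returns ``(pooled_mean, pooled_se, z, p)``; requires a non-empty list with
    all standard errors positive.
    """
    if len(estimates) == 0:
        raise AnalysisError("fixed_effect_pool: empty estimate list")
    m = np.asarray([e[0] for e in estimates], dtype=float)
    se = np.asarray([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise AnalysisError("fixed_effect_pool: all standard errors must be > 0")
    w = 1.0 / se ** 2
    pooled = float((w * m).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return pooled, pooled_se, z, p


def assign_abs_rank(table: pd.DataFrame, mode: str = "abs_desc") -> pd.Series:
    """Within-study gene rank of the mean difference (1 = most extreme).

    ``mode`` is ``abs_desc`` (default, by |mean_diff| descending),
    ``signed_desc`` or ``signed_asc``. Ties are broken by gene symbol,
    ascending, so the ranking is a deterministic permutation of 1..n.
    """
    if mode == "abs_desc":
        key = -table["mean_diff"].abs()
    elif mode == "signed_desc":
        key = -table["mean_diff"]
    elif mode == "signed_asc":
        key = table["mean_diff"]
    else:
        raise AnalysisError(f"unknown rank mode {mode!r}")
    order = pd.DataFrame({"key": key, "gene": table["gene"]}).sort_values(
        ["key", "gene"], kind="mergesort")
    rank = pd.Series(np.arange(1, len(table) + 1), index=order.index)
    return rank.reindex(table.index)


def summarize_study(probe_stats: pd.DataFrame,
                    annotation: dict[str, frozenset[str]],
                    study_id: str,
                    phenotype: str | None = None,
                    rank_mode: str = "abs_desc") -> pd.DataFrame:
    """One gene-level estimate per gene for one study.

    ``probe_stats`` is a per-probe table from
    :func:`twindiff.paired.study_probe_table`; only ``ok``-flagged probes with
    a gene annotation are pooled. Genes whose probes are all flagged or
    unmapped are omitted (and counted in a log line). Returns a frame with
    :data:`twindiff.types.GENE_COLUMNS`; ``q_value`` is NaN until the
    significance stage fills it.
    """
    ok = probe_stats[probe_stats["flag"] == FLAG_OK]
    genes_per_probe = [sorted(annotation.get(p, ())) for p in ok["probe_id"]]
    long = ok.loc[ok.index.repeat([len(g) for g in genes_per_probe]),
                  ["probe_id", "mean_diff", "se"]].copy()
    long["gene"] = [g for gl in genes_per_probe for g in gl]
    if len(long) == 0:
        raise AnalysisError(f"study {study_id}: no usable annotated probes")

    long["w"] = 1.0 / long["se"] ** 2
    long["wm"] = long["w"] * long["mean_diff"]
    agg = long.groupby("gene", sort=True).agg(
        n_probes=("probe_id", "size"), w_sum=("w", "sum"), wm_sum=("wm", "sum"))
    agg["mean_diff"] = agg["wm_sum"] / agg["w_sum"]
    agg["se"] = 1.0 / np.sqrt(agg["w_sum"])
    agg["z_stat"] = agg["mean_diff"] / agg["se"]
    agg["p_value"] = 2.0 * stats.norm.sf(np.abs(agg["z_stat"]))

    table = agg.reset_index()[["gene", "n_probes", "mean_diff", "se", "z_stat", "p_value"]]
    table.insert(1, "study_id", study_id)
    table.insert(2, "phenotype", phenotype if phenotype is not None else study_id)
    table["q_value"] = np.nan
    table["abs_rank"] = assign_abs_rank(table, rank_mode)
    table = table[GENE_COLUMNS]

    n_dropped_probes = len(probe_stats) - len(ok)
    all_genes = set().union(*annotation.values()) if annotation else set()
    n_omitted = len(all_genes) - table["gene"].nunique()
    if n_dropped_probes or n_omitted > 0:
        logger.info("study %s: %d probes excluded, %d annotated genes without usable probes",
                    study_id, n_dropped_probes, max(n_omitted, 0))
    return table
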