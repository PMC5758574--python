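"""Cross-phenotype integration of per-study gene signatures.

Three views of how gene-expression differences in discordant twin pairs relate
across phenotypes:

1. **Pairwise overlap** — for every pair of studies, the significant genes
   shared by both as a percentage of the genes co-measured by both platforms.
2. **Pairwise rank correlation** — Spearman's rho between the two studies'
   gene-level mean differences over co-measured genes.
3. **Per-gene random-effects meta-analysis** — each gene's per-study estimates
   are combined with the DerSimonian–Laird (DL) moment estimator. With
   fixed-effect weights w_j = 1/se_j² and the FE pooled mean μ̂:

       Q    = Σ w_j (m_j − μ̂)²                     (Cochran heterogeneity)
       τ²   = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))   (DL between-study variance)
       w*_j = 1/(se_j² + τ²)
       μ̂_RE = Σ w*_j m_j / Σ w*_j,  se_RE = 1/sqrt(Σ w*_j)

   with a Wald z test for μ̂_RE, the heterogeneity p-value QEp from the χ²_{k−1}
   upper tail at Q, and I² = max(0, (Q − (k−1))/Q)·100 — the percentage of
   total variation across studies attributable to heterogeneity rather than
   sampling error. Genes measured in a single study are kept in the table with
   the degenerate conventions Q = 0, τ² = 0, I² = 0, QEp = 1.

An *overall significant* gene has BH-adjusted meta p below ``alpha``, |pooled
estimate| above the 95th percentile of |pooled estimates|, and measurement in
more than one study.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .significance import bh_fdr, effect_threshold
from .types import META_COLUMNS, PairwiseComparison, SignificanceResult


def overlap_table(results: Mapping[str, SignificanceResult],
                  gene_universes: Mapping[str, frozenset[str]],
                  ) -> pd.DataFrame:
    """Pairwise (incl. self) significant-gene overlap percentages.

    ``overlap_pct = 100 · |SigA ∩ SigB| / |MeasA ∩ MeasB|`` over every
    unordered study pair; the diagonal reports a study's own significant
    fraction. An empty measured intersection yields a missing percentage.
    Percentages are reported rounded to 2 decimals alongside exact counts.
    """
    ids = sorted(results)
    if len(ids) < 2:
        raise AnalysisError("overlap_table: need at least 2 studies")
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i:]:
            measured = gene_universes[a] & gene_universes[b]
            sig = results[a].significant_genes & results[b].significant_genes
            pct = round(100.0 * len(sig) / len(measured), 2) if measured else None
            rows.append({"phenotype_a": a, "phenotype_b": b,
                         "n_measured_both": len(measured), "n_sig_both": len(sig),
                         "overlap_pct": pct})
    return pd.DataFrame(rows)


def diff_correlation(genes_a: pd.DataFrame, genes_b: pd.DataFrame
                     ) -> tuple[float, float, int]:
    """Spearman correlation of two studies' gene-level mean differences.

    Restricted to co-measured genes (≥ 3 required); ties get average ranks and
    the p-value uses the two-sided t approximation. Returns (rho, p, n shared).
    """
    merged = genes_a[["gene", "mean_diff"]].merge(
        genes_b[["gene", "mean_diff"]], on="gene", suffixes=("_a", "_b"))
    n = len(merged)
    if n < 3:
        raise AnalysisError(f"diff_correlation: only {n} co-measured genes (need >= 3)")
    rho, p = stats.spearmanr(merged["mean_diff_a"], merged["mean_diff_b"])
    return float(rho), float(p), n


def pairwise_tables(gene_tables: Mapping[str, pd.DataFrame],
                    results: Mapping[str, SignificanceResult],
                    gene_universes: Mapping[str, frozenset[str]],
                    ) -> pd.DataFrame:
    """Full pairwise comparison table: overlap + Spearman in one long frame."""
    overlaps = overlap_table(results, gene_universes)
    rhos, ps = [], []
    for row in overlaps.itertuples(index=False):
        try:
            rho, p, _ = diff_correlation(gene_tables[row.phenotype_a],
                                         gene_tables[row.phenotype_b])
        except AnalysisError:
            rho, p = np.nan, np.nan
        rhos.append(rho)
        ps.append(p)
    overlaps["spearman_rho"] = rhos
    overlaps["spearman_p"] = ps
    return overlaps


def comparison_records(table: pd.DataFrame) -> list[PairwiseComparison]:
    """View a pairwise table as typed records."""
    return [PairwiseComparison(
        phenotype_a=r.phenotype_a, phenotype_b=r.phenotype_b,
        n_measured_both=int(r.n_measured_both), n_sig_both=int(r.n_sig_both),
        overlap_pct=None if pd.isna(r.overlap_pct) else float(r.overlap_pct),
        spearman_rho=None if pd.isna(r.spearman_rho) else float(r.spearman_rho),
        spearman_p=None if pd.isna(r.spearman_p) else float(r.spearman_p),
    ) for r in table.itertuples(index=False)]


def dl_meta(estimates: Sequence[tuple[float, float]]) -> dict[str, float]:
    """DerSimonian–Laird random-effects meta-analysis of one gene.

    ``estimates`` is the gene's per-study (mean difference, SE) list, k ≥ 1,
    all SEs > 0. Returns the core fields: re_estimate, re_se, z, p_value,
    tau2, Q, Q_df, QEp, I2.
    """
    k = len(estimates)
    if k == 0:
        raise AnalysisError("dl_meta: empty estimate list")
    m = np.asarray([e[0] for e in estimates], dtype=float)
    se = np.asarray([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise AnalysisError("dl_meta: all standard errors must be > 0")

    w = 1.0 / se ** 2
    mu_fe = (w * m).sum() / w.sum()
    Q = float((w * (m - mu_fe) ** 2).sum())
    df = k - 1
    if k == 1:
        tau2, I2, QEp = 0.0, 0.0, 1.0
    else:
        denom = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
        I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
        QEp = float(stats.chi2.sf(Q, df))
    ws = 1.0 / (se ** 2 + tau2)
    re = float((ws * m).sum() / ws.sum())
    re_se = float(1.0 / np.sqrt(ws.sum()))
    z = re / re_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"re_estimate": re, "re_se": re_se, "z": z, "p_value": p,
            "tau2": tau2, "Q": Q, "Q_df": df, "QEp": QEp, "I2": I2}


def meta_analyze_genes(gene_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """DL meta-analysis of every gene across studies (vectorized).

    Concatenates the per-study gene tables, groups by gene, and computes the
    DL fields for every gene, including k = 1 genes with the degenerate
    conventions. Fills ``q_value`` (BH over all genes' meta p-values) and
    ``QEp_fdr`` (BH over all genes' QEp). Returns a frame with
    :data:`twindiff.types.META_COLUMNS`, sorted by gene.
    """
    long = pd.concat([t[["gene", "mean_diff", "se"]] for t in gene_tables.values()],
                     ignore_index=True)
    if len(long) == 0:
        raise AnalysisError("meta_analyze_genes: no gene-level estimates")
    long["w"] = 1.0 / long["se"] ** 2
    long["w2"] = long["w"] ** 2
    long["wm"] = long["w"] * long["mean_diff"]
    long["wm2"] = long["w"] * long["mean_diff"] ** 2
    g = long.groupby("gene", sort=True)
    agg = g.agg(k=("gene", "size"), w_sum=("w", "sum"), w2_sum=("w2", "sum"),
                wm_sum=("wm", "sum"), wm2_sum=("wm2", "sum"))
    agg["mu_fe"] = agg["wm_sum"] / agg["w_sum"]
    Q = (agg["wm2_sum"] - agg["wm_sum"] ** 2 / agg["w_sum"]).clip(lower=0.0)
    df = agg["k"] - 1
    denom = agg["w_sum"] - agg["w2_sum"] / agg["w_sum"]
    tau2 = ((Q - df) / denom).where(denom > 0, 0.0).clip(lower=0.0)
    tau2 = tau2.where(agg["k"] > 1, 0.0)
    I2 = (((Q - df) / Q).clip(lower=0.0) * 100.0).where((Q > 0) & (agg["k"] > 1), 0.0)
    QEp = pd.Series(stats.chi2.sf(Q, df.clip(lower=1)), index=agg.index).where(
        agg["k"] > 1, 1.0)

    long = long.merge(tau2.rename("tau2"), left_on="gene", right_index=True)
    long["ws"] = 1.0 / (long["se"] ** 2 + long["tau2"])
    long["wsm"] = long["ws"] * long["mean_diff"]
    g2 = long.groupby("gene", sort=True)
    ws_sum = g2["ws"].sum()
    re = g2["wsm"].sum() / ws_sum
    re_se = 1.0 / np.sqrt(ws_sum)
    z = re / re_se
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame({
        "gene": agg.index, "k": agg["k"].to_numpy(),
        "re_estimate": re.to_numpy(), "re_se": re_se.to_numpy(),
        "z": z.to_numpy(), "p_value": p,
        "q_value": np.nan,
        "tau2": tau2.to_numpy(), "Q": Q.to_numpy(), "Q_df": df.to_numpy(),
        "QEp": QEp.to_numpy(), "QEp_fdr": np.nan, "I2": I2.to_numpy(),
    }, columns=META_COLUMNS).reset_index(drop=True)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["QEp_fdr"] = bh_fdr(out["QEp"].to_numpy())
    return out


def overall_selection(meta: pd.DataFrame,
                      alpha: float = 0.05,
                      effect_percentile: float = 95.0,
                      threshold_reference: str = "meta",
                      per_study_abs_diffs: np.ndarray | None = None,
                      ) -> tuple[frozenset[str], frozenset[str], float]:
    """Overall-significant and heterogeneous gene sets from the meta table.

    Selected = { g : q_value < alpha AND |re_estimate| > τ95 AND k > 1 } with
    τ95 the 95th percentile of |re_estimate| over all meta-analyzed genes (the
    default ``threshold_reference='meta'``; ``'per_study'`` instead pools the
    per-study |mean_diff| values supplied in ``per_study_abs_diffs``).
    Heterogeneous = { g : QEp_fdr < alpha }. Returns (selected, heterogeneous,
    τ95).
    """
    if threshold_reference == "meta":
        ref = meta["re_estimate"].abs().to_numpy()
    elif threshold_reference == "per_study":
        if per_study_abs_diffs is None:
            raise AnalysisError("per_study threshold reference needs per_study_abs_diffs")
        ref = np.asarray(per_study_abs_diffs, dtype=float)
    else:
        raise AnalysisError(f"unknown threshold reference {threshold_reference!r}")
    tau95 = effect_threshold(ref, percentile=effect_percentile)
    sel = meta[(meta["q_value"] < alpha)
               & (meta["re_estimate"].abs() > tau95)
               & (meta["k"] > 1)]
    het = meta[meta["QEp_fdr"] < alpha]
    return frozenset(sel["gene"]), frozenset(het["gene"]), tau95
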