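"""Per-study significance calls: BH FDR plus a percentile effect-size gate.

Small twin cohorts make p-value-only selection fragile, so a gene is called
significant in a study only if it clears two gates simultaneously:

* Benjamini–Hochberg adjusted p (q) strictly below ``alpha_fdr`` (default 0.05);
* |pooled mean difference| strictly above the study's effect-size threshold
  τ95, the 95th percentile of |mean difference| over all genes summarized in
  that study (linear interpolation between order statistics, the "type 7"
  percentile definition).

Both gates are computed within each study over exactly the genes summarized
there, so τ95 is a per-phenotype quantity on that platform's intensity scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .types import SignificanceResult


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise AnalysisError("bh_fdr: empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AnalysisError("bh_fdr: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effect_threshold(abs_diffs, percentile: float = 95.0,
                     interpolation: str = "linear") -> float:
    """Percentile of |mean difference| used as the effect-size gate.

    Default is the 95th percentile with linear interpolation between order
    statistics (position (n−1)·q, the common "type 7" definition).
    """
    x = np.asarray(abs_diffs, dtype=float)
    if x.size == 0:
        raise AnalysisError("effect_threshold: empty value list")
    if np.any(x < 0):
        raise AnalysisError("effect_threshold: absolute differences must be >= 0")
    return float(np.percentile(x, percentile, method=interpolation))


def select_significant(gene_stats: pd.DataFrame,
                       alpha_fdr: float = 0.05,
                       effect_percentile: float = 95.0,
                       percentile_interpolation: str = "linear",
                       ) -> tuple[pd.DataFrame, SignificanceResult]:
    """Call a study's significant genes and fill its q-values.

    ``gene_stats`` must all come from one study. Returns a copy of the table
    with ``q_value`` filled by BH over that study's genes, plus the
    :class:`~twindiff.types.SignificanceResult` with the τ95 threshold and the
    selected set { g : q < alpha AND |mean_diff| > τ95 } (strict on both
    sides — a gene sitting exactly on the threshold is not selected).
    """
    studies = gene_stats["study_id"].unique()
    if len(studies) != 1:
        raise AnalysisError(f"select_significant: mixed study IDs {sorted(studies)}")
    out = gene_stats.copy()
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    tau95 = effect_threshold(out["mean_diff"].abs().to_numpy(),
                             percentile=effect_percentile,
                             interpolation=percentile_interpolation)
    hits = out[(out["q_value"] < alpha_fdr) & (out["mean_diff"].abs() > tau95)]
    result = SignificanceResult(
        study_id=str(studies[0]),
        threshold_95=tau95,
        significant_genes=frozenset(hits["gene"]),
        n_tested=len(out),
        alpha_fdr=alpha_fdr,
        effect_percentile=effect_percentile,
    )
    return out, result
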