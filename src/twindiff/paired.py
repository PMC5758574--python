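"""Per-probe paired-difference statistics within one study.

For every probe the within-pair difference d_i = affected_i − unaffected_i is
taken over complete pairs (pairs missing either measurement for that probe are
excluded, probe by probe). The statistic is the classical paired t:

    mean_diff = mean(d),  se = sd(d)/sqrt(n)  (sample SD, n−1),
    t = mean_diff / se,   p = two-sided Student-t tail with df = n − 1.

The sign convention is affected − unaffected: a positive mean difference means
the affected twin expresses higher. Probes with fewer than 3 complete pairs or
with zero difference variance carry a flag instead of a p-value and are
excluded from gene-level summarization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .types import (FLAG_INSUFFICIENT_PAIRS, FLAG_OK, FLAG_ZERO_VARIANCE,
                    PROBE_COLUMNS, ExpressionStudy, ProbeStat)

logger = logging.getLogger(__name__)

MIN_PAIRS = 3


def _paired_arrays(study: ExpressionStudy) -> np.ndarray:
    """Probe × pair matrix of within-pair differences (NaN where incomplete)."""
    aff, unaff = study.pair_indices()
    return study.values[:, aff] - study.values[:, unaff]


def study_probe_table(study: ExpressionStudy, min_pairs: int = MIN_PAIRS) -> pd.DataFrame:
    """Paired statistics for every probe of a study, in probe order.

    Returns a frame with :data:`twindiff.types.PROBE_COLUMNS`. Flagged probes
    (``insufficient_pairs``, ``zero_variance``) have NaN t and p.
    """
    diffs = _paired_arrays(study)
    ok_mask = ~np.isnan(diffs)
    n = ok_mask.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(ok_mask, diffs, 0.0), axis=1) /
                        np.maximum(n, 1), np.nan)
        resid = np.where(ok_mask, diffs - mean[:, None], 0.0)
        ss = (resid ** 2).sum(axis=1)
        sd = np.sqrt(np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan))
        se = sd / np.sqrt(np.maximum(n, 1))
        t = mean / se
    df_ = n - 1

    flag = np.full(len(study.probe_ids), FLAG_OK, dtype=object)
    flag[n < min_pairs] = FLAG_INSUFFICIENT_PAIRS
    zero_var = (n >= min_pairs) & (sd == 0)
    flag[zero_var] = FLAG_ZERO_VARIANCE

    ok = flag == FLAG_OK
    p = np.full(len(t), np.nan)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_[ok])
    t = np.where(ok, t, np.nan)

    table = pd.DataFrame({
        "probe_id": study.probe_ids,
        "n_pairs": n,
        "mean_diff": mean,
        "se": se,  # 0 for zero-variance probes; NaN where undefined (n < 2)
        "t_stat": t,
        "df": df_,
        "p_value": p,
        "flag": flag,
    }, columns=PROBE_COLUMNS)
    n_flagged = int((~ok).sum())
    if n_flagged:
        logger.info("study %s: %d/%d probes flagged (not ok)",
                    study.study_id, n_flagged, len(table))
    return table


def paired_ttest(study: ExpressionStudy, probe_id: str) -> ProbeStat:
    """Paired t statistic for one probe of a study."""
    try:
        idx = study.probe_ids.index(probe_id)
    except ValueError:
        raise AnalysisError(f"unknown probe {probe_id!r} in study {study.study_id}")
    row = study_probe_table(study).iloc[idx]
    flagged = row["flag"] != FLAG_OK
    return ProbeStat(
        probe_id=probe_id,
        n_pairs=int(row["n_pairs"]),
        mean_diff=float(row["mean_diff"]),
        se=float(row["se"]) if not np.isnan(row["se"]) else float("nan"),
        t_stat=None if flagged else float(row["t_stat"]),
        df=None if flagged else int(row["df"]),
        p_value=None if flagged else float(row["p_value"]),
        flag=row["flag"],
    )
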