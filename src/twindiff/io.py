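"""Tab-separated input/output for twin-cohort expression studies.

Three input files describe one study:

* expression matrix — header ``probe_id<TAB>sample...``, one row per probe,
  missing values as empty fields or ``NA``;
* sample metadata — columns ``sample_id``, ``pair_id``, ``status``
  (``affected``/``unaffected``) and optionally ``sex``;
* probe annotation — columns ``probe_id``, ``gene_symbol``; cells carrying
  several symbols use the ``" /// "`` delimiter common in platform (GPL)
  annotation tables.

Only this one dialect (tab-delimited, UTF-8, ``.`` decimal) is supported;
converting repository-native formats (series matrices, CEL files) is the
caller's job.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError
from .types import ExpressionStudy, LoadReport, TwinPair

logger = logging.getLogger(__name__)

MULTI_GENE_DELIMITER = "///"
_STATUSES = {"affected", "unaffected"}


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse TSV: {exc}", path=str(path))


def read_annotation(annotation_path) -> dict[str, frozenset[str]]:
    """Read a probe → gene-symbol map.

    Multi-gene cells are split on ``"///"``; surrounding whitespace is
    stripped; empty symbols are dropped (a probe whose cell is empty stays
    unmapped). Several rows per probe are unioned.
    """
    df = _read_tsv(annotation_path)
    cols = [c.strip() for c in df.columns]
    if "probe_id" not in cols or "gene_symbol" not in cols:
        raise FormatError("annotation header must contain 'probe_id' and 'gene_symbol'",
                          path=str(annotation_path), line=1)
    df.columns = cols
    ann: dict[str, set[str]] = {}
    for probe, cell in zip(df["probe_id"], df["gene_symbol"]):
        probe = probe.strip()
        genes = {g.strip() for g in cell.split(MULTI_GENE_DELIMITER)}
        genes.discard("")
        genes.discard("NA")
        ann.setdefault(probe, set()).update(genes)
    return {p: frozenset(g) for p, g in ann.items()}


def _read_matrix(matrix_path) -> tuple[list[str], list[str], np.ndarray]:
    with open(matrix_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2 or header[0] != "probe_id":
        raise FormatError("matrix header must start with 'probe_id' followed by sample IDs",
                          path=str(matrix_path), line=1)
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample IDs in matrix header",
                          path=str(matrix_path), line=1)
    df = _read_tsv(matrix_path)
    probe_ids = [p.strip() for p in df["probe_id"]]
    if len(set(probe_ids)) != len(probe_ids):
        dup = pd.Series(probe_ids)
        first_dup = dup[dup.duplicated()].iloc[0]
        raise FormatError(f"duplicate probe ID {first_dup!r}", path=str(matrix_path))
    body = df.iloc[:, 1:].replace({"": np.nan, "NA": np.nan})
    try:
        values = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}", path=str(matrix_path))
    return probe_ids, sample_ids, values


def _read_pairs(metadata_path, sample_ids: list[str]
                ) -> tuple[list[TwinPair], dict[str, str] | None, list[str], list[str]]:
    df = _read_tsv(metadata_path)
    cols = [c.strip() for c in df.columns]
    for need in ("sample_id", "pair_id", "status"):
        if need not in cols:
            raise FormatError(f"metadata header missing column {need!r}",
                              path=str(metadata_path), line=1)
    df.columns = cols
    has_sex = "sex" in cols
    known = set(sample_ids)

    # pair_id -> {"affected": sample, "unaffected": sample, "sex": {...}, "line": n}
    by_pair: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sample = row.sample_id.strip()
        pid = row.pair_id.strip()
        status = row.status.strip().lower()
        if status not in _STATUSES:
            raise FormatError(f"status must be affected/unaffected, got {row.status!r}",
                              path=str(metadata_path), line=i)
        slot = by_pair.setdefault(pid, {"sex": set(), "line": i})
        if pid not in order:
            order.append(pid)
        if status in slot:
            raise DesignError(
                f"pair {pid!r} has two {status} members ({metadata_path} line {i})")
        slot[status] = sample
        if has_sex:
            sex = getattr(row, "sex", "").strip().lower()
            if sex:
                if sex not in ("male", "female"):
                    raise FormatError(f"sex must be male/female, got {sex!r}",
                                      path=str(metadata_path), line=i)
                slot["sex"].add(sex)

    pairs: list[TwinPair] = []
    dropped: list[str] = []
    warnings: list[str] = []
    sex_map: dict[str, str] = {}
    # Deterministic pair order: sorted by pair_id so that row permutations of
    # the metadata file yield an identical study.
    for pid in sorted(order):
        slot = by_pair[pid]
        missing = [st for st in ("affected", "unaffected") if st not in slot
                   or slot[st] not in known]
        if missing:
            dropped.append(pid)
            msg = f"pair {pid!r} dropped: missing or unknown {'/'.join(missing)} member"
            warnings.append(msg)
            logger.warning("%s: %s", metadata_path, msg)
            continue
        if len(slot["sex"]) > 1:
            raise DesignError(
                f"pair {pid!r} has conflicting sex labels (monozygotic twins share sex)")
        pairs.append(TwinPair(pid, slot["affected"], slot["unaffected"]))
        if slot["sex"]:
            sex_map[pid] = next(iter(slot["sex"]))
    if not pairs:
        raise DesignError(f"no valid twin pairs in {metadata_path}")
    return pairs, (sex_map if has_sex else None), dropped, warnings


def read_expression(matrix_path, metadata_path, annotation_path,
                    study_id: str | None = None, phenotype: str = "",
                    ) -> tuple[ExpressionStudy, LoadReport]:
    """Read one study (matrix + metadata + annotation TSVs) and validate it.

    Pairs with a missing member are dropped with a logged warning. Returns the
    study together with a :class:`LoadReport` carrying pair and unmapped-probe
    counts.
    """
    if study_id is None:
        study_id = Path(matrix_path).stem.replace("_matrix", "")
    probe_ids, sample_ids, values = _read_matrix(matrix_path)
    pairs, sex_map, dropped, warnings = _read_pairs(metadata_path, sample_ids)
    annotation = read_annotation(annotation_path)
    study = ExpressionStudy(
        study_id=study_id, phenotype=phenotype or study_id,
        probe_ids=probe_ids, sample_ids=sample_ids, values=values,
        pairs=pairs, sex=sex_map, annotation=annotation)
    report = LoadReport(
        study_id=study_id, n_pairs=len(pairs), n_probes=len(probe_ids),
        n_unmapped_probes=len(study.unmapped_probes),
        dropped_pairs=dropped, warnings=warnings)
    return study, report


def _format_cell(x) -> str:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    if x is None:
        return "NA"
    return str(x)


def write_results(records: pd.DataFrame, path) -> None:
    """Write a result table as deterministic TSV.

    Column order is taken from the frame; floats are rendered with 6
    significant digits; rows are sorted by ``gene`` then ``study_id`` when
    those columns exist (else left in input order). Writing an empty table is
    an error — a truncated pipeline stage must not masquerade as a result.
    """
    if records is None or len(records) == 0:
        raise FormatError("refusing to write an empty result table", path=str(path))
    df = records.copy()
    sort_cols = [c for c in ("gene", "study_id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_cell(x) for x in row) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results` (``NA`` → NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
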