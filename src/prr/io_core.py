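"""Tabular I/O for expression matrices, study designs, probe maps and results.

All on-disk artifacts are TSV with a header row.  An expression matrix is a
:class:`pandas.DataFrame` of log2 intensities with feature ids as the index
and sample ids as columns; a study design maps each sample id to an organ
(root/shoot), a condition (mock/starved/replete) and a replicate index.
Missing or non-numeric cells are hard load errors — no imputation rule is
defined for these designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("prr")

ORGANS = ("root", "shoot")
CONDITIONS = ("mock", "starved", "replete")

__all__ = [
    "ORGANS",
    "CONDITIONS",
    "ProbeMapReport",
    "read_expression_matrix",
    "read_design",
    "read_probe_map",
    "read_annotations",
    "write_results",
]


def read_expression_matrix(path: str | Path, expect_log2: bool = True) -> pd.DataFrame:
    """Read a features × samples TSV of log2 intensities.

    The first column holds feature ids, the header row sample ids.  Duplicate
    ids and non-finite or missing cells are errors.  ``expect_log2`` is
    recorded in ``df.attrs["log2"]`` — the loader never transforms values.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dup_cols = {h for h in header if h in seen or seen.add(h)}
    if dup_cols:
        raise ValueError(f"duplicate sample ids: {sorted(dup_cols)}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = header
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dup}")
    try:
        out = df.astype(float)
    except (TypeError, ValueError):
        out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() | ~out.apply(lambda c: c.map(_finite))
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise ValueError(
            f"non-numeric or missing cell at feature {out.index[r]!r}, "
            f"sample {out.columns[c]!r}"
        )
    out.index.name = "feature_id"
    out.attrs["log2"] = bool(expect_log2)
    return out


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design table (sample_id, organ, condition, replicate).

    Organ and condition tokens are vocabulary-checked.  Cells (organ,
    condition) with a single replicate are allowed at load time but logged;
    contrasts over such cells fail later.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "organ", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    bad_organ = set(df["organ"]) - set(ORGANS)
    if bad_organ:
        raise ValueError(f"unknown organ {sorted(bad_organ)}; allowed: {ORGANS}")
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(
            f"unknown condition {sorted(bad_cond)}; allowed: {CONDITIONS}"
        )
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValueError("replicate indices must be positive")
    counts = df.groupby(["organ", "condition"]).size()
    for (organ, cond), n in counts.items():
        if n < 2:
            logger.warning(
                "design cell (%s, %s) has %d replicate(s); contrasts on it will fail",
                organ, cond, n,
            )
    return df.set_index("sample_id", drop=False)


@dataclass
class ProbeMapReport:
    """Accounting for an ingested probe → gene map."""

    n_input_probes: int = 0
    n_retained: int = 0
    n_ambiguous_dropped: int = 0
    ambiguous_probes: list[str] = field(default_factory=list)


def read_probe_map(path: str | Path) -> tuple[pd.Series, ProbeMapReport]:
    """Read a probe → gene TSV (columns probe_id, gene_id).

    Probes listed under more than one gene are ambiguous: they are dropped
    (not duplicated) and counted in the returned report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError("probe map needs columns probe_id, gene_id")
    df = df.drop_duplicates()
    if df.empty:
        raise ValueError("probe map is empty")
    genes_per_probe = df.groupby("probe_id")["gene_id"].nunique()
    ambiguous = genes_per_probe.index[genes_per_probe > 1].tolist()
    kept = df[~df["probe_id"].isin(ambiguous)]
    report = ProbeMapReport(
        n_input_probes=int(genes_per_probe.size),
        n_retained=int(kept["probe_id"].nunique()),
        n_ambiguous_dropped=len(ambiguous),
        ambiguous_probes=sorted(ambiguous),
    )
    probe_map = kept.set_index("probe_id")["gene_id"]
    probe_map.name = "gene_id"
    return probe_map, report


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a gene → term annotation TSV (gene_id, term_id[, term_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation table needs columns gene_id, term_id")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    dup = df.duplicated(subset=["gene_id", "term_id"])
    if dup.any():
        df = df[~dup]
    return df.reset_index(drop=True)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with 6-significant-digit floats.

    An empty table is an error; index is written only if it is named (so
    expression matrices keep their feature column on round trip).
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(
        path,
        sep="\t",
        float_format="%.6g",
        index=table.index.name is not None,
    )
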