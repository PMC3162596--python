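"""Readers and writers for the pipeline's table formats.

All tables are tab-separated UTF-8 with a single header line and Unix
newlines; ``NA`` is the missing-value token.  Gene sets are read from GMT
(set name, description, members, tab-separated); ranked lists from the
two-column ``rnk`` dialect (id, score).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ParseError
from .homology import HomologyMap
from .ontology import AnnotationSet

__all__ = [
    "NA_TOKEN",
    "read_counts_table",
    "write_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "parse_gene_sets_gmt",
    "write_gene_sets_gmt",
    "parse_mapping_table",
    "read_rnk",
    "write_rnk",
]

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"
_CSV_KW = dict(sep="\t", na_rep=NA_TOKEN)


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV with columns transcript_id, length_bp, read_count."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("transcript_id", "length_bp", "read_count"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with fixed float formatting (reproducible bytes)."""
    df.to_csv(path, index=index, float_format="%.10g", **_CSV_KW)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a cluster-by-tissue matrix TSV (first column = cluster ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=[NA_TOKEN], keep_default_na=False)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate cluster ids in matrix")
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index=True, float_format="%.10g", **_CSV_KW)


def parse_gene_sets_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into name → member list (order kept, dups removed)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member (got {len(fields)} fields)"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "%s:%d: set %s has duplicate members; kept %d unique",
                    path, lineno, name, len(deduped),
                )
            sets[name] = deduped
    return sets


def write_gene_sets_gmt(sets: Mapping[str, list], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + [str(m) for m in members]) + "\n")


def parse_mapping_table(path: str | Path, kind: str):
    """Parse a two/three-column mapping TSV.

    ``kind="homology"`` → :class:`HomologyMap` (columns source, target
    [, rank]); ``kind="probe"`` → dict probe→cluster (columns probe,
    cluster); ``kind="annotation"`` → list of :class:`AnnotationSet`
    (columns term, namespace, gene).  Malformed rows are rejected with a
    logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str,
                     na_values=[NA_TOKEN, ""], keep_default_na=False)
    if kind == "homology":
        for col in ("source", "target"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing required column {col!r}")
        if "rank" in df.columns:
            df = df.assign(rank=pd.to_numeric(df["rank"], errors="coerce"))
        return HomologyMap.from_table(df)
    if kind == "probe":
        for col in ("probe", "cluster"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing required column {col!r}")
        ok = df.dropna(subset=["probe", "cluster"])
        if len(ok) < len(df):
            logger.warning("%s: rejected %d malformed probe row(s)", path, len(df) - len(ok))
        return dict(zip(ok["probe"], ok["cluster"]))
    if kind == "annotation":
        for col in ("term", "namespace", "gene"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing required column {col!r}")
        ok = df.dropna(subset=["term", "gene"])
        if len(ok) < len(df):
            logger.warning("%s: rejected %d malformed annotation row(s)", path, len(df) - len(ok))
        out = []
        for (term, ns), grp in ok.groupby(["term", "namespace"], sort=True, dropna=False):
            out.append(AnnotationSet(term=term, namespace=ns, genes=frozenset(grp["gene"])))
        return out
    raise ParseError(f"unknown mapping kind {kind!r}")


def read_rnk(path: str | Path) -> pd.Series:
    """Read an id/score two-column ranked-list file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "score"], comment="#")
    out = pd.Series(df["score"].to_numpy(float), index=df["id"].astype(str), name="score")
    out.index.name = None
    return out


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    scores.to_frame().to_csv(path, sep="\t", header=False, float_format="%.10g")
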