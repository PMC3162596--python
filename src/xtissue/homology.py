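"""Transcript-to-cluster collapsing and cross-species homolog projection.

Transcript-level quantifications are collapsed to gene-cluster level
(Unigene-style non-redundant clusters) by taking the maximum RPKM over a
cluster's transcripts; microarray probe signals are collapsed to clusters
the same way.  Gene lists and expression matrices are projected into
another species through a source→targets homolog map, keeping only the
first-listed target per source to avoid family-expansion bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError

__all__ = [
    "HomologyMap",
    "collapse_to_clusters",
    "collapse_probe_signals",
    "project_ids",
    "project_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologyMap:
    """Ordered source→targets homolog mapping for one target species.

    Target lists are non-empty and their order is deterministic: an explicit
    rank wins; otherwise targets are sorted lexicographically (the original
    curation order of a retrieved list is generally unrecoverable).
    """

    mapping: Mapping[str, tuple[str, ...]]
    species: str = "unspecified"

    def __post_init__(self) -> None:
        frozen = {}
        for src, targets in self.mapping.items():
            tt = tuple(targets)
            if not tt:
                raise InputError(f"homolog map entry {src!r} has no targets")
            frozen[src] = tt
        object.__setattr__(self, "mapping", frozen)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, src: str) -> bool:
        return src in self.mapping

    def first(self, src: str) -> str:
        return self.mapping[src][0]

    @classmethod
    def from_table(cls, table: pd.DataFrame, species: str = "unspecified") -> "HomologyMap":
        """Build from a frame with columns ``source``, ``target`` [, ``rank``].

        With a rank column targets follow ascending rank; without one they
        are sorted lexicographically.
        """
        for col in ("source", "target"):
            if col not in table.columns:
                raise InputError(f"homolog table missing column {col!r}")
        tbl = table.dropna(subset=["source", "target"])
        dropped = len(table) - len(tbl)
        if dropped:
            logger.warning("homolog table: dropped %d row(s) with missing fields", dropped)
        mapping: dict[str, list[tuple]] = {}
        if "rank" in tbl.columns:
            key = list(zip(tbl["rank"], tbl["target"]))
        else:
            key = [(0, t) for t in tbl["target"]]
        for src, k, tgt in zip(tbl["source"], key, tbl["target"]):
            mapping.setdefault(str(src), []).append((k, str(tgt)))
        ordered = {
            src: tuple(dict.fromkeys(t for _, t in sorted(pairs)))
            for src, pairs in mapping.items()
        }
        return cls(mapping=ordered, species=species)


def collapse_to_clusters(quants: pd.DataFrame, value_col: str = "rpkm") -> pd.Series:
    """Collapse transcript quantifications to one value per cluster (the max).

    Rows without a ``cluster_id`` are dropped (and counted in the log):
    a transcript with no cluster assignment has no gene-level identity.
    """
    if "cluster_id" not in quants.columns:
        raise InputError("quant table has no cluster_id column")
    if value_col not in quants.columns:
        raise InputError(f"quant table has no {value_col!r} column")
    assigned = quants.dropna(subset=["cluster_id"])
    n_dropped = len(quants) - len(assigned)
    if n_dropped:
        logger.warning("collapse_to_clusters: dropped %d unassigned transcript(s)", n_dropped)
    if assigned.empty:
        return pd.Series(dtype=float, name=value_col)
    out = assigned.groupby("cluster_id", sort=True)[value_col].max()
    out.index.name = "cluster"
    return out


def collapse_probe_signals(
    probe_matrix: pd.DataFrame, probe_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probe-by-tissue signal matrix to cluster-by-tissue maxima.

    Probes absent from *probe_map* are dropped with a logged count.
    """
    mapped = probe_matrix.index.to_series().map(dict(probe_map))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("collapse_probe_signals: dropped %d unmapped probe(s)", n_dropped)
    if not keep.any():
        return pd.DataFrame(columns=probe_matrix.columns)
    sub = probe_matrix.loc[keep]
    out = sub.groupby(mapped[keep].to_numpy(), sort=True).max()
    out.index.name = "cluster"
    return out


def project_ids(ids: Iterable[str], hmap: HomologyMap) -> list[str]:
    """Project source gene ids to the target species.

    Each source with at least one homolog contributes its first-listed
    target; unmapped sources are dropped; duplicate targets are removed
    keeping the first occurrence, so input order is preserved.
    """
    if len(hmap) == 0:
        logger.warning("project_ids: empty homolog map; result is empty")
        return []
    out = []
    n_unmapped = 0
    for src in ids:
        if src in hmap:
            out.append(hmap.first(src))
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.info("project_ids: %d source id(s) had no homolog", n_unmapped)
    return list(dict.fromkeys(out))


def project_matrix(matrix: pd.DataFrame, hmap: HomologyMap) -> pd.DataFrame:
    """Project an expression matrix to target-species cluster ids.

    Row ids are replaced by each source's first-listed homolog; when several
    sources land on one target the per-tissue maximum is kept, consistent
    with the max-representative collapsing convention.
    """
    if len(hmap) == 0:
        logger.warning("project_matrix: empty homolog map; result is empty")
        return pd.DataFrame(columns=matrix.columns)
    targets = matrix.index.to_series().map(
        lambda s: hmap.first(s) if s in hmap else None
    )
    keep = targets.notna()
    sub = matrix.loc[keep]
    if sub.empty:
        return pd.DataFrame(columns=matrix.columns)
    out = sub.groupby(targets[keep].to_numpy(), sort=True).max()
    out.index.name = "cluster"
    return out
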