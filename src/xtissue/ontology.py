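"""Ontology-slim classification, term over-representation, energy distribution.

Over-representation of an annotation term in a gene list is scored with the
one-sided hypergeometric tail: for a list of n genes drawn from a background
of N genes of which K carry the term, and k term carriers observed in the
list, p = P(X >= k) with X ~ Hypergeometric(N, K, n).  The EASE variant
("modified Fisher's exact") removes one observed hit before computing the
same tail — p = P(X >= k - 1) — which penalises terms supported by very few
genes.  Benjamini–Hochberg false-discovery-rate correction is applied over
all tested terms.

The *energy distribution* of a tissue contrasts two shares per functional
category: the share of distinct expressed genes (diversity) and the share
of summed abundance (transcriptional energy).  Genes annotated to several
categories contribute fully to each; genes without annotation form an
"unclassified" bucket reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "AnnotationSet",
    "UNKNOWN_CATEGORY",
    "UNCLASSIFIED",
    "hypergeom_pvalue",
    "ease_pvalue",
    "classify_slim",
    "term_enrichment",
    "energy_distribution",
]

logger = logging.getLogger(__name__)

NAMESPACES = ("Biological Process", "Molecular Function", "Cellular Component", "pathway")
UNKNOWN_CATEGORY = "unknown function"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class AnnotationSet:
    """A named annotation term and the genes it annotates."""

    term: str
    namespace: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))


def hypergeom_pvalue(k, n, K, N):
    """Upper-tail hypergeometric p: P(X >= k), X ~ Hypergeom(N, K, n).

    Accepts scalars or equal-length arrays (returns an ndarray for arrays).
    """
    k, n, K, N, scalar = _check_table(k, n, K, N)
    out = stats.hypergeom.sf(k - 1, N, K, n)
    return float(out) if scalar else out


def ease_pvalue(k, n, K, N):
    """EASE score: hypergeometric tail with one observed hit removed, P(X >= k-1)."""
    k, n, K, N, scalar = _check_table(k, n, K, N)
    out = stats.hypergeom.sf(np.maximum(k - 1, 0) - 1, N, K, n)
    return float(out) if scalar else out


def _check_table(k, n, K, N):
    scalar = np.isscalar(k) and np.isscalar(n) and np.isscalar(K) and np.isscalar(N)
    k, n, K, N = (np.asarray(v, dtype=np.int64) for v in (k, n, K, N))
    if np.any(N < 1):
        raise InputError("background size N must be >= 1")
    if np.any(K < 0) or np.any(K > N) or np.any(n < 0) or np.any(n > N):
        raise InputError("need 0 <= K <= N and 0 <= n <= N")
    if np.any(k < 0) or np.any(k > np.minimum(n, K)):
        raise InputError("observed hits k outside [0, min(n, K)]")
    return k, n, K, N, scalar


def classify_slim(
    genes: Iterable, annotations: Sequence[AnnotationSet]
) -> pd.DataFrame:
    """Tally genes into slim categories per namespace.

    A gene contributes one count to every category annotating it; genes with
    no annotation in a namespace are tallied under ``"unknown function"`` for
    that namespace.  Returns a tidy frame with columns ``namespace``,
    ``category``, ``count``.
    """
    gene_list = list(dict.fromkeys(genes))
    gene_set = set(gene_list)
    rows = []
    namespaces = sorted({a.namespace for a in annotations}) or list(NAMESPACES[:3])
    for ns in namespaces:
        annotated: set = set()
        for ann in annotations:
            if ann.namespace != ns:
                continue
            k = len(ann.genes & gene_set)
            annotated |= ann.genes & gene_set
            rows.append({"namespace": ns, "category": ann.term, "count": k})
        rows.append(
            {
                "namespace": ns,
                "category": UNKNOWN_CATEGORY,
                "count": len(gene_set - annotated),
            }
        )
    return pd.DataFrame(rows, columns=["namespace", "category", "count"])


def term_enrichment(
    list_ids: Iterable,
    background_ids: Iterable,
    annotations: Sequence[AnnotationSet],
    method: str = "hypergeometric",
) -> pd.DataFrame:
    """Score every annotation term for over-representation in a gene list.

    Parameters
    ----------
    list_ids, background_ids
        The selected gene list and the universe it was drawn from; the list
        must be a subset of the background.
    method
        ``"hypergeometric"`` or ``"ease"``.

    Returns a frame with columns term, namespace, k, n, K, N, fold, p, q
    sorted by ascending p; q is the Benjamini–Hochberg FDR over the tested
    terms.  Terms with no background carrier are skipped.
    """
    if method not in ("hypergeometric", "ease"):
        raise InputError(f"unknown method {method!r}")
    lst = set(list_ids)
    bg = set(background_ids)
    if not bg:
        raise InputError("background is empty")
    if not lst <= bg:
        raise InputError(
            f"{len(lst - bg)} list gene(s) absent from the background"
        )
    N, n = len(bg), len(lst)
    pfun = hypergeom_pvalue if method == "hypergeometric" else ease_pvalue
    rows = []
    for ann in annotations:
        K = len(ann.genes & bg)
        if K == 0:
            continue
        k = len(ann.genes & lst)
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append(
            {
                "term": ann.term,
                "namespace": ann.namespace,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold,
                "p": pfun(k, n, K, N),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "namespace", "k", "n", "K", "N", "fold", "p"]
    )
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return table


def energy_distribution(
    expression: pd.Series,
    annotations: Sequence[AnnotationSet],
    namespace: str | None = None,
) -> pd.DataFrame:
    """Gene-count share vs. abundance (energy) share per functional category.

    *expression* maps gene id to abundance (e.g. RPKM).  Multi-category genes
    contribute fully to each of their categories; unannotated genes are
    reported in an ``"unclassified"`` row.  Both share columns sum to 1.
    """
    if (expression < 0).any():
        raise InputError("expression values must be non-negative")
    if float(expression.sum()) == 0.0:
        raise InputError("all expression values are zero")
    anns = [a for a in annotations if namespace is None or a.namespace == namespace]
    genes = set(expression.index)
    rows = []
    classified: set = set()
    for ann in anns:
        members = ann.genes & genes
        classified |= members
        rows.append(
            {
                "category": ann.term,
                "gene_count": len(members),
                "rpkm_sum": float(expression.loc[sorted(members)].sum()),
            }
        )
    rest = genes - classified
    rows.append(
        {
            "category": UNCLASSIFIED,
            "gene_count": len(rest),
            "rpkm_sum": float(expression.loc[sorted(rest)].sum()),
        }
    )
    out = pd.DataFrame(rows)
    total_genes = out["gene_count"].sum()
    total_rpkm = out["rpkm_sum"].sum()
    out["gene_count_share"] = out["gene_count"] / total_genes if total_genes else 0.0
    out["rpkm_sum_share"] = out["rpkm_sum"] / total_rpkm if total_rpkm else 0.0
    return out
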