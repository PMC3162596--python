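"""Preranked running-sum gene-set enrichment with permutation NES/FDR.

Given a gene list ranked by a score, the enrichment of a gene set is the
maximal deviation from zero of a running sum walked down the list: at a
set member ("hit") the sum increases by |score|^w / NR (NR normalising the
hit weights to 1), at a non-member it decreases by 1/(L - H) for L ranked
genes and H hits.  With weight exponent w = 0 this is the classic
Kolmogorov–Smirnov statistic; w = 1 (the default) weights hits by their
scores.  The enrichment score ES lies in [-1, 1].

Significance is assessed against a gene-label permutation null: set
membership is reassigned uniformly at random among the ranked genes,
preserving set size.  The nominal p is the add-one-smoothed exceedance
fraction among same-sign null scores; NES divides ES by the mean |null ES|
of the same sign; the FDR q for a set compares the pooled normalized null
distribution with the observed NES distribution in the standard
positive/negative-tail fashion.

The *leading edge* of a positively enriched set comprises the members at
or before the running-sum maximum; for negative enrichment, at or after
the minimum.

`cross_species_matrix` scores one species' tissue-enriched gene sets
(projected into the other species' id space) against ranked lists built
from each target tissue of the other species, yielding the query-by-target
NES/FDR tissue-relatedness grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "RankedList",
    "GseaResult",
    "NESMatrix",
    "rank_by_neglog_p",
    "rank_by_specificity",
    "enrichment_score",
    "gsea_preranked",
    "cross_species_matrix",
]

logger = logging.getLogger(__name__)

#: Score increment placing exclusively-detected genes above every finite score.
EXCLUSIVE_SCORE_INCREMENT = 1.0


@dataclass(frozen=True)
class RankedList:
    """Gene ids with scores, sorted descending; ties broken by id."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise InputError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("ranked list contains duplicate ids")
        if not all(np.isfinite(self.scores)):
            raise InputError("ranked list scores must be finite")
        order = sorted(range(len(self.ids)), key=lambda i: (-self.scores[i], self.ids[i]))
        object.__setattr__(self, "ids", tuple(self.ids[i] for i in order))
        object.__setattr__(self, "scores", tuple(float(self.scores[i]) for i in order))

    def __len__(self) -> int:
        return len(self.ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.ids), name="score")


@dataclass(frozen=True)
class GseaResult:
    """Enrichment of one gene set against one ranked list."""

    gene_set: str
    size: int  # intersection size with the ranked list
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: frozenset
    running_sum: tuple[float, ...] = field(repr=False)


@dataclass(frozen=True)
class NESMatrix:
    """Query-tissue × target-tissue relatedness grid (the comparison figure)."""

    nes: pd.DataFrame
    fdr: pd.DataFrame
    nominal_p: pd.DataFrame

    def significance(self, strong: float = 0.001, weak: float = 0.05) -> pd.DataFrame:
        """Annotation marks per cell: '**' below *strong*, '*' below *weak*."""
        p = self.nominal_p
        return p.map(lambda v: "**" if v < strong else ("*" if v < weak else ""))


def rank_by_neglog_p(tests: Sequence) -> RankedList:
    """Rank genes by -log10(p) of their enrichment tests, best first.

    Exclusive genes (p unavailable because the gene was detected in the
    target tissue only) outrank everything: they receive the maximum finite
    score plus a fixed increment.  Degenerate tests (zero spread, p
    undefined) are dropped.
    """
    tests = [t for t in tests if t.p is not None or t.exclusive]
    if not tests:
        raise InputError("no usable enrichment tests to rank")
    finite = [-np.log10(t.p) for t in tests if t.p is not None and t.p > 0]
    top = (max(finite) if finite else 0.0) + EXCLUSIVE_SCORE_INCREMENT
    ids, scores = [], []
    for t in tests:
        ids.append(t.cluster)
        if t.exclusive or t.p is None or t.p <= 0:
            scores.append(top)
        else:
            scores.append(float(-np.log10(t.p)))
    return RankedList(ids=tuple(ids), scores=tuple(scores))


def rank_by_specificity(
    matrix: pd.DataFrame, target: str, pseudocount: float = 1.0
) -> RankedList:
    """Rank genes by tissue specificity: log2((target + eps) / (mean others + eps)).

    The pseudocount eps damps ratios of barely-expressed genes.
    """
    if target not in matrix.columns:
        raise InputError(f"target tissue {target!r} is not a matrix column")
    others = [c for c in matrix.columns if c != target]
    if not others:
        raise InputError("need at least 2 tissues to rank by specificity")
    if (matrix.to_numpy() < 0).any():
        raise InputError("expression matrix contains negative values")
    x = matrix[target].to_numpy(float)
    m = matrix[others].to_numpy(float).mean(axis=1)
    scores = np.log2((x + pseudocount) / (m + pseudocount))
    return RankedList(
        ids=tuple(str(i) for i in matrix.index), scores=tuple(float(s) for s in scores)
    )


def enrichment_score(
    ranked: RankedList, gene_set: Iterable, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, frozenset]:
    """Running-sum enrichment of *gene_set* in *ranked*.

    Returns ``(ES, running_sum, leading_edge)``.  A tie between equal
    positive and negative extrema resolves to the negative one.
    """
    gset = set(gene_set)
    ids = np.asarray(ranked.ids)
    scores = np.asarray(ranked.scores, float)
    hits = np.fromiter((g in gset for g in ids), bool, len(ids))
    L, H = len(ids), int(hits.sum())
    if H == 0:
        raise InputError("gene set has empty intersection with the ranked list")
    w = np.abs(scores[hits]) ** weight_exponent
    nr = w.sum()
    steps = np.empty(L)
    steps[hits] = w / nr if nr > 0 else 1.0 / H
    steps[~hits] = -1.0 / (L - H) if L > H else 0.0
    rs = np.cumsum(steps)
    pos, neg = float(rs.max()), float(rs.min())
    if abs(neg) >= pos:
        es = neg
        idx = int(np.argmin(rs))
        leading = ids[idx:][hits[idx:]]
    else:
        es = pos
        idx = int(np.argmax(rs))
        leading = ids[: idx + 1][hits[: idx + 1]]
    return es, rs, frozenset(leading)


def _null_es(
    abs_w: np.ndarray, H: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-label-permutation null ES values, vectorized over permutations.

    *abs_w* holds |score|^w for every ranked position.  For each permutation
    H hit positions are drawn uniformly without replacement; the running-sum
    extrema are evaluated only at hit peaks and the valleys preceding them
    (the sum is monotone decreasing between hits, and ends at zero).
    """
    L = abs_w.size
    pos = np.argsort(rng.random((n_perm, L)), axis=1)[:, :H]
    pos.sort(axis=1)
    w = abs_w[pos]
    nr = w.sum(axis=1, keepdims=True)
    degenerate = nr[:, 0] == 0
    if degenerate.any():  # all-zero weights: fall back to equal weighting
        w[degenerate] = 1.0
        nr = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) / nr
    miss = 1.0 / (L - H) if L > H else 0.0
    drift = (pos - np.arange(H)) * miss
    peaks = cw - drift  # value just after each hit
    valleys = peaks - w / nr  # value just before each hit
    pos_es = peaks.max(axis=1)
    neg_es = np.minimum(valleys.min(axis=1), 0.0)
    return np.where(np.abs(neg_es) >= pos_es, neg_es, pos_es)


def gsea_preranked(
    ranked: RankedList,
    gene_sets: Mapping[str, Iterable],
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int | None = None,
) -> list[GseaResult]:
    """Score each gene set against *ranked* with a permutation null.

    Sets are filtered to those whose intersection with the ranked list has
    at least *min_size* (and at most *max_size*, if given) members.  Null
    scores come from uniform reassignment of set membership among ranked
    genes; results are reproducible for a fixed *seed*.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ids = set(ranked.ids)
    surviving: dict[str, set] = {}
    for name, members in gene_sets.items():
        inter = set(members) & ids
        if len(inter) >= min_size and (max_size is None or len(inter) <= max_size):
            surviving[name] = inter
    if not surviving:
        raise InputError("no gene set survives the size filter")

    abs_w = np.abs(np.asarray(ranked.scores)) ** weight_exponent
    null_cache: dict[int, np.ndarray] = {}
    observed = {}
    for name, inter in surviving.items():
        es, rs, leading = enrichment_score(ranked, inter, weight_exponent)
        H = len(inter)
        if H not in null_cache:
            null_cache[H] = _null_es(abs_w, H, n_perm, rng)
        observed[name] = (es, rs, leading, null_cache[H])

    # Per-set NES and nominal p against same-sign nulls.
    nes_of, p_of = {}, {}
    pooled_pos, pooled_neg = [], []
    for name, (es, rs, leading, null) in observed.items():
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        if pos_null.size:
            pooled_pos.append(pos_null / mean_pos)
        if neg_null.size:
            pooled_neg.append(neg_null / mean_neg)
        if es >= 0:
            b = int((pos_null >= es).sum())
            p_of[name] = (b + 1) / (pos_null.size + 1)
            nes_of[name] = es / mean_pos if np.isfinite(mean_pos) else np.nan
        else:
            b = int((neg_null <= es).sum())
            p_of[name] = (b + 1) / (neg_null.size + 1)
            nes_of[name] = es / mean_neg if np.isfinite(mean_neg) else np.nan

    pooled_pos = np.concatenate(pooled_pos) if pooled_pos else np.empty(0)
    pooled_neg = np.concatenate(pooled_neg) if pooled_neg else np.empty(0)
    obs_nes = np.array([nes_of[n] for n in observed])

    results = []
    for name, (es, rs, leading, _) in observed.items():
        nes = nes_of[name]
        if not np.isfinite(nes):
            q = np.nan
        elif nes >= 0:
            num = (pooled_pos >= nes).mean() if pooled_pos.size else 1.0
            den = (obs_nes[np.isfinite(obs_nes)] >= nes).mean()
            q = min(num / den, 1.0) if den > 0 else 1.0
        else:
            num = (pooled_neg <= nes).mean() if pooled_neg.size else 1.0
            den = (obs_nes[np.isfinite(obs_nes)] <= nes).mean()
            q = min(num / den, 1.0) if den > 0 else 1.0
        results.append(
            GseaResult(
                gene_set=name,
                size=len(surviving[name]),
                es=float(es),
                nes=float(nes),
                nominal_p=float(p_of[name]),
                fdr_q=float(q),
                leading_edge=leading,
                running_sum=tuple(float(v) for v in rs),
            )
        )
    return results


def cross_species_matrix(
    enriched: Mapping[str, Iterable],
    targets: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    pseudocount: float = 1.0,
) -> NESMatrix:
    """Tissue-relatedness grid: query gene sets vs. target-tissue ranked lists.

    *enriched* maps each query tissue to its enriched gene set, already
    projected into the target species' id space; *targets* is the target
    species' cluster-by-tissue matrix.  For every target tissue a
    specificity-ranked list is built and every query set scored against it;
    each cell carries (NES, FDR q, nominal p).  Cells whose query set does
    not intersect the ranked list sufficiently are left NaN and the run
    continues.
    """
    queries = list(enriched)
    cols = list(targets.columns)
    nes = pd.DataFrame(np.nan, index=queries, columns=cols)
    fdr = pd.DataFrame(np.nan, index=queries, columns=cols)
    nom = pd.DataFrame(np.nan, index=queries, columns=cols)
    seeds = np.random.SeedSequence(seed).spawn(len(cols))
    for col_seed, tissue in zip(seeds, cols):
        ranked = rank_by_specificity(targets, tissue, pseudocount)
        usable = {
            q: set(s) & set(ranked.ids)
            for q, s in enriched.items()
            if len(set(s) & set(ranked.ids)) >= min_size
        }
        skipped = set(queries) - set(usable)
        if skipped:
            logger.warning(
                "target %s: query set(s) not assessable: %s", tissue, sorted(skipped)
            )
        if not usable:
            continue
        for res in gsea_preranked(
            ranked,
            usable,
            n_perm=n_perm,
            seed=col_seed,
            weight_exponent=weight_exponent,
            min_size=min_size,
        ):
            nes.loc[res.gene_set, tissue] = res.nes
            fdr.loc[res.gene_set, tissue] = res.fdr_q
            nom.loc[res.gene_set, tissue] = res.nominal_p
    return NESMatrix(nes=nes, fdr=fdr, nominal_p=nom)
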