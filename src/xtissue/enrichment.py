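"""Tissue-enrichment selection by a one-sample t statistic.

A gene is tested for enrichment in a target tissue by comparing its single
target-tissue abundance x against its values in n comparison tissues
(n = 3 in the original four-tissue design):

    t = (x - mu) / (s / sqrt(n))

where mu and s are the mean and sample standard deviation (n-1 denominator)
of the comparison values, and p is the upper tail of Student's t with
n - 1 degrees of freedom.  The p-value is one-sided: enrichment, not
depletion, is of interest, and the conventional alpha of 0.025 is the
one-sided twin of a two-sided 0.05.

Genes detected in the target tissue only (all comparison values zero) have
an undefined p and are flagged *exclusive*; by default they are admitted to
the enriched list, since exclusivity is the strongest form of enrichment.

Note this statistic treats a single observed value as a sample mean; with
one pooled library per tissue no replicate variance exists, so the stated
degrees of freedom understate the true null spread.  Selection is therefore
anticonservative; see the package methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "EnrichmentTest",
    "EnrichedGeneList",
    "enrichment_t_test",
    "enrichment_tests",
    "select_enriched",
]


@dataclass(frozen=True)
class EnrichmentTest:
    """One gene's enrichment test in one target tissue."""

    cluster: str | None
    x_bar: float
    comparisons: tuple[float, ...]
    mu: float
    s: float
    n: int
    t: float | None
    p: float | None
    exclusive: bool
    degenerate: bool = False  # s == 0 with nonzero comparisons: p undefined


@dataclass(frozen=True)
class EnrichedGeneList:
    """Genes passing the enrichment t-test and abundance thresholds."""

    tissue: str
    alpha: float
    rpkm_min: float
    records: pd.DataFrame  # columns: cluster, rpkm, t, p, exclusive


def enrichment_t_test(
    x_bar: float, comparisons: Sequence[float], cluster: str | None = None
) -> EnrichmentTest:
    """Test one gene's target-tissue value against its comparison-tissue values.

    Returns an :class:`EnrichmentTest`; ``p`` is the upper-tail Student-t
    probability with ``len(comparisons) - 1`` degrees of freedom, or ``None``
    when undefined (all comparisons zero → ``exclusive``; zero spread with
    nonzero comparisons → ``degenerate``).
    """
    comp = tuple(float(c) for c in comparisons)
    n = len(comp)
    if n < 2:
        raise InputError(f"need at least 2 comparison values, got {n}")
    if any(c < 0 for c in comp) or x_bar < 0:
        raise InputError("abundance values must be non-negative")
    mu = float(np.mean(comp))
    s = float(np.std(comp, ddof=1))
    if all(c == 0 for c in comp):
        return EnrichmentTest(cluster, x_bar, comp, mu, s, n, None, None, exclusive=True)
    if s == 0.0:
        return EnrichmentTest(
            cluster, x_bar, comp, mu, s, n, None, None, exclusive=False, degenerate=True
        )
    t = (x_bar - mu) / (s / math.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return EnrichmentTest(cluster, x_bar, comp, mu, s, n, t, p, exclusive=False)


def enrichment_tests(matrix: pd.DataFrame, target: str) -> list[EnrichmentTest]:
    """Run :func:`enrichment_t_test` for every row of a cluster-by-tissue matrix."""
    if target not in matrix.columns:
        raise InputError(f"target tissue {target!r} is not a matrix column")
    others = [c for c in matrix.columns if c != target]
    if len(others) < 2:
        raise InputError("need at least 2 comparison tissues")
    return [
        enrichment_t_test(row[target], [row[c] for c in others], cluster=str(idx))
        for idx, row in matrix.iterrows()
    ]


def select_enriched(
    matrix: pd.DataFrame,
    target: str,
    alpha: float = 0.025,
    rpkm_min: float = 10.0,
    include_exclusive: bool = True,
) -> EnrichedGeneList:
    """Select genes enriched in *target* from a cluster-by-tissue matrix.

    Membership requires all of

    * ``p < alpha`` (or *exclusive*, if ``include_exclusive``),
    * target abundance strictly greater than ``rpkm_min``,
    * target abundance strictly greater than the gene's mean abundance over
      all compared tissues (target included).

    Output rows are ordered by descending target abundance.
    """
    if target not in matrix.columns:
        raise InputError(f"target tissue {target!r} is not a matrix column")
    others = [c for c in matrix.columns if c != target]
    if len(others) < 2:
        raise InputError("need at least 2 comparison tissues")
    if (matrix.to_numpy() < 0).any():
        raise InputError("expression matrix contains negative values")

    x = matrix[target].to_numpy(float)
    comp = matrix[others].to_numpy(float)
    n = comp.shape[1]
    mu = comp.mean(axis=1)
    s = comp.std(axis=1, ddof=1)
    exclusive = (comp == 0).all(axis=1)
    valid = (s > 0) & ~exclusive
    t = np.full(len(x), np.nan)
    p = np.full(len(x), np.nan)
    t[valid] = (x[valid] - mu[valid]) / (s[valid] / math.sqrt(n))
    p[valid] = stats.t.sf(t[valid], df=n - 1)

    passes_p = np.where(valid, p < alpha, False)
    if include_exclusive:
        passes_p |= exclusive
    member = passes_p & (x > rpkm_min) & (x > matrix.mean(axis=1).to_numpy(float))

    records = pd.DataFrame(
        {
            "cluster": matrix.index.to_numpy()[member],
            "rpkm": x[member],
            "t": t[member],
            "p": p[member],
            "exclusive": exclusive[member],
        }
    )
    records = records.sort_values(
        ["rpkm", "cluster"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return EnrichedGeneList(tissue=target, alpha=alpha, rpkm_min=rpkm_min, records=records)
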