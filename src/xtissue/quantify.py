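"""Read-count quantification: RPKM, expression cutoff, abundance profiles.

RPKM (reads per kilobase of transcript per million mapped reads) for a
transcript with ``C`` mapped reads, length ``L`` bases, in a library of
``N`` mapped reads is ``10^9 * C / (N * L)``.  A transcript is *detected*
when it has at least one mapped read; the physiological expression cutoff
used downstream retains transcripts with RPKM strictly greater than 10
(roughly three transcript copies per cell in a typical tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "TranscriptQuant",
    "AbundanceProfile",
    "ExpressionSummary",
    "compute_rpkm",
    "quantify_counts",
    "apply_expression_cutoff",
    "abundance_profile",
    "expression_summary",
    "detected_fraction",
]

#: Columns required of a counts table.
COUNT_COLUMNS = ("transcript_id", "length_bp", "read_count")


@dataclass(frozen=True)
class TranscriptQuant:
    """Quantification record for one transcript."""

    transcript_id: str
    length_bp: int
    read_count: int
    rpkm: float
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise InputError(f"length_bp must be >= 1, got {self.length_bp}")
        if self.read_count < 0:
            raise InputError(f"read_count must be >= 0, got {self.read_count}")


@dataclass(frozen=True)
class AbundanceProfile:
    """Transcript tally and count share per abundance category.

    Categories are defined by ascending lower limits on the read count; a
    transcript belongs to the highest category whose lower limit does not
    exceed its count.  The top category is unbounded above.
    """

    bin_lower_limits: tuple[int, ...]
    entries_per_bin: tuple[int, ...]
    count_share_per_bin: tuple[float, ...]


@dataclass(frozen=True)
class ExpressionSummary:
    n_detected: int
    min_rpkm: float
    max_rpkm: float
    log10_dynamic_range: float


def compute_rpkm(read_count: int, length_bp: int, total_mapped: int) -> float:
    """RPKM of one transcript: ``1e9 * read_count / (total_mapped * length_bp)``."""
    if length_bp < 1:
        raise InputError(f"length_bp must be >= 1, got {length_bp}")
    if total_mapped < 1:
        raise InputError(f"total_mapped must be >= 1, got {total_mapped}")
    if read_count < 0:
        raise InputError(f"read_count must be >= 0, got {read_count}")
    return 1e9 * read_count / (total_mapped * length_bp)


def quantify_counts(counts: pd.DataFrame, total_mapped: int | str = "auto") -> pd.DataFrame:
    """Add an ``rpkm`` column to a counts table.

    Parameters
    ----------
    counts
        Table with columns ``transcript_id``, ``length_bp``, ``read_count``
        (``cluster_id`` optional, carried through).
    total_mapped
        Library size; ``"auto"`` uses the column sum of ``read_count``.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise InputError(f"counts table missing column(s): {', '.join(missing)}")
    if (counts["length_bp"] < 1).any():
        raise InputError("counts table contains length_bp < 1")
    if (counts["read_count"] < 0).any():
        raise InputError("counts table contains negative read_count")
    if total_mapped == "auto":
        total = int(counts["read_count"].sum())
    else:
        total = int(total_mapped)
    if total < 1:
        raise InputError(f"total_mapped must be >= 1, got {total}")
    out = counts.copy()
    out["rpkm"] = 1e9 * out["read_count"].to_numpy(float) / (
        total * out["length_bp"].to_numpy(float)
    )
    return out


def apply_expression_cutoff(quants: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Retain rows with ``rpkm`` strictly greater than *threshold*, preserving order."""
    if "rpkm" not in quants.columns:
        raise InputError("quant table has no rpkm column; run quantify_counts first")
    return quants.loc[quants["rpkm"] > threshold]


def abundance_profile(
    quants: pd.DataFrame, bin_lower_limits: Sequence[int]
) -> AbundanceProfile:
    """Tally transcripts and count shares into abundance categories.

    Each transcript is assigned to the highest bin whose lower limit is at
    most its read count; shares are the bin's summed counts over the grand
    total, so they sum to one.
    """
    if len(quants) == 0:
        raise InputError("abundance_profile requires a nonempty quant table")
    limits = np.asarray(list(bin_lower_limits))
    if limits.size == 0:
        raise InputError("at least one bin lower limit is required")
    if np.any(np.diff(limits) <= 0):
        raise InputError("bin lower limits must be strictly ascending")
    counts = quants["read_count"].to_numpy()
    if counts.min() < limits[0]:
        raise InputError(
            f"read_count {counts.min()} below the first bin lower limit {limits[0]}"
        )
    idx = np.searchsorted(limits, counts, side="right") - 1
    n_bins = limits.size
    entries = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=counts, minlength=n_bins)
    shares = sums / counts.sum()
    return AbundanceProfile(
        bin_lower_limits=tuple(int(x) for x in limits),
        entries_per_bin=tuple(int(x) for x in entries),
        count_share_per_bin=tuple(float(x) for x in shares),
    )


def expression_summary(quants: pd.DataFrame) -> ExpressionSummary:
    """Detected-transcript count, RPKM range, and log10 dynamic range.

    Detected means at least one mapped read.
    """
    detected = quants.loc[quants["read_count"] > 0, "rpkm"]
    if detected.empty:
        raise InputError("no detected transcript (all read counts are zero)")
    lo, hi = float(detected.min()), float(detected.max())
    return ExpressionSummary(
        n_detected=int((quants["read_count"] > 0).sum()),
        min_rpkm=lo,
        max_rpkm=hi,
        log10_dynamic_range=math.log10(hi / lo) if lo > 0 else math.inf,
    )


def detected_fraction(n_detected: int, n_database: int) -> float:
    """Percentage of database entries detected: ``100 * n_detected / n_database``."""
    if n_database < 1:
        raise InputError("n_database must be >= 1")
    if not 0 <= n_detected <= n_database:
        raise InputError("n_detected must lie in [0, n_database]")
    return 100.0 * n_detected / n_database
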