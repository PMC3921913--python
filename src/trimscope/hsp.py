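"""The HSP ratio: completeness of protein recovery by assembled transfrags.

For each high-scoring segment pair between a transfrag and an annotated
protein, the HSP ratio is the protein span the HSP covers divided by the
full protein length — 1.0 means full-length recovery, small values mean a
truncated reconstruction. Per-category summaries (n, median, mean, sample
SD) are the quantities compared across read treatments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import HspRecord

DEFAULT_MAX_EVALUE = 1e-10


@dataclass(frozen=True)
class RatioSummary:
    n: int
    median: float
    mean: float
    sd: float


def filter_by_evalue(
    records: Iterable[HspRecord], max_evalue: float = DEFAULT_MAX_EVALUE
) -> list[HspRecord]:
    """Retain HSPs with E-value <= the cutoff (inclusive)."""
    return [r for r in records if r.evalue <= max_evalue]


def hsp_ratio(record: HspRecord, subject_span: bool = True) -> float:
    """Fraction of the protein the HSP recovers, capped at 1.0.

    With ``subject_span`` (default) the numerator is the HSP's span on the
    protein, so the ratio reads directly as fraction of the protein
    recovered; otherwise the alignment column count is used.
    """
    if subject_span:
        length = record.subject_end - record.subject_start + 1
    else:
        length = record.aln_length
    if length <= 0:
        raise ValueError(f"{record.query_id}: non-positive HSP span")
    return min(1.0, length / record.subject_length)


def best_hsp_per_pair(records: Iterable[HspRecord]) -> list[HspRecord]:
    """One HSP per (query, subject) pair: maximal bitscore, ties broken by
    larger subject span then first encountered. Keeps first-seen pair order."""
    best: dict[tuple[str, str], HspRecord] = {}
    order: list[tuple[str, str]] = []
    for r in records:
        key = (r.query_id, r.subject_id)
        cur = best.get(key)
        if cur is None:
            best[key] = r
            order.append(key)
            continue
        span_new = r.subject_end - r.subject_start
        span_cur = cur.subject_end - cur.subject_start
        if (r.bitscore, span_new) > (cur.bitscore, span_cur):
            best[key] = r
    return [best[k] for k in order]


def unique_hsp_count(records: Iterable[HspRecord]) -> int:
    """Number of distinct (query, subject, subject span, query span) HSPs."""
    return len(
        {
            (r.query_id, r.subject_id, r.subject_start, r.subject_end,
             r.qstart, r.qend)
            for r in records
        }
    )


def ratios(records: Iterable[HspRecord], subject_span: bool = True) -> np.ndarray:
    return np.array([hsp_ratio(r, subject_span) for r in records], dtype=float)


def summarize_ratios(
    records: Sequence[HspRecord], subject_span: bool = True
) -> RatioSummary:
    """Median / mean / sample SD of HSP ratios (apply E-value filtering and
    best-per-pair selection upstream). SD uses the n-1 denominator and is
    reported as 0.0 for a single ratio."""
    vals = ratios(records, subject_span)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty HSP set")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RatioSummary(
        n=int(vals.size),
        median=float(np.median(vals)),
        mean=float(np.mean(vals)),
        sd=sd,
    )
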