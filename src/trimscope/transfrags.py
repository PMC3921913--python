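"""Transfrag hygiene and summary statistics: exact deduplication,
minimum-length filtering, counts and N50."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

DEFAULT_MIN_TF_LENGTH = 100


@dataclass(frozen=True)
class Transfrag:
    """An assembled transcribed fragment."""

    id: str
    sequence: str
    category: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"transfrag {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblySummary:
    unique_count: int
    n50: int
    total_bases: int


def deduplicate_exact(
    transfrags: Iterable[Transfrag], reverse_complement: bool = False
) -> list[Transfrag]:
    """One representative per distinct sequence (case-insensitive exact
    match), keeping the first encountered. By default a transfrag and its
    reverse complement are *not* merged; ``reverse_complement=True`` also
    collapses those.
    """
    seen: set[str] = set()
    out: list[Transfrag] = []
    comp = str.maketrans("ACGTN", "TGCAN")
    for tf in transfrags:
        key = tf.sequence.upper()
        if reverse_complement:
            rc = key.translate(comp)[::-1]
            key = min(key, rc)
        if key not in seen:
            seen.add(key)
            out.append(tf)
    return out


def length_filter(
    transfrags: Iterable[Transfrag], min_len: int = DEFAULT_MIN_TF_LENGTH
) -> list[Transfrag]:
    """Retain transfrags of length >= ``min_len`` (inclusive)."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    return [tf for tf in transfrags if len(tf) >= min_len]


def n50(lengths: Sequence[int]) -> int:
    """Standard N50: the length at which the descending cumulative sum
    first reaches half of the total."""
    if not len(lengths):
        raise ValueError("N50 of an empty length set is undefined")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    raise AssertionError("unreachable")


def assembly_summary(
    transfrags: Iterable[Transfrag], min_len: int = DEFAULT_MIN_TF_LENGTH
) -> AssemblySummary:
    """Unique-transfrag count, N50 and total bases, computed after exact
    deduplication then length filtering (in that order)."""
    kept = length_filter(deduplicate_exact(transfrags), min_len)
    if not kept:
        return AssemblySummary(0, 0, 0)
    lengths = [len(tf) for tf in kept]
    return AssemblySummary(len(kept), n50(lengths), sum(lengths))
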