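"""The seven read treatments: untrimmed plus six trimming/filtering categories.

Category definitions (paired-end Illumina reads):

========= ==================================================================
untrimmed identity (the comparison baseline)
one       3' quality trim at Q20, minimum length 36 bp
two       3' quality trim at Q10, minimum length 36 bp
three     adapter removal, then 3' quality trim at Q20, minimum length 36 bp
four      adapter removal, then 3' quality trim at Q10, minimum length 36 bp
five      adapter removal only, minimum length 36 bp
six       discard a read when more than 80% of its bases are below Q10
========= ==================================================================

Quality trimming removes bases strictly below the threshold from the 3' end
only, stopping at the first 3'-terminal base at or above it; internal
low-quality bases are retained. The 5' end is never touched, reads are never
reordered, and sequence/quality strings stay equal-length throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .io import Read

DEFAULT_MIN_LENGTH = 36
DEFAULT_ADAPTER_MIN_OVERLAP = 3
DEFAULT_ADAPTER_MAX_ERROR_RATE = 0.1


@dataclass(frozen=True)
class CategorySpec:
    """Parameters of one read treatment.

    ``adapter_removal`` is one of ``none`` (no adapter step),
    ``before_trim`` (adapter removal precedes quality trimming) or ``only``
    (adapter removal is the whole treatment). ``fraction_filter`` is a
    ``(bad_quality_threshold, max_bad_fraction)`` pair used only by the
    whole-read filter of category six, which applies no length filter.
    """

    name: str
    quality_threshold: Optional[int] = None
    adapter_removal: str = "none"
    min_length: Optional[int] = DEFAULT_MIN_LENGTH
    fraction_filter: Optional[tuple[int, float]] = None

    def __post_init__(self):
        if self.adapter_removal not in ("none", "before_trim", "only"):
            raise ValueError(f"bad adapter_removal {self.adapter_removal!r}")
        if self.fraction_filter is not None:
            bad_q, frac = self.fraction_filter
            if not 0 < frac <= 1:
                raise ValueError("max_bad_fraction must be in (0, 1]")


CATEGORIES: dict[str, CategorySpec] = {
    "untrimmed": CategorySpec("untrimmed", min_length=None),
    "one": CategorySpec("one", quality_threshold=20),
    "two": CategorySpec("two", quality_threshold=10),
    "three": CategorySpec("three", quality_threshold=20, adapter_removal="before_trim"),
    "four": CategorySpec("four", quality_threshold=10, adapter_removal="before_trim"),
    "five": CategorySpec("five", adapter_removal="only"),
    "six": CategorySpec("six", min_length=None, fraction_filter=(10, 0.8)),
}


@dataclass
class RetentionStats:
    """Read/base accounting for one treatment of one read set."""

    input_reads: int = 0
    retained_reads: int = 0
    retained_pairs: int = 0
    singletons: int = 0
    bases_in: int = 0
    bases_out: int = 0

    def add_read(self, before: Read, after: Optional[Read]) -> None:
        self.input_reads += 1
        self.bases_in += len(before)
        if after is not None:
            self.retained_reads += 1
            self.bases_out += len(after)


# ---------------------------------------------------------------------------
# Per-read operations


def trim_quality_3prime(read: Read, qmin: int, min_length: int = 0) -> Optional[Read]:
    """Remove 3'-terminal bases with quality strictly below ``qmin``.

    Trimming proceeds from the 3' end and stops at the first base with
    quality >= qmin; internal low-quality bases 5' of that point survive.
    Returns ``None`` (discarded) when fewer than ``min_length`` bases remain.
    """
    good = np.flatnonzero(read.qualities >= qmin)
    keep = int(good[-1]) + 1 if good.size else 0
    if keep < min_length or keep == 0:
        return None
    if keep == len(read):
        return read
    return read.prefix(keep)


def filter_low_quality_fraction(
    read: Read, bad_q: int = 10, max_bad_fraction: float = 0.8
) -> bool:
    """Keep/discard a whole read on its fraction of low-quality bases.

    Returns ``True`` (keep) unless strictly more than ``max_bad_fraction``
    of the bases have quality below ``bad_q``. Zero-length reads are
    discarded.
    """
    n = len(read)
    if n == 0:
        return False
    bad = int(np.count_nonzero(read.qualities < bad_q))
    return not bad / n > max_bad_fraction


def find_adapter_start(
    sequence: str,
    adapter: str,
    min_overlap: int = DEFAULT_ADAPTER_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_ADAPTER_MAX_ERROR_RATE,
) -> Optional[int]:
    """Leftmost position whose suffix matches an adapter prefix (ungapped).

    The suffix ``sequence[p:]`` is compared against the adapter prefix of
    length ``min(len(sequence) - p, len(adapter))``; a hit requires overlap
    >= ``min_overlap`` and mismatches/overlap <= ``max_error_rate``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, alen = len(sequence), len(adapter)
    for p in range(0, n - min_overlap + 1):
        overlap = min(n - p, alen)
        allowed = int(max_error_rate * overlap)
        mismatches = 0
        window = sequence[p : p + overlap]
        for a, b in zip(window, adapter):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return p
    return None


def trim_adapter_3prime(
    read: Read,
    adapter: str,
    min_overlap: int = DEFAULT_ADAPTER_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_ADAPTER_MAX_ERROR_RATE,
) -> Read:
    """Remove a 3' adapter remnant; the read is unchanged when none is found."""
    p = find_adapter_start(read.sequence, adapter, min_overlap, max_error_rate)
    if p is None:
        return read
    return read.prefix(p)


def apply_to_read(
    read: Read,
    spec: CategorySpec,
    adapter: Optional[str] = None,
    min_overlap: int = DEFAULT_ADAPTER_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_ADAPTER_MAX_ERROR_RATE,
) -> Optional[Read]:
    """Apply one category's treatment to one read; ``None`` means discarded."""
    if spec.name == "untrimmed":
        return read
    if spec.fraction_filter is not None:
        bad_q, frac = spec.fraction_filter
        return read if filter_low_quality_fraction(read, bad_q, frac) else None
    out = read
    if spec.adapter_removal != "none":
        if adapter is None:
            raise ValueError(f"category {spec.name!r} requires an adapter sequence")
        out = trim_adapter_3prime(out, adapter, min_overlap, max_error_rate)
    if spec.quality_threshold is not None:
        out = trim_quality_3prime(out, spec.quality_threshold, 0)
        if out is None:
            return None
    min_len = spec.min_length or 0
    if len(out) < min_len or len(out) == 0:
        return None
    return out


# ---------------------------------------------------------------------------
# Stream operations


def apply_category(
    reads: Iterable[Read],
    spec: CategorySpec | str,
    adapter: Optional[str] = None,
    **adapter_kwargs,
) -> tuple[list[Read], RetentionStats]:
    """Apply a treatment to an unpaired read stream, keeping input order."""
    spec = CATEGORIES[spec] if isinstance(spec, str) else spec
    stats = RetentionStats()
    out: list[Read] = []
    for read in reads:
        processed = apply_to_read(read, spec, adapter, **adapter_kwargs)
        stats.add_read(read, processed)
        if processed is not None:
            out.append(processed)
    stats.retained_pairs = 0
    return out, stats


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def synchronize_pairs(
    processed1: Sequence[Optional[Read]], processed2: Sequence[Optional[Read]]
) -> tuple[list[tuple[Read, Read]], list[Read]]:
    """Re-pair two treated mate streams aligned by position.

    Each stream holds the per-read treatment outcome in input order
    (``None`` = discarded). A pair survives iff both mates survive; a lone
    survivor becomes a singleton. Mate ids must agree pairwise.
    """
    if len(processed1) != len(processed2):
        raise ValueError("mate streams have different lengths")
    pairs: list[tuple[Read, Read]] = []
    singletons: list[Read] = []
    for r1, r2 in zip(processed1, processed2):
        if r1 is not None and r2 is not None:
            if _pair_key(r1.id) != _pair_key(r2.id):
                raise ValueError(f"mate id mismatch: {r1.id!r} vs {r2.id!r}")
            pairs.append((r1, r2))
        elif r1 is not None:
            singletons.append(r1)
        elif r2 is not None:
            singletons.append(r2)
    return pairs, singletons


def apply_category_paired(
    reads1: Sequence[Read],
    reads2: Sequence[Read],
    spec: CategorySpec | str,
    adapter: Optional[str] = None,
    **adapter_kwargs,
) -> tuple[list[tuple[Read, Read]], list[Read], RetentionStats]:
    """Apply a treatment to both mate streams and re-synchronize pairs."""
    spec = CATEGORIES[spec] if isinstance(spec, str) else spec
    if len(reads1) != len(reads2):
        raise ValueError("mate files have different read counts")
    stats = RetentionStats()
    proc1: list[Optional[Read]] = []
    proc2: list[Optional[Read]] = []
    for r1, r2 in zip(reads1, reads2):
        if _pair_key(r1.id) != _pair_key(r2.id):
            raise ValueError(f"mate id mismatch: {r1.id!r} vs {r2.id!r}")
        p1 = apply_to_read(r1, spec, adapter, **adapter_kwargs)
        p2 = apply_to_read(r2, spec, adapter, **adapter_kwargs)
        stats.add_read(r1, p1)
        stats.add_read(r2, p2)
        proc1.append(p1)
        proc2.append(p2)
    pairs, singletons = synchronize_pairs(proc1, proc2)
    stats.retained_pairs = len(pairs)
    stats.singletons = len(singletons)
    return pairs, singletons, stats
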