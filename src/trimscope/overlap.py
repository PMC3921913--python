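"""Genome-alignment filtering and the overlapping/unique/missing-annotation
analysis.

Two assemblies are compared through the genomic loci of their transfrags'
best alignments: a locus is *overlapping* when some locus of the other
assembly intersects it (same target sequence, >= 1 bp, strand-agnostic by
default), otherwise *unique*. Unique-to-untrimmed loci that intersect
annotated CDS genes are *missing annotations* — genes whose evidence the
trimmed assembly lost entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io import AlignmentRecord, Locus

DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_COVERAGE = 95.0


@dataclass(frozen=True)
class OverlapCounts:
    overlapping_a: int
    unique_a: int
    overlapping_b: int
    unique_b: int


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[AlignmentRecord]:
    """High-stringency filter: identity and query coverage both >= the
    thresholds (inclusive)."""
    return [
        r
        for r in records
        if r.identity_pct >= min_identity and r.coverage_pct >= min_coverage
    ]


def best_location(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """One best alignment per transfrag: maximal score, ties broken by
    higher identity then lexicographically smallest (target_seq, start).
    Output preserves first-seen transfrag order."""
    best: dict[str, AlignmentRecord] = {}
    order: list[str] = []
    for r in records:
        cur = best.get(r.tf_id)
        if cur is None:
            best[r.tf_id] = r
            order.append(r.tf_id)
            continue
        key_new = (-r.score, -r.identity_pct, r.target_seq, r.start)
        key_cur = (-cur.score, -cur.identity_pct, cur.target_seq, cur.start)
        if key_new < key_cur:
            best[r.tf_id] = r
    return [best[t] for t in order]


def to_locus(record: AlignmentRecord) -> Locus:
    return Locus(record.target_seq, record.start, record.end, record.strand)


def _build_trees(loci: Iterable[Locus], stranded: bool) -> dict:
    trees: dict = {}
    for loc in loci:
        key = (loc.target_seq, loc.strand) if stranded else loc.target_seq
        trees.setdefault(key, IntervalTree()).addi(loc.start, loc.end)
    return trees


def _intersects(trees: dict, loc: Locus, stranded: bool) -> bool:
    key = (loc.target_seq, loc.strand) if stranded else loc.target_seq
    tree = trees.get(key)
    return bool(tree is not None and tree.overlap(loc.start, loc.end))


def overlap_transfrags(
    loci_a: Sequence[Locus], loci_b: Sequence[Locus], stranded: bool = False
) -> OverlapCounts:
    """Count loci of each assembly that intersect (>= 1 bp, same target)
    some locus of the other; ``overlapping + unique == total`` on each side."""
    trees_a = _build_trees(loci_a, stranded)
    trees_b = _build_trees(loci_b, stranded)
    ov_a = sum(_intersects(trees_b, loc, stranded) for loc in loci_a)
    ov_b = sum(_intersects(trees_a, loc, stranded) for loc in loci_b)
    return OverlapCounts(ov_a, len(loci_a) - ov_a, ov_b, len(loci_b) - ov_b)


def unique_loci(
    loci_a: Sequence[Locus], loci_b: Sequence[Locus], stranded: bool = False
) -> list[Locus]:
    """Loci of A intersecting no locus of B (the unique-to-A set)."""
    trees_b = _build_trees(loci_b, stranded)
    return [loc for loc in loci_a if not _intersects(trees_b, loc, stranded)]


def missing_annotations(
    unique_untrimmed_loci: Sequence[Locus],
    cds_by_gene: Mapping[str, Sequence[Locus]],
) -> tuple[int, list[str]]:
    """Distinct CDS genes intersected (>= 1 bp, same target, strand-agnostic)
    by at least one unique-to-untrimmed locus; each gene counted once."""
    trees = _build_trees(unique_untrimmed_loci, stranded=False)
    genes = sorted(
        gene
        for gene, cds_list in cds_by_gene.items()
        if any(_intersects(trees, cds, False) for cds in cds_list)
    )
    return len(genes), genes
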