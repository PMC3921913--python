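"""Readers and writers for the formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open. 1-based
inclusive coordinates exist only at file boundaries (GFF3, the alignment
table, BLAST subject spans) and are converted exactly once, here.

Quality scores are Phred values; FASTQ files may be encoded with offset 33
or 64 (both occur in early-2010s Illumina data) and the offset can be
auto-detected from the observed character codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

MAX_PHRED = 93
DETECT_SAMPLE_READS = 10_000


class FormatError(ValueError):
    """Raised for malformed input files."""


class Read:
    """A sequenced fragment with per-base Phred qualities.

    ``sequence`` is an upper-case DNA string over {A,C,G,T,N};
    ``qualities`` is an integer array of the same length. ``mate`` is 1 or 2
    for paired-end reads, ``None`` for unpaired.
    """

    __slots__ = ("id", "sequence", "qualities", "mate")

    def __init__(self, id: str, sequence: str, qualities, mate: int | None = None):
        self.id = id
        self.sequence = sequence
        self.qualities = np.asarray(qualities, dtype=np.int16)
        if len(sequence) != len(self.qualities):
            raise ValueError(
                f"read {id!r}: sequence length {len(sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        self.mate = mate

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Read)
            and self.id == other.id
            and self.sequence == other.sequence
            and np.array_equal(self.qualities, other.qualities)
            and self.mate == other.mate
        )

    def __repr__(self) -> str:
        return f"Read({self.id!r}, len={len(self)}, mate={self.mate})"

    def prefix(self, n: int) -> "Read":
        """The 5' prefix of length ``n`` (3'-trimming never touches the 5' end)."""
        return Read(self.id, self.sequence[:n], self.qualities[:n], self.mate)


@dataclass(frozen=True)
class QualityEncoding:
    """FASTQ quality encoding: character code = Phred score + offset."""

    offset: int = 33
    ambiguous: bool = False

    def __post_init__(self):
        if self.offset not in (33, 64):
            raise ValueError(f"quality offset must be 33 or 64, got {self.offset}")


@dataclass(frozen=True)
class AlignmentRecord:
    """One transfrag-to-genome alignment (best-location candidate).

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``coverage_pct`` is the fraction of the transfrag aligned (query
    coverage), in percent.
    """

    tf_id: str
    target_seq: str
    start: int
    end: int
    strand: str
    identity_pct: float
    coverage_pct: float
    score: float

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.tf_id}: bad interval [{self.start},{self.end})")


@dataclass(frozen=True)
class Locus:
    """A genomic locus (target sequence, 0-based half-open interval, strand)."""

    target_seq: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class HspRecord:
    """A high-scoring segment pair between a transfrag and a protein.

    The subject (protein) span is stored 1-based inclusive with
    ``subject_start <= subject_end`` (minus-orientation input is
    normalized); ``subject_length`` is the full protein length in residues.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    subject_length: int

    def __post_init__(self):
        if self.subject_length <= 0:
            raise ValueError(f"{self.query_id}: subject_length must be positive")
        if self.subject_start > self.subject_end:
            raise ValueError(f"{self.query_id}: unnormalized subject span")


# ---------------------------------------------------------------------------
# FASTQ


def detect_quality_encoding(
    quality_strings: Iterable[str], default: int = 33
) -> QualityEncoding:
    """Infer the Phred offset from raw FASTQ quality characters.

    Codes below 59 force offset 33 (they would be negative under +64);
    codes all >= 64 with at least one > 74 indicate offset 64 (Phred > 41
    is not emitted by +33 instruments of the era). Anything else is
    ambiguous and falls back to ``default``.
    """
    lo, hi = 255, 0
    n = 0
    for qs in quality_strings:
        if qs:
            b = qs.encode("ascii")
            lo = min(lo, min(b))
            hi = max(hi, max(b))
            n += 1
    if n == 0:
        raise ValueError("cannot detect quality encoding from empty input")
    if lo < 59:
        return QualityEncoding(33)
    if lo >= 64 and hi > 74:
        return QualityEncoding(64)
    log.warning(
        "quality encoding ambiguous (codes %d..%d); assuming offset %d", lo, hi, default
    )
    return QualityEncoding(default, ambiguous=True)


def detect_file_quality_encoding(path, default: int = 33) -> QualityEncoding:
    """Detect the offset from the first ~10,000 records of a FASTQ file."""

    def sample():
        with open(path) as fh:
            for i, (_, _, qual) in enumerate(FastqGeneralIterator(fh)):
                if i >= DETECT_SAMPLE_READS:
                    break
                yield qual

    return detect_quality_encoding(sample(), default=default)


def read_fastq(path, encoding: QualityEncoding | int | None = None) -> Iterator[Read]:
    """Yield :class:`Read` objects from a 4-line FASTQ file.

    ``encoding`` may be a :class:`QualityEncoding`, a bare offset, or
    ``None`` to auto-detect from the first records.
    """
    if encoding is None:
        encoding = detect_file_quality_encoding(path)
    elif isinstance(encoding, int):
        encoding = QualityEncoding(encoding)
    offset = encoding.offset
    other = 97 - offset  # 33 <-> 64
    with open(path) as fh:
        index = 0
        records = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(f"malformed FASTQ record #{index}: {exc}") from exc
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - offset
            if quals.size and (quals.min() < 0 or quals.max() > MAX_PHRED):
                raise FormatError(
                    f"FASTQ record #{index} ({title.split()[0]}): quality outside "
                    f"[0,{MAX_PHRED}] under offset {offset}; is the file "
                    f"Phred+{other} encoded?"
                )
            rid = title.split()[0]
            mate = None
            if rid.endswith("/1"):
                mate = 1
            elif rid.endswith("/2"):
                mate = 2
            yield Read(rid, seq.upper(), quals, mate)
            index += 1


def write_fastq(reads: Iterable[Read], path, encoding: QualityEncoding | int = 33) -> int:
    """Write reads as 4-line FASTQ; returns the number of records written."""
    offset = encoding.offset if isinstance(encoding, QualityEncoding) else int(encoding)
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            q = read.qualities + offset
            if q.size and q.max() > 126:
                raise ValueError(
                    f"read {read.id!r}: quality {int(q.max()) - offset} not "
                    f"encodable with offset {offset}"
                )
            fh.write(
                f"@{read.id}\n{read.sequence}\n+\n"
                + q.astype(np.uint8).tobytes().decode("ascii")
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, upper-cased sequence) from a text FASTA file."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: sequence before first '>' header")
                break
    with open(path) as fh:
        try:
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0], seq.upper()
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[tuple[str, str]], path, wrap: int = 60) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Alignment table (8-column TSV, 1-based inclusive on disk)

ALIGNMENT_COLUMNS = (
    "tf_id target_seq start end strand identity_pct coverage_pct score".split()
)


def read_alignment_table(path) -> Iterator[AlignmentRecord]:
    """Parse the 8-column transfrag-to-genome alignment TSV.

    On-disk coordinates are 1-based inclusive; they are converted to
    0-based half-open here. Identity and coverage must lie in [0, 100].
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise FormatError(
                    f"{path}:{lineno}: expected 8 tab-separated columns, got {len(parts)}"
                )
            tf_id, target, start, end, strand, ident, cov, score = parts
            start0, end0 = int(start) - 1, int(end)
            if start0 >= end0 or start0 < 0:
                raise FormatError(
                    f"{path}:{lineno}: bad interval {start}..{end} (1-based inclusive)"
                )
            ident_f, cov_f = float(ident), float(cov)
            for name, v in (("identity", ident_f), ("coverage", cov_f)):
                if not 0.0 <= v <= 100.0:
                    raise FormatError(f"{path}:{lineno}: {name} {v} outside [0,100]")
            yield AlignmentRecord(
                tf_id, target, start0, end0, strand, ident_f, cov_f, float(score)
            )


def write_alignment_table(records: Iterable[AlignmentRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ALIGNMENT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.tf_id}\t{r.target_seq}\t{r.start + 1}\t{r.end}\t{r.strand}\t"
                f"{r.identity_pct:.2f}\t{r.coverage_pct:.2f}\t{r.score:g}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# HSP table: BLAST tabular `-outfmt "6 std slen"` (13 columns)

HSP_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore slen".split()
)


def read_hsp_table(path) -> Iterator[HspRecord]:
    """Parse 13-column BLAST-style tabular hits (std 12 columns + slen)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 13:
                raise FormatError(
                    f"{path}:{lineno}: expected 13 columns (12 standard + slen, "
                    f"as produced by -outfmt '6 std slen'), got {len(parts)}"
                )
            (qid, sid, pident, length, mism, gapo, qstart, qend,
             sstart, send, evalue, bits, slen) = parts[:13]
            slen_i = int(slen)
            if slen_i <= 0:
                raise FormatError(f"{path}:{lineno}: slen must be positive, got {slen}")
            ss, se = int(sstart), int(send)
            if ss > se:  # minus-orientation hit: normalize the subject span
                ss, se = se, ss
            yield HspRecord(
                qid, sid, float(pident), int(length), int(mism), int(gapo),
                int(qstart), int(qend), ss, se, float(evalue), float(bits), slen_i,
            )


def write_hsp_table(records: Iterable[HspRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.pident:.2f}\t{r.aln_length}\t"
                f"{r.mismatch}\t{r.gapopen}\t{r.qstart}\t{r.qend}\t"
                f"{r.subject_start}\t{r.subject_end}\t{r.evalue:.2e}\t"
                f"{r.bitscore:.1f}\t{r.subject_length}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# GFF3 (read-only, CDS loci per gene)


def read_cds_loci(path) -> dict[str, list[Locus]]:
    """Map gene id -> CDS intervals (0-based half-open) from a GFF3 file.

    Uses an in-memory gffutils database; the gene id is the ID of the
    enclosing ``gene`` feature when present, else the CDS Parent/ID.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises a mix of ValueError/sqlite errors
        raise FormatError(f"{path}: malformed GFF3 ({exc})") from exc
    loci: dict[str, list[Locus]] = {}
    for cds in db.features_of_type("CDS"):
        gene_id = None
        for parent in db.parents(cds):
            if parent.featuretype == "gene":
                gene_id = parent.id
                break
        if gene_id is None:
            gene_id = cds.attributes.get("Parent", [cds.id])[0]
        loci.setdefault(gene_id, []).append(
            Locus(cds.seqid, cds.start - 1, cds.end, cds.strand)
        )
    return loci
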