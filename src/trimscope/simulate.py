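"""Synthetic genome, transcriptome, reads, and truth-derived evaluation inputs.

This module lets the whole evaluation run with no external data. It
emulates the shape of a fungal RNA-Seq experiment: a toy genome with
spliced gene models, transcripts with a long-tailed (log-normal) expression
distribution, 100 bp paired-end reads whose quality decays linearly toward
the 3' end, substitution errors drawn from the quality scores, and adapter
read-through on fragments shorter than the read length.

Because every read carries exact provenance (its source transcript and
interval), assembly is replaced by a coverage-interval *oracle*: surviving
(possibly trimmed) reads are projected back onto their transcripts and
transfrags are the maximal intervals with sufficient depth. Trimming that
removes coverage therefore truncates, splits, or deletes transfrags in an
exactly computable way — the phenomenon under study — while genome
alignments and protein HSPs are emitted directly from the truth, standing
in for spliced aligners and similarity searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import AlignmentRecord, HspRecord, Read, write_fasta, write_fastq

# Base codes 0..3 = A,C,G,T; complement is 3 - code.
_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

QUALITY_MIN, QUALITY_MAX = 2, 40


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate a deep, duplicate-heavy bulk RNA-Seq run on a small
    gene set: 50 genes with 0.5-3 kb transcripts, 200,000 100 bp read pairs
    at a 200 +/- 30 bp insert, and per-base quality decaying from ~35 at
    the 5' end to ~12 at the 3' end (SD 1) — an early-Illumina profile in
    which Q20 trimming removes roughly the last third of each read while
    Q10 trimming removes only occasional terminal bases. Expression is
    log-normal with sigma 1.8, spanning several orders of magnitude with a
    genuine low-expression tail.

    ``library_fragments_per_bp`` models finite library complexity: each
    transcript contributes a limited pool of distinct cDNA fragments
    (default 0.03 per bp, one distinct fragment start every ~33 bp); deep
    sequencing of an amplified library resamples that pool, so highly
    expressed genes saturate at the pool's coverage while lowly expressed
    genes remain undersampled. Saturated genes therefore sit near the
    coverage-contiguity transition, where quality trimming visibly
    fragments and truncates reconstructed transcripts — the regime of
    over-amplified early-Illumina libraries this generator emulates.
    """

    seed: int = 1
    n_genes: int = 50
    genome_length: int = 400_000
    exons_per_gene: tuple[int, int] = (1, 4)
    transcript_length: tuple[int, int] = (500, 3000)
    expression_mu: float = 0.0
    expression_sigma: float = 1.8
    read_length: int = 100
    insert_size: tuple[float, float] = (200.0, 30.0)
    n_read_pairs: int = 200_000
    q5: float = 35.0
    q3: float = 12.0
    quality_sigma: float = 1.0
    library_fragments_per_bp: float = 0.03
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

    def __post_init__(self):
        if self.q5 < self.q3:
            raise ValueError("quality must decay toward the 3' end (q5 >= q3)")
        for name in ("n_genes", "genome_length", "read_length", "n_read_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


@dataclass
class TranscriptTruth:
    """Ground truth for one gene/transcript."""

    tid: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, ascending
    sequence: str
    orf: Optional[tuple[int, int]]  # transcript coords incl. stop codon
    protein_id: Optional[str]
    protein: Optional[str]
    abundance: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def protein_length(self) -> int:
        return len(self.protein) if self.protein else 0


@dataclass
class ReadsTruth:
    """Per-read provenance: source transcript, fragment, error positions."""

    tid_index: np.ndarray  # (n_pairs,) index into transcripts
    frag_start: np.ndarray  # (n_pairs,) transcript coordinate
    frag_len: np.ndarray  # (n_pairs,)
    # (pair_index, mate) -> list of (position in read, substituted base code)
    errors: dict[tuple[int, int], list[tuple[int, int]]]


@dataclass
class Simulation:
    """A generated genome/transcriptome plus (optionally) simulated reads."""

    config: SimulationConfig
    chrom: str
    genome: str
    transcripts: list[TranscriptTruth]
    reads1: list[Read] = field(default_factory=list)
    reads2: list[Read] = field(default_factory=list)
    reads_truth: Optional[ReadsTruth] = None

    # --- file emission -----------------------------------------------------
    def write_genome_fasta(self, path) -> None:
        write_fasta([(self.chrom, self.genome)], path)

    def write_transcripts_fasta(self, path) -> None:
        write_fasta([(t.tid, t.sequence) for t in self.transcripts], path)

    def write_proteins_fasta(self, path) -> None:
        write_fasta(
            [(t.protein_id, t.protein) for t in self.transcripts if t.protein],
            path,
        )

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.chrom} 1 {len(self.genome)}\n")
            for t in self.transcripts:
                g0 = t.exons[0][0]
                g1 = t.exons[-1][1]
                base = f"{self.chrom}\ttrimscope\t"
                fh.write(
                    f"{base}gene\t{g0 + 1}\t{g1}\t.\t{t.strand}\t.\tID={t.gene_id}\n"
                )
                fh.write(
                    f"{base}mRNA\t{g0 + 1}\t{g1}\t.\t{t.strand}\t.\t"
                    f"ID={t.tid};Parent={t.gene_id}\n"
                )
                for k, (e0, e1) in enumerate(t.exons, 1):
                    fh.write(
                        f"{base}exon\t{e0 + 1}\t{e1}\t.\t{t.strand}\t.\t"
                        f"ID={t.tid}.exon{k};Parent={t.tid}\n"
                    )
                if t.orf is not None:
                    for k, (c0, c1) in enumerate(
                        project_to_genome(t.exons, *t.orf), 1
                    ):
                        fh.write(
                            f"{base}CDS\t{c0 + 1}\t{c1}\t.\t{t.strand}\t0\t"
                            f"ID={t.tid}.cds{k};Parent={t.tid}\n"
                        )

    def write_reads_fastq(self, path1, path2) -> None:
        write_fastq(self.reads1, path1)
        write_fastq(self.reads2, path2)

    def write_truth_table(self, path) -> None:
        """Per-read provenance as TSV (pair, transcript, fragment, errors)."""
        rt = self.reads_truth
        if rt is None:
            raise ValueError("reads have not been simulated")
        with open(path, "w") as fh:
            fh.write("#pair\ttranscript\tfrag_start\tfrag_end\terrors_1\terrors_2\n")
            for i in range(len(rt.tid_index)):
                t = self.transcripts[rt.tid_index[i]]
                errs = []
                for mate in (1, 2):
                    e = rt.errors.get((i, mate), [])
                    errs.append(
                        ",".join(f"{pos}:{'ACGT'[code]}" for pos, code in e) or "."
                    )
                fh.write(
                    f"r{i}\t{t.tid}\t{rt.frag_start[i]}\t"
                    f"{rt.frag_start[i] + rt.frag_len[i]}\t{errs[0]}\t{errs[1]}\n"
                )

    def cds_loci(self):
        """Gene id -> CDS loci, equivalent to parsing the emitted GFF3."""
        from .io import Locus

        out: dict[str, list[Locus]] = {}
        for t in self.transcripts:
            if t.orf is None:
                continue
            out[t.gene_id] = [
                Locus(self.chrom, c0, c1, t.strand)
                for c0, c1 in project_to_genome(t.exons, *t.orf)
            ]
        return out


# ---------------------------------------------------------------------------
# Coordinate projection and ORF finding


def project_to_genome(
    exons: Sequence[tuple[int, int]], t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript interval to genomic intervals through the exon chain."""
    if t_start >= t_end:
        raise ValueError("empty transcript interval")
    out: list[tuple[int, int]] = []
    offset = 0
    for e0, e1 in exons:
        elen = e1 - e0
        lo = max(t_start, offset)
        hi = min(t_end, offset + elen)
        if lo < hi:
            out.append((e0 + (lo - offset), e0 + (hi - offset)))
        offset += elen
    return out


def genomic_span(exons: Sequence[tuple[int, int]], t_start: int, t_end: int):
    """Enclosing genomic interval of a projected transcript interval."""
    pieces = project_to_genome(exons, t_start, t_end)
    return pieces[0][0], pieces[-1][1]


def find_longest_orf(sequence: str, min_codons: int = 33) -> Optional[tuple[int, int]]:
    """Longest forward-strand ATG..stop ORF, as a half-open interval
    including the stop codon; ties broken by leftmost start."""
    best: Optional[tuple[int, int]] = None
    n = len(sequence)
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = sequence[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                end = i + 3
                if (end - start) >= (min_codons + 1) * 3 and (
                    best is None
                    or (end - start, -start) > (best[1] - best[0], -best[0])
                ):
                    best = (start, end)
                start = None
    return best


# ---------------------------------------------------------------------------
# Genome / transcriptome generation


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASE_LUT[rng.integers(0, 4, n)].tobytes().decode("ascii")


def generate_genome(config: SimulationConfig) -> Simulation:
    """Build the toy genome, gene models, transcripts and proteins.

    Genes are non-overlapping, forward-strand, and each transcript embeds a
    single long ORF (start codon, stop-free codons, stop codon) flanked by
    UTRs, so the conceptual translation of its longest ORF is a protein of
    at least 33 residues. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    tmin, tmax = config.transcript_length
    emin, emax = config.exons_per_gene
    chrom = "chr1"

    pieces: list[str] = []
    cursor = 0
    transcripts: list[TranscriptTruth] = []

    abundances = rng.lognormal(config.expression_mu, config.expression_sigma,
                               config.n_genes)
    abundances /= abundances.sum()

    for g in range(config.n_genes):
        tlen = int(rng.integers(tmin, tmax + 1))
        # Embedded ORF: 5' UTR, ATG, stop-free codons, stop codon, 3' UTR.
        u5 = int(rng.integers(30, 121))
        u3_target = int(rng.integers(30, 121))
        n_codons = (tlen - u5 - u3_target - 6) // 3  # aa codons after ATG
        orf_nt = 3 + 3 * n_codons + 3
        u3 = tlen - u5 - orf_nt
        codons = rng.integers(0, len(_CODONS_NO_STOP), n_codons)
        body = "".join(_CODONS_NO_STOP[c] for c in codons)
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        tseq = _random_dna(rng, u5) + "ATG" + body + stop + _random_dna(rng, u3)
        assert len(tseq) == tlen

        orf = find_longest_orf(tseq)
        protein = None
        if orf is not None:
            from Bio.Seq import Seq

            protein = str(Seq(tseq[orf[0] : orf[1] - 3]).translate())

        # Exon structure: split the transcript at random points (exons >= 60 bp).
        k = int(rng.integers(emin, emax + 1))
        k = max(1, min(k, tlen // 60))
        cuts = sorted(rng.choice(np.arange(60, tlen - 59), k - 1, replace=False)
                      ) if k > 1 else []
        bounds = [0, *cuts, tlen]
        # guard against exons shrinking below 60 when cuts collide
        for i in range(1, len(bounds)):
            bounds[i] = max(bounds[i], bounds[i - 1] + 60)
        bounds[-1] = tlen

        intergenic = int(rng.integers(200, 801))
        pieces.append(_random_dna(rng, intergenic))
        cursor += intergenic
        exons: list[tuple[int, int]] = []
        for i in range(k):
            e0, e1 = bounds[i], bounds[i + 1]
            pieces.append(tseq[e0:e1])
            exons.append((cursor, cursor + (e1 - e0)))
            cursor += e1 - e0
            if i < k - 1:
                intron = int(rng.integers(60, 401))
                pieces.append(_random_dna(rng, intron))
                cursor += intron

        transcripts.append(
            TranscriptTruth(
                tid=f"t{g:03d}",
                gene_id=f"g{g:03d}",
                chrom=chrom,
                strand="+",
                exons=exons,
                sequence=tseq,
                orf=orf,
                protein_id=f"p{g:03d}" if protein else None,
                protein=protein,
                abundance=float(abundances[g]),
            )
        )

    if cursor > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_genes} genes; need at least {cursor} bp"
        )
    pieces.append(_random_dna(rng, config.genome_length - cursor))
    genome = "".join(pieces)
    return Simulation(config=config, chrom=chrom, genome=genome,
                      transcripts=transcripts)


# ---------------------------------------------------------------------------
# Read simulation


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def simulate_reads(sim: Simulation, chunk_size: int = 50_000) -> Simulation:
    """Simulate paired-end reads with positional quality decay and
    quality-driven substitution errors; fills ``sim.reads1/reads2`` and the
    per-read truth.

    Mean quality at read position i is ``q5 - (q5 - q3) * i/(L-1)``;
    realized qualities are Normal(mean, sigma) rounded and clipped to
    [2, 40]; each base is substituted with probability ``10**(-q/10)``
    (uniformly among the three alternatives). Fragments shorter than the
    read length run 3' into the adapter (then into random bases). Mate 2
    reads the reverse-complement side of the fragment.
    """
    config = sim.config
    rng = np.random.default_rng([config.seed, 1])
    L = config.read_length
    n_pairs = config.n_read_pairs
    tcodes = [
        np.frombuffer(t.sequence.encode(), dtype=np.uint8) for t in sim.transcripts
    ]
    code_of = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    tcodes = [code_of[tc] for tc in tcodes]
    tlens = np.array([t.length for t in sim.transcripts])
    abund = np.array([t.abundance for t in sim.transcripts])
    abund /= abund.sum()
    adapter_codes = code_of[np.frombuffer(config.adapter.encode(), dtype=np.uint8)]

    mean_q = config.q5 - (config.q5 - config.q3) * np.arange(L) / max(L - 1, 1)

    tid_all = np.empty(n_pairs, dtype=np.int32)
    fstart_all = np.empty(n_pairs, dtype=np.int32)
    flen_all = np.empty(n_pairs, dtype=np.int32)
    errors: dict[tuple[int, int], list[tuple[int, int]]] = {}
    reads1: list[Read] = []
    reads2: list[Read] = []

    mu_ins, sd_ins = config.insert_size
    min_frag = min(40, int(tlens.min()))

    # Finite library complexity: per transcript, a fixed pool of distinct
    # (start, length) fragments; sequencing resamples the pool, so deep
    # sampling of an amplified library yields duplicate fragments.
    pool_start: list[np.ndarray] = []
    pool_len: list[np.ndarray] = []
    for L_t in tlens:
        n_pool = max(1, int(round(config.library_fragments_per_bp * L_t)))
        flen = np.rint(rng.normal(mu_ins, sd_ins, n_pool)).astype(np.int32)
        flen = np.clip(flen, min(min_frag, int(L_t)), L_t)
        fstart = (rng.random(n_pool) * (L_t - flen + 1)).astype(np.int32)
        pool_start.append(fstart)
        pool_len.append(flen)

    for lo in range(0, n_pairs, chunk_size):
        hi = min(lo + chunk_size, n_pairs)
        n = hi - lo
        tids = rng.choice(len(tcodes), size=n, p=abund).astype(np.int32)
        pool_pick = rng.random(n)
        frag = np.empty(n, dtype=np.int32)
        start = np.empty(n, dtype=np.int32)
        for i in range(n):
            j = int(pool_pick[i] * pool_start[tids[i]].size)
            start[i] = pool_start[tids[i]][j]
            frag[i] = pool_len[tids[i]][j]
        tid_all[lo:hi] = tids
        fstart_all[lo:hi] = start
        flen_all[lo:hi] = frag

        seqs = np.empty((2 * n, L), dtype=np.uint8)
        for i in range(n):
            tc = tcodes[tids[i]]
            s, f = int(start[i]), int(frag[i])
            take = min(f, L)
            row1 = seqs[2 * i]
            row1[:take] = tc[s : s + take]
            row2 = seqs[2 * i + 1]
            row2[:take] = _revcomp_codes(tc[s + f - take : s + f])
            if take < L:
                pad = L - take
                a = min(pad, len(adapter_codes))
                row1[take : take + a] = adapter_codes[:a]
                row2[take : take + a] = adapter_codes[:a]
                if a < pad:
                    filler = rng.integers(0, 4, pad - a).astype(np.uint8)
                    row1[take + a :] = filler
                    row2[take + a :] = filler

        quals = np.rint(
            rng.normal(mean_q[None, :], config.quality_sigma, (2 * n, L))
        ).astype(np.int16)
        np.clip(quals, QUALITY_MIN, QUALITY_MAX, out=quals)
        p_err = 10.0 ** (-quals / 10.0)
        err_mask = rng.random((2 * n, L)) < p_err
        err_rows, err_cols = np.nonzero(err_mask)
        shifts = rng.integers(1, 4, err_rows.size).astype(np.uint8)
        new_bases = (seqs[err_rows, err_cols] + shifts) % 4
        seqs[err_rows, err_cols] = new_bases

        for r, c, b in zip(err_rows, err_cols, new_bases):
            pair = lo + int(r) // 2
            mate = int(r) % 2 + 1
            errors.setdefault((pair, mate), []).append((int(c), int(b)))

        letters = _BASE_LUT[seqs]
        for i in range(n):
            pid = lo + i
            reads1.append(
                Read(f"r{pid}/1", letters[2 * i].tobytes().decode("ascii"),
                     quals[2 * i], 1)
            )
            reads2.append(
                Read(f"r{pid}/2", letters[2 * i + 1].tobytes().decode("ascii"),
                     quals[2 * i + 1], 2)
            )

    sim.reads1 = reads1
    sim.reads2 = reads2
    sim.reads_truth = ReadsTruth(tid_all, fstart_all, flen_all, errors)
    return sim


# ---------------------------------------------------------------------------
# Oracle assembler and truth-derived evaluation inputs


@dataclass(frozen=True)
class OracleTransfrag:
    """A transfrag with its provenance (transcript interval, retained errors)."""

    tf_id: str
    tid_index: int
    start: int  # transcript coords, 0-based half-open
    end: int
    sequence: str
    n_errors: int
    category: str


def oracle_assemble(
    reads: Iterable[Read],
    sim: Simulation,
    category: str,
    min_depth: int = 1,
    max_gap: int = 0,
    min_len: int = 100,
) -> list[OracleTransfrag]:
    """Assemble transfrags by projecting surviving reads onto their truth.

    Each read covers the surviving (5') portion of its true source interval
    (bases read through into the adapter never map). Transfrags are maximal
    intervals with coverage >= ``min_depth`` after closing gaps <=
    ``max_gap``; intervals shorter than ``min_len`` are dropped. A
    simulated substitution error is retained in the emitted sequence only
    where a single read covers the base (deeper positions are taken as
    consensus-corrected).
    """
    rt = sim.reads_truth
    if rt is None:
        raise ValueError("reads have not been simulated")
    n_t = len(sim.transcripts)
    cov = [np.zeros(t.length, dtype=np.int32) for t in sim.transcripts]
    errcnt = [np.zeros(t.length, dtype=np.int16) for t in sim.transcripts]
    errbase = [np.full(t.length, -1, dtype=np.int8) for t in sim.transcripts]

    for read in reads:
        rid = read.id
        try:
            base, mate_s = rid.rsplit("/", 1)
            pair = int(base[1:])
            mate = int(mate_s)
            ti = int(rt.tid_index[pair])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"read id {rid!r} not resolvable in the truth") from exc
        s = int(rt.frag_start[pair])
        f = int(rt.frag_len[pair])
        take = min(len(read), f)
        if take <= 0:
            continue
        if mate == 1:
            a, b = s, s + take
        else:
            a, b = s + f - take, s + f
        cov[ti][a:b] += 1
        elist = rt.errors.get((pair, mate))
        if elist:
            for pos, code in elist:
                if pos < take:
                    if mate == 1:
                        tpos, tcode = s + pos, code
                    else:
                        tpos, tcode = s + f - 1 - pos, 3 - code
                    errcnt[ti][tpos] += 1
                    errbase[ti][tpos] = tcode

    out: list[OracleTransfrag] = []
    for ti in range(n_t):
        t = sim.transcripts[ti]
        mask = cov[ti] >= min_depth
        if not mask.any():
            continue
        # maximal covered runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        runs = list(zip(edges[::2], edges[1::2]))
        if max_gap > 0:
            merged = [list(runs[0])]
            for a, b in runs[1:]:
                if a - merged[-1][1] <= max_gap:
                    merged[-1][1] = b
                else:
                    merged.append([a, b])
            runs = [(a, b) for a, b in merged]
        k = 0
        for a, b in runs:
            a, b = int(a), int(b)
            if b - a < min_len:
                continue
            retained = (cov[ti][a:b] == 1) & (errcnt[ti][a:b] == 1)
            seq = t.sequence[a:b]
            n_err = int(retained.sum())
            if n_err:
                arr = bytearray(seq, "ascii")
                for off in np.flatnonzero(retained):
                    arr[off] = b"ACGT"[errbase[ti][a + off]]
                seq = arr.decode("ascii")
            out.append(
                OracleTransfrag(
                    tf_id=f"{category}.{t.tid}.{k}",
                    tid_index=ti,
                    start=a,
                    end=b,
                    sequence=seq,
                    n_errors=n_err,
                    category=category,
                )
            )
            k += 1
    return out


def emit_truth_alignments(
    transfrags: Iterable[OracleTransfrag], sim: Simulation
) -> list[AlignmentRecord]:
    """Genome alignments derived from the truth (stand-in for a spliced
    aligner): one record per transfrag at its genomic span, identity
    reflecting retained errors, query coverage 100%."""
    out = []
    for tf in transfrags:
        t = sim.transcripts[tf.tid_index]
        g0, g1 = genomic_span(t.exons, tf.start, tf.end)
        length = tf.end - tf.start
        identity = 100.0 * (length - tf.n_errors) / length
        out.append(
            AlignmentRecord(
                tf_id=tf.tf_id,
                target_seq=t.chrom,
                start=g0,
                end=g1,
                strand=t.strand,
                identity_pct=identity,
                coverage_pct=100.0,
                score=float(length - tf.n_errors),
            )
        )
    return out


def emit_truth_hsps(
    transfrags: Iterable[OracleTransfrag],
    sim: Simulation,
    evalue: float = 1e-20,
) -> list[HspRecord]:
    """Protein HSPs derived from the truth (stand-in for a similarity
    search): one HSP per transfrag that overlaps its transcript's ORF, with
    the subject span being the protein portion the transfrag covers."""
    out = []
    for tf in transfrags:
        t = sim.transcripts[tf.tid_index]
        if t.orf is None or t.protein is None:
            continue
        os_, oe = t.orf
        plen = t.protein_length
        coding_end = os_ + 3 * plen  # excludes the stop codon
        lo = max(tf.start, os_)
        hi = min(tf.end, coding_end)
        if hi <= lo:
            continue
        aa_start = (lo - os_) // 3 + 1
        aa_end = min(plen, -((os_ - hi) // 3))  # ceil((hi - os_)/3)
        if aa_end < aa_start:
            continue
        aln_len = hi - lo
        identity = 100.0 * (aln_len - min(tf.n_errors, aln_len)) / aln_len
        out.append(
            HspRecord(
                query_id=tf.tf_id,
                subject_id=t.protein_id,
                pident=identity,
                aln_length=aln_len,
                mismatch=min(tf.n_errors, aln_len),
                gapopen=0,
                qstart=lo - tf.start + 1,
                qend=hi - tf.start,
                subject_start=aa_start,
                subject_end=aa_end,
                evalue=evalue,
                bitscore=2.0 * (aa_end - aa_start + 1),
                subject_length=plen,
            )
        )
    return out
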