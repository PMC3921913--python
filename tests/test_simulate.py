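"""Synthetic data generator: determinism, self-consistency, error model,
and the coverage-interval oracle assembler."""

import numpy as np
import pytest

from trimscope.io import Read
from trimscope.simulate import (
    SimulationConfig,
    emit_truth_alignments,
    emit_truth_hsps,
    find_longest_orf,
    generate_genome,
    genomic_span,
    oracle_assemble,
    project_to_genome,
    simulate_reads,
)


def small_config(**kw):
    base = dict(seed=5, n_genes=6, genome_length=60_000,
                transcript_length=(500, 1500), n_read_pairs=800)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_single_exon_transcript_equals_genomic_substring(self):
        sim = generate_genome(small_config(exons_per_gene=(1, 1)))
        for t in sim.transcripts:
            (e0, e1), = t.exons
            assert sim.genome[e0:e1] == t.sequence

    def test_determinism_byte_identical(self, tmp_path):
        outs = []
        for run in range(2):
            sim = simulate_reads(generate_genome(small_config()))
            d = tmp_path / f"run{run}"
            d.mkdir()
            sim.write_genome_fasta(d / "g.fasta")
            sim.write_gff3(d / "g.gff3")
            sim.write_reads_fastq(d / "r1.fastq", d / "r2.fastq")
            sim.write_truth_table(d / "t.tsv")
            outs.append(
                tuple((d / n).read_bytes()
                      for n in ("g.fasta", "g.gff3", "r1.fastq", "r2.fastq", "t.tsv"))
            )
        assert outs[0] == outs[1]

    def test_exon_splicing_reproduces_transcripts(self):
        sim = generate_genome(small_config(exons_per_gene=(2, 4)))
        for t in sim.transcripts:
            spliced = "".join(sim.genome[a:b] for a, b in t.exons)
            assert spliced == t.sequence

    def test_genes_non_overlapping(self):
        sim = generate_genome(small_config())
        spans = sorted((t.exons[0][0], t.exons[-1][1]) for t in sim.transcripts)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0

    def test_proteins_translate_longest_orf(self):
        sim = generate_genome(small_config())
        for t in sim.transcripts:
            assert t.orf == find_longest_orf(t.sequence)
            assert t.protein_length >= 33

    def test_genome_too_short_errors_with_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            generate_genome(small_config(genome_length=2_000))


class TestProjection:
    def test_projection_through_two_exons(self):
        exons = [(100, 200), (300, 400)]
        assert project_to_genome(exons, 50, 150) == [(150, 200), (300, 350)]
        assert genomic_span(exons, 50, 150) == (150, 350)

    def test_single_exon_span_length_matches(self):
        assert genomic_span([(10, 510)], 20, 120) == (30, 130)


class TestReads:
    def test_quality_decays_toward_3prime(self):
        sim = simulate_reads(generate_genome(small_config(q5=35, q3=10)))
        q = np.vstack([r.qualities for r in sim.reads1[:500]])
        assert q[:, -10:].mean() < q[:, :10].mean()

    def test_error_rate_matches_quality_expectation(self):
        # constant Q30 -> error probability 1e-3 per base; check 3 binomial SD
        cfg = small_config(seed=11, q5=30, q3=30, quality_sigma=0,
                           n_read_pairs=1000)
        sim = simulate_reads(generate_genome(cfg))
        n_bases = 2 * cfg.n_read_pairs * cfg.read_length
        n_errors = sum(len(v) for v in sim.reads_truth.errors.values())
        expected = n_bases * 1e-3
        sd = np.sqrt(n_bases * 1e-3 * (1 - 1e-3))
        assert abs(n_errors - expected) <= 3 * sd

    def test_adapter_readthrough_on_short_fragments(self):
        cfg = small_config(seed=13, insert_size=(60.0, 5.0), quality_sigma=0,
                           q5=40, q3=40)  # error-free for exact comparison
        sim = simulate_reads(generate_genome(cfg))
        rt = sim.reads_truth
        hits = 0
        for i, read in enumerate(sim.reads1[:200]):
            f = int(rt.frag_len[i])
            if f < cfg.read_length:
                a = min(cfg.read_length - f, len(cfg.adapter))
                assert read.sequence[f : f + a] == cfg.adapter[:a]
                hits += 1
        assert hits > 0

    def test_mate2_is_reverse_complement_side(self):
        cfg = small_config(seed=17, quality_sigma=0, q5=40, q3=40)
        sim = simulate_reads(generate_genome(cfg))
        rt = sim.reads_truth
        comp = str.maketrans("ACGT", "TGCA")
        for i in range(50):
            t = sim.transcripts[rt.tid_index[i]]
            s, f = int(rt.frag_start[i]), int(rt.frag_len[i])
            take = min(f, cfg.read_length)
            frag_end = t.sequence[s + f - take : s + f]
            assert sim.reads2[i].sequence[:take] == frag_end.translate(comp)[::-1]


class TestOracleAssembler:
    def test_full_tiling_reconstructs_transcript(self):
        cfg = small_config(seed=19, n_genes=2, genome_length=30_000,
                           expression_sigma=0.2, n_read_pairs=3000,
                           quality_sigma=0, q5=40, q3=40)
        sim = simulate_reads(generate_genome(cfg))
        reads = [r for pair in zip(sim.reads1, sim.reads2) for r in pair]
        otfs = oracle_assemble(reads, sim, "untrimmed")
        by_tid = {}
        for o in otfs:
            by_tid.setdefault(o.tid_index, []).append(o)
        for ti, t in enumerate(sim.transcripts):
            pieces = by_tid.get(ti, [])
            assert len(pieces) >= 1
            covered = sum(o.end - o.start for o in pieces)
            assert covered >= 0.9 * t.length

    def test_truncation_matches_interval_arithmetic(self):
        # trim every read to its first 60 bases; the oracle transfrags must
        # equal the >=100 bp runs of the union of the trimmed true intervals
        cfg = small_config(seed=23, n_genes=3, genome_length=30_000,
                           n_read_pairs=600, quality_sigma=0, q5=40, q3=40)
        sim = simulate_reads(generate_genome(cfg))
        keep = 60
        trimmed = [r.prefix(keep) for r in sim.reads1 + sim.reads2]
        otfs = oracle_assemble(trimmed, sim, "t")
        rt = sim.reads_truth
        masks = [np.zeros(t.length, bool) for t in sim.transcripts]
        for i in range(cfg.n_read_pairs):
            ti, s, f = int(rt.tid_index[i]), int(rt.frag_start[i]), int(rt.frag_len[i])
            take = min(keep, f)
            masks[ti][s : s + take] = True          # mate 1
            masks[ti][s + f - take : s + f] = True  # mate 2
        expected = []
        for ti, m in enumerate(masks):
            edges = np.flatnonzero(np.diff(np.r_[0, m.view(np.int8), 0]))
            for a, b in zip(edges[::2], edges[1::2]):
                if b - a >= 100:
                    expected.append((ti, int(a), int(b)))
        assert sorted((o.tid_index, o.start, o.end) for o in otfs) == sorted(expected)

    def test_uncovered_transcript_yields_no_transfrag(self):
        cfg = small_config(seed=29)
        sim = simulate_reads(generate_genome(cfg))
        covered_tids = set(sim.reads_truth.tid_index.tolist())
        otfs = oracle_assemble(sim.reads1 + sim.reads2, sim, "u")
        assert {o.tid_index for o in otfs} <= covered_tids

    def test_unknown_read_id_fatal(self, tiny_sim):
        bad = Read("zzz/1", "ACGT", [30] * 4, 1)
        with pytest.raises(ValueError, match="not resolvable"):
            oracle_assemble([bad], tiny_sim, "x")

    def test_total_length_monotone_in_quality_threshold(self, tiny_sim):
        from trimscope.preprocess import apply_category_paired

        totals = {}
        for cat in ("untrimmed", "two", "one"):  # thresholds -, 10, 20
            pairs, singles, _ = apply_category_paired(
                tiny_sim.reads1, tiny_sim.reads2, cat,
                adapter=tiny_sim.config.adapter,
            )
            reads = [r for p in pairs for r in p] + singles
            otfs = oracle_assemble(reads, tiny_sim, cat)
            totals[cat] = sum(o.end - o.start for o in otfs)
        assert totals["untrimmed"] >= totals["two"] >= totals["one"]


@pytest.fixture(scope="module")
def assembled(tiny_sim):
    reads = [r for p in zip(tiny_sim.reads1, tiny_sim.reads2) for r in p]
    return oracle_assemble(reads, tiny_sim, "untrimmed")


class TestTruthEmission:
    def test_alignment_identity_counts_retained_errors(self, assembled, tiny_sim):
        for rec, otf in zip(emit_truth_alignments(assembled, tiny_sim), assembled):
            length = otf.end - otf.start
            assert rec.coverage_pct == 100.0
            assert rec.identity_pct == pytest.approx(
                100.0 * (length - otf.n_errors) / length
            )

    def test_single_exon_span_equals_transfrag_length(self):
        cfg = small_config(seed=31, exons_per_gene=(1, 1))
        sim = simulate_reads(generate_genome(cfg))
        otfs = oracle_assemble(sim.reads1 + sim.reads2, sim, "u")
        for rec, otf in zip(emit_truth_alignments(otfs, sim), otfs):
            assert rec.end - rec.start == otf.end - otf.start

    def test_hsp_spans_protein_portion(self, assembled, tiny_sim):
        hsps = {h.query_id: h for h in emit_truth_hsps(assembled, tiny_sim)}
        for otf in assembled:
            t = tiny_sim.transcripts[otf.tid_index]
            os_, oe = t.orf
            plen = t.protein_length
            coding_end = os_ + 3 * plen
            lo, hi = max(otf.start, os_), min(otf.end, coding_end)
            if hi <= lo:
                assert otf.tf_id not in hsps  # UTR-only transfrag: no hit
                continue
            h = hsps[otf.tf_id]
            assert h.subject_length == plen
            assert h.subject_start == (lo - os_) // 3 + 1
            assert 1 <= h.subject_start <= h.subject_end <= plen
            if otf.start <= os_ and otf.end >= coding_end:
                assert (h.subject_start, h.subject_end) == (1, plen)
            assert h.evalue < 1e-10
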