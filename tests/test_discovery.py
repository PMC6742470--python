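"""uORF scanning rules, annotation construction and annotation file I/O."""

import numpy as np
import pytest

from uorfkit.annotation import (
    GenomicInterval,
    ReducedAnnotation,
    TranscriptModel,
    reverse_complement,
)
from uorfkit.counting import CountTable
from uorfkit.discovery import (
    STOP_CODONS,
    ScanConfig,
    UORF,
    build_uorf_annotation,
    filter_by_evidence,
    peptide_length,
    read_uorf_annotation,
    scan_uorfs,
    write_bed12,
    write_uorf_annotation,
)
from uorfkit.errors import DataError, UsageError

from conftest import brute_force_scan


class TestScanUorfs:
    def test_minimal_nine_nt_orf(self):
        assert scan_uorfs("AAATGTTTTAACC") == [(2, 11, "ATG")]

    def test_start_without_in_frame_stop_yields_nothing(self):
        assert scan_uorfs("CCATGTTTTTTTT") == []

    def test_first_in_frame_stop_terminates(self):
        # ATG TTT TAA ... TAG: the first stop wins
        hits = scan_uorfs("ATGTTTTAATTTTAG")
        assert hits == [(0, 9, "ATG")]

    def test_max_length_excludes_long_span(self):
        seq = "ATG" + "GCT" * 133 + "TAA"  # 405 nt start->stop
        assert scan_uorfs(seq) == []
        assert scan_uorfs(seq, ScanConfig(max_len_nt=405)) == [(0, 405, "ATG")]

    def test_below_min_length_excluded(self):
        assert scan_uorfs("ATGTAA") == []  # 6 nt < 9

    def test_n_bases_never_match(self):
        assert scan_uorfs("ATNGTTTAAACC") == []
        assert scan_uorfs("ATGTTTTNACC") == []

    def test_nested_starts_sharing_stop_all_reported(self):
        # two in-frame ATGs running into the same TAA
        seq = "ATGATGTTTTAA"
        assert scan_uorfs(seq) == [(0, 12, "ATG"), (3, 12, "ATG")]

    def test_alternative_start_codons_opt_in(self):
        seq = "CTGTTTTAA"
        assert scan_uorfs(seq) == []
        cfg = ScanConfig(start_codons=frozenset({"ATG", "CTG"}))
        assert scan_uorfs(seq, cfg) == [(0, 9, "CTG")]

    def test_equals_brute_force_oracle_on_random_sequences(self):
        """Exhaustive every-position-every-frame oracle, 300 random leaders."""
        rng = np.random.default_rng(1234)
        for _ in range(300):
            n = int(rng.integers(0, 600))
            seq = "".join(rng.choice(list("ACGTACGTN"), size=n))
            assert sorted(scan_uorfs(seq)) == brute_force_scan(seq)

    def test_monotonicity_in_config(self):
        rng = np.random.default_rng(77)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 400))))
            for _ in range(50)
        ]
        wide = ScanConfig(max_len_nt=500)
        both = ScanConfig(start_codons=frozenset({"ATG", "GTG"}))
        for seq in seqs:
            base = set(scan_uorfs(seq))
            assert base <= set(scan_uorfs(seq, wide))  # larger max keeps hits
            assert base <= set(scan_uorfs(seq, both))  # more starts only add


class TestPeptideLength:
    @pytest.mark.parametrize("nt,aa", [(81, 26), (69, 22), (9, 2), (402, 133)])
    def test_examples(self, nt, aa):
        assert peptide_length(nt) == aa

    def test_non_multiple_of_three_rejected(self):
        with pytest.raises(DataError):
            peptide_length(10)


def _host_transcript(tls_seq, seed=5):
    """Single transcript whose TLS is tls_seq, split over two exons."""
    rng = np.random.default_rng(seed)
    cds = "ATG" + "GCA" * 20 + "TGA"
    tx_seq = tls_seq + cds + "".join(rng.choice(list("ACGT"), size=30))
    half = len(tx_seq) // 2
    exons = [
        GenomicInterval("chrS", 10, 10 + half, "+"),
        GenomicInterval("chrS", 10 + half + 50, 10 + len(tx_seq) + 50, "+"),
    ]
    genome_seq = (
        "".join(rng.choice(list("ACGT"), size=10))
        + tx_seq[:half]
        + "".join(rng.choice(list("ACGT"), size=50))
        + tx_seq[half:]
        + "".join(rng.choice(list("ACGT"), size=20))
    )
    tm = TranscriptModel(
        "tx1", "gene1", "chrS", "+", exons, len(tls_seq), len(tls_seq) + len(cds),
        confidence_level=1,
    )
    return tm, {"chrS": genome_seq}


class TestBuildAnnotation:
    def test_ordinals_follow_transcript_position(self):
        tls = "CCCCCCCCCCCCCCC" + "ATGTTTTAA" + "CC" + "ATGCCCCCCTAG" + "CCCC"
        tm, genome = _host_transcript(tls)
        reduced = ReducedAnnotation({"gene1": tm})
        uorfs = build_uorf_annotation(reduced, genome)
        assert [u.uorf_id for u in uorfs] == ["tx1.u1", "tx1.u2"]
        assert [(u.t_start, u.t_end) for u in uorfs] == [(15, 24), (26, 38)]

    def test_empty_tls_yields_nothing(self):
        tm, genome = _host_transcript("")
        # cds_start_t == 0: no leader at all
        assert build_uorf_annotation(ReducedAnnotation({"g": tm}), genome) == []

    def test_junction_spanning_uorf_blocks_sum_and_translate(self):
        # exon junction at half the transcript falls inside the 36-nt uORF
        tls = "C" * 130 + "ATG" + "CTC" * 10 + "TAA" + "C" * 30
        tm, genome = _host_transcript(tls)
        reduced = ReducedAnnotation({"gene1": tm})
        (uorf,) = build_uorf_annotation(reduced, genome)
        assert len(uorf.genome_blocks) == 2  # split at the exon junction
        assert sum(len(b) for b in uorf.genome_blocks) == uorf.length_nt
        # re-extract from the genome: must start with ATG and end in a stop
        seq = "".join(
            genome[b.chrom][b.start : b.end] for b in uorf.genome_blocks
        )
        assert seq.startswith("ATG") and seq[-3:] in STOP_CODONS

    def test_sequence_name_mismatch_is_fatal(self):
        tm, _ = _host_transcript("C" * 20 + "ATGTTTTAA" + "C" * 20)
        with pytest.raises(UsageError, match="chrS"):
            build_uorf_annotation(
                ReducedAnnotation({"g": tm}), {"chrOther": "ACGT" * 100}
            )

    def test_minus_strand_uorf_reextraction(self, small_world):
        """Every discovered block chain re-reads as start...stop on both strands."""
        from uorfkit.annotation import read_gtf, reduce_annotation

        world, _ = small_world
        reduced = reduce_annotation(read_gtf(world.gtf_path))
        uorfs = build_uorf_annotation(reduced, world.genome)
        assert any(u.strand == "-" for u in uorfs)
        for u in uorfs:
            parts = []
            for b in u.genome_blocks:
                seq = world.genome[b.chrom][b.start : b.end]
                parts.append(reverse_complement(seq) if u.strand == "-" else seq)
            seq = "".join(parts)
            assert seq.startswith(u.start_codon)
            assert seq[-3:] in STOP_CODONS


class TestEvidenceFilter:
    def _counts(self, totals):
        ids = [f"t.u{i}" for i in range(len(totals))]
        return CountTable(ids, ["s1", "s2"], np.array([[t, 0] for t in totals]),
                          feature_kind="uORF")

    def _uorfs(self, n):
        return [
            UORF(f"t.u{i}", "t", "g", "c", "+", 15, 24)
            for i in range(n)
        ]

    def test_zero_count_excluded_at_default_threshold(self):
        kept = filter_by_evidence(self._uorfs(2), self._counts([0, 3]))
        assert [u.uorf_id for u in kept] == ["t.u1"]

    def test_threshold_zero_is_identity(self):
        cands = self._uorfs(3)
        assert filter_by_evidence(cands, self._counts([0, 0, 0]), 0) == cands

    def test_threshold_two_keeps_only_strong(self):
        kept = filter_by_evidence(self._uorfs(3), self._counts([0, 3, 1]), 2)
        assert [u.uorf_id for u in kept] == ["t.u1"]

    def test_missing_feature_treated_as_zero(self):
        counts = CountTable(["other"], ["s1", "s2"], np.array([[5, 5]]))
        assert filter_by_evidence(self._uorfs(1), counts) == []


class TestAnnotationIO:
    def _random_uorfs(self, n, seed=9):
        rng = np.random.default_rng(seed)
        uorfs = []
        for i in range(n):
            start = int(rng.integers(10, 200))
            length = 3 * int(rng.integers(3, 40))
            strand = "+" if rng.random() < 0.5 else "-"
            split = 3 * int(rng.integers(1, length // 3))
            g = int(rng.integers(0, 5000))
            blocks = [
                GenomicInterval("chr2", g, g + split, strand),
                GenomicInterval("chr2", g + split + 90, g + length + 90, strand),
            ]
            uorfs.append(
                UORF(f"tx{i}.u1", f"tx{i}", f"g{i}", "chr2", strand,
                     start, start + length, blocks)
            )
        return uorfs

    def test_round_trip_identity(self, tmp_path):
        uorfs = self._random_uorfs(10)
        path = tmp_path / "u.csv"
        write_uorf_annotation(uorfs, str(path))
        back = read_uorf_annotation(str(path))
        assert back == uorfs
        header = path.read_text().splitlines()[0]
        assert header == (
            "uorf_id,transcript_id,gene_id,chrom,strand,genome_blocks,"
            "t_start,t_end,length_nt,peptide_len_aa,start_codon"
        )

    def test_bad_length_row_rejected(self, tmp_path):
        path = tmp_path / "u.csv"
        write_uorf_annotation(self._random_uorfs(2), str(path))
        lines = path.read_text().splitlines()
        parts = lines[1].split(",")
        parts[7] = str(int(parts[6]) + 10)  # t_end: 10-nt span, not codon-sized
        lines[1] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        assert len(read_uorf_annotation(str(path))) == 1

    def test_duplicate_id_is_fatal(self, tmp_path):
        path = tmp_path / "u.csv"
        uorfs = self._random_uorfs(2)
        uorfs[1].uorf_id = uorfs[0].uorf_id
        write_uorf_annotation(uorfs, str(path))
        with pytest.raises(DataError, match="duplicate"):
            read_uorf_annotation(str(path))

    def test_bed12_blocks_are_consistent(self, tmp_path):
        uorfs = self._random_uorfs(5)
        path = tmp_path / "u.bed"
        write_bed12(uorfs, str(path))
        for line, uorf in zip(path.read_text().splitlines(), uorfs):
            f = line.split("\t")
            assert f[3] == uorf.uorf_id and f[5] == uorf.strand
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            assert len(sizes) == int(f[9]) == len(uorf.genome_blocks)
            assert sum(sizes) == uorf.length_nt
            assert starts[0] == 0
            assert int(f[1]) + starts[-1] + sizes[-1] == int(f[2])
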