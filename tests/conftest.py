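import numpy as np
import pysam
import pytest

from uorfkit.annotation import GenomicInterval, TranscriptModel


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the package's own mapping/scanning code)
# ---------------------------------------------------------------------------


def walk_transcript_positions(exons, strand):
    """Genome positions in transcript (5'->3') order by explicit per-base walk."""
    if strand == "+":
        return [g for e in exons for g in range(e.start, e.end)]
    return [g for e in reversed(exons) for g in range(e.end - 1, e.start - 1, -1)]


def blocks_from_positions(positions, chrom, strand):
    """Group a position walk into maximal runs of consecutive coordinates."""
    blocks = []
    run = [positions[0]]
    for g in positions[1:]:
        expected = run[-1] + (1 if strand == "+" else -1)
        if g == expected:
            run.append(g)
        else:
            blocks.append(run)
            run = [g]
    blocks.append(run)
    return [
        GenomicInterval(chrom, min(r), max(r) + 1, strand) for r in blocks
    ]


def brute_force_scan(seq, start_codons=("ATG",), min_len=9, max_len=400):
    """Exhaustive ORF oracle: every start x every in-frame stop, min stop wins."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    hits = []
    for i in range(len(seq)):
        if seq[i : i + 3] not in start_codons:
            continue
        stop_ends = [
            j + 3
            for j in range(i + 3, len(seq) - 2)
            if (j - i) % 3 == 0 and seq[j : j + 3] in stops
        ]
        if not stop_ends:
            continue
        end = min(stop_ends)
        if min_len <= end - i <= max_len:
            hits.append((i, end, seq[i : i + 3]))
    return sorted(hits)


def median_of_ratios_oracle(mat):
    """Direct evaluation of the median-of-ratios definition via scipy."""
    from scipy import stats

    mat = np.asarray(mat, dtype=float)
    keep = (mat > 0).all(axis=1)
    g = stats.gmean(mat[keep], axis=1)
    return np.median(mat[keep] / g[:, None], axis=0)


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def plus_transcript():
    """Two-exon plus-strand transcript: exons [0,50) and [100,150)."""
    return TranscriptModel(
        transcript_id="txP",
        gene_id="gP",
        chrom="chrT",
        strand="+",
        exons=[
            GenomicInterval("chrT", 0, 50, "+"),
            GenomicInterval("chrT", 100, 150, "+"),
        ],
        cds_start_t=60,
        cds_end_t=99,
        confidence_level=1,
    )


@pytest.fixture
def minus_transcript():
    """Two-exon minus-strand transcript: exons [200,260) and [300,340)."""
    return TranscriptModel(
        transcript_id="txM",
        gene_id="gM",
        chrom="chrT",
        strand="-",
        exons=[
            GenomicInterval("chrT", 200, 260, "-"),
            GenomicInterval("chrT", 300, 340, "-"),
        ],
        cds_start_t=30,
        cds_end_t=90,
        confidence_level=2,
    )


@pytest.fixture
def toy_genome():
    """Deterministic 400-nt toy chromosome as a plain mapping."""
    rng = np.random.default_rng(42)
    return {"chrT": "".join(rng.choice(list("ACGT"), size=400))}


def write_sam(path, reads, references=(("chrT", 3000),)):
    """Write a small SAM file from (name, flag, ref, pos, cigartuples, seq)."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        ref_index = {name: i for i, (name, _) in enumerate(references)}
        for name, flag, ref, pos, cigar, seq in reads:
            aln = pysam.AlignedSegment()
            aln.query_name = name
            aln.flag = flag
            aln.reference_id = ref_index[ref]
            aln.reference_start = pos
            aln.mapping_quality = 255
            aln.cigartuples = cigar
            aln.query_sequence = seq
            out.write(aln)
    return str(path)


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A 30-gene synthetic world with alignments, shared across tests."""
    from uorfkit.simulate import SyntheticSpec, make_world, simulate_rpfs

    outdir = tmp_path_factory.mktemp("small_world")
    spec = SyntheticSpec(seed=314, n_genes=30, n_effect_genes=4)
    world = make_world(spec, str(outdir))
    paths = simulate_rpfs(world, str(outdir))
    return world, paths
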