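"""Self-contained synthetic worlds for end-to-end testing.

``make_world`` builds a toy genome FASTA and a Gencode-style GTF in which
every gene carries one longest high-confidence protein-coding transcript
(plus a shorter decoy transcript to exercise annotation reduction) and a
known set of planted uORFs in its transcript leader.  Background leader
sequence is scrubbed of spurious ATGs, so the set of discoverable uORFs
equals the planted set exactly and discovery can be checked for identity
rather than statistically.

``simulate_rpfs`` then emits per-sample alignment files.  Per transcript and
library, a negative-binomial read total is split between the CDS and the
planted uORFs by a baseline allocation fraction; in treatment libraries the
CDS:uORF allocation ratio is shifted by a planted per-gene log2 effect.  Read
5' ends are placed so that the default 12-nt P-site offset lands inside the
intended feature, and reads may span exon junctions (the placement walk
splits them into gapped alignments).

Everything is driven by one integer seed; identical specs and seeds give
byte-identical FASTA/GTF/truth outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from uorfkit.annotation import (
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    transcript_to_genome,
)
from uorfkit.errors import DataError, UsageError

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
# C/T-only codons: contain neither ATG nor stop codons, in any frame or
# across codon boundaries.
_SAFE_CODONS = ["CTC", "CCT", "TCC", "CTT", "TCT", "TTC", "CCC", "TTT"]
_STOPS = ["TAA", "TAG", "TGA"]
_PSITE_OFFSET = 12  # simulation targets the counting default


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated ribosome-profiling experiment.

    Defaults describe the reference study conditions used throughout the test
    suite: 200 uORF-bearing genes, 4 control + 4 treatment libraries,
    negative-binomial dispersion 0.1, and 10 genes carrying a ±2 log2 shift
    of the main-ORF-to-uORF read allocation in treatment.
    """

    seed: int
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (1, 3)
    tls_len: tuple[int, int] = (120, 260)
    cds_len: tuple[int, int] = (300, 600)
    utr3_len: tuple[int, int] = (30, 90)
    planted_uorfs_per_gene: tuple[int, int] = (1, 2)
    uorf_len: tuple[int, int] = (9, 36)
    strand_minus_fraction: float = 0.5
    n_control: int = 4
    n_treatment: int = 4
    base_reads_per_feature: float = 200.0
    uorf_allocation: float = 0.3
    n_effect_genes: int = 10
    effect_log2: float = 2.0
    planted_effects: tuple[tuple[str, float], ...] | None = None
    nb_dispersion: float = 0.1
    read_len: tuple[int, int] = (28, 32)

    def __post_init__(self):
        if not (0.0 <= self.strand_minus_fraction <= 1.0):
            raise UsageError("strand_minus_fraction must be in [0, 1]")
        if not (0.0 < self.uorf_allocation < 1.0):
            raise UsageError("uorf_allocation must be in (0, 1)")
        if self.n_control < 1 or self.n_treatment < 1:
            raise UsageError("each condition needs at least one replicate")
        for name in (
            "exons_per_gene",
            "tls_len",
            "cds_len",
            "utr3_len",
            "planted_uorfs_per_gene",
            "uorf_len",
            "read_len",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise UsageError(f"bad range for {name}: ({lo}, {hi})")
        # Every read must keep its P-site inside the target feature while
        # fitting inside the transcript; margins below guarantee that.
        if self.read_len[1] - _PSITE_OFFSET > self.utr3_len[0]:
            raise UsageError("3'UTR too short for the read length range")

    def effects(self) -> dict[str, float]:
        """Per-gene planted log2 shifts (explicit map or alternating ±)."""
        if self.planted_effects is not None:
            return dict(self.planted_effects)
        return {
            _gene_id(i): self.effect_log2 * (1 if i % 2 == 0 else -1)
            for i in range(min(self.n_effect_genes, self.n_genes))
        }


def _gene_id(i: int) -> str:
    return f"gene{i + 1:04d}"


@dataclass
class SyntheticWorld:
    """A generated world: file paths plus in-memory models and truth."""

    spec: SyntheticSpec
    genome: dict[str, str]
    transcripts: dict[str, TranscriptModel]  # main transcript per gene
    transcript_seqs: dict[str, str]
    truth: pd.DataFrame
    fasta_path: str
    gtf_path: str
    truth_path: str
    manifest_path: str


# ---------------------------------------------------------------------------
# World construction
# ---------------------------------------------------------------------------


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _scrub_atg(seq: list[str], protected: list[tuple[int, int]]) -> None:
    """Mutate spurious ATGs to C in place, never touching protected spans."""
    protected_starts = {s for s, _ in protected}

    def in_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    changed = True
    while changed:
        changed = False
        text = "".join(seq)
        idx = text.find("ATG")
        while idx != -1:
            if idx not in protected_starts:
                for pos in (idx + 1, idx, idx + 2):
                    if not in_protected(pos):
                        seq[pos] = "C"
                        changed = True
                        break
                else:  # pragma: no cover - layout precludes this
                    raise DataError("cannot scrub ATG inside protected span")
            idx = text.find("ATG", idx + 1)


def _build_tls(rng, tls_len: int, spec: SyntheticSpec) -> tuple[str, list[tuple[int, int]]]:
    """Random TLS with planted uORFs and no other ATG anywhere."""
    lo, hi = spec.planted_uorfs_per_gene
    n_uorfs = int(rng.integers(lo, hi + 1))
    margin = _PSITE_OFFSET + 3  # keep read 5' ends on-transcript
    spans: list[tuple[int, int]] = []
    cursor = margin
    lengths = []
    for _ in range(n_uorfs):
        n_codons = int(rng.integers(spec.uorf_len[0] // 3, spec.uorf_len[1] // 3 + 1))
        lengths.append(3 * n_codons)
    if cursor + sum(lengths) + 2 * len(lengths) > tls_len:
        raise DataError(
            f"TLS of {tls_len} nt cannot host {n_uorfs} uORFs of lengths "
            f"{lengths}; enlarge tls_len or shrink uorf_len"
        )
    slack = tls_len - cursor - sum(lengths) - 2 * len(lengths)
    for length in lengths:
        cursor += int(rng.integers(0, max(1, slack // max(1, len(lengths)))))
        spans.append((cursor, cursor + length))
        cursor += length + 2  # >=2 nt gap so planted ORFs never abut

    seq = list(_random_seq(rng, tls_len))
    for s, e in spans:
        n_inner = (e - s) // 3 - 2
        codons = ["ATG"] + [
            _SAFE_CODONS[int(rng.integers(0, len(_SAFE_CODONS)))]
            for _ in range(n_inner)
        ] + [_STOPS[int(rng.integers(0, len(_STOPS)))]]
        seq[s:e] = list("".join(codons))
    _scrub_atg(seq, spans)
    return "".join(seq), spans


def _build_cds(rng, cds_len: int) -> str:
    n_inner = cds_len // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_inner + 1:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(_STOPS[int(rng.integers(0, 3))])
    return "".join(codons)


def _split_exons(rng, total: int, n_exons: int) -> list[int]:
    """Split a mature length into exon lengths, each at least 30 nt."""
    if n_exons == 1 or total < 30 * n_exons:
        return [total]
    cuts = sorted(
        int(rng.integers(30, total - 30 * (n_exons - 1) + 1))
        for _ in range(n_exons - 1)
    )
    # Cumulative cut points, spaced at least 30 apart.
    points, prev = [], 0
    for c in cuts:
        c = max(c, prev + 30)
        if c > total - 30:
            break
        points.append(c)
        prev = c
    lengths = []
    prev = 0
    for p in points:
        lengths.append(p - prev)
        prev = p
    lengths.append(total - prev)
    return lengths


def make_world(spec: SyntheticSpec, outdir: str) -> SyntheticWorld:
    """Generate genome FASTA, GTF, truth table and manifest under ``outdir``."""
    rng = np.random.default_rng(spec.seed)
    os.makedirs(outdir, exist_ok=True)

    genes_per_chrom = 50
    chrom_parts: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    transcripts: dict[str, TranscriptModel] = {}
    transcript_seqs: dict[str, str] = {}
    gtf_lines: list[str] = []
    truth_rows: list[dict] = []
    effects = spec.effects()

    unknown = set(effects) - {_gene_id(i) for i in range(spec.n_genes)}
    if unknown:
        raise UsageError(f"planted effects for unknown genes: {sorted(unknown)}")

    for i in range(spec.n_genes):
        gene_id = _gene_id(i)
        chrom = f"chr{i // genes_per_chrom + 1}"
        parts = chrom_parts.setdefault(chrom, [])
        cursor = chrom_cursor.get(chrom, 0)

        tls_len = int(rng.integers(spec.tls_len[0], spec.tls_len[1] + 1))
        cds_len = 3 * int(rng.integers(spec.cds_len[0] // 3, spec.cds_len[1] // 3 + 1))
        utr3_len = int(rng.integers(spec.utr3_len[0], spec.utr3_len[1] + 1))
        tls_seq, uorf_spans = _build_tls(rng, tls_len, spec)
        tx_seq = tls_seq + _build_cds(rng, cds_len) + _random_seq(rng, utr3_len)
        mature = len(tx_seq)
        strand = "-" if rng.random() < spec.strand_minus_fraction else "+"
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lengths = _split_exons(rng, mature, n_exons)

        # Intergenic padding, then lay exons (genomic ascending) with introns.
        pad = int(rng.integers(100, 201))
        parts.append(_random_seq(rng, pad))
        cursor += pad
        gene_start = cursor
        genomic_seq = tx_seq if strand == "+" else reverse_complement(tx_seq)
        genomic_exon_lengths = (
            exon_lengths if strand == "+" else list(reversed(exon_lengths))
        )
        exons = []
        offset = 0
        for k, length in enumerate(genomic_exon_lengths):
            if k > 0:
                intron = int(rng.integers(40, 81))
                parts.append(_random_seq(rng, intron))
                cursor += intron
            parts.append(genomic_seq[offset : offset + length])
            exons.append(GenomicInterval(chrom, cursor, cursor + length, strand))
            cursor += length
            offset += length
        chrom_cursor[chrom] = cursor

        tid = f"{gene_id}.t1"
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start_t=tls_len,
            cds_end_t=tls_len + cds_len,
            confidence_level=1 if i % 2 == 0 else 2,
            transcript_type="protein_coding",
        )
        transcripts[gene_id] = tm
        transcript_seqs[tid] = tx_seq

        gtf_lines.extend(_gtf_records(tm))
        gtf_lines.extend(
            _decoy_records(gene_id, chrom, strand, gene_start, level=2 if i % 2 else 3)
        )

        uorf_spans.sort()
        for ordinal, (s, e) in enumerate(uorf_spans, start=1):
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tid,
                    "uorf_id": f"{tid}.u{ordinal}",
                    "t_start": s,
                    "t_end": e,
                    "length_nt": e - s,
                    "start_codon": "ATG",
                    "effect_log2": effects.get(gene_id, 0.0),
                }
            )

    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    truth = pd.DataFrame(truth_rows)

    fasta_path = os.path.join(outdir, "genome.fa")
    with open(fasta_path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")

    gtf_path = os.path.join(outdir, "annotation.gtf")
    with open(gtf_path, "w") as fh:
        fh.write("##provider: uorfkit-simulated\n")
        fh.writelines(gtf_lines)

    truth_path = os.path.join(outdir, "truth.csv")
    truth.to_csv(truth_path, index=False)

    manifest_path = os.path.join(outdir, "world_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "spec": _spec_to_jsonable(spec),
                "files": {
                    "genome": "genome.fa",
                    "gtf": "annotation.gtf",
                    "truth": "truth.csv",
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return SyntheticWorld(
        spec=spec,
        genome=genome,
        transcripts=transcripts,
        transcript_seqs=transcript_seqs,
        truth=truth,
        fasta_path=fasta_path,
        gtf_path=gtf_path,
        truth_path=truth_path,
        manifest_path=manifest_path,
    )


def _spec_to_jsonable(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _attrs(gene_id: str, tid: str, level: int) -> str:
    return (
        f'gene_id "{gene_id}"; transcript_id "{tid}"; '
        f'gene_type "protein_coding"; transcript_type "protein_coding"; '
        f'level {level};'
    )


def _gtf_records(tm: TranscriptModel) -> list[str]:
    a = _attrs(tm.gene_id, tm.transcript_id, tm.confidence_level)
    lines = [
        f"{tm.chrom}\tsim\ttranscript\t{tm.exons[0].start + 1}\t{tm.exons[-1].end}"
        f"\t.\t{tm.strand}\t.\t{a}\n"
    ]
    for exon in tm.exons:
        lines.append(
            f"{tm.chrom}\tsim\texon\t{exon.start + 1}\t{exon.end}\t.\t{tm.strand}\t.\t{a}\n"
        )
    for block in sorted(
        transcript_to_genome(tm, tm.cds_start_t, tm.cds_end_t), key=lambda b: b.start
    ):
        lines.append(
            f"{tm.chrom}\tsim\tCDS\t{block.start + 1}\t{block.end}\t.\t{tm.strand}\t0\t{a}\n"
        )
    return lines


def _decoy_records(
    gene_id: str, chrom: str, strand: str, gene_start: int, level: int
) -> list[str]:
    """A short sibling transcript that annotation reduction must discard.

    With level 2 it tests the length rule, with level 3 the confidence rule.
    """
    tid = f"{gene_id}.t2"
    a = _attrs(gene_id, tid, level)
    e_start, e_end = gene_start + 1, gene_start + 150  # 1-based closed
    c_start, c_end = gene_start + 31, gene_start + 120
    return [
        f"{chrom}\tsim\ttranscript\t{e_start}\t{e_end}\t.\t{strand}\t.\t{a}\n",
        f"{chrom}\tsim\texon\t{e_start}\t{e_end}\t.\t{strand}\t.\t{a}\n",
        f"{chrom}\tsim\tCDS\t{c_start}\t{c_end}\t.\t{strand}\t0\t{a}\n",
    ]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def sample_ids_for(spec: SyntheticSpec) -> list[str]:
    return [f"ctrl_rep{r + 1}" for r in range(spec.n_control)] + [
        f"tx_rep{r + 1}" for r in range(spec.n_treatment)
    ]


def simulate_rpfs(
    world: SyntheticWorld, outdir: str, fmt: str = "bam"
) -> dict[str, str]:
    """Write one alignment file per sample; returns sample_id -> path.

    BAM output is coordinate-sorted and indexed; ``fmt='sam'`` writes plain
    text in read-generation order.
    """
    if fmt not in ("bam", "sam"):
        raise UsageError(f"fmt must be 'bam' or 'sam', got {fmt!r}")
    spec = world.spec
    os.makedirs(outdir, exist_ok=True)
    chroms = sorted(world.genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if fmt == "bam" else "unsorted"},
        "SQ": [{"SN": c, "LN": len(world.genome[c])} for c in chroms],
    }
    chrom_index = {c: k for k, c in enumerate(chroms)}
    effects = spec.effects()
    truth_by_tid: dict[str, list[tuple[int, int]]] = {}
    for row in world.truth.itertuples():
        truth_by_tid.setdefault(row.transcript_id, []).append(
            (row.t_start, row.t_end)
        )

    paths: dict[str, str] = {}
    conditions = ["control"] * spec.n_control + ["treatment"] * spec.n_treatment
    for j, (sample, condition) in enumerate(zip(sample_ids_for(spec), conditions)):
        rng = np.random.default_rng([spec.seed, 1000 + j])
        path = os.path.join(outdir, f"{sample}.{fmt}")
        raw_path = path + ".unsorted.bam" if fmt == "bam" else path
        mode = "wb" if fmt == "bam" else "w"
        with pysam.AlignmentFile(raw_path, mode, header=header) as out:
            read_no = 0
            for gene_id in sorted(world.transcripts):
                tm = world.transcripts[gene_id]
                tx_seq = world.transcript_seqs[tm.transcript_id]
                spans = sorted(truth_by_tid.get(tm.transcript_id, []))
                total = _nb_draw(rng, spec.base_reads_per_feature, spec.nb_dispersion)
                if total == 0:
                    continue
                f = spec.uorf_allocation
                if condition == "treatment" and gene_id in effects:
                    ratio = (1 - f) / f * 2.0 ** effects[gene_id]
                    f = 1.0 / (1.0 + ratio)
                n_uorf_total = int(rng.binomial(total, f)) if spans else 0
                per_uorf = (
                    rng.multinomial(n_uorf_total, [1.0 / len(spans)] * len(spans))
                    if spans
                    else []
                )
                targets = [(tm.cds_start_t, tm.cds_end_t, total - n_uorf_total)]
                targets += [
                    (s, e, int(n)) for (s, e), n in zip(spans, per_uorf)
                ]
                for t_start, t_end, n_reads in targets:
                    for _ in range(n_reads):
                        read_no += 1
                        _emit_read(
                            out,
                            rng,
                            tm,
                            tx_seq,
                            t_start,
                            t_end,
                            chrom_index[tm.chrom],
                            f"{sample}.{tm.transcript_id}.{read_no}",
                            spec,
                        )
        if fmt == "bam":
            pysam.sort("-o", path, raw_path)
            os.remove(raw_path)
            pysam.index(path)
        paths[sample] = path

    with open(os.path.join(outdir, "samples_manifest.json"), "w") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "samples": {
                    s: {"path": os.path.basename(p), "condition": c}
                    for (s, p), c in zip(paths.items(), conditions)
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


def _emit_read(
    out: pysam.AlignmentFile,
    rng,
    tm: TranscriptModel,
    tx_seq: str,
    t_start: int,
    t_end: int,
    ref_id: int,
    name: str,
    spec: SyntheticSpec,
) -> None:
    """One read whose P-site (5'-end offset 12) falls inside [t_start, t_end)."""
    read_len = int(rng.integers(spec.read_len[0], spec.read_len[1] + 1))
    lo = max(t_start, _PSITE_OFFSET)
    hi = min(t_end, tm.mature_length - (read_len - _PSITE_OFFSET))
    if lo >= hi:  # feature too close to a transcript end for this read length
        logger.debug("dropped read on %s: no valid P-site placement", name)
        return
    p = int(rng.integers(lo, hi))
    pos5 = p - _PSITE_OFFSET
    blocks = transcript_to_genome(tm, pos5, pos5 + read_len)
    blocks = sorted(blocks, key=lambda b: b.start)
    read_tx_seq = tx_seq[pos5 : pos5 + read_len]

    aln = pysam.AlignedSegment()
    aln.query_name = name
    aln.flag = 16 if tm.strand == "-" else 0
    aln.reference_id = ref_id
    aln.reference_start = blocks[0].start
    aln.mapping_quality = 255
    cigar = []
    for k, block in enumerate(blocks):
        if k > 0:
            cigar.append((3, block.start - blocks[k - 1].end))  # N gap
        cigar.append((0, len(block)))  # M
    aln.cigartuples = cigar
    aln.query_sequence = (
        reverse_complement(read_tx_seq) if tm.strand == "-" else read_tx_seq
    )
    out.write(aln)
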