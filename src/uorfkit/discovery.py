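"""uORF enumeration in transcript leader sequences, plus annotation I/O.

A uORF here is a maximal in-frame span from a configured start codon (ATG by
default) to the first in-frame stop codon, lying fully inside the transcript
leader sequence (TLS).  Spans are 0-based half-open in transcript space and
include the stop codon, so the shortest admissible uORF — start, one coding
codon, stop — is 9 nt and encodes a 2-residue peptide.  The default upper
bound is 400 nt, reflecting the convention that uORFs are short peptide-coding
elements.

Overlapping and nested uORFs are all reported: every distinct start position
gives at most one uORF, and two starts may legitimately share a stop.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from uorfkit.annotation import (
    GenomicInterval,
    ReducedAnnotation,
    TranscriptModel,
    transcript_sequence,
    transcript_to_genome,
)
from uorfkit.errors import DataError, UsageError

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

UORF_CSV_HEADER = [
    "uorf_id",
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "genome_blocks",
    "t_start",
    "t_end",
    "length_nt",
    "peptide_len_aa",
    "start_codon",
]


@dataclass(frozen=True)
class ScanConfig:
    """Rules for uORF enumeration.

    ``min_len_nt``/``max_len_nt`` bound the full start→stop span, stop codon
    included.  Alternative start codons (e.g. CTG, GTG) are opt-in; the stop
    set is fixed to the standard genetic code.
    """

    start_codons: frozenset[str] = frozenset({"ATG"})
    min_len_nt: int = 9
    max_len_nt: int = 400
    require_contained_in_tls: bool = True

    def __post_init__(self):
        if not (3 <= self.min_len_nt <= self.max_len_nt):
            raise UsageError(
                f"need 3 <= min_len_nt <= max_len_nt, got "
                f"{self.min_len_nt}/{self.max_len_nt}"
            )
        for codon in self.start_codons:
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise UsageError(f"invalid start codon {codon!r}")


@dataclass
class UORF:
    """One upstream open reading frame with both coordinate systems."""

    uorf_id: str
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    t_start: int
    t_end: int  # exclusive; includes the stop codon
    genome_blocks: list[GenomicInterval] = field(default_factory=list)
    start_codon: str = "ATG"

    def __post_init__(self):
        if self.length_nt % 3 != 0:
            raise DataError(
                f"{self.uorf_id}: length {self.length_nt} not divisible by 3"
            )

    @property
    def length_nt(self) -> int:
        return self.t_end - self.t_start

    @property
    def peptide_len_aa(self) -> int:
        return peptide_length(self.length_nt)


def peptide_length(length_nt: int) -> int:
    """Peptide length in amino acids for a start→stop span of ``length_nt``.

    The stop codon is excluded and the initiator methionine counted, so an
    81-nt uORF encodes 26 residues and the 9-nt minimum encodes 2.
    """
    if length_nt % 3 != 0:
        raise DataError(f"uORF length {length_nt} nt is not a multiple of 3")
    if length_nt < 6:
        raise DataError(f"uORF length {length_nt} nt is below start+stop minimum")
    return length_nt // 3 - 1


def scan_uorfs(
    tls_seq: str, cfg: ScanConfig = ScanConfig()
) -> list[tuple[int, int, str]]:
    """Enumerate (t_start, t_end, start_codon) spans in a TLS sequence.

    Each position matching a configured start codon is extended codon by codon
    to the first in-frame stop; the span is reported if it lies fully inside
    the sequence and its length is within the configured bounds.  Codons
    containing N match neither start nor stop.  Output is sorted by
    (t_start, t_end).
    """
    seq = tls_seq.upper()
    n = len(seq)
    hits: list[tuple[int, int, str]] = []
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon not in cfg.start_codons:
            continue
        j = i + 3
        while j + 3 <= n:
            if seq[j : j + 3] in STOP_CODONS:
                span = j + 3 - i
                if cfg.min_len_nt <= span <= cfg.max_len_nt:
                    hits.append((i, j + 3, codon))
                break
            j += 3
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def build_uorf_annotation(
    reduced: ReducedAnnotation, genome, cfg: ScanConfig = ScanConfig()
) -> list[UORF]:
    """Scan every reduced transcript's TLS and lift hits to genome blocks.

    uORF ids are ``<transcript_id>.u<k>`` with ordinals assigned by ascending
    transcript start position.  With ``require_contained_in_tls`` off, the
    scan extends over the whole transcript but starts must still precede the
    main-ORF start.
    """
    genome_names = _genome_sequence_names(genome)
    missing = sorted(
        {tm.chrom for tm in reduced} - genome_names
    )
    if missing:
        raise UsageError(
            "annotation sequence names absent from genome: " + ", ".join(missing)
        )

    uorfs: list[UORF] = []
    for tm in sorted(reduced, key=lambda t: t.transcript_id):
        if tm.cds_start_t == 0:
            continue
        if cfg.require_contained_in_tls:
            scan_seq = transcript_sequence(tm, genome, 0, tm.cds_start_t)
        else:
            scan_seq = transcript_sequence(tm, genome)
        hits = [
            h for h in scan_uorfs(scan_seq, cfg) if h[0] < tm.cds_start_t
        ]
        for ordinal, (t_start, t_end, start_codon) in enumerate(hits, start=1):
            uorfs.append(
                UORF(
                    uorf_id=f"{tm.transcript_id}.u{ordinal}",
                    transcript_id=tm.transcript_id,
                    gene_id=tm.gene_id,
                    chrom=tm.chrom,
                    strand=tm.strand,
                    t_start=t_start,
                    t_end=t_end,
                    genome_blocks=transcript_to_genome(tm, t_start, t_end),
                    start_codon=start_codon,
                )
            )
    return uorfs


def _genome_sequence_names(genome) -> set[str]:
    try:
        return set(genome.keys())
    except AttributeError:
        return {rec.name for rec in genome}


def filter_by_evidence(
    candidates: list[UORF], counts, min_total_reads: int = 1
) -> list[UORF]:
    """Keep uORFs whose summed raw RPF counts across all samples pass a floor.

    With ``min_total_reads=0`` every candidate passes, matching the behaviour
    of a pre-built comprehensive annotation in which zero-count uORFs are
    retained.  Candidates absent from the count table count as zero.
    """
    kept = []
    for uorf in candidates:
        try:
            total = counts.feature_total(uorf.uorf_id)
        except KeyError:
            logger.warning("uORF %s missing from counts; treated as 0", uorf.uorf_id)
            total = 0
        if total >= min_total_reads:
            kept.append(uorf)
    return kept


# ---------------------------------------------------------------------------
# Annotation file I/O
# ---------------------------------------------------------------------------


def _format_blocks(blocks: list[GenomicInterval]) -> str:
    return ";".join(f"{b.start}-{b.end}" for b in blocks)


def _parse_blocks(text: str, chrom: str, strand: str) -> list[GenomicInterval]:
    blocks = []
    for part in text.split(";"):
        start, end = part.split("-")
        blocks.append(GenomicInterval(chrom, int(start), int(end), strand))
    return blocks


def write_uorf_annotation(uorfs: list[UORF], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(UORF_CSV_HEADER)
        for u in uorfs:
            writer.writerow(
                [
                    u.uorf_id,
                    u.transcript_id,
                    u.gene_id,
                    u.chrom,
                    u.strand,
                    _format_blocks(u.genome_blocks),
                    u.t_start,
                    u.t_end,
                    u.length_nt,
                    u.peptide_len_aa,
                    u.start_codon,
                ]
            )


def read_uorf_annotation(path: str) -> list[UORF]:
    """Read a uORF annotation CSV, validating invariants row by row.

    Rows whose span length is not a multiple of 3 (or that are otherwise
    inconsistent) are rejected with a logged message; a duplicate uORF id is
    fatal.
    """
    uorfs: list[UORF] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(UORF_CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise DataError(
                f"{path}: missing uORF annotation columns: {sorted(missing)}"
            )
        for row_no, row in enumerate(reader, start=2):
            uid = row["uorf_id"]
            if uid in seen:
                raise DataError(f"{path}: duplicate uorf_id {uid!r}")
            t_start, t_end = int(row["t_start"]), int(row["t_end"])
            if (t_end - t_start) % 3 != 0:
                logger.warning(
                    "%s row %d (%s): length %d not divisible by 3; rejected",
                    path,
                    row_no,
                    uid,
                    t_end - t_start,
                )
                continue
            try:
                uorf = UORF(
                    uorf_id=uid,
                    transcript_id=row["transcript_id"],
                    gene_id=row["gene_id"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    t_start=t_start,
                    t_end=t_end,
                    genome_blocks=_parse_blocks(
                        row["genome_blocks"], row["chrom"], row["strand"]
                    ),
                    start_codon=row["start_codon"],
                )
            except (ValueError, DataError) as exc:
                logger.warning("%s row %d rejected: %s", path, row_no, exc)
                continue
            if int(row["length_nt"]) != uorf.length_nt or int(
                row["peptide_len_aa"]
            ) != uorf.peptide_len_aa:
                logger.warning(
                    "%s row %d (%s): inconsistent length columns; rejected",
                    path,
                    row_no,
                    uid,
                )
                continue
            seen.add(uid)
            uorfs.append(uorf)
    return uorfs


def write_bed12(uorfs: list[UORF], path: str) -> None:
    """Write uORFs as BED12, one record per uORF with exon-split blocks."""
    with open(path, "w") as fh:
        for u in uorfs:
            blocks = sorted(u.genome_blocks, key=lambda b: b.start)
            chrom_start = blocks[0].start
            chrom_end = blocks[-1].end
            sizes = ",".join(str(len(b)) for b in blocks) + ","
            starts = ",".join(str(b.start - chrom_start) for b in blocks) + ","
            fh.write(
                "\t".join(
                    [
                        u.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        u.uorf_id,
                        "0",
                        u.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
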