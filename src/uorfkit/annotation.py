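"""Gene-model handling: GTF input, annotation reduction, coordinate mapping.

The reduction step mirrors the convention of keeping, per gene, only the
longest protein-coding transcript among those carrying Gencode confidence
level 1 (validated) or 2 (manually annotated).  "Longest" means mature
transcript length — the sum of exon lengths — because leader-sequence content
matters for uORF discovery, not just the CDS.

Internally all coordinates are 0-based half-open.  GTF I/O converts from the
format's 1-based closed convention at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils

from uorfkit.errors import DataError, GtfParseError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on a named sequence."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One gene model: exon chain, CDS span in transcript space, provenance.

    ``exons`` are kept in genomic order (ascending start) and must be
    non-overlapping.  Transcript coordinates run 5'→3' along the transcript:
    position 0 is the first base of the first exon on the plus strand, and the
    last base of the last exon on the minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start_t: int
    cds_end_t: int
    confidence_level: int = 3
    transcript_type: str = "protein_coding"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise DataError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if not (0 <= self.cds_start_t < self.cds_end_t <= self.mature_length):
            raise DataError(
                f"{self.transcript_id}: CDS span [{self.cds_start_t},"
                f"{self.cds_end_t}) outside mature length {self.mature_length}"
            )

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end_t - self.cds_start_t

    @property
    def cds_in_frame(self) -> bool:
        return self.cds_length % 3 == 0

    def genome_position(self, t_pos: int) -> int:
        """Genome coordinate of a single transcript position (per-base walk)."""
        if not (0 <= t_pos < self.mature_length):
            raise IndexError(f"transcript position {t_pos} out of range")
        if self.strand == "+":
            remaining = t_pos
            for exon in self.exons:
                if remaining < len(exon):
                    return exon.start + remaining
                remaining -= len(exon)
        else:
            remaining = t_pos
            for exon in reversed(self.exons):
                if remaining < len(exon):
                    return exon.end - 1 - remaining
                remaining -= len(exon)
        raise AssertionError("unreachable")


@dataclass
class ReducedAnnotation:
    """Exactly one accepted transcript per gene, plus filter provenance."""

    transcripts: dict[str, TranscriptModel]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())


# ---------------------------------------------------------------------------
# GTF input
# ---------------------------------------------------------------------------

_REQUIRED_GTF_FIELDS = 9


def _prevalidate_gtf(path: str) -> None:
    """Cheap structural scan so parse failures carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < _REQUIRED_GTF_FIELDS:
                raise GtfParseError(
                    f"expected {_REQUIRED_GTF_FIELDS} tab-separated fields, "
                    f"got {len(fields)}",
                    line_number=lineno,
                )
            if fields[2] in ("exon", "CDS") and "transcript_id" not in fields[8]:
                raise GtfParseError(
                    "attribute block lacks transcript_id", line_number=lineno
                )


def read_gtf(path: str) -> list[TranscriptModel]:
    """Read a Gencode-dialect GTF into transcript models.

    Only transcripts with at least one exon and at least one CDS record are
    returned; coordinates are converted from 1-based closed to 0-based
    half-open.  Confidence is read from the Gencode ``level`` attribute;
    transcripts without one are treated as level 3 (fail-closed).
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for feature in db.all_features():
        if feature.featuretype not in ("exon", "CDS"):
            continue
        tid = feature.attributes["transcript_id"][0]
        bucket = exons if feature.featuretype == "exon" else cds
        bucket.setdefault(tid, []).append(feature)
        if tid not in meta:
            meta[tid] = {
                "gene_id": feature.attributes.get("gene_id", [tid])[0],
                "chrom": feature.seqid,
                "strand": feature.strand,
                "attributes": {k: list(v) for k, v in feature.attributes.items()},
            }

    models: list[TranscriptModel] = []
    n_skipped = 0
    for tid in sorted(meta):
        if tid not in cds:
            continue  # non-coding or CDS-less transcript: not a uORF host
        if tid not in exons:
            logger.warning("transcript %s has CDS but no exons; skipped", tid)
            n_skipped += 1
            continue
        info = meta[tid]
        attrs = info["attributes"]
        exon_ivs = [
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
            for f in exons[tid]
        ]
        model_exons = sorted(exon_ivs, key=lambda e: e.start)

        # CDS genomic span -> transcript span via the per-exon coordinate map.
        cds_gmin = min(f.start - 1 for f in cds[tid])
        cds_gmax = max(f.end for f in cds[tid])
        tmp = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=model_exons,
            cds_start_t=0,
            cds_end_t=1,
        )
        t_of = _genome_to_transcript_map(tmp)
        try:
            if info["strand"] == "+":
                cds_start_t = t_of[cds_gmin]
                cds_end_t = t_of[cds_gmax - 1] + 1
            else:
                cds_start_t = t_of[cds_gmax - 1]
                cds_end_t = t_of[cds_gmin] + 1
        except KeyError as exc:
            logger.warning(
                "transcript %s: CDS position %s not covered by exons; skipped",
                tid,
                exc,
            )
            n_skipped += 1
            continue

        level = attrs.get("level", ["3"])[0]
        try:
            level = int(level)
        except ValueError:
            level = 3
        ttype = attrs.get(
            "transcript_type", attrs.get("transcript_biotype", ["unknown"])
        )[0]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=model_exons,
                cds_start_t=cds_start_t,
                cds_end_t=cds_end_t,
                confidence_level=level,
                transcript_type=ttype,
                attributes=attrs,
            )
        )
    if n_skipped:
        logger.warning("skipped %d malformed transcript records", n_skipped)
    return models


def _genome_to_transcript_map(tm: TranscriptModel) -> dict[int, int]:
    """Exhaustive genome-position -> transcript-position map (small models)."""
    mapping = {}
    t = 0
    exon_iter = tm.exons if tm.strand == "+" else list(reversed(tm.exons))
    for exon in exon_iter:
        positions = (
            range(exon.start, exon.end)
            if tm.strand == "+"
            else range(exon.end - 1, exon.start - 1, -1)
        )
        for g in positions:
            mapping[g] = t
            t += 1
    return mapping


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------


def reduce_annotation(
    transcripts: list[TranscriptModel],
    accepted_levels: frozenset[int] | set[int] = frozenset({1, 2}),
    strict_cds_frame: bool = False,
) -> ReducedAnnotation:
    """Keep one longest high-confidence protein-coding transcript per gene.

    Per gene, transcripts are filtered to ``transcript_type == protein_coding``
    with ``confidence_level`` in ``accepted_levels``; of those, the one with
    the greatest mature length wins, ties broken by lexicographically smallest
    transcript id.  Genes without a qualifying transcript are dropped (their
    count is logged).  With ``strict_cds_frame`` transcripts whose CDS length
    is not a multiple of 3 are also excluded; by default they are kept but
    flagged via :attr:`TranscriptModel.cds_in_frame`.
    """
    if not transcripts:
        raise DataError("no transcripts to reduce")
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tm in transcripts:
        by_gene.setdefault(tm.gene_id, []).append(tm)

    kept: dict[str, TranscriptModel] = {}
    n_dropped_genes = 0
    for gene_id in sorted(by_gene):
        candidates = [
            tm
            for tm in by_gene[gene_id]
            if tm.transcript_type == "protein_coding"
            and tm.confidence_level in accepted_levels
            and (tm.cds_in_frame or not strict_cds_frame)
        ]
        if not candidates:
            n_dropped_genes += 1
            continue
        winner = max(candidates, key=lambda tm: (tm.mature_length, _neg_id(tm)))
        kept[gene_id] = winner
    if n_dropped_genes:
        logger.info(
            "%d genes had no qualifying protein-coding transcript", n_dropped_genes
        )
    return ReducedAnnotation(
        transcripts=kept,
        provenance={
            "accepted_levels": sorted(accepted_levels),
            "strict_cds_frame": strict_cds_frame,
            "n_input_transcripts": len(transcripts),
            "n_dropped_genes": n_dropped_genes,
        },
    )


class _neg_id:
    """Inverted-ordering key so max() picks the lexicographically smallest id."""

    __slots__ = ("tid",)

    def __init__(self, tm: TranscriptModel):
        self.tid = tm.transcript_id

    def __lt__(self, other: "_neg_id") -> bool:
        return self.tid > other.tid

    def __eq__(self, other) -> bool:
        return self.tid == other.tid


# ---------------------------------------------------------------------------
# Coordinate mapping and sequence extraction
# ---------------------------------------------------------------------------


def transcript_to_genome(
    tm: TranscriptModel, t_start: int, t_end: int
) -> list[GenomicInterval]:
    """Map a transcript-space span to genome blocks.

    Blocks are returned in transcript (5'→3') order, so a minus-strand
    transcript yields blocks with descending genomic coordinates.  Block
    lengths always sum to ``t_end - t_start``; spans crossing exon junctions
    are split at the junction.
    """
    if not (0 <= t_start < t_end <= tm.mature_length):
        raise IndexError(
            f"span [{t_start}, {t_end}) outside mature length {tm.mature_length}"
        )
    blocks: list[GenomicInterval] = []
    t = 0
    exon_iter = tm.exons if tm.strand == "+" else list(reversed(tm.exons))
    for exon in exon_iter:
        exon_t_start, exon_t_end = t, t + len(exon)
        lo = max(t_start, exon_t_start)
        hi = min(t_end, exon_t_end)
        if lo < hi:
            if tm.strand == "+":
                g_start = exon.start + (lo - exon_t_start)
                blocks.append(
                    GenomicInterval(tm.chrom, g_start, g_start + (hi - lo), "+")
                )
            else:
                g_end = exon.end - (lo - exon_t_start)
                blocks.append(
                    GenomicInterval(tm.chrom, g_end - (hi - lo), g_end, "-")
                )
        t = exon_t_end
    return blocks


def fetch_interval(genome, iv: GenomicInterval) -> str:
    """Plus-strand sequence of a genomic interval, uppercased.

    ``genome`` may be a :class:`pyfaidx.Fasta` or any mapping of chromosome
    name to string-like sliceable sequence.
    """
    return str(genome[iv.chrom][iv.start : iv.end]).upper()


def transcript_sequence(
    tm: TranscriptModel, genome, t_start: int = 0, t_end: int | None = None
) -> str:
    """Transcript-space (5'→3') sequence of a span, strand-resolved."""
    if t_end is None:
        t_end = tm.mature_length
    if t_start == t_end:
        return ""
    parts = []
    for block in transcript_to_genome(tm, t_start, t_end):
        seq = fetch_interval(genome, block)
        parts.append(reverse_complement(seq) if tm.strand == "-" else seq)
    return "".join(parts)


def extract_tls(tm: TranscriptModel, genome) -> str:
    """Transcript leader sequence (5'UTR): transcript span [0, cds_start_t).

    Empty when the CDS starts at the transcript's first base — a valid model
    that simply cannot host uORFs.
    """
    if tm.cds_start_t == 0:
        return ""
    return transcript_sequence(tm, genome, 0, tm.cds_start_t)


# ---------------------------------------------------------------------------
# Reduced-annotation GTF output
# ---------------------------------------------------------------------------


def write_reduced_gtf(reduced: ReducedAnnotation, path: str) -> None:
    """Write the reduced annotation as GTF, tagging kept transcripts.

    Original attributes are preserved; a ``tag "longest_protein_coding"``
    attribute is appended to every record.
    """

    def fmt_attrs(attrs: dict) -> str:
        parts = []
        for key, values in attrs.items():
            for v in values:
                parts.append(f'{key} "{v}";')
        parts.append('tag "longest_protein_coding";')
        return " ".join(parts)

    with open(path, "w") as out:
        out.write("##description: reduced to longest protein-coding transcripts\n")
        for tm in sorted(reduced, key=lambda t: (t.chrom, t.exons[0].start)):
            attrs = dict(tm.attributes) or {
                "gene_id": [tm.gene_id],
                "transcript_id": [tm.transcript_id],
                "transcript_type": [tm.transcript_type],
                "level": [str(tm.confidence_level)],
            }
            attr_text = fmt_attrs(attrs)
            tx_start = tm.exons[0].start + 1
            tx_end = tm.exons[-1].end
            out.write(
                f"{tm.chrom}\tuorfkit\ttranscript\t{tx_start}\t{tx_end}\t.\t"
                f"{tm.strand}\t.\t{attr_text}\n"
            )
            for exon in tm.exons:
                out.write(
                    f"{tm.chrom}\tuorfkit\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{tm.strand}\t.\t{attr_text}\n"
                )
            for block in sorted(
                transcript_to_genome(tm, tm.cds_start_t, tm.cds_end_t),
                key=lambda b: b.start,
            ):
                out.write(
                    f"{tm.chrom}\tuorfkit\tCDS\t{block.start + 1}\t{block.end}\t.\t"
                    f"{tm.strand}\t0\t{attr_text}\n"
                )
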