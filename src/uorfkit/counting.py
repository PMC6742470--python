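"""P-site assignment of RPF alignments to CDS and uORF features.

Each passing read contributes a single genomic point — the inferred ribosomal
P-site, a fixed offset from the read's 5' end walked through the alignment
blocks (junction gaps are skipped).  Point assignment keeps a read from being
counted to both a uORF and its downstream main ORF, which overlap counting
could not guarantee.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from uorfkit.annotation import GenomicInterval
from uorfkit.errors import DataError, UsageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountingConfig:
    """Read filters and the P-site offset.

    The default 12-nt offset is the classical distance from the 5' end of a
    ~28-30 nt RPF to the P-site codon; ``offsets_by_length`` optionally
    overrides it per read length.  ``strandedness`` 'forward' means a read
    must align to its feature's strand (the usual ribo-seq library layout).
    """

    psite_offset_nt: int = 12
    strandedness: str = "forward"
    primary_only: bool = True
    min_read_len: int = 25
    max_read_len: int = 35
    offsets_by_length: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strandedness not in ("forward", "reverse", "unstranded"):
            raise UsageError(f"bad strandedness {self.strandedness!r}")
        if self.psite_offset_nt < 0 or self.min_read_len < 0:
            raise UsageError("offsets and read lengths must be non-negative")
        if self.min_read_len > self.max_read_len:
            raise UsageError("min_read_len > max_read_len")

    def offset_for(self, read_len: int) -> int:
        for length, offset in self.offsets_by_length:
            if length == read_len:
                return offset
        return self.psite_offset_nt


@dataclass
class CountTable:
    """Integer feature × sample count matrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_kind: str = "CDS"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"count matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.values < 0).any():
            raise DataError("negative counts")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("duplicate feature ids")
        self._index = {fid: i for i, fid in enumerate(self.feature_ids)}

    def feature_total(self, feature_id: str) -> int:
        return int(self.values[self._index[feature_id]].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str, feature_kind: str = "CDS") -> "CountTable":
        df = pd.read_csv(path, index_col="feature_id")
        return cls(
            feature_ids=list(df.index),
            sample_ids=list(df.columns),
            values=df.to_numpy(),
            feature_kind=feature_kind,
        )


def psite_position(alignment: pysam.AlignedSegment, cfg: CountingConfig) -> int | None:
    """Genomic coordinate of the inferred P-site, or None if filtered out.

    The offset is walked from the 5' end in transcript direction: from the
    leftmost aligned base for forward reads, from the rightmost for reverse
    reads, skipping junction (N) gaps.  Reads failing the length or primary
    filters, and reads whose aligned span is shorter than the offset, yield
    None.
    """
    if alignment.is_unmapped:
        return None
    if cfg.primary_only and (alignment.is_secondary or alignment.is_supplementary):
        return None
    read_len = alignment.query_length or alignment.infer_read_length() or 0
    if not (cfg.min_read_len <= read_len <= cfg.max_read_len):
        return None
    offset = cfg.offset_for(read_len)
    blocks = alignment.get_blocks()
    if not blocks:
        return None
    remaining = offset
    if alignment.is_reverse:
        for start, end in reversed(blocks):
            if remaining < end - start:
                return end - 1 - remaining
            remaining -= end - start
    else:
        for start, end in blocks:
            if remaining < end - start:
                return start + remaining
            remaining -= end - start
    logger.debug("P-site offset beyond aligned length for %s", alignment.query_name)
    return None


def _strand_compatible(read_reverse: bool, feature_strand: str, mode: str) -> bool:
    if mode == "unstranded":
        return True
    read_strand = "-" if read_reverse else "+"
    if mode == "forward":
        return read_strand == feature_strand
    return read_strand != feature_strand


FeatureSpec = tuple[str, list[GenomicInterval], str]


def count_features(
    alignment_paths: list[str],
    features: list[FeatureSpec],
    cfg: CountingConfig = CountingConfig(),
    sample_ids: list[str] | None = None,
    feature_kind: str = "CDS",
) -> CountTable:
    """Count P-sites per feature per sample.

    ``features`` is a list of (feature_id, genome_blocks, strand).  A read
    increments every feature whose blocks contain its P-site on a compatible
    strand; blocks of a single feature set normally do not overlap, and when
    they do a warning is emitted once.  Alignment files (SAM or BAM) are
    scanned sequentially, so no index is required and the result is
    independent of file order and threading.
    """
    if sample_ids is None:
        sample_ids = [_sample_name(p) for p in alignment_paths]
    if len(sample_ids) != len(alignment_paths):
        raise UsageError("sample_ids and alignment_paths differ in length")

    trees: dict[str, IntervalTree] = {}
    feature_ids = []
    for fidx, (fid, blocks, strand) in enumerate(features):
        feature_ids.append(fid)
        for block in blocks:
            trees.setdefault(block.chrom, IntervalTree()).addi(
                block.start, block.end, (fidx, strand)
            )
    feature_chroms = set(trees)

    values = np.zeros((len(features), len(alignment_paths)), dtype=np.int64)
    warned_overlap = False
    for j, path in enumerate(alignment_paths):
        if not os.path.exists(path):
            raise UsageError(f"alignment file not found: {path}")
        with pysam.AlignmentFile(path, check_sq=False) as af:
            header_chroms = set(af.references or [])
            absent = feature_chroms - header_chroms
            if absent:
                logger.warning(
                    "%s: feature chromosomes absent from header "
                    "(counted 0): %s", path, ", ".join(sorted(absent))
                )
            for aln in af.fetch(until_eof=True):
                pos = psite_position(aln, cfg)
                if pos is None:
                    continue
                tree = trees.get(aln.reference_name)
                if tree is None:
                    continue
                hits = [
                    iv.data[0]
                    for iv in tree.at(pos)
                    if _strand_compatible(aln.is_reverse, iv.data[1], cfg.strandedness)
                ]
                if len(set(hits)) > 1 and not warned_overlap:
                    logger.warning(
                        "overlapping features within one feature set; "
                        "a read may increment several"
                    )
                    warned_overlap = True
                for fidx in set(hits):
                    values[fidx, j] += 1
    return CountTable(
        feature_ids=feature_ids,
        sample_ids=list(sample_ids),
        values=values,
        feature_kind=feature_kind,
    )


def _sample_name(path: str) -> str:
    base = os.path.basename(path)
    for suffix in (".bam", ".sam", ".cram"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return base
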