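"""End-to-end orchestration: reduce → discover/load → count → rank → write."""

from __future__ import annotations

import hashlib
import json
import logging
import os

import pyfaidx

from uorfkit import __version__
from uorfkit.annotation import (
    read_gtf,
    reduce_annotation,
    transcript_to_genome,
    write_reduced_gtf,
)
from uorfkit.config import RunConfig
from uorfkit.counting import count_features
from uorfkit.discovery import (
    build_uorf_annotation,
    filter_by_evidence,
    read_uorf_annotation,
    write_bed12,
    write_uorf_annotation,
)
from uorfkit.ratios import UorfRatioModel

logger = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a dict of output paths.

    Stages: annotation reduction; uORF discovery (or comprehensive-annotation
    loading); P-site counting of CDS and uORF features; size-factor
    normalization; ratio and log2FC computation; quantile flagging; output
    and manifest writing.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    logger.info("stage reduce: reading %s", cfg.gtf)
    transcripts = read_gtf(cfg.gtf)
    reduced = reduce_annotation(transcripts)
    logger.info("stage reduce: %d genes kept", len(reduced))
    reduced_gtf = os.path.join(cfg.outdir, "longest_protein_coding.gtf")
    write_reduced_gtf(reduced, reduced_gtf)

    genome = pyfaidx.Fasta(cfg.genome)

    if cfg.mode == "comprehensive":
        logger.info(
            "stage discover: skipped; loading uORF annotation %s",
            cfg.uorf_annotation,
        )
        uorfs = read_uorf_annotation(cfg.uorf_annotation)
    else:
        logger.info("stage discover: scanning transcript leaders")
        uorfs = build_uorf_annotation(reduced, genome, cfg.scan)
    logger.info("stage discover: %d candidate uORFs", len(uorfs))

    cds_features = [
        (
            tm.transcript_id,
            transcript_to_genome(tm, tm.cds_start_t, tm.cds_end_t),
            tm.strand,
        )
        for tm in reduced
    ]
    uorf_features = [(u.uorf_id, u.genome_blocks, u.strand) for u in uorfs]

    sample_ids = sorted(cfg.design.sample_to_condition)
    bam_by_sample = _match_samples(cfg.bams, sample_ids)
    paths_in_order = [bam_by_sample[s] for s in sample_ids]

    logger.info("stage count: %d alignment files", len(paths_in_order))
    cds_counts = count_features(
        paths_in_order, cds_features, cfg.counting, sample_ids, feature_kind="CDS"
    )
    uorf_counts = count_features(
        paths_in_order, uorf_features, cfg.counting, sample_ids, feature_kind="uORF"
    )
    cds_counts.to_csv(os.path.join(cfg.outdir, "ribo_raw_CDS_reads.csv"))
    uorf_counts.to_csv(os.path.join(cfg.outdir, "ribo_raw_uORFs_reads.csv"))

    if cfg.mode == "discover":
        uorfs = filter_by_evidence(uorfs, uorf_counts, cfg.min_total_reads)
        keep = {u.uorf_id for u in uorfs}
        idx = [i for i, f in enumerate(uorf_counts.feature_ids) if f in keep]
        uorf_counts = type(uorf_counts)(
            feature_ids=[uorf_counts.feature_ids[i] for i in idx],
            sample_ids=uorf_counts.sample_ids,
            values=uorf_counts.values[idx],
            feature_kind="uORF",
        )
        logger.info("stage discover: %d uORFs pass the evidence filter", len(uorfs))

    annotation_csv = os.path.join(cfg.outdir, "uORF_annotation.csv")
    write_uorf_annotation(uorfs, annotation_csv)
    write_bed12(uorfs, os.path.join(cfg.outdir, "uORFs.bed"))

    logger.info("stage analyze: fitting ratio model")
    model = UorfRatioModel(
        cds_counts,
        uorf_counts,
        cfg.design,
        cfg.quantile,
        uorf_meta={u.uorf_id: (u.transcript_id, u.gene_id) for u in uorfs},
    )
    results = model.fit()
    out_paths = results.write_outputs(cfg.outdir)
    summary_path = os.path.join(cfg.outdir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write(results.summary() + "\n")

    manifest = {
        "tool": "uorfkit",
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "inputs": {
            "genome": {"path": cfg.genome, "sha256": _sha256(cfg.genome)},
            "gtf": {"path": cfg.gtf, "sha256": _sha256(cfg.gtf)},
            "alignments": {
                s: {"path": p, "sha256": _sha256(p)}
                for s, p in sorted(bam_by_sample.items())
            },
        },
        "config_hash": _config_hash(cfg),
        "outputs": {
            "reduced_gtf": reduced_gtf,
            "uorf_annotation": annotation_csv,
            **out_paths,
            "summary": summary_path,
        },
    }
    manifest_path = os.path.join(cfg.outdir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["outputs"]["manifest"] = manifest_path
    logger.info("pipeline complete: %s", cfg.outdir)
    return manifest["outputs"]


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {
            "mode": cfg.mode,
            "scan": sorted(cfg.scan.start_codons)
            + [cfg.scan.min_len_nt, cfg.scan.max_len_nt],
            "counting": [
                cfg.counting.psite_offset_nt,
                cfg.counting.strandedness,
                cfg.counting.min_read_len,
                cfg.counting.max_read_len,
            ],
            "quantile": [cfg.quantile.q, cfg.quantile.pseudocount],
            "design": sorted(cfg.design.sample_to_condition.items()),
            "control": cfg.design.control,
            "min_total_reads": cfg.min_total_reads,
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()


def _match_samples(bam_paths: list[str], sample_ids: list[str]) -> dict[str, str]:
    """Pair alignment files with design samples by file-name stem."""
    from uorfkit.counting import _sample_name
    from uorfkit.errors import UsageError

    by_stem = {_sample_name(p): p for p in bam_paths}
    missing = [s for s in sample_ids if s not in by_stem]
    if missing:
        raise UsageError(
            f"design samples with no matching alignment file: {missing}; "
            f"available stems: {sorted(by_stem)}"
        )
    return {s: by_stem[s] for s in sample_ids}
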