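"""YAML run configuration: schema, defaults, fail-fast validation.

Validation is aggregated: every unknown key, missing file and type mismatch
in the file is reported in one error, before any expensive computation runs.
Exactly one annotation mode must be active — either uORFs are discovered from
the data (``mode: discover``) or a pre-built uORF annotation CSV is supplied
(``mode: comprehensive`` with ``uorf_annotation``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os

import yaml

from uorfkit.counting import CountingConfig
from uorfkit.discovery import ScanConfig
from uorfkit.errors import UsageError
from uorfkit.ratios import ConditionDesign, QuantileConfig

_TOP_KEYS = {
    "genome",
    "gtf",
    "bams",
    "uorf_annotation",
    "mode",
    "design",
    "control_condition",
    "scan",
    "counting",
    "quantile",
    "outdir",
    "seed",
    "min_total_reads",
}
_SCAN_KEYS = {"start_codons", "min_len_nt", "max_len_nt", "require_contained_in_tls"}
_COUNT_KEYS = {
    "psite_offset_nt",
    "strandedness",
    "primary_only",
    "min_read_len",
    "max_read_len",
}
_QUANTILE_KEYS = {"q", "pseudocount"}


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration."""

    genome: str
    gtf: str
    bams: list[str]
    design: ConditionDesign
    outdir: str
    mode: str = "discover"
    uorf_annotation: str | None = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    counting: CountingConfig = field(default_factory=CountingConfig)
    quantile: QuantileConfig = field(default_factory=QuantileConfig)
    min_total_reads: int = 1
    seed: int = 0


def validate_config(path: str) -> RunConfig:
    """Load and validate a YAML config, aggregating all problems."""
    if not os.path.exists(path):
        raise UsageError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise UsageError(f"{path}: top level must be a mapping")

    errors: list[str] = []

    for key in sorted(set(raw) - _TOP_KEYS):
        errors.append(f"unknown key: {key!r}")
    for section, allowed in (
        ("scan", _SCAN_KEYS),
        ("counting", _COUNT_KEYS),
        ("quantile", _QUANTILE_KEYS),
    ):
        sub = raw.get(section) or {}
        if not isinstance(sub, dict):
            errors.append(f"{section}: must be a mapping")
            continue
        for key in sorted(set(sub) - allowed):
            errors.append(f"unknown key: {section}.{key!r}")

    for key in ("genome", "gtf", "bams", "design", "outdir"):
        if key not in raw:
            errors.append(f"missing required key: {key!r}")

    mode = raw.get("mode")
    uorf_annotation = raw.get("uorf_annotation")
    if mode is None:
        mode = "comprehensive" if uorf_annotation else "discover"
    if mode not in ("discover", "comprehensive"):
        errors.append(f"mode must be 'discover' or 'comprehensive', got {mode!r}")
    elif mode == "discover" and uorf_annotation:
        errors.append(
            "both modes requested: mode is 'discover' but uorf_annotation is set"
        )
    elif mode == "comprehensive" and not uorf_annotation:
        errors.append("mode 'comprehensive' requires uorf_annotation")

    bams = raw.get("bams", [])
    if not isinstance(bams, list) or not bams:
        errors.append("bams: must be a non-empty list of file paths")
        bams = []
    for p in ["genome", "gtf"]:
        if p in raw and not os.path.exists(str(raw[p])):
            errors.append(f"{p}: file not found: {raw[p]}")
    for p in bams:
        if not os.path.exists(str(p)):
            errors.append(f"bams: file not found: {p}")
    if uorf_annotation and not os.path.exists(str(uorf_annotation)):
        errors.append(f"uorf_annotation: file not found: {uorf_annotation}")

    design = None
    design_raw = raw.get("design")
    if design_raw is not None:
        if not isinstance(design_raw, dict) or not design_raw:
            errors.append("design: must be a non-empty sample -> condition mapping")
        else:
            conditions = sorted(set(design_raw.values()))
            control = raw.get("control_condition")
            if len(conditions) != 2:
                errors.append(
                    f"design: need exactly two conditions, got {conditions}"
                )
            else:
                if control is None:
                    errors.append(
                        "control_condition is required "
                        f"(one of {conditions})"
                    )
                elif control not in conditions:
                    errors.append(
                        f"control_condition {control!r} not in design "
                        f"conditions {conditions}"
                    )
                else:
                    treatment = next(c for c in conditions if c != control)
                    design = ConditionDesign(
                        sample_to_condition=dict(design_raw),
                        control=control,
                        treatment=treatment,
                    )

    def build(cls, section_raw, name):
        try:
            if name == "scan" and "start_codons" in section_raw:
                section_raw = dict(section_raw)
                section_raw["start_codons"] = frozenset(
                    str(c).upper() for c in section_raw["start_codons"]
                )
            return cls(**section_raw)
        except (TypeError, UsageError) as exc:
            errors.append(f"{name}: {exc}")
            return cls()

    scan = build(ScanConfig, raw.get("scan") or {}, "scan")
    counting = build(CountingConfig, raw.get("counting") or {}, "counting")
    quantile = build(QuantileConfig, raw.get("quantile") or {}, "quantile")

    if errors:
        raise UsageError(
            f"invalid configuration ({path}):\n  - " + "\n  - ".join(errors)
        )

    return RunConfig(
        genome=str(raw["genome"]),
        gtf=str(raw["gtf"]),
        bams=[str(p) for p in bams],
        design=design,
        outdir=str(raw["outdir"]),
        mode=mode,
        uorf_annotation=str(uorf_annotation) if uorf_annotation else None,
        scan=scan,
        counting=counting,
        quantile=quantile,
        min_total_reads=int(raw.get("min_total_reads", 1)),
        seed=int(raw.get("seed", 0)),
    )
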