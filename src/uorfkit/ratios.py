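"""Main-ORF-to-uORF ratio analysis.

The regulatory readout is deliberately simple.  Per library, counts are
scaled by median-of-ratios size factors.  For each uORF and each condition
the ratio

    R_c = (mean normalized CDS counts + pseudocount)
          / (mean normalized uORF counts + pseudocount)

measures how strongly ribosomes favour the main ORF over the uORF; its
between-condition change, log2FC = log2(R_treatment / R_control), is the
statistic.  A positive log2FC means uORF-mediated repression of the main ORF
is relieved under treatment.  Records are ranked by |log2FC| and the extreme
5% tails flagged: ``strongest_change`` (candidate regulatory uORFs) and
``least_change``.  No p-values are attached — the method is a ranking.

The module is organised as a model/results pair: build a
:class:`UorfRatioModel` from the two count tables and a two-condition design,
``fit()`` it, and read estimates, flags and summaries off the returned
:class:`UorfRatioResults`.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from uorfkit.counting import CountTable
from uorfkit.errors import DataError, UsageError

logger = logging.getLogger(__name__)

REGULATION_COLUMNS = [
    "uorf_id",
    "transcript_id",
    "gene_id",
    "R_ctrl",
    "R_tx",
    "log2FC",
    "flag",
]


@dataclass(frozen=True)
class QuantileConfig:
    """Quantile fraction for candidate flagging and the ratio pseudocount."""

    q: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.q < 0.5):
            raise UsageError(f"quantile fraction must be in (0, 0.5), got {self.q}")
        if self.pseudocount < 0:
            raise UsageError("pseudocount must be non-negative")


@dataclass(frozen=True)
class ConditionDesign:
    """Two-condition sample design: which libraries are control vs treatment."""

    sample_to_condition: dict
    control: str
    treatment: str

    def __post_init__(self):
        labels = set(self.sample_to_condition.values())
        if labels != {self.control, self.treatment}:
            raise UsageError(
                f"design labels {sorted(labels)} must be exactly "
                f"{{{self.control!r}, {self.treatment!r}}}"
            )

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_to_condition.items() if c == condition]

    def swapped(self) -> "ConditionDesign":
        return ConditionDesign(
            sample_to_condition=dict(self.sample_to_condition),
            control=self.treatment,
            treatment=self.control,
        )


# ---------------------------------------------------------------------------
# Normalization primitives
# ---------------------------------------------------------------------------


def size_factors(counts: CountTable) -> pd.Series:
    """Median-of-ratios size factors, one per library.

    For each feature with strictly positive counts in every sample, the count
    is divided by the feature's geometric mean across samples; the per-sample
    median of these ratios is the size factor.  Requires at least two samples
    and at least one all-positive feature.
    """
    if len(counts.sample_ids) < 2:
        raise UsageError("size factors need at least 2 samples")
    mat = counts.values.astype(float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise DataError(
            "no feature has positive counts in every sample; size factors "
            "are undefined — use less sparse features or fewer samples"
        )
    sub = mat[all_positive]
    geo_mean = np.exp(np.log(sub).mean(axis=1))
    sf = np.median(sub / geo_mean[:, None], axis=0)
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalize(counts: CountTable, sf: pd.Series) -> pd.DataFrame:
    """Divide each library's counts by its size factor."""
    missing = set(counts.sample_ids) - set(sf.index)
    if missing:
        raise UsageError(f"no size factor for samples: {sorted(missing)}")
    df = counts.to_dataframe().astype(float)
    return df / sf[df.columns]


def log2fc(r_tx: float, r_ctrl: float) -> float:
    """log2 fold change of the treatment ratio over the control ratio."""
    if r_tx <= 0 or r_ctrl <= 0:
        raise DataError(f"ratios must be positive, got {r_tx}, {r_ctrl}")
    return math.log2(r_tx) - math.log2(r_ctrl)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def flag_quantiles(records: pd.DataFrame, cfg: QuantileConfig) -> pd.DataFrame:
    """Flag the strongest- and least-changing tails of |log2FC|.

    uORFs with zero raw counts in every library (``raw_uorf_zero``) are
    excluded from the ranking; of the remaining N records, the
    round-half-up(q x N) largest |log2FC| become ``strongest_change`` and the
    same number of smallest become ``least_change``.  Ties break on uorf_id
    so the flag set is deterministic.
    """
    out = records.copy()
    out["flag"] = "none"
    eligible = out.index[~out["raw_uorf_zero"]]
    n_eligible = len(eligible)
    if n_eligible == 0:
        logger.warning("no uORF has any raw counts; nothing to flag")
        return out
    n_flag = _round_half_up(cfg.q * n_eligible)
    if n_flag == 0:
        return out
    abs_fc = out.loc[eligible, "log2FC"].abs()
    order = sorted(eligible, key=lambda uid: (-abs_fc[uid], uid))
    strongest = order[:n_flag]
    least = [uid for uid in reversed(order) if uid not in set(strongest)][:n_flag]
    out.loc[strongest, "flag"] = "strongest_change"
    out.loc[least, "flag"] = "least_change"
    return out


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------


class UorfRatioModel:
    """Ratio-of-ratios model over a CDS and a uORF count table.

    Parameters
    ----------
    cds_counts, uorf_counts
        Integer count tables over the same libraries.  CDS features are
        indexed by transcript id; uORF features by uORF id, and each uORF id
        must resolve to a CDS feature via ``uorf_to_transcript`` (by default
        the ``<transcript>.u<k>`` naming convention is used).
    design
        Two-condition sample design.
    quantiles
        Flagging and pseudocount configuration.
    uorf_to_transcript
        Optional explicit uORF id -> transcript id mapping; also the source
        of gene ids when given as a mapping of uORF id -> (transcript, gene).
    """

    def __init__(
        self,
        cds_counts: CountTable,
        uorf_counts: CountTable,
        design: ConditionDesign,
        quantiles: QuantileConfig = QuantileConfig(),
        uorf_meta: dict | None = None,
    ):
        if cds_counts.sample_ids != uorf_counts.sample_ids:
            raise UsageError("CDS and uORF tables cover different samples")
        unlabeled = set(cds_counts.sample_ids) - set(design.sample_to_condition)
        if unlabeled:
            raise UsageError(f"samples missing from design: {sorted(unlabeled)}")
        self.cds_counts = cds_counts
        self.uorf_counts = uorf_counts
        self.design = design
        self.quantiles = quantiles
        self.uorf_meta = uorf_meta or {}

    def _transcript_of(self, uorf_id: str) -> str:
        if uorf_id in self.uorf_meta:
            return self.uorf_meta[uorf_id][0]
        return uorf_id.rsplit(".", 1)[0]

    def _gene_of(self, uorf_id: str) -> str:
        if uorf_id in self.uorf_meta:
            return self.uorf_meta[uorf_id][1]
        return ""

    def fit(self) -> "UorfRatioResults":
        """Compute size factors, per-condition ratios, log2FCs and flags."""
        sf = size_factors(self.cds_counts)
        cds_norm = normalize(self.cds_counts, sf)
        uorf_norm = normalize(self.uorf_counts, sf)

        ctrl = self.design.samples(self.design.control)
        tx = self.design.samples(self.design.treatment)
        pc = self.quantiles.pseudocount
        raw_uorf = self.uorf_counts.to_dataframe()

        rows = []
        n_skipped = 0
        for uorf_id in self.uorf_counts.feature_ids:
            transcript_id = self._transcript_of(uorf_id)
            if transcript_id not in cds_norm.index:
                logger.warning(
                    "uORF %s: transcript %s has no CDS feature; skipped",
                    uorf_id,
                    transcript_id,
                )
                n_skipped += 1
                continue
            cds_row = cds_norm.loc[transcript_id]
            uorf_row = uorf_norm.loc[uorf_id]
            r_ctrl = (cds_row[ctrl].mean() + pc) / (uorf_row[ctrl].mean() + pc)
            r_tx = (cds_row[tx].mean() + pc) / (uorf_row[tx].mean() + pc)
            rows.append(
                {
                    "uorf_id": uorf_id,
                    "transcript_id": transcript_id,
                    "gene_id": self._gene_of(uorf_id),
                    "R_ctrl": r_ctrl,
                    "R_tx": r_tx,
                    "log2FC": log2fc(r_tx, r_ctrl),
                    "raw_uorf_zero": bool(raw_uorf.loc[uorf_id].sum() == 0),
                }
            )
        records = pd.DataFrame(
            rows,
            columns=[
                "uorf_id",
                "transcript_id",
                "gene_id",
                "R_ctrl",
                "R_tx",
                "log2FC",
                "raw_uorf_zero",
            ],
        ).set_index("uorf_id", drop=False)
        records.index.name = None
        records = flag_quantiles(records, self.quantiles)
        return UorfRatioResults(
            model=self,
            size_factors=sf,
            cds_norm=cds_norm,
            uorf_norm=uorf_norm,
            records=records,
            n_skipped=n_skipped,
        )


class UorfRatioResults:
    """Fitted ratio analysis: normalized tables, per-uORF records, flags."""

    def __init__(self, model, size_factors, cds_norm, uorf_norm, records, n_skipped=0):
        self.model = model
        self.size_factors = size_factors
        self.cds_norm = cds_norm
        self.uorf_norm = uorf_norm
        self.records = records
        self.n_skipped = n_skipped

    @property
    def strongest_change(self) -> pd.DataFrame:
        return self.records[self.records["flag"] == "strongest_change"]

    @property
    def least_change(self) -> pd.DataFrame:
        return self.records[self.records["flag"] == "least_change"]

    def summarize(self) -> dict:
        """Directional summary of the log2FC distribution.

        Counts below/above 0 and ±1, the means of the negative and positive
        log2FCs, and how many strongest-change candidates move toward more
        uORF repression (negative log2FC).
        """
        if self.records.empty:
            raise DataError("no records to summarize")
        fc = self.records["log2FC"]
        neg, pos = fc[fc < 0], fc[fc > 0]
        strongest = self.strongest_change
        return {
            "n_records": int(len(fc)),
            "n_negative": int(len(neg)),
            "n_below_minus1": int((fc < -1).sum()),
            "n_positive": int(len(pos)),
            "n_above_plus1": int((fc > 1).sum()),
            "mean_negative": float(neg.mean()) if len(neg) else float("nan"),
            "mean_positive": float(pos.mean()) if len(pos) else float("nan"),
            "n_strongest": int(len(strongest)),
            "n_strongest_negative": int((strongest["log2FC"] < 0).sum()),
            "mean_R_ctrl": float(self.records["R_ctrl"].mean()),
            "mean_R_tx": float(self.records["R_tx"].mean()),
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.summarize()
        d = self.model.design
        lines = [
            "Main-ORF-to-uORF ratio analysis",
            "=" * 47,
            f"uORFs analysed:            {s['n_records']}",
            f"skipped (no CDS feature):  {self.n_skipped}",
            f"control samples:           {len(d.samples(d.control))}"
            f" ({d.control})",
            f"treatment samples:         {len(d.samples(d.treatment))}"
            f" ({d.treatment})",
            f"mean ratio, control:       {s['mean_R_ctrl']:.2f}",
            f"mean ratio, treatment:     {s['mean_R_tx']:.2f}",
            f"log2FC < 0 / < -1:         {s['n_negative']} / {s['n_below_minus1']}",
            f"log2FC > 0 / > +1:         {s['n_positive']} / {s['n_above_plus1']}",
            f"mean negative log2FC:      {s['mean_negative']:.2f}",
            f"mean positive log2FC:      {s['mean_positive']:.2f}",
            f"strongest-change flagged:  {s['n_strongest']}"
            f" ({s['n_strongest_negative']} with negative log2FC)",
            f"least-change flagged:      {len(self.least_change)}",
        ]
        return "\n".join(lines)

    def write_outputs(self, outdir: str) -> dict:
        """Write the normalized tables and the regulation ranking.

        Produces ``ribo_norm_CDS_reads.csv``, ``ribo_norm_uORFs_reads.csv``
        and ``uORF_regulation.csv`` in ``outdir``.
        """
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "cds_norm": os.path.join(outdir, "ribo_norm_CDS_reads.csv"),
            "uorf_norm": os.path.join(outdir, "ribo_norm_uORFs_reads.csv"),
            "regulation": os.path.join(outdir, "uORF_regulation.csv"),
        }
        self.cds_norm.rename_axis("feature_id").to_csv(
            paths["cds_norm"], float_format="%.6f"
        )
        self.uorf_norm.rename_axis("feature_id").to_csv(
            paths["uorf_norm"], float_format="%.6f"
        )
        self.records[REGULATION_COLUMNS].to_csv(
            paths["regulation"], index=False, float_format="%.6f"
        )
        return paths
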