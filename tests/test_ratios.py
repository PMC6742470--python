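"""Size factors, normalization, ratio statistics, flagging and outputs."""

import math

import numpy as np
import pandas as pd
import pytest

from uorfkit.counting import CountTable
from uorfkit.errors import DataError, UsageError
from uorfkit.ratios import (
    ConditionDesign,
    QuantileConfig,
    UorfRatioModel,
    UorfRatioResults,
    flag_quantiles,
    log2fc,
    normalize,
    size_factors,
)


def _table(values, kind="CDS", prefix="f"):
    values = np.asarray(values)
    return CountTable(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        feature_kind=kind,
    )


from conftest import median_of_ratios_oracle  # noqa: E402


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        sf = size_factors(_table([[10, 10], [7, 7], [120, 120]]))
        assert np.allclose(sf, 1.0)

    def test_doubled_library(self):
        sf = size_factors(_table([[10, 20], [50, 100], [7, 14]]))
        assert np.allclose(sf.values, [1 / math.sqrt(2), math.sqrt(2)])
        assert np.isclose(sf.iloc[1] / sf.iloc[0], 2.0)

    def test_zero_containing_feature_excluded(self):
        with_zero = _table([[10, 20], [50, 100], [0, 33]])
        without = _table([[10, 20], [50, 100]])
        assert np.allclose(size_factors(with_zero), size_factors(without))

    def test_matches_direct_oracle_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            mat = rng.integers(0, 500, size=(30, 5))
            if not (mat > 0).all(axis=1).any():
                continue
            assert np.allclose(size_factors(_table(mat)), median_of_ratios_oracle(mat))

    def test_all_zero_matrix_is_fatal(self):
        with pytest.raises(DataError):
            size_factors(_table([[0, 1], [1, 0]]))

    def test_single_sample_rejected(self):
        with pytest.raises(UsageError):
            size_factors(_table([[5], [9]]))


class TestNormalize:
    def test_division_by_factor(self):
        table = _table([[10, 10]])
        sf = pd.Series([2.0, 1.0], index=["s0", "s1"])
        norm = normalize(table, sf)
        assert norm.loc["f0", "s0"] == 5.0 and norm.loc["f0", "s1"] == 10.0

    def test_scale_invariance_of_normalized_values(self):
        """Scaling one library and renormalizing restores the table shape.

        The median-of-ratios reference (per-feature geometric mean) absorbs a
        per-library factor c up to a single global constant c^(1/S); all
        normalized values therefore agree up to that one constant, which
        cancels in every downstream ratio.
        """
        rng = np.random.default_rng(5)
        mat = rng.integers(1, 300, size=(40, 4))
        base = _table(mat)
        scaled_mat = mat.copy()
        scaled_mat[:, 2] = scaled_mat[:, 2] * 3
        scaled = _table(scaled_mat)
        a = normalize(base, size_factors(base)).values
        b = normalize(scaled, size_factors(scaled)).values
        lam = b[0, 0] / a[0, 0]
        assert np.allclose(b, lam * a, rtol=1e-9)


class TestLog2FC:
    def test_basic_values(self):
        assert log2fc(4, 2) == 1.0
        assert log2fc(3.7, 3.7) == 0.0

    def test_ratio_arithmetic_on_stress_response_example(self):
        # control ratio 5.51 -> treatment ratio 21.61 is a 1.97 log2 shift
        assert math.isclose(log2fc(21.61, 5.51), 1.9716, abs_tol=5e-4)

    def test_non_positive_rejected(self):
        with pytest.raises(DataError):
            log2fc(0.0, 1.0)


def _records(log2fcs, zero_mask=None):
    n = len(log2fcs)
    zero_mask = zero_mask or [False] * n
    df = pd.DataFrame(
        {
            "uorf_id": [f"t{i:05d}.u1" for i in range(n)],
            "transcript_id": [f"t{i:05d}" for i in range(n)],
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "R_ctrl": 1.0,
            "R_tx": [2.0**x for x in log2fcs],
            "log2FC": log2fcs,
            "raw_uorf_zero": zero_mask,
        }
    )
    return df.set_index("uorf_id", drop=False).rename_axis(None)


class TestFlagQuantiles:
    def test_tail_sizes_round_half_up(self):
        rng = np.random.default_rng(0)
        flagged = flag_quantiles(_records(rng.normal(0, 1, 939)), QuantileConfig())
        assert (flagged["flag"] == "strongest_change").sum() == 47
        assert (flagged["flag"] == "least_change").sum() == 47

    def test_zero_count_uorfs_not_ranked(self):
        rng = np.random.default_rng(1)
        fc = rng.normal(0, 1, 1933)
        mask = [i < 55 for i in range(1933)]  # 55 never-covered uORFs
        flagged = flag_quantiles(_records(fc, mask), QuantileConfig())
        assert (flagged["flag"] == "strongest_change").sum() == 94
        assert (flagged.loc[flagged["raw_uorf_zero"], "flag"] == "none").all()

    def test_strongest_are_the_largest_absolute_changes(self):
        fc = [0.1, -3.0, 2.5, 0.0, -0.2, 1.0] * 10
        flagged = flag_quantiles(_records(fc), QuantileConfig(q=0.1))
        strongest = flagged[flagged["flag"] == "strongest_change"]
        rest = flagged[flagged["flag"] != "strongest_change"]
        assert strongest["log2FC"].abs().min() >= rest["log2FC"].abs().max() - 1e-12
        least = flagged[flagged["flag"] == "least_change"]
        assert least["log2FC"].abs().max() <= 0.1 + 1e-12

    def test_ties_break_deterministically_on_id(self):
        flagged = flag_quantiles(_records([1.0] * 40), QuantileConfig())
        strongest = sorted(flagged.index[flagged["flag"] == "strongest_change"])
        assert strongest == ["t00000.u1", "t00001.u1"]


def _fitted(seed=0, n=50, effect_ids=(), pseudocount=1.0):
    rng = np.random.default_rng(seed)
    cds = rng.integers(50, 400, size=(n, 4))
    uorf = rng.integers(40, 80, size=(n, 4))
    for i in effect_ids:
        uorf[i, 2:] = 1  # near-total loss of uORF occupancy in treatment
    cds_t = CountTable([f"t{i}" for i in range(n)], ["c1", "c2", "x1", "x2"], cds)
    uorf_t = CountTable(
        [f"t{i}.u1" for i in range(n)], ["c1", "c2", "x1", "x2"], uorf, "uORF"
    )
    design = ConditionDesign(
        {"c1": "ctrl", "c2": "ctrl", "x1": "tx", "x2": "tx"}, "ctrl", "tx"
    )
    model = UorfRatioModel(
        cds_t, uorf_t, design, QuantileConfig(pseudocount=pseudocount)
    )
    return model, model.fit()


class TestModelFit:
    def test_condition_ratio_definition(self):
        cds = CountTable(["t0"], ["a", "b"], np.array([[100, 100]]))
        uorf = CountTable(["t0.u1"], ["a", "b"], np.array([[10, 0]]), "uORF")
        design = ConditionDesign({"a": "ctrl", "b": "tx"}, "ctrl", "tx")
        res = UorfRatioModel(cds, uorf, design).fit()
        rec = res.records.iloc[0]
        # size factors are computed on the CDS table: both samples identical
        assert rec["R_ctrl"] == pytest.approx(101 / 11)
        assert rec["R_tx"] == pytest.approx(101 / 1)  # zero uORF mean: pseudocount only
        assert rec["log2FC"] == pytest.approx(math.log2(101) - math.log2(101 / 11))

    def test_antisymmetry_under_condition_swap(self):
        model, res = _fitted(seed=2)
        swapped = UorfRatioModel(
            model.cds_counts, model.uorf_counts, model.design.swapped(),
            model.quantiles,
        ).fit()
        assert np.allclose(
            res.records["log2FC"], -swapped.records["log2FC"], atol=1e-12
        )

    def test_scale_invariance_of_ratios_and_log2fc(self):
        # pseudocount 0: the global renormalization constant cancels exactly
        model, res = _fitted(seed=3, pseudocount=0.0)
        scaled_cds = model.cds_counts.values.copy()
        scaled_uorf = model.uorf_counts.values.copy()
        scaled_cds[:, 0] *= 7
        scaled_uorf[:, 0] *= 7
        res2 = UorfRatioModel(
            CountTable(model.cds_counts.feature_ids,
                       model.cds_counts.sample_ids, scaled_cds),
            CountTable(model.uorf_counts.feature_ids,
                       model.uorf_counts.sample_ids, scaled_uorf, "uORF"),
            model.design, model.quantiles,
        ).fit()
        for col in ("R_ctrl", "R_tx", "log2FC"):
            assert np.allclose(res.records[col], res2.records[col], atol=1e-9)

    def test_uorf_without_cds_feature_skipped(self):
        cds = CountTable(["tA"], ["a", "b"], np.array([[100, 90]]))
        uorf = CountTable(
            ["tA.u1", "tB.u1"], ["a", "b"], np.array([[10, 9], [5, 4]]), "uORF"
        )
        design = ConditionDesign({"a": "ctrl", "b": "tx"}, "ctrl", "tx")
        res = UorfRatioModel(cds, uorf, design).fit()
        assert list(res.records["uorf_id"]) == ["tA.u1"]
        assert res.n_skipped == 1

    def test_summary_counts_match_direct_recomputation(self):
        _, res = _fitted(seed=4, n=80)
        s = res.summarize()
        fc = res.records["log2FC"].to_numpy()
        assert s["n_negative"] == (fc < 0).sum()
        assert s["n_above_plus1"] == (fc > 1).sum()
        assert s["mean_positive"] == pytest.approx(fc[fc > 0].mean())
        assert s["mean_negative"] == pytest.approx(fc[fc < 0].mean())
        assert "ratio analysis" in res.summary()

    def test_planted_suppression_is_top_ranked(self):
        _, res = _fitted(seed=6, n=60, effect_ids=(7,))
        top = res.records.sort_values(
            "log2FC", key=lambda s: s.abs(), ascending=False
        )
        assert top.iloc[0]["transcript_id"] == "t7"

    def test_write_outputs_round_trip(self, tmp_path):
        _, res = _fitted(seed=5, n=20)
        paths = res.write_outputs(str(tmp_path))
        cds_back = pd.read_csv(paths["cds_norm"], index_col="feature_id")
        assert np.allclose(cds_back.values, res.cds_norm.values, atol=5e-7)
        reg = pd.read_csv(paths["regulation"])
        assert list(reg.columns) == [
            "uorf_id", "transcript_id", "gene_id",
            "R_ctrl", "R_tx", "log2FC", "flag",
        ]
        assert len(reg) == 20

    def test_mismatched_samples_rejected(self):
        cds = CountTable(["t0"], ["a", "b"], np.array([[1, 2]]))
        uorf = CountTable(["t0.u1"], ["a", "c"], np.array([[1, 2]]), "uORF")
        design = ConditionDesign({"a": "ctrl", "b": "tx"}, "ctrl", "tx")
        with pytest.raises(UsageError):
            UorfRatioModel(cds, uorf, design)


class TestConfigs:
    def test_quantile_config_bounds(self):
        with pytest.raises(UsageError):
            QuantileConfig(q=0.6)
        with pytest.raises(UsageError):
            QuantileConfig(pseudocount=-1)

    def test_design_requires_two_conditions(self):
        with pytest.raises(UsageError):
            ConditionDesign({"a": "x", "b": "x"}, "x", "y")
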