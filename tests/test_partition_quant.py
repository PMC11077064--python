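import numpy as np
import pytest

from comphom import (
    ROIStats,
    enrichment_ratio,
    fold_change_series,
    make_roi_series,
    partition_coefficient,
    read_roi_csv,
    summarize_by_stage,
)


def roi(i_chr=1.0, a_chr=1.0, i_cyt=1.0, a_cyt=1.0, cell="c1", t=0.0, stage="metaphase"):
    return ROIStats(cell, t, stage, i_chr, a_chr, i_cyt, a_cyt)


class TestPartitionCoefficient:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(i_chr=1, a_chr=1, i_cyt=1, a_cyt=1), 0.5),
            (dict(i_chr=2, a_chr=1, i_cyt=1, a_cyt=2), 0.5),
            (dict(i_chr=3, a_chr=1, i_cyt=1, a_cyt=1), 0.75),
        ],
    )
    def test_examples(self, kwargs, expected):
        assert partition_coefficient(roi(**kwargs)) == pytest.approx(expected)

    def test_zero_signal_everywhere_rejected(self):
        with pytest.raises(ValueError):
            partition_coefficient(roi(i_chr=0, i_cyt=0))

    def test_intensity_rescaling_invariance(self):
        base = roi(i_chr=3, a_chr=2, i_cyt=1.5, a_cyt=7)
        scaled = roi(i_chr=30, a_chr=2, i_cyt=15, a_cyt=7)
        assert partition_coefficient(base) == pytest.approx(
            partition_coefficient(scaled)
        )

    def test_monotone_in_intensities(self):
        lo = partition_coefficient(roi(i_chr=1))
        hi = partition_coefficient(roi(i_chr=2))
        assert hi > lo
        assert partition_coefficient(roi(i_cyt=2)) < lo

    def test_negative_intensity_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            r = roi(i_chr=-0.5)
        assert r.i_chr == 0.0
        assert "clamped" in caplog.text

    def test_nonpositive_areas_rejected(self):
        with pytest.raises(ValueError):
            roi(a_chr=0)


class TestEnrichmentRatio:
    def test_examples(self):
        assert enrichment_ratio(roi(i_chr=1, i_cyt=1)) == 1.0
        assert enrichment_ratio(roi(i_chr=29, i_cyt=10)) == pytest.approx(2.9)
        assert enrichment_ratio(roi(i_chr=0, i_cyt=5)) == 0.0

    def test_zero_cytosol_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(roi(i_cyt=0))


class TestFoldChange:
    def test_constant_series_is_all_ones(self):
        rows = [roi(t=t, stage=s) for t, s in enumerate(["metaphase", "anaphase", "telophase"])]
        out = fold_change_series(rows)
        assert np.allclose(out.fold_change, 1.0)

    def test_doubling_gives_fold_change_two(self):
        rows = [
            roi(i_chr=1, t=0, stage="metaphase"),
            roi(i_chr=3, a_cyt=1 / 3, t=1, stage="telophase"),
        ]
        # partitions: 0.5 and 0.75/ (0.75+...)  -> use enrichment metric instead
        out = fold_change_series(rows, metric="enrichment")
        assert out.fold_change.iloc[1] == pytest.approx(3.0)

    def test_reference_mean_over_multiple_metaphase_rows(self):
        rows = [
            roi(i_chr=1, a_cyt=1, t=0),  # partition 0.5
            roi(i_chr=3, t=1),  # partition 0.75
            roi(i_chr=4, a_chr=1, i_cyt=1, a_cyt=0.0001, t=2, stage="telophase"),
        ]
        out = fold_change_series(rows)
        ref = (0.5 + 0.75) / 2
        assert out.fold_change.iloc[0] == pytest.approx(0.5 / ref)
        assert np.isclose(out.loc[out.stage == "metaphase", "fold_change"].mean(), 1.0)

    def test_missing_reference_stage_names_cell(self):
        rows = [roi(stage="telophase", cell="c9")]
        with pytest.raises(ValueError, match="c9"):
            fold_change_series(rows)

    def test_multiple_cells_rejected(self):
        rows = [roi(cell="a"), roi(cell="b")]
        with pytest.raises(ValueError):
            fold_change_series(rows)


class TestSummarizeByStage:
    def test_identical_cells_have_zero_sd(self):
        rows = []
        for c in ("a", "b", "c"):
            rows += [roi(cell=c, stage="metaphase"), roi(cell=c, i_chr=3, stage="telophase")]
        out = summarize_by_stage(rows)
        assert np.allclose(out.sd, 0.0)
        assert out.attrs["p_value"] < 1e-6 or out["mean"].iloc[0] != out["mean"].iloc[1]

    def test_equal_stage_means_give_p_near_one(self):
        rows = []
        for i, c in enumerate(("a", "b", "c")):
            jitter = 1.0 + 0.1 * i
            rows += [
                roi(cell=c, i_chr=jitter, stage="metaphase"),
                roi(cell=c, i_chr=jitter, stage="telophase"),
            ]
        out = summarize_by_stage(rows)
        assert out.attrs["p_value"] > 0.99

    def test_matches_textbook_pooled_t(self):
        """Hand-built 3-cell case against the closed-form pooled t."""
        meta = [0.2, 0.3, 0.25]
        telo = [0.5, 0.6, 0.58]
        rows = []
        for i, (m, t) in enumerate(zip(meta, telo)):
            c = f"c{i}"
            rows.append(roi(cell=c, i_chr=m, a_chr=1, i_cyt=1 - m, a_cyt=1, stage="metaphase"))
            rows.append(roi(cell=c, i_chr=t, a_chr=1, i_cyt=1 - t, a_cyt=1, stage="telophase", t=1))
        out = summarize_by_stage(rows)
        x, y = np.array(meta), np.array(telo)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert out.attrs["t_statistic"] == pytest.approx(t_oracle, abs=1e-9)
        assert out["mean"].iloc[0] == pytest.approx(x.mean())
        assert out["sd"].iloc[1] == pytest.approx(y.std(ddof=1))

    def test_single_cell_per_stage_rejected(self):
        rows = [roi(cell="a"), roi(cell="a", stage="telophase")]
        with pytest.raises(ValueError):
            summarize_by_stage(rows)


class TestRoundTripAndRecovery:
    def test_csv_round_trip(self, tmp_path):
        rows = make_roi_series(3, {"metaphase": 0.3, "telophase": 0.6}, 0.05, seed=2)
        import dataclasses

        import pandas as pd

        path = tmp_path / "rois.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(path, index=False)
        back = read_roi_csv(path)
        assert len(back) == len(rows)
        assert back[0] == rows[0]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("cell_id,timepoint\nc1,0\n")
        with pytest.raises(ValueError, match="missing"):
            read_roi_csv(path)

    def test_programmed_stage_effect_recovered(self):
        rows = make_roi_series(
            20, {"metaphase": 0.24, "telophase": 0.56}, noise_cv=0.1, seed=31
        )
        out = summarize_by_stage(rows)
        for stage, target in (("metaphase", 0.24), ("telophase", 0.56)):
            row = out[out.stage == stage].iloc[0]
            assert abs(row["mean"] - target) <= 2 * max(row["sd"], 1e-9)
        assert out.attrs["p_value"] < 1e-6
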