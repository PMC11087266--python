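"""Seeding arithmetic, ROUT outliers, correlation and report bundle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import orgzone as oz


def test_pbmc_seeding_reproduces_the_dome_examples():
    plan = oz.pbmc_seeding(10, 1)
    assert plan.pbmcs_needed == 220_000
    assert plan.epithelial_cells == 200_000
    assert plan.et_ratio == (1.1, 1.0)
    assert oz.pbmc_seeding(25, 1).pbmcs_needed == 550_000
    assert oz.pbmc_seeding(25, 1).epithelial_cells == 500_000
    assert oz.pbmc_seeding(0, 5).pbmcs_needed == 0
    with pytest.raises(ValueError):
        oz.pbmc_seeding(-1, 1)
    with pytest.raises(ValueError):
        oz.pbmc_seeding(10, -2)


@given(st.integers(min_value=0, max_value=1000), st.integers(min_value=0, max_value=96))
def test_pbmc_seeding_is_exact_integer_arithmetic(volume, n):
    plan = oz.pbmc_seeding(volume, n)
    assert plan.pbmcs_needed == volume * 22_000 * n
    assert isinstance(plan.pbmcs_needed, int)


def test_rout_flags_a_gross_outlier_and_partitions_the_sample():
    res = oz.rout_outliers([1.0, 1.0, 1.0, 1.0, 1.0, 100.0])
    assert list(res.flagged) == [100.0]
    assert sorted(np.concatenate([res.kept, res.flagged])) == sorted(
        [1.0, 1.0, 1.0, 1.0, 1.0, 100.0])
    assert res.center == 1.0


def test_rout_is_permutation_invariant():
    rng = np.random.default_rng(3)
    values = np.concatenate([rng.normal(0, 1, 50), [8.0, -9.0]])
    flagged = sorted(oz.rout_outliers(values).flagged)
    for _ in range(5):
        rng.shuffle(values)
        assert sorted(oz.rout_outliers(values).flagged) == flagged


def test_rout_input_validation():
    with pytest.raises(ValueError):
        oz.rout_outliers([1.0, 2.0])
    with pytest.raises(ValueError):
        oz.rout_outliers([1.0, 2.0, 3.0], q=0.6)


def test_linreg_r2_exact_fit_and_affine_invariance():
    x = np.arange(10.0)
    slope, intercept, r2 = oz.linreg_r2(x, 2 * x + 1)
    assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))
    rng = np.random.default_rng(0)
    y = 3 * x + rng.normal(0, 1, 10)
    _, _, r2a = oz.linreg_r2(x, y)
    _, _, r2b = oz.linreg_r2(5 * x - 2, 0.1 * y + 7)
    assert r2a == pytest.approx(r2b)
    # independent y: R2 near zero for large n
    xn = np.arange(2000.0)
    _, _, r2n = oz.linreg_r2(xn, rng.normal(0, 1, 2000))
    assert r2n < 0.01
    with pytest.raises(ValueError):
        oz.linreg_r2(np.ones(5), np.arange(5.0))


def _toy_tables():
    counts = pd.DataFrame({
        "condition": ["EpCAM"] * 2 + ["NT"] * 2,
        "timepoint_h": [24.0, 24.0, 24.0, 24.0],
        "object_id": [1, 1, 1, 1],
        "zone": [2, 3, 2, 3],
        "phenotype": ["CD4", "CD8", "CD4", "CD8"],
        "count": [5, 3, 1, 2],
    })
    killing = pd.DataFrame({
        "condition": ["EpCAM", "NT", "EpCAM", "NT"],
        "timepoint_h": [24.0, 24.0, 48.0, 48.0],
        "mean_afu": [300.0, 100.0, 500.0, 125.0],
    })
    killing = oz.normalize_to_control(killing)
    integrity = pd.DataFrame({
        "condition": ["EpCAM", "NT"],
        "timepoint_h": [24.0, 24.0],
        "fraction_panck": [0.4, 0.95],
        "fraction_caspase": [0.55, 0.02],
        "fraction_other": [0.05, 0.03],
    })
    return counts, killing, integrity


def test_report_matches_hand_computed_fold_matrix(tmp_path):
    counts, killing, integrity = _toy_tables()
    report = oz.build_report(counts, killing, integrity, outdir=tmp_path / "a")
    fm = report["fold_matrix"].set_index("condition")
    assert fm.loc["EpCAM", "t24h"] == pytest.approx(3.0)
    assert fm.loc["EpCAM", "t48h"] == pytest.approx(4.0)
    assert fm.loc["NT", "t24h"] == 1.0
    zc = report["zone_counts"]
    row = zc[(zc.condition == "EpCAM") & (zc.phenotype == "CD4")]
    assert row["zone_2"].item() == 5
    # byte-identical reruns
    oz.build_report(counts, killing, integrity, outdir=tmp_path / "b")
    for name in ("zone_counts", "fold_matrix", "integrity_summary"):
        a = (tmp_path / "a" / f"{name}.csv").read_bytes()
        b = (tmp_path / "b" / f"{name}.csv").read_bytes()
        assert a == b


def test_report_handles_empty_inputs_and_key_mismatches():
    report = oz.build_report(None, None, None)
    assert set(report) == {"zone_counts", "fold_matrix", "integrity_summary"}
    assert all(len(df) == 0 for df in report.values())
    counts, killing, _ = _toy_tables()
    bad = killing.assign(condition=killing["condition"].replace("EpCAM", "CEA"))
    with pytest.raises(ValueError, match="CEA"):
        oz.build_report(counts, bad)


def test_stat_wrappers_pass_through():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
    assert oz.ttest_two_sample(a, b).pvalue < 1e-6
    assert oz.anova_oneway(a, b, rng.normal(0, 1, 30)).pvalue < 1e-6
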