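"""Generator: determinism, geometry truth, infiltration and caspase kinetics."""

import dataclasses
import math

import numpy as np
import pytest

import orgzone as oz
from orgzone.synthgen import CHANNELS, apoptotic_fraction, true_zone


def test_counts_match_config_and_seed_is_bit_deterministic(small_config):
    fields_a, truth_a = oz.generate_field(small_config)
    fields_b, truth_b = oz.generate_field(small_config)
    assert len(fields_a) == len(small_config.timepoints_h)
    assert len(truth_a.objects) == small_config.n_organoids
    for t in small_config.timepoints_h:
        assert (truth_a.cells["timepoint_h"] == t).sum() == small_config.n_immune_cells
    for fa, fb in zip(fields_a, fields_b):
        for name in CHANNELS:
            assert fa.channels[name].dtype == np.uint16
            assert np.array_equal(fa.channels[name], fb.channels[name])
    assert truth_a.cells.equals(truth_b.cells)


def test_zero_infiltration_rate_freezes_positions(small_config):
    cfg = dataclasses.replace(small_config, infiltration_rate=0.0)
    _, truth = oz.generate_field(cfg)
    ref = truth.positions(cfg.timepoints_h[0])
    for t in cfg.timepoints_h[1:]:
        assert np.array_equal(ref, truth.positions(t))
    # zones identical at all timepoints as well
    zones = truth.cells.pivot(index="cell_id", columns="timepoint_h", values="zone")
    assert (zones.nunique(axis=1) == 1).all()


def test_rate_one_infiltrates_every_cell_in_one_step():
    cfg = oz.SynthConfig(field_size_px=(768, 768), n_organoids=1,
                         radius_range_um=(55.0, 60.0), n_immune_cells=20,
                         infiltration_rate=1.0, timepoints_h=(0.0, 24.0), seed=4)
    _, truth = oz.generate_field(cfg)
    t24 = truth.cells[truth.cells["timepoint_h"] == 24.0]
    assert t24["zone"].isin([1, 2]).all()


def test_infiltrated_fraction_matches_binomial_expectation():
    # one 24 h step at rate 0.5 is a Bernoulli(0.5) trial per cell
    cfg = oz.SynthConfig(field_size_px=(2048, 2048), n_organoids=12,
                         n_immune_cells=1000, infiltration_rate=0.5,
                         timepoints_h=(0.0, 24.0), seed=7)
    _, truth = oz.generate_field(cfg)
    t24 = truth.cells[truth.cells["timepoint_h"] == 24.0]
    infiltrated = int(t24["zone"].isin([1, 2]).sum())
    n, p = 1000, 0.5
    se = math.sqrt(n * p * (1 - p))
    assert abs(infiltrated - n * p) <= 3 * se


def test_mean_infiltrated_count_nondecreasing_over_seeds(small_config):
    per_tp = np.zeros(len(small_config.timepoints_h))
    for seed in range(20):
        cfg = oz.synthgen.with_seed(small_config, seed)
        _, truth = oz.generate_field(cfg)
        for i, t in enumerate(cfg.timepoints_h):
            sub = truth.cells[truth.cells["timepoint_h"] == t]
            count = int(sub["zone"].isin([1, 2]).sum())
            per_tp[i] += count
        # within one run, infiltrated cells never leave
        series = [int(truth.cells[truth.cells["timepoint_h"] == t]["zone"]
                      .isin([1, 2]).sum()) for t in cfg.timepoints_h]
        assert all(a <= b for a, b in zip(series, series[1:]))
    assert all(a <= b for a, b in zip(per_tp, per_tp[1:]))
    assert per_tp[-1] > per_tp[0]


def test_stored_zones_match_independent_distance_oracle(small_config):
    """Re-derive each cell's zone from the analytic circle geometry."""
    _, truth = oz.generate_field(small_config)
    obj = truth.objects.iloc[0]
    px = small_config.pixel_size_um_per_px
    for _, cell in truth.cells.iterrows():
        d = math.hypot(cell["row_px"] - obj["row_px"],
                       cell["col_px"] - obj["col_px"]) * px
        g = d - obj["radius_um"]
        if g <= 0:
            expected = 2 if g >= -25.0 else 1
        elif g <= 25.0:
            expected = 3
        elif g <= 50.0:
            expected = 4
        else:
            expected = 0
        assert cell["zone"] == expected


def test_step_infiltration_appends_timepoint_and_is_monotone(small_config):
    _, truth = oz.generate_field(small_config)
    before = int(truth.cells[truth.cells["timepoint_h"] == 72.0]["zone"]
                 .isin([1, 2]).sum())
    stepped = oz.step_infiltration(truth, rate=1.0, dt_h=24.0, rng=0)
    assert stepped.cells["timepoint_h"].max() == 96.0
    after = int(stepped.cells[stepped.cells["timepoint_h"] == 96.0]["zone"]
                .isin([1, 2]).sum())
    assert after >= before


def test_caspase_render_matches_closed_form(small_config):
    cfg = dataclasses.replace(small_config, caspase_rate=0.5, noise_sd=0.0)
    _, truth = oz.generate_field(cfg)
    for t_h, expected in [(0.0, 0.0), (24.0, 0.5), (48.0, 0.75)]:
        raster = oz.render_caspase(truth, rate=0.5, t_h=t_h)
        bright = int((raster > 1500).sum())
        shell = int((raster > 100).sum())   # baseline + bright epithelium
        assert bright / shell == pytest.approx(expected, abs=0.01)
    assert apoptotic_fraction(0.5, 48.0) == pytest.approx(0.75)
    # limit cases
    assert (oz.render_caspase(truth, rate=0.0, t_h=72.0) > 1500).sum() == 0
    full = oz.render_caspase(truth, rate=1.0, t_h=24.0)
    assert int((full > 100).sum()) == int((full > 1500).sum())


def test_true_zone_handles_contested_and_empty_fields(small_config):
    _, truth = oz.generate_field(small_config)
    empty = truth.objects.iloc[:0]
    assert true_zone(10, 10, empty, 0.5) == (-1, 0)
    # a point in the outward bands of two synthetic objects is 'outside'
    import pandas as pd
    two = pd.DataFrame({"object_id": [0, 1], "row_px": [100.0, 100.0],
                        "col_px": [100.0, 260.0], "radius_um": [30.0, 30.0],
                        "lumen_radius_um": [5.0, 5.0],
                        "object_class": "organoid", "perturb_phase": 0.0})
    # centre point is 40 um from both boundaries (gap 20 um at 0.5 um/px)
    assert true_zone(100, 180, two, 0.5) == (-1, 0)


def test_invalid_configs_are_rejected(small_config):
    with pytest.raises(ValueError):
        oz.generate_field(dataclasses.replace(small_config, infiltration_rate=1.5))
    with pytest.raises(ValueError):
        oz.generate_field(dataclasses.replace(small_config, caspase_rate=-0.1))
    with pytest.raises(ValueError):
        oz.generate_field(dataclasses.replace(
            small_config, radius_range_um=(300.0, 300.0)))
    with pytest.raises(RuntimeError):
        # far too many large objects for the field
        oz.generate_field(dataclasses.replace(small_config, n_organoids=30))
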