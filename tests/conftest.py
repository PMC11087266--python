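import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import orgzone as oz
from orgzone.objects import OrganoidObject

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def disk_object():
    """Factory for a rasterized disk ROI with an analytic area oracle."""

    def make(radius_um, pixel_size_um=0.5, label=1, shape=None, center=None):
        rpx = radius_um / pixel_size_um
        if shape is None:
            n = 2 * (int(math.ceil(rpx)) + int(math.ceil(2 * 25.0 / pixel_size_um)) + 4) + 1
            shape = (n, n)
        if center is None:
            center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= rpx * rpx
        return OrganoidObject(label=label, mask=mask, origin=(0, 0),
                              field_shape=shape, pixel_size_um=pixel_size_um)

    return make


@pytest.fixture
def small_config():
    """Fast single-organoid time course used by most pipeline tests."""
    return oz.SynthConfig(field_size_px=(768, 768), n_organoids=1,
                          radius_range_um=(50.0, 60.0), n_immune_cells=40,
                          infiltration_rate=0.4, caspase_rate=0.3, seed=0)


@pytest.fixture
def recover_counts():
    """Run the full pipeline on one seeded field and compare to ground truth.

    Returns a callable mapping a seed to the list of per-timepoint
    (measured, truth) count-table pairs, with measured object labels mapped
    onto ground-truth ids by centroid matching.
    """

    def run(seed, config=None):
        cfg = config or oz.SynthConfig(seed=seed)
        cfg = oz.synthgen.with_seed(cfg, seed)
        fields, truth = oz.generate_field(cfg)
        thresholds = oz.negative_control_thresholds(oz.blank_control_field(cfg))
        objs = oz.segment_field(fields[0])
        zsets = oz.resolve_overlaps([oz.build_zones(o) for o in objs])
        mapping = truth.match_objects(objs)
        for zs in zsets:
            zs.object_id = mapping[zs.object_id]
        pairs = []
        for t, field in zip(cfg.timepoints_h, fields):
            res = oz.analyze_field(field, thresholds, zonesets=zsets)
            cols = ["object_id", "zone", "phenotype", "count"]
            meas = (res.counts[cols].sort_values(cols[:3])
                    .reset_index(drop=True))
            tru = (truth.zone_occupancy(t).sort_values(cols[:3])
                   .reset_index(drop=True))
            tru["count"] = tru["count"].astype(meas["count"].dtype)
            pairs.append((meas, tru))
        return pairs

    return run


def assert_frames_equal(meas, tru):
    pd.testing.assert_frame_equal(meas, tru)
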