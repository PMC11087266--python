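"""Concentric zones: analytic annulus oracle, partition identity, overlaps."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

import orgzone as oz
from orgzone.objects import OrganoidObject


def _annulus_area(r_in, r_out):
    return math.pi * (r_out ** 2 - r_in ** 2)


def test_disk_zone_areas_match_annulus_formulas(disk_object):
    obj = disk_object(100.0)
    zs = oz.build_zones(obj, margin_um=25.0)
    areas = zs.areas_um2()
    expected = {1: math.pi * 75 ** 2, 2: _annulus_area(75, 100),
                3: _annulus_area(100, 125), 4: _annulus_area(125, 150)}
    for z in (1, 2, 3, 4):
        assert areas[z] == pytest.approx(expected[z], rel=0.02)
    assert int(zs.zones[1].sum() + zs.zones[2].sum()) == int(obj.mask.sum())


@pytest.mark.parametrize("radius_um", [20.0, 40.0, 100.0])
def test_zones_partition_roi_exactly_and_are_disjoint(disk_object, radius_um):
    zs = oz.build_zones(disk_object(radius_um))
    n_roi = int(disk_object(radius_um).mask.sum())
    assert int(zs.zones[1].sum() + zs.zones[2].sum()) == n_roi
    for a in (1, 2, 3, 4):
        for b in (1, 2, 3, 4):
            if a < b:
                assert not (zs.zones[a] & zs.zones[b]).any()


def test_roi_thinner_than_margin_has_empty_interior(disk_object):
    zs = oz.build_zones(disk_object(20.0))
    assert zs.areas_um2()[1] == 0.0
    assert int(zs.zones[2].sum()) == int(disk_object(20.0).mask.sum())


def test_centred_disk_zones_are_rotation_invariant(disk_object):
    zs = oz.build_zones(disk_object(60.0))
    for z in (1, 2, 3, 4):
        assert np.array_equal(zs.zones[z], np.rot90(np.asarray(zs.zones[z])))


def test_zone_areas_are_translation_invariant(disk_object):
    a = oz.build_zones(disk_object(40.0, shape=(601, 601), center=(300.0, 300.0)))
    b = oz.build_zones(disk_object(40.0, shape=(601, 601), center=(217.0, 389.0)))
    assert a.areas_um2() == b.areas_um2()


def test_raster_assignment_matches_analytic_circle_oracle(disk_object):
    radius, px = 80.0, 0.5
    obj = disk_object(radius, pixel_size_um=px)
    zs = oz.build_zones(obj)
    c = ((obj.field_shape[0] - 1) / 2.0, (obj.field_shape[1] - 1) / 2.0)
    rng = np.random.default_rng(0)
    checked = 0
    for _ in range(300):
        r = rng.uniform(0, obj.field_shape[0] - 1)
        q = rng.uniform(0, obj.field_shape[1] - 1)
        d = math.hypot(r - c[0], q - c[1]) * px
        g = d - radius
        if g <= 0:
            expected = 2 if g >= -25 else 1
        elif g <= 25:
            expected = 3
        elif g <= 50:
            expected = 4
        else:
            expected = 0
        boundary_dist = min(abs(g + 25), abs(g), abs(g - 25), abs(g - 50))
        if boundary_dist <= px:      # within one pixel of a zone boundary
            continue
        assert zs.zone_at(int(round(r)), int(round(q))) == expected
        checked += 1
    assert checked >= 100


def _two_disks(gap_um, radius_um=50.0, px=0.5):
    h, w = 600, 900
    c1 = (300.0, 250.0)
    c2 = (300.0, 250.0 + (2 * radius_um + gap_um) / px)
    yy, xx = np.mgrid[0:h, 0:w]
    objs = []
    for lab, (cy, cx) in enumerate([c1, c2], start=1):
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= (radius_um / px) ** 2
        objs.append(OrganoidObject(label=lab, mask=m, origin=(0, 0),
                                   field_shape=(h, w), pixel_size_um=px))
    return objs


def test_contested_outward_pixels_are_deleted_from_both_objects():
    objs = _two_disks(gap_um=30.0)
    resolved = oz.resolve_overlaps([oz.build_zones(o) for o in objs])
    # independent oracle: per-pixel distance to each ROI via KD-trees
    trees = [cKDTree(np.argwhere(o.mask)) for o in objs]
    background = np.argwhere(~(objs[0].mask | objs[1].mask))
    d1 = trees[0].query(background)[0] * 0.5
    d2 = trees[1].query(background)[0] * 0.5
    contested = background[(d1 > 0) & (d1 <= 50) & (d2 > 0) & (d2 <= 50)]
    assert len(contested) > 0
    claimed = np.zeros((600, 900), bool)
    for zs in resolved:
        for z in (1, 2, 3, 4):
            claimed |= zs.full(z)
    assert not claimed[tuple(contested.T)].any()
    # pixels claimed by exactly one object survive
    only_first = background[(d1 > 0) & (d1 <= 25) & (d2 > 50)]
    assert all(resolved[0].zone_at(r, c) == 3 for r, c in only_first[::500])
    # inner zones untouched
    for before, after in zip([oz.build_zones(o) for o in objs], resolved):
        assert np.array_equal(before.zones[1], after.zones[1])
        assert np.array_equal(before.zones[2], after.zones[2])


def test_far_apart_or_single_objects_lose_no_pixels():
    objs = _two_disks(gap_um=120.0)
    zsets = [oz.build_zones(o) for o in objs]
    resolved = oz.resolve_overlaps(zsets)
    for before, after in zip(zsets, resolved):
        for z in (1, 2, 3, 4):
            assert np.array_equal(before.zones[z], after.zones[z])
    single = oz.resolve_overlaps([zsets[0]])
    for z in (1, 2, 3, 4):
        assert np.array_equal(single[0].zones[z], zsets[0].zones[z])
    assert oz.resolve_overlaps([]) == []


def test_zone_label_raster_encodes_object_and_zone(disk_object):
    obj = disk_object(40.0)
    resolved = oz.resolve_overlaps([oz.build_zones(obj)])
    raster = oz.zone_label_raster(resolved)
    c = int((obj.field_shape[0] - 1) / 2)
    assert raster[c, c] == obj.label * 10 + 1
    assert set(np.unique(raster)) <= {0, 11, 12, 13, 14}
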