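"""Concentric-zone partition around each epithelial object.

Each object's filled ROI is partitioned into four zones by exact Euclidean
distance transforms scaled to micrometres: zone 1 is the object interior
(deeper than one margin from the boundary), zone 2 the epithelial-barrier
band (within one margin inside the boundary), and zones 3 and 4 the proximal
and distal extracellular bands (one margin each, outward).  The default
margin is 25 um.  Outward-zone pixels claimed by more than one object, or
lying inside another object's ROI, are deleted from all claimants; cells on
deleted pixels are counted in no zone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

log = logging.getLogger(__name__)

DEFAULT_MARGIN_UM = 25.0

ZONE_IDS = (1, 2, 3, 4)


@dataclass
class ZoneSet:
    """The four zone rasters of one object, cropped to a common window.

    ``zones`` maps zone id (1-4) to a boolean raster of identical shape,
    positioned at ``origin`` within ``field_shape``.  Zones are pairwise
    disjoint and zone1 | zone2 equals the ROI exactly, pixelwise.
    """

    object_id: int
    zones: dict
    origin: tuple
    field_shape: tuple
    margin_um: float
    pixel_size_um: float

    @property
    def window(self):
        r0, c0 = self.origin
        h, w = next(iter(self.zones.values())).shape
        return (slice(r0, r0 + h), slice(c0, c0 + w))

    def roi(self):
        return self.zones[1] | self.zones[2]

    def areas_um2(self):
        a = self.pixel_size_um ** 2
        return {z: float(self.zones[z].sum()) * a for z in ZONE_IDS}

    def zone_at(self, row, col):
        """Zone id at a field pixel, 0 if this object claims no zone there."""
        r0, c0 = self.origin
        h, w = next(iter(self.zones.values())).shape
        r, c = int(row) - r0, int(col) - c0
        if not (0 <= r < h and 0 <= c < w):
            return 0
        for z in ZONE_IDS:
            if self.zones[z][r, c]:
                return z
        return 0

    def full(self, zone):
        out = np.zeros(self.field_shape, bool)
        out[self.window] = self.zones[zone]
        return out


def build_zones(obj, margin_um=DEFAULT_MARGIN_UM):
    """Concentric partition of one object: one inward, two outward margins.

    With ``d_in`` the exact Euclidean distance (um) of an ROI pixel to the
    nearest background pixel and ``d_out`` the distance of a background pixel
    to the nearest ROI pixel:

    - zone 2: ROI with ``d_in <= margin`` (epithelial barrier band)
    - zone 1: ROI with ``d_in > margin`` (interior; may be empty for thin ROIs)
    - zone 3: background with ``0 < d_out <= margin``
    - zone 4: background with ``margin < d_out <= 2 * margin``

    Ties at exactly one margin go to the band nearer the boundary, keeping
    the partition deterministic.  Zones are computed per object independently
    of any neighbours; use :func:`resolve_overlaps` afterwards.
    """
    if margin_um <= 0:
        raise ValueError("margin_um must be positive")
    px = obj.pixel_size_um
    pad = int(math.ceil(2 * margin_um / px)) + 2
    r0 = max(obj.origin[0] - pad, 0)
    c0 = max(obj.origin[1] - pad, 0)
    r1 = min(obj.origin[0] + obj.mask.shape[0] + pad, obj.field_shape[0])
    c1 = min(obj.origin[1] + obj.mask.shape[1] + pad, obj.field_shape[1])
    m = np.zeros((r1 - r0, c1 - c0), bool)
    m[obj.origin[0] - r0:obj.origin[0] - r0 + obj.mask.shape[0],
      obj.origin[1] - c0:obj.origin[1] - c0 + obj.mask.shape[1]] = obj.mask
    d_in = ndi.distance_transform_edt(m) * px
    d_out = ndi.distance_transform_edt(~m) * px
    zone2 = m & (d_in <= margin_um)
    zone1 = m & ~zone2
    zone3 = ~m & (d_out <= margin_um)
    zone4 = ~m & (d_out > margin_um) & (d_out <= 2 * margin_um)
    if not zone1.any():
        log.info("object %d: ROI thinner than the margin everywhere, zone 1 empty",
                 obj.label)
    return ZoneSet(object_id=obj.label,
                   zones={1: zone1, 2: zone2, 3: zone3, 4: zone4},
                   origin=(r0, c0), field_shape=obj.field_shape,
                   margin_um=margin_um, pixel_size_um=px)


def resolve_overlaps(zonesets):
    """Delete contested outward-zone pixels, per the assay's overlap rule.

    Any background pixel claimed by the outward zones (3 or 4) of two or more
    objects is removed from every claimant, and any outward-zone pixel lying
    inside another object's ROI is removed.  Inner zones (1 and 2) are never
    modified; results are independent of the processing order.
    """
    if not zonesets:
        return []
    shape = zonesets[0].field_shape
    claims = np.zeros(shape, np.int16)
    roi_count = np.zeros(shape, np.int16)
    for zs in zonesets:
        win = zs.window
        claims[win] += (zs.zones[3] | zs.zones[4]).astype(np.int16)
        roi_count[win] += zs.roi().astype(np.int16)
    contested = claims >= 2
    out = []
    for zs in zonesets:
        win = zs.window
        own_roi = zs.roi()
        other_roi = (roi_count[win] - own_roi.astype(np.int16)) >= 1
        bad = contested[win] | other_roi
        new_zones = {1: zs.zones[1].copy(), 2: zs.zones[2].copy(),
                     3: zs.zones[3] & ~bad, 4: zs.zones[4] & ~bad}
        n_del = int((zs.zones[3] & bad).sum() + (zs.zones[4] & bad).sum())
        if n_del:
            log.info("object %d: deleted %d contested outward-zone pixels",
                     zs.object_id, n_del)
        out.append(ZoneSet(object_id=zs.object_id, zones=new_zones,
                           origin=zs.origin, field_shape=zs.field_shape,
                           margin_um=zs.margin_um, pixel_size_um=zs.pixel_size_um))
    return out


def zone_areas(zoneset):
    """Zone areas in um2 (pixel counts times squared pixel size)."""
    return zoneset.areas_um2()


def zone_areas_table(zonesets):
    rows = []
    for zs in zonesets:
        areas = zs.areas_um2()
        for z in ZONE_IDS:
            rows.append((zs.object_id, z, areas[z]))
    return pd.DataFrame(rows, columns=["object_id", "zone", "area_um2"])


def zone_of_point(zonesets, row, col):
    """(object_id, zone) claiming a field pixel, or (-1, 0) if none.

    After :func:`resolve_overlaps` at most one object claims any pixel.
    """
    for zs in zonesets:
        z = zs.zone_at(row, col)
        if z:
            return zs.object_id, z
    return -1, 0


def zone_label_raster(zonesets, encode=None):
    """Integer raster encoding object and zone, default ``object_id * 10 + zone``.

    Intended for resolved zone sets (later objects overwrite earlier ones on
    any remaining shared pixel).
    """
    if not zonesets:
        raise ValueError("no zone sets given")
    if encode is None:
        encode = lambda oid, z: oid * 10 + z
    out = np.zeros(zonesets[0].field_shape, np.int32)
    for zs in zonesets:
        win = zs.window
        for z in ZONE_IDS:
            sub = out[win]
            sub[zs.zones[z]] = encode(zs.object_id, z)
    return out
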