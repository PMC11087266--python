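"""End-to-end orchestration of the zonal co-culture analysis.

One call takes a multi-channel field from raster to tidy tables: epithelium
segmentation (panCK + caspase composite), area filtering, concentric-zone
construction with overlap resolution, nuclear detection, marker phenotyping
against negative-control thresholds, centroid zone assignment and counting,
plus per-object killing records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import objects as _objects
from . import phenotyping as _pheno
from . import quantify as _quant
from . import synthgen as _synth
from . import zones as _zones

log = logging.getLogger(__name__)

#: Channels whose composite carries the epithelial outline.
SEGMENTATION_CHANNELS = ("panCK", "caspase")


@dataclass
class FieldAnalysis:
    """All stage outputs for one field at one timepoint."""

    objects: list
    zonesets: list
    cells: list
    counts: pd.DataFrame
    killing: pd.DataFrame


def blank_control_field(config, seed=None):
    """A signal-free field with the same noise model (negative control)."""
    from dataclasses import replace
    cfg = replace(config, n_organoids=0, n_immune_cells=0,
                  timepoints_h=(0.0,), field_size_px=(256, 256),
                  seed=config.seed if seed is None else seed)
    fields, _ = _synth.generate_field(cfg)
    return fields[0]


def negative_control_thresholds(control_field, channels=None, k=3.0,
                                n_sample=5000, seed=0):
    """Per-channel positivity thresholds from a negative-control field.

    Samples ``n_sample`` pixels per channel and applies the mean + k SD rule,
    mirroring secondary-only control thresholds in multiplexed staining.
    """
    rng = np.random.default_rng(seed)
    channels = channels or list(control_field.channels)
    out = {}
    for name in channels:
        arr = np.asarray(control_field.channels[name], float).ravel()
        idx = rng.choice(arr.size, size=min(n_sample, arr.size), replace=False)
        out[name] = _pheno.threshold_from_negative_control(arr[idx], k=k)
    return out


def segment_field(field, min_area_um2=_objects.MIN_OBJECT_AREA_UM2,
                  object_class="organoid", label_mask=None):
    """Segment and area-filter the epithelial objects of one field.

    With ``label_mask`` given (any external segmenter's output), the baseline
    segmenter is bypassed.
    """
    if label_mask is None:
        composite = sum(np.asarray(field.channels[c], float)
                        for c in SEGMENTATION_CHANNELS)
        label_mask = _objects.segment_baseline(composite, field.pixel_size_um)
    objs = _objects.extract_objects(label_mask, object_class=object_class)
    return _objects.filter_by_area(objs, min_area_um2)


def analyze_field(field, thresholds, margin_um=_zones.DEFAULT_MARGIN_UM,
                  min_area_um2=_objects.MIN_OBJECT_AREA_UM2,
                  object_class="organoid", label_mask=None, zonesets=None):
    """Full zonal analysis of one field; returns a :class:`FieldAnalysis`.

    ``thresholds`` maps marker channel names to positivity thresholds (see
    :func:`negative_control_thresholds`).  Precomputed ``zonesets`` (e.g.
    shared across the timepoints of a fixed geometry) skip segmentation.
    """
    if zonesets is None:
        objs = segment_field(field, min_area_um2, object_class, label_mask)
        zsets = _zones.resolve_overlaps(
            [_zones.build_zones(o, margin_um) for o in objs])
    else:
        objs = []          # geometry supplied by the caller
        zsets = zonesets
    cells = _pheno.detect_nuclei(field.channels["DAPI"], field.pixel_size_um)
    marker_channels = {m: field.channels[m] for m in _pheno.MARKER_PRIORITY
                       if m in field.channels}
    _pheno.measure_intensities(cells, marker_channels, field.pixel_size_um)
    _pheno.call_phenotypes(cells, thresholds)
    _pheno.assign_zones(cells, zsets, field_shape=field.shape)
    areas = {(zs.object_id, z): a for zs in zsets
             for z, a in zs.areas_um2().items()}
    counts = _pheno.tabulate(cells, metadata=field.metadata, zone_areas_um2=areas)
    if objs:
        killing = _quant.object_intensity(field.channels["caspase"], objs,
                                          metadata=field.metadata)
    else:
        killing = pd.DataFrame(columns=["object_id", "area_um2", "mean_afu"])
    return FieldAnalysis(objects=objs or [], zonesets=zsets, cells=cells,
                         counts=counts, killing=killing)


def analyze_timecourse(fields, thresholds, share_geometry=True, **kwargs):
    """Analyze a list of timepoint fields; returns concatenated tables.

    With ``share_geometry`` (sacrificial imaging of a fixed dome), objects
    and zones are segmented on the first field and reused, so zone geometry
    is identical across timepoints.
    """
    if not fields:
        return pd.DataFrame(), pd.DataFrame()
    counts, killing = [], []
    shared = None
    shared_objs = None
    for field in fields:
        if share_geometry and shared is None:
            shared_objs = segment_field(field, kwargs.get(
                "min_area_um2", _objects.MIN_OBJECT_AREA_UM2),
                kwargs.get("object_class", "organoid"))
            shared = _zones.resolve_overlaps(
                [_zones.build_zones(o, kwargs.get("margin_um",
                                                  _zones.DEFAULT_MARGIN_UM))
                 for o in shared_objs])
        res = analyze_field(field, thresholds,
                            zonesets=shared if share_geometry else None,
                            **kwargs)
        if share_geometry:
            res.objects = shared_objs
            res.killing = _quant.object_intensity(
                field.channels["caspase"], shared_objs, metadata=field.metadata)
        counts.append(res.counts)
        killing.append(res.killing)
    return (pd.concat(counts, ignore_index=True),
            pd.concat(killing, ignore_index=True))
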