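"""Nuclear detection, marker positivity calls, zone assignment and counting.

Nuclei are detected on the DAPI channel by thresholding plus a watershed
split on distance-transform maxima.  Marker positivity is decided against a
threshold derived from a negative control (mean + k SD of control pixels),
mirroring the use of secondary-only controls in multiplexed staining.  A
cell's phenotype is the first positive marker in a fixed priority order with
pan-cytokeratin first, so epithelial cells are never miscounted as immune.
Zone membership is decided by the pixel under the nucleus centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .objects import default_threshold
from .zones import zone_of_point

log = logging.getLogger(__name__)

#: Tie-break priority for positivity calls; panCK wins over immune markers.
MARKER_PRIORITY = ("panCK", "CD8", "CD4", "CD14", "CD20")

PHENOTYPE_OF_MARKER = {"panCK": "epithelial", "CD8": "CD8", "CD4": "CD4",
                       "CD14": "CD14", "CD20": "CD20"}


@dataclass
class Cell:
    """One detected nucleus with its marker readout and spatial assignment.

    ``zone`` is 1-4 or 0 for outside/deleted pixels; ``object_id`` is -1 when
    the cell belongs to no object.
    """

    cell_id: int
    row: float
    col: float
    area_um2: float
    intensities: dict = dc_field(default_factory=dict)
    phenotype: str | None = None
    object_id: int = -1
    zone: int = 0


def detect_nuclei(dapi, pixel_size_um, threshold=None,
                  min_distance_um=4.0, min_area_um2=10.0):
    """Detect nuclei on a DAPI raster; returns cells with positions only.

    Threshold (Otsu with a noise-floor guard by default), exact Euclidean
    distance transform, local maxima at least ``min_distance_um`` apart as
    watershed seeds, then one cell per watershed basin.  Basins below
    ``min_area_um2`` are discarded.  Two nuclei closer than the minimum
    separation may merge and are then counted once (logged as a QC note).
    """
    img = np.asarray(dapi, float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D DAPI raster")
    if threshold is None:
        threshold = default_threshold(img)
    binary = img > threshold
    if not binary.any():
        return []
    dist = ndi.distance_transform_edt(binary)
    md = max(int(round(min_distance_um / pixel_size_um)), 1)
    coords = peak_local_max(dist, min_distance=md, labels=binary)
    if len(coords) == 0:
        return []
    markers = np.zeros(img.shape, np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-dist, markers, mask=binary)
    cells = []
    min_px = min_area_um2 / pixel_size_um ** 2
    small = 0
    for prop in regionprops(labels):
        if prop.area < min_px:
            small += 1
            continue
        cells.append(Cell(cell_id=0, row=prop.centroid[0], col=prop.centroid[1],
                          area_um2=float(prop.area) * pixel_size_um ** 2))
    if small:
        log.info("detect_nuclei: discarded %d sub-minimum regions", small)
    cells.sort(key=lambda c: (c.row, c.col))
    for i, c in enumerate(cells):
        c.cell_id = i
    log.info("detect_nuclei: %d nuclei", len(cells))
    return cells


def threshold_from_negative_control(values, k=3.0):
    """Positivity threshold from negative-control intensities: mean + k SD."""
    values = np.asarray(values, float).ravel()
    if values.size < 10:
        raise ValueError("need at least 10 negative-control values")
    return float(values.mean() + k * values.std(ddof=1))


def _disk_offsets(radius_um, pixel_size_um):
    r = radius_um / pixel_size_um
    n = int(math.ceil(r))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    keep = yy ** 2 + xx ** 2 <= r * r
    return yy[keep], xx[keep]


def measure_intensities(cells, channels, pixel_size_um, radius_um=3.0):
    """Mean intensity per channel in a fixed-radius disk around each centroid.

    Approximates membrane/cytoplasmic staining without full cell
    segmentation; out-of-raster pixels are ignored.  Fills
    ``cell.intensities`` in place and returns the cells.
    """
    if not cells:
        return cells
    dy, dx = _disk_offsets(radius_um, pixel_size_um)
    shape = next(iter(channels.values())).shape
    for cell in cells:
        rr = np.rint(cell.row).astype(int) + dy
        cc = np.rint(cell.col).astype(int) + dx
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        for name, arr in channels.items():
            cell.intensities[name] = float(arr[rr[ok], cc[ok]].mean())
    return cells


def call_phenotype(cell, thresholds):
    """First marker above threshold in priority order, else 'other'.

    Priority: panCK > CD8 > CD4 > CD14 > CD20; panCK positivity maps to the
    'epithelial' phenotype.  Markers without a measured intensity or without
    a threshold are skipped (logged once per call at debug level).
    """
    for marker in MARKER_PRIORITY:
        if marker not in cell.intensities or marker not in thresholds:
            log.debug("marker %s unavailable for cell %d, skipped",
                      marker, cell.cell_id)
            continue
        if cell.intensities[marker] > thresholds[marker]:
            return PHENOTYPE_OF_MARKER[marker]
    return "other"


def call_phenotypes(cells, thresholds):
    for cell in cells:
        cell.phenotype = call_phenotype(cell, thresholds)
    return cells


def assign_zone(cell, zonesets, field_shape=None):
    """Assign (object_id, zone) from the pixel under the nucleus centroid.

    Deleted-overlap pixels (claimed by no resolved zone) map to outside
    (object -1, zone 0).  A centroid off the raster raises ``ValueError``.
    """
    if field_shape is None and zonesets:
        field_shape = zonesets[0].field_shape
    if field_shape is not None:
        if not (0 <= cell.row < field_shape[0] and 0 <= cell.col < field_shape[1]):
            raise ValueError(f"cell {cell.cell_id} centroid off the raster")
    oid, zone = zone_of_point(zonesets, int(round(cell.row)), int(round(cell.col)))
    cell.object_id = oid
    cell.zone = zone
    return oid, zone


def assign_zones(cells, zonesets, field_shape=None):
    for cell in cells:
        assign_zone(cell, zonesets, field_shape)
    return cells


def tabulate(cells, metadata=None, zone_areas_um2=None):
    """Tidy per-object, per-zone, per-phenotype counts.

    Zone 0 rows collect cells outside every zone, so the column sum equals
    the number of detected cells (conservation).  With ``zone_areas_um2``
    (a mapping ``(object_id, zone) -> um2``), a density column in cells per
    mm2 is added.  ``metadata`` key/values are repeated on every row.
    """
    rows = [(c.object_id, c.zone, c.phenotype if c.phenotype else "other")
            for c in cells]
    df = pd.DataFrame(rows, columns=["object_id", "zone", "phenotype"])
    counts = (df.groupby(["object_id", "zone", "phenotype"], sort=True)
                .size().rename("count").reset_index())
    if zone_areas_um2 is not None:
        areas = counts.apply(
            lambda r: zone_areas_um2.get((r["object_id"], r["zone"]), np.nan), axis=1)
        counts["density_per_mm2"] = counts["count"] / (areas / 1e6)
    if metadata:
        for key, val in metadata.items():
            counts[key] = val
    return counts
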