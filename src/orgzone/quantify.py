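"""Killing-assay and epithelial-integrity quantification.

Per-object killing is the mean caspase-3/7 reporter intensity (a.f.u.)
within the filled ROI; the mean (rather than the integrated sum) makes the
normalized fold independent of object size.  Folds are computed against the
mean a.f.u. of the non-targeting (NT) control at the matching timepoint.
Epithelial integrity is read out as mutually exclusive panCK-live /
caspase-apoptotic pixel-class fractions of the zone-2 barrier band, with
caspase taking precedence on double-positive pixels (apoptotic epithelium
still expresses cytokeratin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .objects import default_threshold

log = logging.getLogger(__name__)


@dataclass
class IntegrityRecord:
    """Pixel-class fractions of one object's epithelial band; they sum to 1."""

    fraction_panck: float
    fraction_caspase: float
    fraction_other: float

    def as_tuple(self):
        return (self.fraction_panck, self.fraction_caspase, self.fraction_other)


def object_intensity(caspase, objects, metadata=None):
    """Mean caspase a.f.u. within each filled ROI, as a tidy killing table.

    Columns: object_id, area_um2, mean_afu, plus any ``metadata`` columns
    (condition, concentration, timepoint, well...).  Objects are expected to
    be area-filtered upstream.  Raises if an ROI lies outside the raster.
    """
    caspase = np.asarray(caspase)
    rows = []
    for obj in objects:
        if obj.field_shape != caspase.shape:
            raise ValueError(f"object {obj.label} does not match the raster shape")
        vals = caspase[obj.window][obj.mask]
        rows.append((obj.label, obj.area_um2, float(vals.mean())))
    df = pd.DataFrame(rows, columns=["object_id", "area_um2", "mean_afu"])
    if metadata:
        for key, val in metadata.items():
            df[key] = val
    return df


def normalize_to_control(records, control_condition="NT",
                         condition_col="condition", value_col="mean_afu",
                         group_cols=("timepoint_h",)):
    """NT-normalized fold change per condition and timepoint group.

    fold(condition, group) = mean a.f.u.(condition, group) / mean a.f.u.
    (control, group); the fold of the control itself is exactly 1.  The
    group key defaults to the timepoint and may include a plate or donor
    column.  A group without a positive-mean control record raises an error
    naming the group.  Returns a copy of ``records`` with a ``fold`` column
    (constant within each condition-group).
    """
    records = records.copy()
    group_cols = list(group_cols)
    means = records.groupby([condition_col] + group_cols, sort=True)[value_col].mean()
    ctrl = {}
    for key, val in means.items():
        cond = key[0] if isinstance(key, tuple) else key
        grp = key[1:] if isinstance(key, tuple) else ()
        if cond == control_condition:
            ctrl[grp] = val
    folds = {}
    for key, val in means.items():
        cond = key[0] if isinstance(key, tuple) else key
        grp = key[1:] if isinstance(key, tuple) else ()
        if grp not in ctrl or not ctrl[grp] > 0:
            raise ValueError(
                f"missing or non-positive '{control_condition}' control for group "
                f"{dict(zip(group_cols, grp))}")
        folds[key] = 1.0 if cond == control_condition else float(val / ctrl[grp])
    keys = list(zip(records[condition_col], *(records[g] for g in group_cols)))
    records["fold"] = [folds[k if len(group_cols) else k[0]] for k in keys]
    return records


def fold_table(records, condition_col="condition", group_cols=("timepoint_h",)):
    """Condition-level fold summary (one row per condition and group)."""
    return (records.groupby([condition_col] + list(group_cols), sort=True)["fold"]
                   .first().reset_index())


def classify_epithelium(panck, caspase, caspase_threshold,
                        panck_threshold=None):
    """Binary, mutually exclusive panCK-live / caspase-apoptotic rasters.

    The caspase threshold should come from a negative control on untreated
    (live) epithelium -- live cells carry a dim reporter baseline that a
    background-only threshold would misclassify.  panCK defaults to an Otsu
    threshold.  Caspase wins double-positive pixels.
    """
    caspase = np.asarray(caspase, float)
    panck = np.asarray(panck, float)
    if panck_threshold is None:
        panck_threshold = default_threshold(panck)
    caspase_pos = caspase > caspase_threshold
    panck_pos = (panck > panck_threshold) & ~caspase_pos
    return panck_pos, caspase_pos


def epithelium_class_fractions(zone2_mask, panck_mask, caspase_mask):
    """Pixel-class fractions of the zone-2 epithelial band.

    Fractions of live (panCK+), apoptotic (caspase+) and unclassified pixels
    within the resolved zone-2 raster; caspase wins ties and the three
    fractions sum to 1 by construction.  An empty zone 2 raises.
    """
    z = np.asarray(zone2_mask, bool)
    n = int(z.sum())
    if n == 0:
        raise ValueError("zone 2 is empty")
    casp = int((z & np.asarray(caspase_mask, bool)).sum())
    pan = int((z & np.asarray(panck_mask, bool) & ~np.asarray(caspase_mask, bool)).sum())
    f_c = casp / n
    f_p = pan / n
    return IntegrityRecord(fraction_panck=f_p, fraction_caspase=f_c,
                           fraction_other=1.0 - f_p - f_c)


def positive_area_fraction(obj, stain_mask):
    """Percent of an object's ROI covered by a thresholded stain mask.

    The stain mask is expected to be thresholded upstream against isotype or
    secondary-only negative controls.  An empty ROI raises.
    """
    stain = np.asarray(stain_mask, bool)
    if obj.field_shape != stain.shape:
        raise ValueError("stain mask does not match the object's raster shape")
    n = int(obj.mask.sum())
    if n == 0:
        raise ValueError("object ROI is empty")
    pos = int((stain[obj.window] & obj.mask).sum())
    return 100.0 * pos / n
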