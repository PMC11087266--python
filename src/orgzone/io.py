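"""Raster and table input/output (TIFF via tifffile, CSV via pandas, YAML config)."""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd
import tifffile
import yaml

from .objects import LabelMask, objects_table
from .synthgen import ImageField, SynthConfig


def save_field(field, directory, basename="field"):
    """One TIFF per channel plus a YAML sidecar with pixel size and metadata."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, arr in field.channels.items():
        path = os.path.join(directory, f"{basename}_{name}.tif")
        tifffile.imwrite(path, np.asarray(arr))
        paths[name] = path
    sidecar = {"pixel_size_um": field.pixel_size_um,
               "metadata": {k: (float(v) if isinstance(v, (int, float)) else v)
                            for k, v in field.metadata.items()},
               "channels": {k: os.path.basename(v) for k, v in paths.items()}}
    with open(os.path.join(directory, f"{basename}.yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return paths


def load_field(directory, basename="field"):
    with open(os.path.join(directory, f"{basename}.yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    channels = {name: tifffile.imread(os.path.join(directory, fname))
                for name, fname in sidecar["channels"].items()}
    return ImageField(channels=channels,
                      pixel_size_um=float(sidecar["pixel_size_um"]),
                      metadata=sidecar.get("metadata", {}))


def save_label_mask(mask, path):
    tifffile.imwrite(path, mask.labels.astype(np.int32))


def load_label_mask(path, pixel_size_um):
    """Import an externally produced label raster (any segmenter)."""
    return LabelMask(labels=np.asarray(tifffile.imread(path)).astype(np.int32),
                     pixel_size_um=pixel_size_um)


def save_truth(truth, directory, prefix="truth"):
    """Ground-truth object and cell tables as CSV plus the config as YAML."""
    os.makedirs(directory, exist_ok=True)
    truth.objects.to_csv(os.path.join(directory, f"{prefix}_objects.csv"),
                         index=False)
    truth.cells.to_csv(os.path.join(directory, f"{prefix}_cells.csv"), index=False)
    save_config(truth.config, os.path.join(directory, f"{prefix}_config.yaml"))


def save_config(config, path):
    data = dataclasses.asdict(config)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("field_size_px", "radius_range_um", "timepoints_h"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SynthConfig(**data)


def save_objects_table(objects, path):
    objects_table(objects).to_csv(path, index=False)
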