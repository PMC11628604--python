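"""Reading and writing the pipeline's on-disk formats.

Images travel as OME-TIFF with physical pixel size metadata; instance labels
as 16-bit label TIFF; tables as CSV; configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import FieldOfView


def write_fov_tiff(path, fov: FieldOfView) -> None:
    """Write a FieldOfView as OME-TIFF (CYX) with pixel-size metadata."""
    channel_names = [None] * fov.channels.shape[0]
    for role, idx in fov.channel_roles.items():
        channel_names[idx] = role
    tifffile.imwrite(
        path, fov.channels.astype(np.float32), ome=True,
        metadata={"axes": "CYX",
                  "PhysicalSizeX": fov.pixel_size_um,
                  "PhysicalSizeXUnit": "µm",
                  "PhysicalSizeY": fov.pixel_size_um,
                  "PhysicalSizeYUnit": "µm",
                  "Channel": {"Name": channel_names}})


def read_fov_tiff(path, channel_roles=None,
                  pixel_size_um=None) -> FieldOfView:
    """Read an OME-TIFF written by `write_fov_tiff` (or any CYX stack)."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        px = pixel_size_um
        roles = dict(channel_roles) if channel_roles else None
        if tf.ome_metadata is not None:
            import xml.etree.ElementTree as ET
            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pixels = root.find(".//ome:Pixels", ns)
            if px is None and pixels is not None:
                px = float(pixels.get("PhysicalSizeX", "0") or 0) or None
            if roles is None and pixels is not None:
                names = [c.get("Name") for c in pixels.findall("ome:Channel", ns)]
                if all(names):
                    roles = {n: i for i, n in enumerate(names)}
    if data.ndim == 2:
        data = data[None]
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size_um")
    if roles is None:
        roles = {f"ch{i}": i for i in range(data.shape[0])}
    return FieldOfView(channels=data.astype(float), channel_roles=roles,
                       pixel_size_um=px,
                       fov_size_um=data.shape[1] * px)


def write_labels_tiff(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def read_seeds_csv(path) -> np.ndarray:
    """Seed centroids CSV with columns x, y (0-based px, x = column);
    returned as (row, col) for the watershed."""
    df = pd.read_csv(path)
    return np.column_stack([df["y"].to_numpy(float), df["x"].to_numpy(float)])


def read_labels_csv(path, shape) -> np.ndarray:
    """Sparse training labels CSV (x, y, class) -> label image
    (0 unlabelled, 1 background, 2 foreground)."""
    df = pd.read_csv(path)
    img = np.zeros(shape, np.int64)
    cls = df["class"].map({"background": 1, "foreground": 2}).fillna(df["class"])
    img[df["y"].to_numpy(int), df["x"].to_numpy(int)] = cls.to_numpy(int)
    return img


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
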