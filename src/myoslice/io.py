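"""File formats: OME-TIFF images, TIFF masks/labels, CSV tables, YAML specs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import tifffile
import yaml

from .image import MultiChannelImage
from .synthetic import GroundTruth, SliceSpec


def write_ome_tiff(image: MultiChannelImage, path) -> None:
    """Write one page per channel with channel names and the physical
    pixel size in the OME metadata."""
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
        ome=True,
    )


def read_multichannel(
    path,
    channel_map: Optional[Mapping[str, str]] = None,
    pixel_size_um: Optional[float] = None,
) -> MultiChannelImage:
    """Read a multi-page TIFF / OME-TIFF into channel planes keyed by role.

    ``channel_map`` maps file channel names to stain roles; without it the
    file's channel names are used as roles directly.  The pixel size is
    taken from OME metadata unless overridden; if neither is available a
    ``ValueError`` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        names = None
        px = None
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pixels = root.find(".//ome:Pixels", ns)
            if pixels is not None:
                px_attr = pixels.get("PhysicalSizeX")
                if px_attr is not None:
                    px = float(px_attr)
                names = [
                    ch.get("Name") or f"channel_{i}"
                    for i, ch in enumerate(pixels.findall("ome:Channel", ns))
                ]
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D multi-channel image, got shape {data.shape}")
    if names is None or len(names) != data.shape[0]:
        names = [f"channel_{i}" for i in range(data.shape[0])]

    if pixel_size_um is not None:
        px = pixel_size_um
    if px is None:
        raise ValueError(
            "pixel size missing from metadata; pass pixel_size_um explicitly"
        )

    channels: Dict[str, np.ndarray] = {}
    if channel_map:
        available = {n: i for i, n in enumerate(names)}
        for file_name, role in channel_map.items():
            if file_name not in available:
                raise ValueError(
                    f"channel {file_name!r} not found in {path.name}; "
                    f"file has {names}"
                )
            if role in channels:
                raise ValueError(f"role {role!r} mapped more than once")
            channels[role] = data[available[file_name]]
    else:
        for i, n in enumerate(names):
            channels[n] = data[i]
    return MultiChannelImage(channels, pixel_size_um=px)


def write_label_tiff(labels: np.ndarray, path) -> None:
    """Integer label map as 16-bit TIFF."""
    lab = np.asarray(labels)
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def write_mask_tiff(mask: np.ndarray, path) -> None:
    """Binary mask as 8-bit TIFF (0 / 255)."""
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def save_slice_spec(spec: SliceSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_slice_spec(path) -> SliceSpec:
    with open(path) as fh:
        return SliceSpec.from_dict(yaml.safe_load(fh))


def save_ground_truth(truth: GroundTruth, directory) -> None:
    """Label map as 16-bit TIFF plus per-cell states as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_label_tiff(truth.label_map, directory / "truth_labels.tif")
    truth.states_frame().to_csv(directory / "truth_states.csv", index=False)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default, sort_keys=True)
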