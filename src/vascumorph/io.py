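"""File I/O: TIFF images, NIfTI volumes, JSON/YAML sidecars, CSV tables,
and overlay/colormap PNG rendering."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import tifffile
import yaml

from .core import VesselImage

__all__ = [
    "save_vessel_tiff",
    "load_vessel_tiff",
    "save_lfd_tiff",
    "save_labels_tiff",
    "save_nifti",
    "load_nifti",
    "save_json",
    "save_yaml",
    "load_yaml",
    "save_overlay_png",
    "save_lfd_png",
    "network_to_json",
]


def save_vessel_tiff(path, image: VesselImage) -> None:
    """16-bit grayscale TIFF with the pixel size recorded in the image
    description tag."""
    data = np.clip(image.data, 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        description=json.dumps({"pixel_size_um": image.pixel_size_um}),
    )


def load_vessel_tiff(path, pixel_size_um: float | None = None) -> VesselImage:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float32)
        if pixel_size_um is None:
            desc = tf.pages[0].description or "{}"
            try:
                pixel_size_um = float(json.loads(desc).get("pixel_size_um", 1.0))
            except (ValueError, json.JSONDecodeError):
                pixel_size_um = 1.0
    return VesselImage(data=data, pixel_size_um=pixel_size_um)


def save_lfd_tiff(path, lfd_map) -> None:
    tifffile.imwrite(path, np.asarray(lfd_map.lfd, dtype=np.float32))


def save_labels_tiff(path, label_image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(label_image, dtype=np.uint8))


def save_nifti(path, volume: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


class _DataclassEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_DataclassEncoder))


def save_yaml(path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def network_to_json(network) -> dict:
    return {
        "segments": [
            {"start_rc_px": list(a), "end_rc_px": list(b), "width_px": w}
            for a, b, w in network.segments
        ],
        "junction_points": [list(p) for p in network.junction_points],
        "junction_count": network.junction_count,
        "total_length_um": network.total_length_um,
        "pixel_size_um": network.pixel_size_um,
    }


def save_overlay_png(path, mask, skeleton, junction_positions) -> None:
    """Vessels (red), skeleton (white) and junction dots (blue), the layout
    classical angiography tools display."""
    H, W = mask.shape
    rgb = np.zeros((H, W, 3), dtype=float)
    rgb[..., 0] = np.where(mask, 0.6, 0.0)
    rgb[np.asarray(skeleton, bool)] = (1.0, 1.0, 1.0)
    fig, ax = plt.subplots(figsize=(W / 100, H / 100), dpi=100)
    ax.imshow(rgb, interpolation="nearest")
    if junction_positions:
        ys = [p[0] for p in junction_positions]
        xs = [p[1] for p in junction_positions]
        ax.scatter(xs, ys, s=6, c="tab:blue", linewidths=0)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def save_lfd_png(path, lfd_map, vmin=0.8, vmax=2.0) -> None:
    """Colorized LFD map: red = low complexity through purple = high."""
    data = np.ma.masked_invalid(lfd_map.lfd)
    fig, ax = plt.subplots(figsize=(6, 5), dpi=120)
    im = ax.imshow(data, cmap="rainbow_r", vmin=vmin, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="local fractal dimension")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
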