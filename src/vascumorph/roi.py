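"""Analysis regions: concentric rings around an injury epicenter,
hemispheric halves, and mirrored contralateral ROIs.

Ring 1 is the disk of the first radius; ring k>1 is the annulus with
exclusive inner and inclusive outer radius, so rings are pairwise disjoint
and per-ring metrics are never double-counted. Radii are supplied in
millimetres and converted to pixels as ``radius_mm * 1000 / pixel_size_um``
rounded half-up. Rings are clipped to the cortex mask and the clipped
fraction of each ring's ideal area is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError

__all__ = ["RoiSet", "concentric_rings", "hemisphere_masks", "mirror_mask", "mm_to_px"]


def mm_to_px(radius_mm: float, pixel_size_um: float) -> int:
    """Millimetres to pixels, rounded half-up."""
    return int(math.floor(radius_mm * 1000.0 / pixel_size_um + 0.5))


@dataclass(frozen=True)
class RoiSet:
    """Concentric-ring ROI family around an epicenter."""

    cortex_mask: np.ndarray
    epicenter_rc_px: tuple[float, float]
    ring_masks: tuple[np.ndarray, ...]
    ring_radii_mm: tuple[float, ...]
    ring_radii_px: tuple[int, ...]
    clipping_fractions: tuple[float, ...]

    @property
    def n_rings(self) -> int:
        return len(self.ring_masks)

    def disk_mask(self) -> np.ndarray:
        """Union of all rings: the full disk of the outermost radius."""
        out = np.zeros_like(self.cortex_mask, dtype=bool)
        for m in self.ring_masks:
            out |= m
        return out


def concentric_rings(
    epicenter_rc_px: tuple[float, float],
    radii_mm,
    pixel_size_um: float,
    cortex_mask: np.ndarray,
) -> RoiSet:
    """Disk/annulus masks at pixel resolution, clipped to the cortex mask.

    The clipping fraction per ring is the share of the ring's ideal
    (continuous) area lost to the image bounds and the cortex outline.
    """
    cortex = np.asarray(cortex_mask, dtype=bool)
    radii_mm = tuple(float(r) for r in radii_mm)
    if any(b <= a for a, b in zip(radii_mm, radii_mm[1:])) or radii_mm[0] <= 0:
        raise ConfigurationError("radii_mm must be positive and strictly increasing")
    er, ec = epicenter_rc_px
    ri, ci = int(round(er)), int(round(ec))
    if not (0 <= ri < cortex.shape[0] and 0 <= ci < cortex.shape[1]) or not cortex[ri, ci]:
        raise ConfigurationError("epicenter must lie inside the cortex mask")

    rr, cc = np.mgrid[: cortex.shape[0], : cortex.shape[1]]
    dist = np.hypot(rr - er, cc - ec)
    radii_px = tuple(mm_to_px(r, pixel_size_um) for r in radii_mm)

    masks = []
    clip_fracs = []
    prev = 0
    for rpx in radii_px:
        ring = (dist > prev) & (dist <= rpx) if prev else dist <= rpx
        clipped = ring & cortex
        ideal = math.pi * (rpx**2 - prev**2)
        clip_fracs.append(max(0.0, 1.0 - clipped.sum() / ideal))
        masks.append(clipped)
        prev = rpx
    return RoiSet(
        cortex_mask=cortex,
        epicenter_rc_px=(float(er), float(ec)),
        ring_masks=tuple(masks),
        ring_radii_mm=radii_mm,
        ring_radii_px=radii_px,
        clipping_fractions=tuple(clip_fracs),
    )


def hemisphere_masks(
    cortex_mask: np.ndarray, midline_col_px: int, ipsilateral_side: str = "right"
) -> tuple[np.ndarray, np.ndarray]:
    """Split the cortex into (ipsilateral, contralateral) halves.

    The midline column itself belongs to neither half. ``ipsilateral_side``
    names the injured side ('right' matches a right-hemisphere impact).
    """
    cortex = np.asarray(cortex_mask, dtype=bool)
    if not 0 <= midline_col_px < cortex.shape[1]:
        raise ConfigurationError("midline column must lie within the image")
    cols = np.arange(cortex.shape[1])
    left = cortex & (cols < midline_col_px)[None, :]
    right = cortex & (cols > midline_col_px)[None, :]
    if ipsilateral_side == "right":
        return right, left
    if ipsilateral_side == "left":
        return left, right
    raise ConfigurationError("ipsilateral_side must be 'left' or 'right'")


def mirror_mask(roi_mask: np.ndarray, midline_col_px: int) -> np.ndarray:
    """Reflect a mask across the vertical midline column.

    Pixels whose reflection falls outside the image are dropped; when the
    reflection stays in-bounds the operation is an involution and preserves
    pixel area exactly.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    out = np.zeros_like(roi)
    rows, cols = np.nonzero(roi)
    mirrored = 2 * midline_col_px - cols
    ok = (mirrored >= 0) & (mirrored < roi.shape[1])
    out[rows[ok], mirrored[ok]] = True
    return out
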