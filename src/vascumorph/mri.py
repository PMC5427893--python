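"""MR lesion analysis: SWI phase-mask processing and hierarchical region
splitting (HRS) segmentation.

SWI processing follows standard homodyne practice: per slice, the complex
image (magnitude * exp(i*phase)) is divided by its own low-pass estimate —
obtained by windowing k-space with a centred 48x48 Hanning window — leaving
the high-frequency ("filtered") phase. Negative filtered phase builds a
linear mask f = (phi + pi)/pi that is multiplied into the magnitude four
times, darkening paramagnetic (hemorrhagic) voxels.

HRS segments a volume by recursively modelling each region's intensity
histogram as bimodal and splitting at the valley between the two dominant
peaks, stopping when a region is uniform (low coefficient of variation),
too small, unimodal, or too deep. Leaves carry mean intensities in original
units; lesion (or hemorrhage) voxels are extracted as the union of leaves
whose mean lies within a tolerance of an a-priori target mean (meanTh).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import ConfigurationError, DegenerateInputError

__all__ = [
    "HRSConfig",
    "HRSNode",
    "HRSTree",
    "LesionResult",
    "negative_phase_mask",
    "swi_process",
    "hrs_segment",
    "extract_lesion",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class HRSConfig:
    """Knobs of the recursive bimodal splitting.

    ``min_peak_separation`` and ``mean_threshold`` tolerance are in the
    rescaled/original intensity units respectively; ``uniformity_cv_max``
    stops recursion once a region's coefficient of variation (on the
    rescaled values) is at or below it.
    """

    histogram_bins: int = 256
    smoothing_window: int = 5
    min_peak_separation: float = 10.0
    uniformity_cv_max: float = 0.05
    min_region_voxels: int = 50
    max_depth: int = 6
    mean_threshold: tuple[float, float] = (180.0, 15.0)  # (target_mean, tolerance)
    split_leaf_components: bool = True

    def validate(self) -> None:
        if self.histogram_bins < 8:
            raise ConfigurationError("histogram_bins must be >= 8")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigurationError("smoothing_window must be a positive odd int")
        if self.min_peak_separation <= 0 or self.uniformity_cv_max <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.min_region_voxels < 1 or self.max_depth < 1:
            raise ConfigurationError("min_region_voxels and max_depth must be >= 1")


@dataclass
class HRSNode:
    mask: np.ndarray
    mean_intensity: float  # original intensity units
    depth: int
    split_value: float | None = None  # rescaled units; None at leaves
    children: list["HRSNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class HRSTree:
    root: HRSNode
    rescale_offset: float  # original = rescaled / rescale_gain + rescale_offset
    rescale_gain: float

    def leaves(self) -> list[HRSNode]:
        out: list[HRSNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children)
        return out

    def check_partition(self) -> None:
        """Assert that children partition the parent mask at every node."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.children:
                union = np.zeros_like(node.mask)
                total = 0
                for ch in node.children:
                    assert not (union & ch.mask).any(), "HRS children overlap"
                    union |= ch.mask
                    total += ch.n_voxels
                assert (union == node.mask).all(), "HRS children do not cover parent"
                stack.extend(node.children)


@dataclass(frozen=True)
class LesionResult:
    lesion_mask: np.ndarray
    brain_mask: np.ndarray
    volume_percent: float  # 100 * |lesion| / |brain|


def negative_phase_mask(phase: np.ndarray, power: int = 4) -> np.ndarray:
    """Linear negative-phase mask raised to ``power``:
    f(phi) = (phi + pi)/pi for phi < 0, else 1."""
    phi = np.asarray(phase, dtype=np.float64)
    f = np.where(phi < 0, (phi + np.pi) / np.pi, 1.0)
    return f**power


def swi_process(
    magnitude_volume: np.ndarray,
    phase_volume: np.ndarray,
    hanning_size: int = 48,
    mask_power: int = 4,
) -> np.ndarray:
    """Susceptibility-weighted volume from magnitude and phase.

    Per slice (first axis), the phase is high-pass filtered by homodyne
    complex division against a central ``hanning_size`` x ``hanning_size``
    Hanning-windowed k-space low-pass; the negative-phase mask of the
    filtered phase, raised to ``mask_power``, multiplies the magnitude.
    """
    mag = np.asarray(magnitude_volume, dtype=np.float64)
    phi = np.asarray(phase_volume, dtype=np.float64)
    if mag.shape != phi.shape:
        raise ConfigurationError("magnitude and phase volumes must share a shape")
    if np.nanmax(np.abs(phi)) > np.pi + 1e-9:
        raise ConfigurationError("phase must lie in [-pi, pi]")
    if mag.ndim == 2:
        mag = mag[None]
        phi = phi[None]
        squeeze = True
    elif mag.ndim == 3:
        squeeze = False
    else:
        raise ConfigurationError("volumes must be 2D or 3D")

    ny, nx = mag.shape[1:]

    def hann_axis(n: int, size: int) -> np.ndarray:
        # raised cosine of half-width size/2 centred exactly on the DC bin
        # of the fftshifted spectrum (symmetric, so the low-pass of a real
        # image stays real and introduces no spurious phase)
        k = np.arange(n) - n // 2
        half = min(size, n) / 2.0
        w = 0.5 * (1.0 + np.cos(np.pi * k / half))
        w[np.abs(k) > half] = 0.0
        return w

    win = np.outer(hann_axis(ny, hanning_size), hann_axis(nx, hanning_size))

    swi = np.empty_like(mag)
    for z in range(mag.shape[0]):
        cplx = mag[z] * np.exp(1j * phi[z])
        spec = np.fft.fftshift(np.fft.fft2(cplx))
        low = np.fft.ifft2(np.fft.ifftshift(spec * win))
        filtered_phase = np.angle(cplx * np.conj(low))
        mask = negative_phase_mask(filtered_phase, power=mask_power)
        swi[z] = mag[z] * mask
    return swi[0] if squeeze else swi


def _smooth_histogram(counts: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(counts, kernel, mode="same")


def _find_split(
    values: np.ndarray, config: HRSConfig
) -> float | None:
    """Valley between the two dominant, well-separated histogram peaks of a
    region's rescaled values, or None if the histogram is unimodal."""
    counts, edges = np.histogram(values, bins=config.histogram_bins, range=(0.0, 255.0))
    smooth = _smooth_histogram(counts, config.smoothing_window)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    min_sep_bins = max(1, int(round(config.min_peak_separation / bin_width)))
    peaks, props = signal.find_peaks(smooth, height=1e-12)
    if len(peaks) < 2:
        return None
    # a genuine mode must rise well above Poisson counting noise on the
    # histogram; spurious bumps on the flank of a single mode do not
    prom = signal.peak_prominences(smooth, peaks)[0]
    heights = props["peak_heights"]
    keep = prom >= np.maximum(3.0 * np.sqrt(heights), 5.0)
    peaks, heights = peaks[keep], heights[keep]
    if len(peaks) < 2:
        return None
    order = np.argsort(heights)[::-1]
    # two tallest peaks separated by at least min_peak_separation
    first = peaks[order[0]]
    second = None
    for idx in order[1:]:
        if abs(peaks[idx] - first) >= min_sep_bins:
            second = peaks[idx]
            break
    if second is None:
        return None
    lo, hi = sorted((first, second))
    between = smooth[lo : hi + 1]
    # with well-separated modes the valley floor is a flat (often zero) run;
    # split at its middle, not its first bin
    min_idx = np.flatnonzero(between == between.min())
    valley = lo + int(min_idx[len(min_idx) // 2])
    return float(centers[valley])


def hrs_segment(
    volume: np.ndarray, brain_mask: np.ndarray, config: HRSConfig = HRSConfig()
) -> HRSTree:
    """Recursive bimodal-split segmentation of a masked volume.

    Preprocessing restricts to ``brain_mask`` and linearly rescales the
    masked intensities to [0, 255] (the inverse transform is stored on the
    tree and applied when reporting leaf means in original units).
    Recursion smooths the region histogram, splits at the valley between
    the two dominant peaks, and stops on uniformity (CV <=
    ``uniformity_cv_max``), region size, unimodality, or ``max_depth``.
    When a region becomes a leaf its spatially connected components
    (6-connectivity) are attached as separate leaf masks.
    """
    config.validate()
    brain = np.asarray(brain_mask, dtype=bool)
    if not brain.any():
        raise DegenerateInputError("brain mask is empty")
    vol = np.asarray(volume, dtype=np.float64)
    if vol.shape != brain.shape:
        raise ConfigurationError("volume and brain_mask must share a shape")

    vmin = float(vol[brain].min())
    vmax = float(vol[brain].max())
    gain = 255.0 / (vmax - vmin) if vmax > vmin else 1.0
    rescaled = np.zeros_like(vol)
    rescaled[brain] = (vol[brain] - vmin) * gain

    def make_node(mask: np.ndarray, depth: int) -> HRSNode:
        vals = rescaled[mask]
        node = HRSNode(
            mask=mask,
            mean_intensity=float(vol[mask].mean()),
            depth=depth,
        )
        mean = float(vals.mean())
        cv = float(vals.std() / mean) if mean > 0 else 0.0
        stop = (
            vals.size < 2 * config.min_region_voxels
            or depth >= config.max_depth
            or cv <= config.uniformity_cv_max
        )
        split = None if stop else _find_split(vals, config)
        if split is not None:
            lo_mask = mask & (rescaled <= split)
            hi_mask = mask & (rescaled > split)
            if lo_mask.sum() >= config.min_region_voxels and hi_mask.sum() >= config.min_region_voxels:
                node.split_value = split
                node.children = [
                    make_node(lo_mask, depth + 1),
                    make_node(hi_mask, depth + 1),
                ]
                return node
        # leaf: optionally split into spatial connected components
        if config.split_leaf_components:
            labels, n = ndimage.label(mask, structure=_STRUCT6)
            if n > 1:
                node.split_value = None
                node.children = [
                    make_node_leaf(labels == i, depth + 1) for i in range(1, n + 1)
                ]
        return node

    def make_node_leaf(mask: np.ndarray, depth: int) -> HRSNode:
        return HRSNode(mask=mask, mean_intensity=float(vol[mask].mean()), depth=depth)

    root = make_node(brain, 0)
    tree = HRSTree(root=root, rescale_offset=vmin, rescale_gain=gain)
    tree.check_partition()
    return tree


def extract_lesion(
    tree: HRSTree, config: HRSConfig, brain_mask: np.ndarray
) -> LesionResult:
    """Union of leaves whose mean (original units) lies within
    ``mean_threshold`` tolerance of the target; volume percent vs brain."""
    target, tol = config.mean_threshold
    brain = np.asarray(brain_mask, dtype=bool)
    lesion = np.zeros_like(brain)
    for leaf in tree.leaves():
        if abs(leaf.mean_intensity - target) <= tol:
            lesion |= leaf.mask
    lesion &= brain
    n_brain = int(brain.sum())
    pct = 100.0 * lesion.sum() / n_brain if n_brain else 0.0
    return LesionResult(lesion_mask=lesion, brain_mask=brain, volume_percent=float(pct))
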