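"""Synthetic vessel networks and MR phantoms with exact ground truth.

The vessel generator emulates the dense branching plexus seen on the dorsal
cortical surface of a vessel-painted rodent brain: trunks enter from the
image border and grow inward as jittered random walks that split into two
daughter branches, while a collision buffer keeps distinct branches from
overlapping so that every junction in the rendered image corresponds to a
recorded branch point. Because segments — not pixels — are the unit of both
growth and ablation, junction counts and total length are known exactly and
downstream measurements can be scored against them.

A focal injury is modelled as segment-wise ablation whose probability decays
with distance from an epicenter, superimposed on a global (both-hemisphere)
rarefication; the MR phantom provides a bimodal-intensity volume with a
hyperintense cortical lesion cap and a small hemorrhage core carrying
negative phase, mimicking the appearance of T2-weighted and
susceptibility-weighted acquisitions of a contused brain.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, VesselImage

__all__ = [
    "NetworkConfig",
    "GroundTruthNetwork",
    "LesionSpec",
    "MRPhantomConfig",
    "MRPhantom",
    "generate_vessel_network",
    "ablate_network",
    "rasterize_network",
    "generate_mr_phantom",
]

# Safety cap on total segments: a branching walk is formally exponential even
# though collisions make it self-limiting in a bounded field.
_MAX_SEGMENTS = 200_000


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the stochastic branching growth model.

    Defaults describe a sham-like dorsal plexus on a 512x640 field at
    20 um/px (a 10.2 x 12.8 mm cortical slab).
    """

    image_height_px: int = 512
    image_width_px: int = 640
    pixel_size_um: float = 20.0
    n_seed_trunks: int = 50
    branch_probability: float = 0.11
    step_length_px: float = 6.0
    max_steps: int = 110
    direction_jitter_rad: float = 0.35
    width_range_px: tuple[int, int] = (3, 6)
    rng_seed: int = 0
    clearance_px: float = 3.0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.n_seed_trunks < 0:
            raise ConfigurationError("n_seed_trunks must be >= 0")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ConfigurationError("branch_probability must be in [0, 1]")
        if not self.step_length_px > 0:
            raise ConfigurationError("step_length_px must be > 0")
        if self.width_range_px[0] < 1 or self.width_range_px[1] < self.width_range_px[0]:
            raise ConfigurationError("width_range_px must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Segment-level network with exact junction and length bookkeeping.

    ``segments`` are straight strokes ``(start_rc, end_rc, width_px)`` in
    pixel coordinates; ``junction_points`` are exactly the points where at
    least three segments meet.
    """

    segments: tuple[tuple[tuple[float, float], tuple[float, float], int], ...]
    junction_points: tuple[tuple[float, float], ...]
    total_length_um: float
    pixel_size_um: float

    @classmethod
    def from_segments(
        cls,
        segments,
        pixel_size_um: float,
    ) -> "GroundTruthNetwork":
        """Build a network, recomputing junctions and total length exactly.

        A junction is any endpoint shared by >= 3 segments (mid-chain points
        of an unbranched walk are shared by exactly 2 and do not count).
        """
        segments = tuple(
            ((float(a[0]), float(a[1])), (float(b[0]), float(b[1])), int(w))
            for a, b, w in segments
        )
        incidence: dict[tuple[float, float], int] = {}
        total_px = 0.0
        for a, b, _w in segments:
            incidence[a] = incidence.get(a, 0) + 1
            incidence[b] = incidence.get(b, 0) + 1
            total_px += math.hypot(b[0] - a[0], b[1] - a[1])
        junctions = tuple(sorted(p for p, k in incidence.items() if k >= 3))
        return cls(
            segments=segments,
            junction_points=junctions,
            total_length_um=total_px * pixel_size_um,
            pixel_size_um=float(pixel_size_um),
        )

    @property
    def junction_count(self) -> int:
        return len(self.junction_points)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class LesionSpec:
    """Focal + global segment-ablation model of a cortical contusion.

    A segment whose midpoint lies at distance ``d`` from ``center_rc_px`` is
    removed with probability ``max(global_ablation_fraction,
    core_ablation_fraction * falloff(d))``; ``falloff`` is 1 at the center
    and reaches 0 at ``radius_px`` ("linear") or is a top-hat ("flat").
    """

    center_rc_px: tuple[float, float] = (180.0, 460.0)
    radius_px: float = 75.0
    core_ablation_fraction: float = 0.9
    global_ablation_fraction: float = 0.3
    falloff: str = "linear"

    def validate(self) -> None:
        if self.radius_px < 0:
            raise ConfigurationError("radius_px must be >= 0")
        for name in ("core_ablation_fraction", "global_ablation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.falloff not in ("linear", "flat"):
            raise ConfigurationError("falloff must be 'linear' or 'flat'")

    def falloff_at(self, distance_px: float) -> float:
        if self.radius_px == 0 or distance_px >= self.radius_px:
            return 0.0
        if self.falloff == "flat":
            return 1.0
        return 1.0 - distance_px / self.radius_px


def generate_vessel_network(config: NetworkConfig) -> GroundTruthNetwork:
    """Grow a planar branching network by a seeded biased random walk.

    Trunks are seeded on the image border pointing inward. Each active tip
    advances ``step_length_px`` per step with Gaussian heading jitter; with
    ``branch_probability`` the tip splits into two daughters at roughly
    +/- 45 degrees (the branch point becomes a junction: incoming segment
    plus two daughters). A tip dies when it leaves the field, exhausts its
    step budget, or would come closer than ``clearance_px`` to an existing
    branch — which keeps the network planar and its ground truth exact.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    H, W = config.image_height_px, config.image_width_px

    # occupancy records pixels within clearance of drawn segments
    occ = np.zeros((H, W), dtype=bool)
    segments: list[tuple[tuple[float, float], tuple[float, float], int]] = []

    def stamp(a, b, width):
        rad = width / 2.0 + config.clearance_px
        r0 = max(0, int(math.floor(min(a[0], b[0]) - rad)))
        r1 = min(H - 1, int(math.ceil(max(a[0], b[0]) + rad)))
        c0 = max(0, int(math.floor(min(a[1], b[1]) - rad)))
        c1 = min(W - 1, int(math.ceil(max(a[1], b[1]) + rad)))
        if r1 < r0 or c1 < c0:
            return
        rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        d = _point_segment_distance(rr, cc, a, b)
        occ[r0 : r1 + 1, c0 : c1 + 1] |= d <= rad

    def collides(a, b) -> bool:
        # Only the step endpoint is tested: the near portion of the step is
        # legitimately inside the tip's own clearance stamp, and because
        # step_length is smaller than any stamped stroke's diameter
        # (width + 2*clearance) a step can never jump across another branch
        # without its endpoint landing inside that branch's stamp.
        ri, ci = int(round(b[0])), int(round(b[1]))
        if not (0 <= ri < H and 0 <= ci < W):
            return True
        return bool(occ[ri, ci])

    margin = config.width_range_px[1] / 2.0 + 1.0
    tips: deque = deque()
    for _ in range(config.n_seed_trunks):
        side = rng.integers(0, 4)
        if side == 0:  # top
            pos = (margin, float(rng.uniform(margin, W - margin)))
            heading = math.pi / 2
        elif side == 1:  # bottom
            pos = (H - margin, float(rng.uniform(margin, W - margin)))
            heading = -math.pi / 2
        elif side == 2:  # left
            pos = (float(rng.uniform(margin, H - margin)), margin)
            heading = 0.0
        else:  # right
            pos = (float(rng.uniform(margin, H - margin)), W - margin)
            heading = math.pi
        heading += float(rng.uniform(-0.6, 0.6))
        width = int(rng.integers(config.width_range_px[0], config.width_range_px[1] + 1))
        # grace=True lets the very first step escape the border stamp region
        tips.append((pos, heading, width, config.max_steps, True))

    while tips:
        pos, heading, width, remaining, grace = tips.popleft()
        if remaining <= 0 or len(segments) >= _MAX_SEGMENTS:
            continue
        heading += float(rng.normal(0.0, config.direction_jitter_rad))
        new = (
            pos[0] + config.step_length_px * math.sin(heading),
            pos[1] + config.step_length_px * math.cos(heading),
        )
        if not (margin <= new[0] <= H - margin and margin <= new[1] <= W - margin):
            continue
        if not grace and collides(pos, new):
            continue
        segments.append((pos, new, width))
        stamp(pos, new, width)
        if rng.random() < config.branch_probability:
            for sign in (-1.0, 1.0):
                dh = sign * (math.pi / 4 + float(rng.normal(0.0, 0.1)))
                tips.append((new, heading + dh, width, remaining - 1, True))
        else:
            tips.append((new, heading, width, remaining - 1, False))

    return GroundTruthNetwork.from_segments(segments, config.pixel_size_um)


def ablate_network(
    network: GroundTruthNetwork, lesion: LesionSpec, rng_seed: int
) -> GroundTruthNetwork:
    """Remove segments under the focal+global lesion model and rebuild
    junctions and total length exactly from the survivors."""
    lesion.validate()
    rng = np.random.default_rng(rng_seed)
    survivors = []
    cr, cc = lesion.center_rc_px
    for seg in network.segments:
        (a, b, _w) = seg
        mid_r = 0.5 * (a[0] + b[0])
        mid_c = 0.5 * (a[1] + b[1])
        d = math.hypot(mid_r - cr, mid_c - cc)
        p_remove = max(
            lesion.global_ablation_fraction,
            lesion.core_ablation_fraction * lesion.falloff_at(d),
        )
        if rng.random() >= p_remove:
            survivors.append(seg)
    return GroundTruthNetwork.from_segments(survivors, network.pixel_size_um)


def _point_segment_distance(rr, cc, a, b):
    """Vectorized distance from pixel centers to the segment a-b."""
    ar, ac = a
    br, bc = b
    vr, vc = br - ar, bc - ac
    denom = vr * vr + vc * vc
    if denom == 0.0:
        return np.hypot(rr - ar, cc - ac)
    t = ((rr - ar) * vr + (cc - ac) * vc) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rr - (ar + t * vr), cc - (ac + t * vc))


def rasterize_network(
    network: GroundTruthNetwork,
    config: NetworkConfig,
    noise_sd: float = 8.0,
    *,
    foreground_level: float = 200.0,
    background_level: float = 30.0,
    rng_seed: int | None = None,
) -> VesselImage:
    """Render segments at their widths as bright strokes over a dim
    background, with additive Gaussian noise.

    A pixel belongs to a segment of width ``w`` when its center lies within
    ``w/2`` of the segment's axis, so a width-1 stroke is a single-pixel
    line. The returned image carries the pixel size from ``config``.
    """
    H, W = config.image_height_px, config.image_width_px
    fg = np.zeros((H, W), dtype=bool)
    for a, b, w in network.segments:
        rad = w / 2.0
        r0 = max(0, int(math.floor(min(a[0], b[0]) - rad - 1)))
        r1 = min(H - 1, int(math.ceil(max(a[0], b[0]) + rad + 1)))
        c0 = max(0, int(math.floor(min(a[1], b[1]) - rad - 1)))
        c1 = min(W - 1, int(math.ceil(max(a[1], b[1]) + rad + 1)))
        if r1 < r0 or c1 < c0:
            continue
        rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        d = _point_segment_distance(rr, cc, a, b)
        fg[r0 : r1 + 1, c0 : c1 + 1] |= d <= rad
    img = np.full((H, W), background_level, dtype=np.float32)
    img[fg] = foreground_level
    if noise_sd > 0:
        seed = network_noise_seed(config) if rng_seed is None else rng_seed
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return VesselImage(data=img, pixel_size_um=config.pixel_size_um)


def network_noise_seed(config: NetworkConfig) -> int:
    """Deterministic noise seed derived from the network seed."""
    return (int(config.rng_seed) * 2654435761 + 97) % (2**31 - 1)


# ---------------------------------------------------------------------------
# MR phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MRPhantomConfig:
    """Bimodal-intensity MR phantom: ellipsoidal brain in dark background,
    hyperintense spherical-cap lesion at a cortical site, and a small
    hemorrhage core that carries negative phase.

    Intensity means are in arbitrary scanner units; fractions are of brain
    voxels. Defaults give a lesion occupying ~4% of the brain with a
    hemorrhage core ~0.3% of the brain, the scale seen on T2/SWI one day
    after a moderate cortical contusion.
    """

    shape_voxels: tuple[int, int, int] = (32, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.128, 0.128)
    brain_mean: float = 120.0
    lesion_mean: float = 180.0
    hemorrhage_mean: float = 60.0
    background_mean: float = 20.0
    magnitude_mean: float = 100.0
    magnitude_hemorrhage_mean: float = 60.0  # short T2* darkens blood on magnitude
    noise_sd: float = 5.0
    lesion_fraction_of_brain: float = 0.04
    hemorrhage_fraction_of_brain: float = 0.003
    hemorrhage_phase_rad: float = -1.8
    phase_noise_sd: float = 0.02
    rng_seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.shape_voxels):
            raise ConfigurationError("shape_voxels must be positive")
        if self.noise_sd < 0 or self.phase_noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        for name in ("lesion_fraction_of_brain", "hemorrhage_fraction_of_brain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        means = [self.background_mean, self.brain_mean]
        if self.lesion_fraction_of_brain > 0:
            means.append(self.lesion_mean)
        if self.hemorrhage_fraction_of_brain > 0:
            means.append(self.hemorrhage_mean)
        if len(set(means)) != len(means):
            raise ConfigurationError("compartment intensity means must be pairwise distinct")
        if not -math.pi <= self.hemorrhage_phase_rad <= math.pi:
            raise ConfigurationError("hemorrhage_phase_rad must be in [-pi, pi]")


@dataclass(frozen=True)
class MRPhantom:
    t2: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray
    masks: dict = field(default_factory=dict)  # brain / lesion / hemorrhage
    config: MRPhantomConfig | None = None


def _sphere_mask(shape, center, radius):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


def _fit_sphere_fraction(brain, center, target_voxels, r_max):
    """Binary-search a sphere radius so |sphere ∩ brain| hits target_voxels."""
    lo, hi = 0.0, float(r_max)
    best = None
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        m = _sphere_mask(brain.shape, center, mid) & brain
        n = int(m.sum())
        best = (m, n)
        if n < target_voxels:
            lo = mid
        else:
            hi = mid
    return best


def generate_mr_phantom(config: MRPhantomConfig) -> MRPhantom:
    """Build T2-like, magnitude and phase volumes plus ground-truth masks.

    The lesion is the intersection of a sphere centred on the dorsal brain
    surface with the brain (a spherical cap); its radius is solved so the
    realized fraction of brain voxels matches the request within 10%
    discretization. The hemorrhage is a smaller sphere just beneath the
    lesion center. The magnitude volume is flat across the brain so that
    susceptibility contrast comes entirely from the phase channel.
    """
    config.validate()
    nz, ny, nx = config.shape_voxels
    rng = np.random.default_rng(config.rng_seed)

    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    c = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    semi = (0.42 * nz, 0.40 * ny, 0.42 * nx)
    brain = ((zz - c[0]) / semi[0]) ** 2 + ((yy - c[1]) / semi[1]) ** 2 + (
        (xx - c[2]) / semi[2]
    ) ** 2 <= 1.0
    n_brain = int(brain.sum())
    if n_brain == 0:
        raise ConfigurationError("brain ellipsoid is empty at this shape")

    lesion = np.zeros_like(brain)
    hemorrhage = np.zeros_like(brain)

    if config.lesion_fraction_of_brain > 0:
        target = config.lesion_fraction_of_brain * n_brain
        # center on the dorsal (low-y) brain surface at mid z/x
        surf_y = int(c[1] - semi[1]) + 1
        center = (int(c[0]), surf_y, int(c[2]))
        lesion, n_les = _fit_sphere_fraction(brain, center, target, max(ny, nx))
        if not (0.9 * target <= n_les <= 1.1 * target):
            raise ConfigurationError(
                f"lesion fraction {config.lesion_fraction_of_brain} cannot be realized "
                f"in shape {config.shape_voxels} (got {n_les / n_brain:.4f})"
            )
    if config.hemorrhage_fraction_of_brain > 0:
        if config.lesion_fraction_of_brain <= 0:
            raise ConfigurationError("hemorrhage requires a lesion compartment")
        target = config.hemorrhage_fraction_of_brain * n_brain
        les_z, les_y, les_x = np.nonzero(lesion)
        center = (
            int(round(les_z.mean())),
            int(round(les_y.mean())),
            int(round(les_x.mean())),
        )
        hemorrhage, n_hem = _fit_sphere_fraction(brain, center, target, max(ny, nx))
        if not (0.8 * target <= n_hem <= 1.25 * target):
            raise ConfigurationError(
                f"hemorrhage fraction {config.hemorrhage_fraction_of_brain} cannot be "
                f"realized in shape {config.shape_voxels}"
            )
        hemorrhage &= lesion | brain

    t2 = np.full(config.shape_voxels, config.background_mean, dtype=np.float64)
    t2[brain] = config.brain_mean
    t2[lesion] = config.lesion_mean
    t2[hemorrhage] = config.hemorrhage_mean

    magnitude = np.full(config.shape_voxels, config.background_mean, dtype=np.float64)
    magnitude[brain] = config.magnitude_mean
    magnitude[hemorrhage] = config.magnitude_hemorrhage_mean

    phase = np.zeros(config.shape_voxels, dtype=np.float64)
    phase[hemorrhage] = config.hemorrhage_phase_rad

    if config.noise_sd > 0:
        t2 = t2 + rng.normal(0.0, config.noise_sd, t2.shape)
        magnitude = np.maximum(
            magnitude + rng.normal(0.0, config.noise_sd, magnitude.shape), 0.0
        )
    if config.phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, config.phase_noise_sd, phase.shape)
    phase = np.clip(phase, -math.pi, math.pi)

    masks = {"brain": brain, "lesion": lesion, "hemorrhage": hemorrhage}
    return MRPhantom(t2=t2, magnitude=magnitude, phase=phase, masks=masks, config=config)
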