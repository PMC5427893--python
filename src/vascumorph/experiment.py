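"""End-to-end synthetic experiment: sham and injured cohorts through the
full measurement pipeline.

Each subject is a freshly grown synthetic network; injured subjects
additionally undergo focal-plus-global segment ablation before rendering.
Every rendered image is binarized, skeletonized and measured (junctions,
length, density) and LFD-mapped once; metrics and fractal features are then
read out per analysis region (whole cortex, hemispheres, concentric rings),
producing a tidy table and a group-comparison report. All per-subject
randomness derives deterministically from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fractal as _fractal
from . import metrics as _metrics
from . import roi as _roi
from . import stats_report as _stats
from .core import ConfigurationError
from .synthetic import (
    GroundTruthNetwork,
    LesionSpec,
    NetworkConfig,
    ablate_network,
    generate_vessel_network,
    rasterize_network,
)

__all__ = ["ExperimentConfig", "SubjectResult", "ExperimentResult", "run_experiment", "analyze_image"]

logger = logging.getLogger(__name__)

FRACTAL_METRICS = ("peak_lfd", "peak_frequency", "skewness", "kurtosis")
CLASSICAL_METRICS = ("junction_count", "total_length_um", "vessel_density")


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one synthetic cohort study.

    Defaults mirror a small-animal study: 5 subjects per group, a focal
    epicenter in the right hemisphere, 1/2/3 mm analysis rings, moderate
    global rarefication (30%) with near-complete loss at the impact core.
    """

    n_sham: int = 5
    n_tbi: int = 5
    network: NetworkConfig = field(default_factory=NetworkConfig)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    ring_radii_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    fractal: _fractal.FractalConfig = field(
        default_factory=lambda: _fractal.FractalConfig(stride_px=2)
    )
    epicenter_rc_px: tuple[float, float] = (180.0, 460.0)
    midline_col_px: int = 320
    noise_sd: float = 8.0
    rng_master_seed: int = 0

    def validate(self) -> None:
        if self.n_sham < 1 or self.n_tbi < 1:
            raise ConfigurationError("cohort sizes must be >= 1")
        self.network.validate()
        self.lesion.validate()
        self.fractal.validate()


@dataclass
class SubjectResult:
    subject: str
    group: str
    network: GroundTruthNetwork
    rows: list[dict]


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    report: _stats.Report
    subjects: list[SubjectResult]
    config: ExperimentConfig


def _subject_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-subject seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(3 * n, dtype=np.uint32).reshape(n, 3) >> np.uint32(1)


def region_masks(config: ExperimentConfig, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Analysis regions on the synthetic field (whole image = cortex)."""
    cortex = np.ones(shape, dtype=bool)
    ipsi, contra = _roi.hemisphere_masks(cortex, config.midline_col_px, "right")
    rings = _roi.concentric_rings(
        config.epicenter_rc_px,
        config.ring_radii_mm,
        config.network.pixel_size_um,
        cortex,
    )
    regions = {"whole": cortex, "ipsilateral": ipsi, "contralateral": contra}
    for k, m in enumerate(rings.ring_masks, start=1):
        regions[f"ring{k}"] = m
    return regions


def analyze_image(
    image,
    regions: dict[str, np.ndarray],
    fractal_config: _fractal.FractalConfig,
    compute_fractal: bool = True,
) -> list[dict]:
    """Measure one image in every region; returns tidy metric rows."""
    mask = _metrics.binarize(image, method="otsu")
    sk = _metrics.skeletonize_mask(mask)
    graph = _metrics.extract_network_graph(
        sk, mask.pixel_size_um, prune_spur_px=_metrics.SPUR_PRUNE_DEFAULT_PX
    )
    lfd_map = (
        _fractal.local_fractal_dimension_map(mask, None, fractal_config)
        if compute_fractal
        else None
    )
    rows = []
    for region, rmask in regions.items():
        m = _metrics.compute_metrics(mask, graph, rmask)
        rows += [
            {"region": region, "metric": "junction_count", "value": m.junction_count},
            {"region": region, "metric": "total_length_um", "value": m.total_length_um},
            {"region": region, "metric": "vessel_density", "value": m.vessel_density},
        ]
        if lfd_map is not None:
            sub = _fractal.LFDMap(
                lfd=lfd_map.lfd, valid_mask=lfd_map.valid_mask & rmask
            )
            if sub.n_valid >= 10:
                feats = _fractal.fractal_features(sub)
                rows += [
                    {"region": region, "metric": "peak_lfd", "value": feats.peak_lfd},
                    {"region": region, "metric": "peak_frequency", "value": feats.peak_frequency},
                    {"region": region, "metric": "skewness", "value": feats.skewness},
                    {"region": region, "metric": "kurtosis", "value": feats.kurtosis},
                ]
    return rows


def run_experiment(config: ExperimentConfig, compute_fractal: bool = True) -> ExperimentResult:
    """Run the full sham-vs-injured synthetic study."""
    config.validate()
    seeds = _subject_seeds(
        config.rng_master_seed, config.n_sham + config.n_tbi
    )
    shape = (config.network.image_height_px, config.network.image_width_px)
    regions = region_masks(config, shape)

    subjects: list[SubjectResult] = []
    all_rows: list[dict] = []
    groups = ["sham"] * config.n_sham + ["tbi"] * config.n_tbi
    for i, group in enumerate(groups):
        net_seed, abl_seed, noise_seed = (int(s) for s in seeds[i])
        net_cfg = replace(config.network, rng_seed=net_seed)
        network = generate_vessel_network(net_cfg)
        if group == "tbi":
            network = ablate_network(network, config.lesion, abl_seed)
        image = rasterize_network(
            network, net_cfg, noise_sd=config.noise_sd, rng_seed=noise_seed
        )
        rows = analyze_image(image, regions, config.fractal, compute_fractal)
        subject = f"{group}-{i:02d}"
        for row in rows:
            row.update(subject=subject, group=group)
        logger.info("subject %s: %d metric rows", subject, len(rows))
        subjects.append(SubjectResult(subject=subject, group=group, network=network, rows=rows))
        all_rows += rows

    table = pd.DataFrame(all_rows, columns=["group", "subject", "region", "metric", "value"])
    report = _stats.build_report(table, control_group="sham", treated_group="tbi")
    return ExperimentResult(table=table, report=report, subjects=subjects, config=config)
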