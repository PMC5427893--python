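"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from vascumorph.metrics import (
    SPUR_PRUNE_DEFAULT_PX,
    binarize,
    extract_network_graph,
    skeletonize_mask,
)
from vascumorph.synthetic import (
    LesionSpec,
    NetworkConfig,
    ablate_network,
    generate_vessel_network,
    rasterize_network,
)


def measure_network(network, config, noise_seed):
    """Full measurement pipeline: raster -> binarize -> skeleton -> graph."""
    img = rasterize_network(network, config, rng_seed=noise_seed)
    mask = binarize(img)
    graph = extract_network_graph(
        skeletonize_mask(mask), mask.pixel_size_um, prune_spur_px=SPUR_PRUNE_DEFAULT_PX
    )
    return mask, graph


@pytest.fixture(scope="session")
def ablation_study():
    """Ground-truth recovery and graded global ablation over 20 seeds.

    For each seed: the sham network's measured junctions/length, and for
    each global ablation fraction f in {0.2, 0.4, 0.6} the ablated
    network's ground truth and measurements. Shared by the recovery,
    ablation-response and monotonicity tests because it is the expensive
    part of the suite.
    """
    fractions = (0.2, 0.4, 0.6)
    records = []
    for seed in range(20):
        cfg = NetworkConfig(rng_seed=seed)
        net = generate_vessel_network(cfg)
        _, g0 = measure_network(net, cfg, noise_seed=seed + 1000)
        rec = {
            "gt_junctions": net.junction_count,
            "gt_length_um": net.total_length_um,
            "junctions": g0.junction_count,
            "length_um": g0.total_length_um,
            "ablated": {},
        }
        for f in fractions:
            les = LesionSpec(
                radius_px=0.0, core_ablation_fraction=0.0, global_ablation_fraction=f
            )
            abl = ablate_network(net, les, rng_seed=seed + 99)
            _, g1 = measure_network(abl, cfg, noise_seed=seed + 1000)
            rec["ablated"][f] = {
                "junctions": g1.junction_count,
                "length_um": g1.total_length_um,
            }
        records.append(rec)
    return {"fractions": fractions, "records": records}


@pytest.fixture(scope="session")
def dense_mask():
    """Binarized raster of one sham-like default network."""
    cfg = NetworkConfig(rng_seed=11)
    net = generate_vessel_network(cfg)
    img = rasterize_network(net, cfg, rng_seed=1011)
    return binarize(img)


@pytest.fixture(scope="session")
def sierpinski():
    """Level-7 Sierpinski triangle raster (128 x 128)."""
    n = 128
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (i & j) == 0
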