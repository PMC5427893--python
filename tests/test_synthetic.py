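"""Synthetic vessel-network and MR-phantom generators: exact ground truth,
seeded determinism, and the lesion ablation model."""

import dataclasses

import numpy as np
import pytest

from vascumorph.core import ConfigurationError
from vascumorph.synthetic import (
    GroundTruthNetwork,
    LesionSpec,
    MRPhantomConfig,
    NetworkConfig,
    ablate_network,
    generate_mr_phantom,
    generate_vessel_network,
    rasterize_network,
)

SMALL = NetworkConfig(
    image_height_px=256, image_width_px=320, n_seed_trunks=20, max_steps=40
)


class TestGenerateNetwork:
    def test_no_branching_means_no_junctions(self):
        cfg = dataclasses.replace(SMALL, branch_probability=0.0, rng_seed=5)
        net = generate_vessel_network(cfg)
        assert net.n_segments > 0
        assert net.junction_count == 0

    def test_seeded_determinism(self):
        cfg = dataclasses.replace(SMALL, rng_seed=7)
        assert generate_vessel_network(cfg) == generate_vessel_network(cfg)

    def test_branching_rate_raises_junction_count(self):
        # Monte-Carlo over 20 seeds: more branching -> more junctions
        means = {}
        for bp in (0.02, 0.10):
            counts = [
                generate_vessel_network(
                    dataclasses.replace(SMALL, branch_probability=bp, rng_seed=s)
                ).junction_count
                for s in range(20)
            ]
            means[bp] = np.mean(counts)
        assert means[0.10] > means[0.02]

    def test_segments_inside_bounds(self):
        cfg = dataclasses.replace(SMALL, rng_seed=3)
        net = generate_vessel_network(cfg)
        for a, b, _w in net.segments:
            for r, c in (a, b):
                assert 0 <= r < cfg.image_height_px
                assert 0 <= c < cfg.image_width_px

    def test_junctions_are_exactly_triple_points(self):
        cfg = dataclasses.replace(SMALL, rng_seed=9)
        net = generate_vessel_network(cfg)
        incidence = {}
        for a, b, _w in net.segments:
            incidence[a] = incidence.get(a, 0) + 1
            incidence[b] = incidence.get(b, 0) + 1
        expected = sorted(p for p, k in incidence.items() if k >= 3)
        assert sorted(net.junction_points) == expected

    @pytest.mark.parametrize(
        "bad",
        [
            {"image_height_px": 0},
            {"pixel_size_um": 0.0},
            {"branch_probability": 1.5},
            {"width_range_px": (0, 3)},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            generate_vessel_network(dataclasses.replace(SMALL, **bad))


@pytest.fixture(scope="module")
def net():
    return generate_vessel_network(dataclasses.replace(SMALL, rng_seed=21))


class TestAblateNetwork:

    def test_zero_lesion_is_identity(self, net):
        les = LesionSpec(radius_px=0.0, core_ablation_fraction=0.0, global_ablation_fraction=0.0)
        assert ablate_network(net, les, rng_seed=1) == net

    def test_full_global_ablation_empties_network(self, net):
        les = LesionSpec(radius_px=0.0, global_ablation_fraction=1.0)
        out = ablate_network(net, les, rng_seed=1)
        assert out.n_segments == 0
        assert out.total_length_um == 0.0
        assert out.junction_count == 0

    def test_flat_core_ablation_clears_radius(self, net):
        center = (128.0, 160.0)
        les = LesionSpec(
            center_rc_px=center,
            radius_px=60.0,
            core_ablation_fraction=1.0,
            global_ablation_fraction=0.0,
            falloff="flat",
        )
        out = ablate_network(net, les, rng_seed=2)
        for a, b, _w in out.segments:
            mid = (0.5 * (a[0] + b[0]), 0.5 * (a[1] + b[1]))
            d = np.hypot(mid[0] - center[0], mid[1] - center[1])
            assert d >= les.radius_px

    @pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
    def test_ablation_never_increases_ground_truth(self, net, f):
        les = LesionSpec(global_ablation_fraction=f)
        out = ablate_network(net, les, rng_seed=3)
        assert out.junction_count <= net.junction_count
        assert out.total_length_um <= net.total_length_um


class TestRasterize:
    def test_empty_network_is_pure_background(self):
        net = GroundTruthNetwork.from_segments([], SMALL.pixel_size_um)
        img = rasterize_network(net, SMALL, noise_sd=0.0)
        assert np.all(img.data == img.data.flat[0])
        assert img.data.flat[0] < 100

    def test_single_line_pixel_count(self):
        net = GroundTruthNetwork.from_segments(
            [((100.0, 50.0), (100.0, 150.0), 1)], SMALL.pixel_size_um
        )
        img = rasterize_network(net, SMALL, noise_sd=0.0)
        n_fg = int((img.data > 100).sum())
        assert 99 <= n_fg <= 102

    def test_total_length_round_trip(self):
        # 10 well-separated horizontal strokes: skeleton length within 10%
        from vascumorph.metrics import binarize, extract_network_graph, skeletonize_mask

        segs = [((20.0 + 22 * k, 30.0), (20.0 + 22 * k, 290.0), 3) for k in range(10)]
        net = GroundTruthNetwork.from_segments(segs, SMALL.pixel_size_um)
        img = rasterize_network(net, SMALL, noise_sd=0.0)
        mask = binarize(img)
        graph = extract_network_graph(skeletonize_mask(mask), mask.pixel_size_um)
        assert graph.total_length_um == pytest.approx(net.total_length_um, rel=0.10)


class TestMRPhantom:
    def test_no_lesion_is_bimodal_brain_background(self):
        cfg = MRPhantomConfig(
            lesion_fraction_of_brain=0.0, hemorrhage_fraction_of_brain=0.0, noise_sd=0.0
        )
        ph = generate_mr_phantom(cfg)
        assert not ph.masks["lesion"].any()
        assert set(np.unique(ph.t2)) == {cfg.background_mean, cfg.brain_mean}

    def test_zero_noise_gives_exact_compartment_means(self):
        cfg = MRPhantomConfig(noise_sd=0.0, phase_noise_sd=0.0)
        ph = generate_mr_phantom(cfg)
        m = ph.masks
        assert np.all(ph.t2[m["hemorrhage"]] == cfg.hemorrhage_mean)
        assert np.all(ph.t2[m["lesion"] & ~m["hemorrhage"]] == cfg.lesion_mean)
        assert np.all(ph.t2[m["brain"] & ~m["lesion"]] == cfg.brain_mean)
        assert np.all(ph.t2[~m["brain"]] == cfg.background_mean)

    def test_requested_lesion_fraction_realized(self):
        cfg = MRPhantomConfig(lesion_fraction_of_brain=0.038)
        ph = generate_mr_phantom(cfg)
        frac = ph.masks["lesion"].sum() / ph.masks["brain"].sum()
        assert 0.034 <= frac <= 0.042

    def test_hemorrhage_carries_negative_phase(self):
        ph = generate_mr_phantom(MRPhantomConfig(rng_seed=2))
        assert np.median(ph.phase[ph.masks["hemorrhage"]]) < -1.0
        assert abs(np.median(ph.phase[~ph.masks["hemorrhage"]])) < 0.1

    def test_seeded_determinism(self):
        cfg = MRPhantomConfig(rng_seed=4)
        a, b = generate_mr_phantom(cfg), generate_mr_phantom(cfg)
        assert np.array_equal(a.t2, b.t2)
        assert np.array_equal(a.phase, b.phase)

    def test_unrealizable_fraction_rejected(self):
        # sub-voxel lesion cannot be discretized within 10%
        with pytest.raises(ConfigurationError):
            generate_mr_phantom(MRPhantomConfig(lesion_fraction_of_brain=1e-6))
        # hemorrhage needs a lesion to sit in
        with pytest.raises(ConfigurationError):
            generate_mr_phantom(
                MRPhantomConfig(
                    lesion_fraction_of_brain=0.0, hemorrhage_fraction_of_brain=0.01
                )
            )
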