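"""Classical skeleton morphometry: thresholding, thinning, junction
clustering, step-counted lengths, ROI-restricted metrics."""

import math

import numpy as np
import pytest

from vascumorph.core import (
    BinaryVesselMask,
    ConfigurationError,
    DegenerateInputError,
    VesselImage,
)
from vascumorph.metrics import (
    binarize,
    compute_metrics,
    extract_network_graph,
    skeletonize_mask,
)

SQRT2 = math.sqrt(2.0)


def graph_of(skeleton, pixel_size_um=1.0, **kw):
    return extract_network_graph(np.asarray(skeleton, bool), pixel_size_um, **kw)


class TestBinarize:
    def test_two_valued_image_separates_exactly(self):
        rng = np.random.default_rng(0)
        data = np.where(rng.random((32, 32)) < 0.3, 200.0, 10.0)
        mask = binarize(VesselImage(data, 2.0), method="otsu")
        assert np.array_equal(mask.mask, data == 200.0)
        assert mask.pixel_size_um == 2.0

    def test_fixed_threshold_on_zero_image(self):
        mask = binarize(VesselImage(np.zeros((8, 8)), 1.0), method="fixed", fixed_threshold=1.0)
        assert not mask.mask.any()

    def test_constant_image_otsu_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            binarize(VesselImage(np.full((8, 8), 7.0), 1.0), method="otsu")


class TestSkeletonize:
    def test_thin_rectangle_reduces_to_single_path(self):
        mask = np.zeros((20, 120), bool)
        mask[8:11, 10:110] = True  # 3 x 100 rectangle
        sk = skeletonize_mask(BinaryVesselMask(mask, 1.0))
        g = graph_of(sk)
        assert g.junction_count == 0
        assert 90 <= g.total_length_um <= 101

    def test_empty_in_empty_out(self):
        sk = skeletonize_mask(BinaryVesselMask(np.zeros((10, 10), bool), 1.0))
        assert not sk.any()
        assert graph_of(sk).total_length_um == 0.0

    def test_disk_collapses_to_near_point(self):
        rr, cc = np.mgrid[:50, :50]
        disk = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20**2
        sk = skeletonize_mask(BinaryVesselMask(disk, 1.0))
        g = graph_of(sk)
        assert g.total_length_um < 0.10 * (40 * math.pi)


class TestGraphExtraction:
    def test_plus_sign_is_one_junction_four_endpoints(self):
        sk = np.zeros((13, 13), bool)
        sk[6, 1:12] = True
        sk[1:12, 6] = True
        g = graph_of(sk)
        assert g.junction_count == 1
        kinds = [k for _, _, k in g.nodes]
        assert kinds.count("endpoint") == 4

    def test_straight_line_length_is_steps_times_pixel_size(self):
        sk = np.zeros((5, 12), bool)
        sk[2, 1:11] = True  # 10 pixels
        g = graph_of(sk, pixel_size_um=1.0)
        assert g.total_length_um == pytest.approx(9.0)
        assert g.junction_count == 0

    def test_diagonal_line_uses_sqrt2_steps(self):
        sk = np.zeros((12, 12), bool)
        for i in range(10):
            sk[i + 1, i + 1] = True
        g = graph_of(sk, pixel_size_um=1.0)
        assert g.total_length_um == pytest.approx(9 * SQRT2)

    def test_length_linear_in_pixel_size(self):
        rng = np.random.default_rng(1)
        sk = skeletonize_mask(BinaryVesselMask(rng.random((40, 40)) < 0.4, 1.0))
        g1 = graph_of(sk, pixel_size_um=1.0)
        g2 = graph_of(sk, pixel_size_um=2.0)
        assert g2.total_length_um == pytest.approx(2.0 * g1.total_length_um)
        assert g2.junction_count == g1.junction_count

    @pytest.mark.parametrize("seed", range(20))
    def test_rotation_and_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        blob = rng.random((36, 36)) < 0.35
        sk = skeletonize_mask(BinaryVesselMask(blob, 1.0))
        ref = graph_of(sk)
        for variant in (np.rot90(sk), np.rot90(sk, 2), np.fliplr(sk), np.flipud(sk)):
            g = graph_of(np.ascontiguousarray(variant))
            assert g.junction_count == ref.junction_count
            assert g.total_length_um == pytest.approx(ref.total_length_um, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_junction_count_matches_bruteforce_clustering(self, seed):
        # oracle: per-pixel neighbour counting + exhaustive cluster flooding
        rng = np.random.default_rng(100 + seed)
        sk = skeletonize_mask(BinaryVesselMask(rng.random((20, 20)) < 0.4, 1.0))
        H, W = sk.shape

        def nbrs(r, c):
            return [
                (r + dr, c + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr or dc)
                and 0 <= r + dr < H
                and 0 <= c + dc < W
                and sk[r + dr, c + dc]
            ]

        jpix = {
            (r, c)
            for r in range(H)
            for c in range(W)
            if sk[r, c] and len(nbrs(r, c)) >= 3
        }
        clusters = 0
        seen = set()
        for p in sorted(jpix):
            if p in seen:
                continue
            clusters += 1
            stack = [p]
            while stack:
                q = stack.pop()
                if q in seen:
                    continue
                seen.add(q)
                stack.extend(n for n in nbrs(*q) if n in jpix)
        assert graph_of(sk).junction_count == clusters

    def test_spur_pruning_removes_short_terminal_branch(self):
        sk = np.zeros((15, 30), bool)
        sk[7, 2:28] = True  # long horizontal path
        sk[5:7, 10] = True  # 2-px spur hanging off it
        raw = graph_of(sk)
        pruned = graph_of(sk, prune_spur_px=4.0)
        assert raw.junction_count == 1
        assert pruned.junction_count == 0
        assert pruned.total_length_um < raw.total_length_um


class TestComputeMetrics:
    def test_empty_mask_gives_zero_metrics(self):
        mask = BinaryVesselMask(np.zeros((10, 10), bool), 1.0)
        g = graph_of(np.zeros((10, 10), bool))
        m = compute_metrics(mask, g, np.ones((10, 10), bool))
        assert m.junction_count == 0
        assert m.total_length_um == 0.0
        assert m.vessel_density == 0.0

    def test_full_foreground_density_is_one(self):
        full = np.ones((10, 10), bool)
        mask = BinaryVesselMask(full, 2.0)
        g = graph_of(skeletonize_mask(mask), pixel_size_um=2.0)
        m = compute_metrics(mask, g, full)
        assert m.vessel_density == 1.0
        assert m.vessel_area_um2 == m.roi_area_um2 == 100 * 4.0

    def test_empty_roi_rejected(self):
        mask = BinaryVesselMask(np.ones((5, 5), bool), 1.0)
        g = graph_of(np.zeros((5, 5), bool))
        with pytest.raises(DegenerateInputError):
            compute_metrics(mask, g, np.zeros((5, 5), bool))

    def test_roi_shape_mismatch_rejected(self):
        mask = BinaryVesselMask(np.ones((5, 5), bool), 1.0)
        g = graph_of(np.zeros((5, 5), bool))
        with pytest.raises(ConfigurationError):
            compute_metrics(mask, g, np.ones((4, 4), bool))

    def test_roi_restriction_splits_whole_image_length(self):
        sk = np.zeros((9, 40), bool)
        sk[4, 0:40] = True
        mask = BinaryVesselMask(sk, 1.0)
        g = graph_of(sk)
        left = np.zeros((9, 40), bool)
        left[:, :20] = True
        m_left = compute_metrics(mask, g, left)
        m_all = compute_metrics(mask, g, np.ones((9, 40), bool))
        assert m_left.total_length_um < m_all.total_length_um
        assert m_left.vessel_area_um2 == 20.0
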