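import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as skdisk

from marrowquant import (AdipocyteGhost, filter_ghosts, fragment_ghosts,
                         measure_ghost, measure_ghosts, size_distribution)
from marrowquant.adipocytes import retained_mask
from marrowquant import default_config


def disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    rr, cc = skdisk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestFragmentation:
    def test_single_disk_single_label(self, marrow_cfg):
        cand = disk_mask((60, 60), (30, 30), 15)
        labels = fragment_ghosts(cand, np.zeros((60, 60)), marrow_cfg)
        assert labels.max() == 1
        assert np.array_equal(labels > 0, cand)

    def test_touching_disks_split_on_membrane(self, marrow_cfg):
        # two disks joined by a neck, with an eosin membrane line across it
        cand = disk_mask((60, 100), (30, 30), 14) | disk_mask((60, 100), (30, 62), 14)
        cand[28:33, 42:50] = True  # 2 μm-scale neck
        membrane = np.zeros((60, 100))
        membrane[:, 45:47] = 0.5
        labels = fragment_ghosts(cand, membrane, marrow_cfg)
        assert labels.max() == 2
        left = np.unique(labels[30, :40]); right = np.unique(labels[30, 52:])
        assert left[left > 0][0] != right[right > 0][0]

    def test_empty_candidates(self, marrow_cfg):
        labels = fragment_ghosts(np.zeros((20, 20), bool), np.zeros((20, 20)),
                                 marrow_cfg)
        assert labels.max() == 0

    def test_labels_partition_candidates(self, marrow_cfg):
        rng = np.random.default_rng(4)
        cand = np.zeros((120, 120), bool)
        for _ in range(12):
            cand |= disk_mask((120, 120), tuple(rng.integers(15, 105, 2)),
                              int(rng.integers(5, 14)))
        labels = fragment_ghosts(cand, np.zeros((120, 120)), marrow_cfg)
        assert np.array_equal(labels > 0, cand)

    def test_deterministic(self, marrow_cfg):
        rng = np.random.default_rng(9)
        cand = np.zeros((80, 80), bool)
        for _ in range(6):
            cand |= disk_mask((80, 80), tuple(rng.integers(10, 70, 2)), 9)
        membrane = rng.random((80, 80)) * 0.3
        a = fragment_ghosts(cand, membrane, marrow_cfg)
        b = fragment_ghosts(cand.copy(), membrane.copy(), marrow_cfg)
        assert np.array_equal(a, b)

    def test_shallow_component_still_labeled(self, marrow_cfg):
        # 1-px-deep sliver: no h-maximum survives, fallback labeling applies
        cand = np.zeros((20, 40), bool)
        cand[10, 5:35] = True
        labels = fragment_ghosts(cand, np.zeros((20, 40)), marrow_cfg)
        assert np.array_equal(labels > 0, cand)


class TestMorphometry:
    def test_digitized_disk(self):
        # radius 40 px at 0.5 μm/px → radius 20 μm
        mask = disk_mask((100, 100), (50, 50), 40)
        g = measure_ghost(mask, pixel_size=0.5)
        assert g.area == pytest.approx(np.pi * 20 ** 2, rel=0.02)
        assert g.circularity >= 0.95

    def test_square_circularity_near_pi_over_4(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        g = measure_ghost(mask, pixel_size=1.0)
        assert g.circularity == pytest.approx(np.pi / 4, abs=0.05)

    def test_thin_line_low_circularity(self):
        mask = np.zeros((10, 60), bool)
        mask[5, 5:55] = True
        g = measure_ghost(mask, pixel_size=1.0)
        assert g.circularity < 0.3

    def test_centroid_and_area_units(self):
        mask = np.zeros((20, 20), bool)
        mask[4:8, 10:14] = True  # 16 px
        g = measure_ghost(mask, pixel_size=2.0)
        assert g.area == 16 * 4.0
        assert g.centroid == (11.5, 5.5)  # (x, y)

    def test_edge_touching_against_excluded(self):
        mask = disk_mask((40, 40), (20, 8), 6)
        analysis = np.zeros((40, 40), bool)
        analysis[:, 3:] = True  # excluded stripe on the left
        g = measure_ghost(mask, 1.0, analysis_mask=analysis)
        assert g.edge_touching
        g2 = measure_ghost(disk_mask((40, 40), (20, 25), 6), 1.0,
                           analysis_mask=analysis)
        assert not g2.edge_touching

    def test_measure_ghosts_matches_single(self, marrow_cfg):
        labels = np.zeros((50, 50), np.int32)
        labels[disk_mask((50, 50), (25, 25), 10)] = 1
        many = measure_ghosts(labels, 1.0)
        one = measure_ghost(labels == 1, 1.0)
        assert len(many) == 1
        assert many[0].area == one.area
        assert many[0].circularity == pytest.approx(one.circularity, abs=1e-6)


def ghost(area, circ=0.9, edge=False):
    return AdipocyteGhost(id=1, area=area, perimeter=1.0, circularity=circ,
                          centroid=(0.0, 0.0), edge_touching=edge,
                          pixel_count=int(area))


class TestFilters:
    def test_marrow_examples(self):
        cfg = default_config("marrow")
        _, rej = filter_ghosts([ghost(100.0, 0.9)], cfg)
        assert rej[0].rejection_reason == "too_small"
        _, rej = filter_ghosts([ghost(600.0, 0.2)], cfg)
        assert rej[0].rejection_reason == "low_circularity"
        ret, _ = filter_ghosts([ghost(120.0, 0.3)], cfg)
        assert ret and ret[0].retained  # boundaries inclusive

    def test_adipo_edge_exclusion(self):
        cfg = default_config("adipo")
        _, rej = filter_ghosts([ghost(1000.0, 0.8, edge=True)], cfg)
        assert rej[0].rejection_reason == "edge"
        ret, _ = filter_ghosts([ghost(1000.0, 0.8, edge=False)], cfg)
        assert ret[0].retained

    def test_rejection_reason_order(self):
        cfg = default_config("adipo")  # min 300, exclude edges
        _, rej = filter_ghosts([ghost(100.0, 0.0, edge=True)], cfg)
        assert rej[0].rejection_reason == "too_small"  # size tested first
        _, rej = filter_ghosts([ghost(5000.0, 0.0, edge=True)], cfg)
        assert rej[0].rejection_reason == "too_large"

    def test_retained_mask_union(self):
        labels = np.zeros((20, 20), np.int32)
        labels[:5, :5] = 1
        labels[10:, 10:] = 2
        ghosts = [ghost(25.0), ghost(100.0)]
        ghosts[0].id, ghosts[1].id = 1, 2
        ghosts[1].retained = False
        mask = retained_mask(labels, ghosts)
        assert mask[:5, :5].all() and not mask[10:, 10:].any()


class TestSizeDistribution:
    def test_direct_binning(self):
        hist = size_distribution([400.0, 600.0, 620.0], 250.0, upper=1000.0)
        assert hist.counts.tolist() == [0, 1, 2, 0]

    def test_empty_input(self):
        hist = size_distribution([], 250.0, upper=1000.0)
        assert hist.counts.sum() == 0
        assert hist.frequencies.sum() == 0

    def test_conservation_lognormal(self):
        rng = np.random.default_rng(0)
        areas = np.exp(rng.normal(6.5, 0.5, 1000))
        hist = size_distribution(list(areas), 250.0)
        assert hist.counts.sum() == 1000
        assert hist.frequencies.sum() == pytest.approx(1.0)

    def test_rejected_ghosts_not_counted(self):
        a, b = ghost(400.0), ghost(600.0)
        b.retained = False
        hist = size_distribution([a, b], 250.0, upper=1000.0)
        assert hist.counts.sum() == 1
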