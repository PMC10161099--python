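"""Image pipeline: top-hat, segmentation, counting, aggregation.

Independent oracles: a brute-force min-then-max morphological opening
for the top-hat, and an exhaustive flood fill for component counting.
"""

import numpy as np
import pytest
from skimage.morphology import disk

from colloidquant.imaging import (
    ChannelConfig,
    Micrograph,
    Treatment,
    aggregate_replicate,
    colocalization_count,
    count_objects,
    default_quant_config,
    quantify_image,
    segment,
    tophat_filter,
)
from colloidquant.synthetic import SceneParams, generate_micrograph


def brute_force_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Erosion (min) then dilation (max) over an explicit disk, pixel by
    pixel, with edge replication matching the morphology convention."""
    fp = disk(radius).astype(bool)
    h, w = img.shape
    pad = radius

    def sweep(src, op):
        padded = np.pad(src, pad, mode="symmetric")
        out = np.empty_like(src)
        for r in range(h):
            for c in range(w):
                window = padded[r:r + 2 * pad + 1, c:c + 2 * pad + 1]
                out[r, c] = op(window[fp])
        return out

    eroded = sweep(img, min)
    return sweep(eroded, max)


def flood_fill_count(binary: np.ndarray) -> int:
    """Exhaustive BFS connected-component count (8-connectivity)."""
    seen = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and binary[rr, cc]
                                    and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


class TestTophat:
    def test_constant_raster_maps_to_zero(self):
        out = tophat_filter(np.full((32, 32), 700.0), 3)
        np.testing.assert_allclose(out, 0.0)

    def test_matches_brute_force_opening(self):
        rng = np.random.default_rng(0)
        img = np.full((64, 64), 500.0)
        rr, cc = np.mgrid[0:64, 0:64]
        img += 2000.0 * np.exp(-((rr - 30) ** 2 + (cc - 33) ** 2) / (2 * 2**2))
        img += rng.normal(0, 20, img.shape)
        expected = img - brute_force_opening(img, 5)
        np.testing.assert_allclose(tophat_filter(img, 5), expected,
                                   atol=1e-9)
        # the spot survives, the offset does not
        out = tophat_filter(img, 5)
        assert out[30, 33] > 1500
        assert abs(out[5, 5]) < 200

    def test_offset_translation_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1000, (48, 48))
        np.testing.assert_allclose(
            tophat_filter(img + 250.0, 4), tophat_filter(img, 4), atol=1e-9
        )

    @pytest.mark.parametrize("radius", [0, 30])
    def test_bad_radius_rejected(self, radius):
        with pytest.raises(ValueError):
            tophat_filter(np.zeros((40, 40)), radius)


def _two_disk_scene(r=10, sep=14):
    img = np.zeros((64, 64))
    rr, cc = np.mgrid[0:64, 0:64]
    for center in ((32, 25), (32, 25 + sep)):
        img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r * r] = 1.0
    return img


class TestSegment:
    FIXED = dict(threshold_method="fixed", threshold_value=0.5, min_area=1)

    def test_blank_raster_gives_no_labels(self):
        cfg = ChannelConfig()
        assert count_objects(segment(np.zeros((32, 32)), cfg)) == 0

    def test_otsu_on_constant_raster_gives_empty_mask(self):
        cfg = ChannelConfig(threshold_method="otsu")
        assert count_objects(segment(np.full((32, 32), 5.0), cfg)) == 0

    def test_watershed_splits_touching_disks(self):
        img = _two_disk_scene()
        with_ws = ChannelConfig(**self.FIXED, watershed_enabled=True)
        without = ChannelConfig(**self.FIXED, watershed_enabled=False)
        assert count_objects(segment(img, with_ws)) == 2
        assert count_objects(segment(img, without)) == 1

    def test_min_area_filter_drops_small_objects(self):
        img = np.zeros((32, 32))
        img[10:12, 10:12] = 1.0  # 4 px
        cfg = ChannelConfig(threshold_method="fixed", threshold_value=0.5,
                            min_area=5)
        assert count_objects(segment(img, cfg)) == 0

    def test_connected_component_equivalence_without_watershed(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            binary = rng.random((64, 64)) < 0.25
            cfg = ChannelConfig(threshold_method="fixed",
                                threshold_value=0.5, min_area=1,
                                watershed_enabled=False)
            labels = segment(binary.astype(float), cfg)
            assert count_objects(labels) == flood_fill_count(binary)

    def test_increasing_min_area_never_increases_count(self, small_scene):
        _, channels, _ = small_scene
        filtered = tophat_filter(channels["did"].astype(float), 5)
        counts = [
            count_objects(segment(filtered, ChannelConfig(min_area=a)))
            for a in (1, 3, 9, 27, 81)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCounting:
    def test_count_empty_and_labeled_masks(self):
        assert count_objects(np.zeros((8, 8), dtype=int)) == 0
        labels = np.arange(11).reshape(1, 11).repeat(2, axis=0)
        assert count_objects(labels) == 10

    def test_full_pipeline_counts_match_truth(self, study_scene):
        params, channels, truth = study_scene
        counts = quantify_image(Micrograph(channels=channels))
        for attr, objects in (("nuclei", "nuclei"), ("foci", "foci"),
                              ("puncta", "puncta"), ("vesicles", "vesicles")):
            expected = truth.count(objects)
            assert abs(getattr(counts, attr) - expected) <= 0.05 * expected

    def test_ratios_are_counts_over_nuclei(self, study_scene):
        _, channels, _ = study_scene
        c = quantify_image(Micrograph(channels=channels))
        assert c.puncta_per_cell == pytest.approx(c.puncta / c.nuclei)
        assert c.ratios_defined

    def test_blocker_well_has_zero_puncta(self):
        params = SceneParams(n_nuclei=20, n_puncta=0, n_foci=8, n_vesicles=0)
        channels, _ = generate_micrograph(params, (256, 256), seed=9)
        c = quantify_image(Micrograph(channels=channels))
        assert c.puncta == 0 and c.puncta_per_cell == 0.0

    def test_blank_image_counts_zero_ratios_undefined(self):
        params = SceneParams(n_nuclei=0, n_puncta=0, n_foci=0, n_vesicles=0,
                             noise_sd=0.0)
        channels, _ = generate_micrograph(params, (128, 128), seed=0)
        c = quantify_image(Micrograph(channels=channels))
        assert (c.nuclei, c.foci, c.puncta, c.vesicles) == (0, 0, 0, 0)
        assert not c.ratios_defined and np.isnan(c.foci_per_cell)


class TestAggregate:
    def test_mean_of_ratios(self, small_scene):
        _, channels, _ = small_scene
        base = quantify_image(Micrograph(channels=channels))
        import dataclasses
        images = [
            dataclasses.replace(base, foci_per_cell=v)
            for v in (0.2, 0.4, 0.6)
        ]
        rec = aggregate_replicate(images, well_id="w1")
        assert rec.foci_per_cell == pytest.approx(0.4)

    def test_identical_images_aggregate_to_themselves(self, small_scene):
        _, channels, _ = small_scene
        c = quantify_image(Micrograph(channels=channels))
        rec = aggregate_replicate([c, c, c])
        assert rec.puncta_per_cell == pytest.approx(c.puncta_per_cell)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicate([])


class TestMicrographType:
    def test_mismatched_channel_shapes_rejected(self):
        with pytest.raises(ValueError):
            Micrograph(channels={"nuclei": np.zeros((4, 4)),
                                 "did": np.zeros((5, 5))})

    def test_colocalization_counts_mutual_overlaps(self):
        a = np.zeros((32, 32), dtype=int)
        b = np.zeros((32, 32), dtype=int)
        a[5:10, 5:10] = 1     # overlaps b label 1
        b[5:10, 5:10] = 1
        a[20:25, 20:25] = 2   # no partner
        assert colocalization_count(a, b) == 1
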