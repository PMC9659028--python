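"""Synthetic slide/heatmap/cohort generators."""

import numpy as np
import pytest

from lymphmet.detection import extract_detections, filter_itc_size
from lymphmet.synthetic import (
    CODE_HEALTHY,
    CODE_TUMOR,
    CohortSpec,
    HeatmapSpec,
    ScoreDist,
    generate_cohort,
    generate_heatmap,
    generate_patch_set,
    generate_slide,
    patch_extent_um,
    perfect_heatmap_spec,
    simulate_slides,
)
from lymphmet.tnm import gt_label_from_diameters


def spec(**kw):
    base = dict(dataset_name="t", n_negative=2, n_positive=2, seed=9,
                slide_extent_mm=(6.0, 6.0), raster_spacing_um=16.0,
                macro_diameter_mm=(2.2, 2.8))
    base.update(kw)
    return CohortSpec(**base)


class TestGenerateSlide:
    def test_negative_slide_has_no_lesions(self):
        _, ann, rec = generate_slide(spec(n_positive=0, n_negative=1), 0)
        assert len(ann) == 0
        assert rec.gt_label == "negative"

    def test_positive_slide_has_lesions_and_consistent_label(self):
        for idx in (2, 3):
            _, ann, rec = generate_slide(spec(), idx)
            assert len(ann) >= 1
            assert rec.gt_label == gt_label_from_diameters(ann.diameters_mm())

    def test_micro_fraction_one_forces_micro_label(self):
        s = spec(micro_fraction=1.0, n_positive=4, n_negative=0)
        for idx in range(4):
            _, ann, rec = generate_slide(s, idx)
            assert all(0.2 < d <= 2.0 for d in ann.diameters_mm())
            assert rec.gt_label == "micro"

    def test_itc_fraction_one_labels_itc_only(self):
        s = spec(itc_fraction=1.0, n_positive=3, n_negative=0)
        for idx in range(3):
            _, ann, rec = generate_slide(s, idx)
            assert all(d <= 0.2 for d in ann.diameters_mm())
            assert rec.gt_label == "itc_only"

    def test_deterministic_given_seed_and_index(self):
        t1, a1, r1 = generate_slide(spec(), 3)
        t2, a2, r2 = generate_slide(spec(), 3)
        assert np.array_equal(t1, t2)
        assert len(a1) == len(a2)
        for l1, l2 in zip(a1, a2):
            assert np.array_equal(l1.polygon_um, l2.polygon_um)
        assert r1 == r2

    def test_different_indices_differ(self):
        t1, _, _ = generate_slide(spec(), 0)
        t2, _, _ = generate_slide(spec(), 1)
        assert not np.array_equal(t1, t2)

    def test_degenerate_extent_rejected(self):
        s = spec(slide_extent_mm=(2.0, 2.0), macro_diameter_mm=(2.5, 2.5),
                 micro_fraction=0.0)
        with pytest.raises(ValueError, match="lesion|tissue"):
            for idx in range(2, 4):
                generate_slide(s, idx)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            generate_slide(spec(), 4)

    def test_lesions_inside_tissue(self):
        tissue, ann, rec = generate_slide(spec(), 2)
        mask = ann.rasterize(tissue.shape, rec.spacing_um)
        assert (tissue[mask > 0] > 0.3).all()


class TestGenerateHeatmap:
    def test_perfect_scores_inside_lesions(self):
        s = spec()
        tissue, ann, rec = generate_slide(s, 2)
        hm, truth = generate_heatmap(ann, perfect_heatmap_spec(), s.slide_extent_mm,
                                     s.raster_spacing_um, seed=1)
        label = ann.rasterize(hm.values.shape, s.raster_spacing_um)
        assert (hm.values[label > 0] == 1.0).all()
        assert (hm.values[label == 0] < 0.5).all()
        assert truth.lesion_max_scores == [1.0] * len(ann)

    def test_empty_annotations_no_blobs_stays_low(self):
        from lymphmet.annotations import AnnotationSet

        hm, truth = generate_heatmap(AnnotationSet(), HeatmapSpec(seed=4),
                                     (6.0, 6.0), 16.0)
        assert hm.values.max() < 0.5
        assert truth.fp_blobs == []

    def test_scores_in_unit_interval(self):
        s = spec()
        _, ann, _ = generate_slide(s, 3)
        hm, _ = generate_heatmap(ann, HeatmapSpec(fp_blob_rate=3.0, seed=2),
                                 s.slide_extent_mm, s.raster_spacing_um, seed=2)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0

    def test_deterministic_given_seed(self):
        s = spec()
        _, ann, _ = generate_slide(s, 2)
        h1, _ = generate_heatmap(ann, HeatmapSpec(fp_blob_rate=2.0, seed=8),
                                 s.slide_extent_mm, s.raster_spacing_um)
        h2, _ = generate_heatmap(ann, HeatmapSpec(fp_blob_rate=2.0, seed=8),
                                 s.slide_extent_mm, s.raster_spacing_um)
        assert np.array_equal(h1.values, h2.values)

    def test_fp_blob_count_matches_poisson_rate(self):
        """Retained detections on negative slides are Poisson(rate)."""
        from lymphmet.annotations import AnnotationSet

        rate, n_slides = 8.0, 60
        counts = []
        for i in range(n_slides):
            hm, truth = generate_heatmap(
                AnnotationSet(), HeatmapSpec(fp_blob_rate=rate, seed=100),
                (10.0, 10.0), 16.0, seed=100 + i)
            retained = filter_itc_size(extract_detections(hm))
            assert len(retained) == len(truth.fp_blobs)
            counts.append(len(retained))
        mean = np.mean(counts)
        se = np.sqrt(rate / n_slides)
        assert abs(mean - rate) < 3 * se


class TestGenerateCohort:
    def test_manifest_counts_match_specs(self, tmp_path):
        specs = [spec(dataset_name="a", n_negative=2, n_positive=1),
                 spec(dataset_name="b", n_negative=1, n_positive=0)]
        m = generate_cohort(specs, HeatmapSpec(seed=1), tmp_path / "c")
        assert len(m) == 4
        assert m.count("a") == 3 and m.count("b") == 1

    def test_empty_spec_list(self, tmp_path):
        m = generate_cohort([], HeatmapSpec(), tmp_path / "c")
        assert len(m) == 0

    def test_duplicate_names_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unique"):
            generate_cohort([spec(), spec()], HeatmapSpec(), tmp_path / "c")

    def test_nonempty_dir_without_overwrite(self, tmp_path):
        out = tmp_path / "c"
        generate_cohort([spec(n_negative=1, n_positive=0)], HeatmapSpec(), out)
        with pytest.raises(FileExistsError):
            generate_cohort([spec(n_negative=1, n_positive=0)], HeatmapSpec(), out)

    def test_reruns_byte_identical(self, tmp_path):
        specs = [spec(n_negative=1, n_positive=1)]
        generate_cohort(specs, HeatmapSpec(seed=3), tmp_path / "c1")
        generate_cohort(specs, HeatmapSpec(seed=3), tmp_path / "c2")
        for name in ("manifest.csv", "truth.json"):
            assert (tmp_path / "c1" / name).read_bytes() == \
                   (tmp_path / "c2" / name).read_bytes()

    def test_annotation_roundtrip(self, tmp_path):
        from lymphmet.annotations import AnnotationSet

        out = tmp_path / "c"
        m = generate_cohort([spec(n_negative=0, n_positive=1)],
                            HeatmapSpec(seed=5), out)
        rec = m[0]
        back = AnnotationSet.from_asap_xml(out / rec.annotation_path)
        _, ann, _ = generate_slide(spec(n_negative=0, n_positive=1), 0)
        assert len(back) == len(ann)
        for l1, l2 in zip(back, ann):
            assert np.allclose(l1.polygon_um, l2.polygon_um, atol=1e-3)


@pytest.fixture(scope="module")
def slide_pair():
    s = spec(n_negative=0, n_positive=1, lesions_per_positive_slide=(2, 2))
    sims = list(simulate_slides(s, perfect_heatmap_spec()))
    sim = sims[0]
    return [(sim.tissue, sim.label_mask())]


class TestGeneratePatchSet:
    def test_tumor_fraction_binomial(self, slide_pair):
        n = 4000
        frac = 0.2
        _, labels = generate_patch_set(slide_pair, n, frac, patch_px=9, seed=0)
        sd = np.sqrt(n * frac * (1 - frac))
        assert abs(labels.sum() - n * frac) < 3 * sd

    def test_zero_tumor_fraction_all_healthy(self, slide_pair):
        _, labels = generate_patch_set(slide_pair, 200, 0.0, patch_px=9, seed=1)
        assert (labels == 0).all()

    def test_labels_match_center_pixel(self, slide_pair):
        tissue, mask = slide_pair[0]
        patches, labels = generate_patch_set(slide_pair, 100, 0.5,
                                             patch_px=9, seed=2)
        # tumor patches are centered on tumor-coded pixels: the center
        # value must equal some tumor-region tissue value
        assert patches.shape == (100, 9, 9)
        assert set(np.unique(labels)) <= {0, 1}

    def test_no_tumor_pixels_error(self):
        tissue = np.full((64, 64), 0.6, dtype=np.float32)
        mask = np.full((64, 64), CODE_HEALTHY, dtype=np.uint8)
        with pytest.raises(ValueError, match="no tumor"):
            generate_patch_set([(tissue, mask)], 10, 0.5, patch_px=9, seed=0)

    def test_physical_patch_side(self):
        assert patch_extent_um(279, 0.5) == pytest.approx(139.5)


class TestScoreDist:
    def test_constant_dist(self):
        d = ScoreDist(1.0)
        assert (d.sample(np.random.default_rng(0), 10) == 1.0).all()

    def test_clipping(self):
        d = ScoreDist(0.5, 10.0, low=0.2, high=0.8)
        x = d.sample(np.random.default_rng(0), 1000)
        assert x.min() >= 0.2 and x.max() <= 0.8

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ScoreDist(0.5, 0.1, low=0.9, high=0.1)


def test_planted_truth_recovery_small(small_cohort):
    """Label of every simulated slide follows the TNM rule on its lesions."""
    for sim in small_cohort:
        assert sim.record.gt_label == gt_label_from_diameters(
            sim.annotations.diameters_mm())
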