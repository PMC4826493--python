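import numpy as np
import pytest
from shapely.geometry import Polygon
from shapely.affinity import translate

from mitospot import PhantomSpec, detect_cells, render_phantom
from mitospot.config import DetectConfig, RunConfig
from mitospot.detect import (
    CellObject,
    TumorMask,
    fuse_chromatin,
    mart1_surround,
    measure_objects,
    score_objects,
    tumor_area,
)
from mitospot.stains import ClassMap, PixelClass

from conftest import clean_spec, greedy_match


def _class_map(labels, s=1.0):
    return ClassMap(np.asarray(labels, dtype=np.int8), s)


def _two_blobs(gap_px, blob=3, height=5):
    """Two brown blocks separated by gap_px background columns."""
    w = 2 * blob + gap_px
    labels = np.zeros((height, w + 4), dtype=np.int8)
    labels[1:4, 2 : 2 + blob] = int(PixelClass.PHH3)
    labels[1:4, 2 + blob + gap_px : 2 + 2 * blob + gap_px] = int(PixelClass.PHH3)
    return _class_map(labels)


class TestFuseChromatin:
    def test_small_gap_fuses(self):
        labeled = fuse_chromatin(_two_blobs(gap_px=3), dilation_radius_um=2.0)
        assert labeled.max() == 1  # 2 + 2 >= 3 closes the gap

    def test_large_gap_stays_split(self):
        labeled = fuse_chromatin(_two_blobs(gap_px=10), dilation_radius_um=2.0)
        assert len(np.unique(labeled[labeled > 0])) == 2

    def test_labels_only_on_original_pixels(self):
        cmap = _two_blobs(gap_px=3)
        labeled = fuse_chromatin(cmap, dilation_radius_um=2.0)
        assert np.all((labeled > 0) == (cmap.labels == int(PixelClass.PHH3)))

    def test_phantom_anaphase_count(self):
        spec = clean_spec(
            n_positive=20, n_tumor_nuclei=0, phase_mix=(0.0, 0.0, 1.0, 0.0),
            chromatin_gap_um=(4.0, 4.0), seed=31,
        )
        image, truth = render_phantom(spec)
        cells, _ = detect_cells(image, spec.lesion())
        assert len(cells.positives()) == 20
        assert len(cells) == 20  # each split figure fused into ONE object

    def test_too_large_gap_splits_figure(self):
        # the documented failure mode: chromatin separated beyond twice the
        # dilation radius is not fused
        spec = clean_spec(
            n_positive=10, n_tumor_nuclei=0, phase_mix=(0.0, 0.0, 0.0, 1.0),
            chromatin_gap_um=(8.0, 8.0), seed=32,
        )
        image, _ = render_phantom(spec)
        cells, _ = detect_cells(image, spec.lesion())
        assert len(cells) == 20  # 10 figures -> 20 split objects


class TestMart1Surround:
    def test_fully_enclosed_nucleus(self):
        labels = np.full((40, 40), int(PixelClass.MART1), dtype=np.int8)
        yy, xx = np.mgrid[:40, :40]
        obj = (yy - 20) ** 2 + (xx - 20) ** 2 <= 6**2
        labels[obj] = int(PixelClass.PHH3)
        frac = mart1_surround(obj, _class_map(labels), ring_width_um=2.0)
        assert frac == pytest.approx(1.0, abs=0.05)

    def test_isolated_blob_on_background(self):
        labels = np.zeros((40, 40), dtype=np.int8)
        yy, xx = np.mgrid[:40, :40]
        obj = (yy - 20) ** 2 + (xx - 20) ** 2 <= 6**2
        labels[obj] = int(PixelClass.PHH3)
        assert mart1_surround(obj, _class_map(labels), 2.0) == 0.0

    def test_half_contact(self):
        labels = np.zeros((40, 40), dtype=np.int8)
        labels[:, :20] = int(PixelClass.MART1)
        yy, xx = np.mgrid[:40, :40]
        obj = (yy - 20) ** 2 + (xx - 20) ** 2 <= 6**2
        labels[obj] = int(PixelClass.PHH3)
        frac = mart1_surround(obj, _class_map(labels), 2.0)
        assert frac == pytest.approx(0.5, abs=0.1)

    def test_border_clipping(self):
        labels = np.full((20, 20), int(PixelClass.MART1), dtype=np.int8)
        obj = np.zeros((20, 20), dtype=bool)
        obj[:5, :5] = True  # touches two borders
        labels[obj] = int(PixelClass.PHH3)
        frac = mart1_surround(obj, _class_map(labels), 2.0)
        assert frac == pytest.approx(1.0, abs=0.05)  # over available ring only


class TestScoreObjects:
    def _obj(self, **kw):
        base = dict(
            label=1, centroid_um=(10.0, 10.0), area_um2=25.0, mean_brown_od=0.8,
            irregularity=0.1, mart1_surround_fraction=0.9,
        )
        base.update(kw)
        return CellObject(**base)

    def test_small_pigment_granule_rejected(self):
        cells = score_objects([self._obj(area_um2=3.0)], DetectConfig())
        assert cells.cells[0].positive is False

    def test_oversized_rejected(self):
        cells = score_objects([self._obj(area_um2=500.0)], DetectConfig())
        assert not cells.cells[0].positive

    def test_no_surround_rejected(self):
        cells = score_objects([self._obj(mart1_surround_fraction=0.0)], DetectConfig())
        assert not cells.cells[0].positive

    def test_nominal_object_accepted(self):
        cells = score_objects([self._obj()], DetectConfig())
        assert cells.cells[0].positive

    def test_phantom_metaphase_positive(self):
        spec = clean_spec(n_positive=8, phase_mix=(0.0, 1.0, 0.0, 0.0), seed=33)
        image, _ = render_phantom(spec)
        cells, _ = detect_cells(image, spec.lesion())
        assert len(cells.positives()) == 8

    def test_phantom_lymphocyte_negative(self):
        spec = clean_spec(n_positive=0, n_lymphocytes=6, seed=34)
        image, _ = render_phantom(spec)
        cells, _ = detect_cells(image, spec.lesion())
        assert len(cells) >= 1  # lymphocytes are detected as objects...
        assert len(cells.positives()) == 0  # ...but fail the MART1-surround gate


class TestTumorArea:
    def test_no_stain_zero_area(self, unit_square_mm):
        cmap = _class_map(np.zeros((100, 100), dtype=np.int8), s=10.0)
        assert tumor_area(cmap, unit_square_mm).area_mm2 == 0.0

    def test_solid_red_square(self, unit_square_mm):
        s = 0.8
        n = int(round(1000 / s))
        labels = np.full((n, n), int(PixelClass.MART1), dtype=np.int8)
        mask = tumor_area(_class_map(labels, s), unit_square_mm)
        assert mask.area_mm2 == pytest.approx(1.0, rel=0.01)

    def test_area_formula_exact(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[:10, :10] = True
        tm = TumorMask(mask, um_per_px=2.0)
        assert tm.area_mm2 == 100 * 4.0 / 1e6

    def test_phantom_jaccard(self, confounder_phantom):
        spec, _, truth, _, tumor = confounder_phantom
        inter = (tumor.mask & truth.tumor_mask).sum()
        union = (tumor.mask | truth.tumor_mask).sum()
        assert inter / union >= 0.85


class TestDetectCells:
    def test_blank_image_empty(self, unit_square_mm):
        from mitospot.stains import CalibratedImage

        img = CalibratedImage(np.full((200, 200, 3), 255, dtype=np.uint8), 5.0)
        cells, tumor = detect_cells(img, unit_square_mm)
        assert len(cells) == 0
        assert tumor.area_mm2 == 0.0

    def test_noisefree_exact_count(self, noisefree_phantom):
        spec, _, truth, cells, _ = noisefree_phantom
        assert len(cells.positives()) == len(truth.positive_centroids)

    def test_confounders_sensitivity_precision(self, confounder_phantom):
        spec, _, truth, cells, _ = confounder_phantom
        tp, n_det, n_truth = greedy_match(
            cells.positive_centroids(), truth.positive_centroids
        )
        assert tp / n_truth >= 0.9
        assert tp / n_det >= 0.9

    def test_pigment_only_no_positives(self):
        spec = clean_spec(n_positive=0, n_tumor_nuclei=40, n_pigment=30, seed=35)
        image, _ = render_phantom(spec)
        cells, _ = detect_cells(image, spec.lesion())
        assert len(cells.positives()) == 0

    def test_exclusion_monotonicity(self, noisefree_phantom):
        spec, image, _, cells, tumor = noisefree_phantom
        exclusion = Polygon([(300, 300), (700, 300), (700, 700), (300, 700)])
        cells_ex, tumor_ex = detect_cells(image, spec.lesion(), [exclusion])
        assert len(cells_ex.positives()) <= len(cells.positives())
        assert tumor_ex.area_mm2 <= tumor.area_mm2

    def test_translation_stability(self, noisefree_phantom):
        spec, image, _, cells, _ = noisefree_phantom
        from mitospot.stains import CalibratedImage

        shifted = CalibratedImage(
            np.roll(image.pixels, (1, 1), axis=(0, 1)), image.um_per_px
        )
        outline = translate(spec.lesion(), spec.um_per_px, spec.um_per_px)
        cells_shift, _ = detect_cells(shifted, outline)
        assert len(cells_shift.positives()) == len(cells.positives())

    def test_provenance_recorded(self, noisefree_phantom):
        _, _, _, cells, _ = noisefree_phantom
        assert cells.provenance["config_hash"] == RunConfig().hash()
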