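import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from spinepath.palette import REFERENCE_HEC, compose_rgb
from spinepath.morphometry import (
    HistomorphometryFeatures,
    collagen_fraction,
    compute_features,
    feature_table,
    marrow_adiposity,
    nuclei_morphometry,
    segment_bone,
    trabecular_metrics,
)
from spinepath.synth.slides import render_slide, spec_for_class


def max_inscribed_disc_width(mask: np.ndarray) -> float:
    """Oracle: diameter of the largest disc inscribed in the structure."""
    return 2.0 * float(ndi.distance_transform_edt(mask).max())


class TestSegmentBone:
    def test_dice_against_planted_mask(self, class_slides):
        for cls, (img, gt) in class_slides.items():
            bone, marrow = segment_bone(img, gt.tissue_mask)
            dice = 2 * (bone & gt.bone_mask).sum() / (bone.sum() + gt.bone_mask.sum())
            assert dice >= 0.9, f"class {cls}: Dice {dice:.3f}"

    def test_marrow_only_fixture_zero_bone(self):
        conc = np.zeros((256, 256, 3))
        conc[..., 1] = 0.18  # faint eosin marrow, no dense bone
        img = compose_rgb(conc, REFERENCE_HEC)
        tissue = np.ones((256, 256), dtype=bool)
        bone, marrow = segment_bone(img, tissue)
        assert bone.sum() / tissue.sum() < 0.02

    def test_bone_plus_marrow_equals_tissue(self, class_slides):
        img, gt = class_slides[1]
        bone, marrow = segment_bone(img, gt.tissue_mask)
        assert np.array_equal(bone | marrow, gt.tissue_mask)
        assert not (bone & marrow).any()

    def test_no_tissue_gives_empty_masks(self):
        img = np.full((256, 256, 3), 255, dtype=np.uint8)
        bone, marrow = segment_bone(img, np.zeros((256, 256), bool))
        assert not bone.any() and not marrow.any()


class TestTrabecularMetrics:
    @pytest.mark.parametrize("width", [4, 8, 16, 32])
    def test_bar_thickness_matches_inscribed_disc_oracle(self, width):
        mask = np.zeros((80, 200), dtype=bool)
        mask[40 - width // 2 : 40 + (width + 1) // 2, :] = True
        m = trabecular_metrics(mask, microns_per_pixel=1.0)
        assert abs(m["thickness_um"] - max_inscribed_disc_width(mask)) <= 1.0
        assert abs(m["thickness_um"] - width) <= 1.0

    def test_scale_multiplies_thickness(self):
        mask = np.zeros((80, 200), dtype=bool)
        mask[36:44, :] = True
        t1 = trabecular_metrics(mask, 1.0)["thickness_um"]
        t2 = trabecular_metrics(mask, 2.0)["thickness_um"]
        assert np.isclose(t2, 2 * t1)

    def test_solid_disc_component_term_zero(self):
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = draw_disk((100, 100), 60)
        mask[rr, cc] = True
        n_comp = ndi.label(mask)[1]
        assert n_comp - 1 == 0

    def test_disruption_strictly_increases_with_cuts(self):
        base = np.zeros((300, 300), dtype=bool)
        for pos in range(20, 300, 40):
            base[pos : pos + 8, :] = True
            base[:, pos : pos + 8] = True
        scores = []
        mask = base.copy()
        scores.append(trabecular_metrics(mask, 2.0)["disruption_score"])
        cut_positions = [(24, 150), (64, 70), (104, 230), (144, 110)]
        for r, c in cut_positions:
            mask[r - 6 : r + 10, c - 6 : c + 6] = False
            scores.append(trabecular_metrics(mask, 2.0)["disruption_score"])
        assert all(b > a for a, b in zip(scores, scores[1:])), scores

    def test_empty_mask_missing_metrics(self):
        m = trabecular_metrics(np.zeros((50, 50), bool), 2.0)
        assert m["bone_fraction"] == 0.0
        assert np.isnan(m["thickness_um"])

    def test_bone_fraction_is_pixel_ratio(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:30] = True
        m = trabecular_metrics(mask, 1.0)
        assert np.isclose(m["bone_fraction"], 0.3)


class TestAdiposity:
    def _marrow_image(self, vacuole_centers, radius=10, shape=(256, 256)):
        conc = np.zeros(shape + (3,))
        conc[..., 1] = 0.2
        fat = np.zeros(shape, dtype=bool)
        for r, c in vacuole_centers:
            rr, cc = draw_disk((r, c), radius, shape=shape)
            fat[rr, cc] = True
        conc[fat] = 0.0
        return compose_rgb(conc, REFERENCE_HEC), fat

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(0)
        centers = [(r, c) for r in range(20, 240, 40) for c in range(20, 240, 40)]
        img, fat = self._marrow_image(centers)
        marrow = np.ones((256, 256), dtype=bool)
        frac = marrow_adiposity(img, marrow)
        true = fat.sum() / marrow.sum()
        assert abs(frac - true) <= 0.03

    def test_no_vacuoles_zero(self):
        img, _ = self._marrow_image([])
        assert marrow_adiposity(img, np.ones((256, 256), bool)) == 0.0

    def test_empty_marrow_missing(self):
        img, _ = self._marrow_image([])
        assert np.isnan(marrow_adiposity(img, np.zeros((256, 256), bool)))

    def test_tumor_packed_marrow_near_zero(self, class_slides):
        img, gt = class_slides[2]
        tumor = gt.discriminative_mask
        if tumor.sum() > 500:
            frac = marrow_adiposity(img, tumor)
            assert frac < 0.05


class TestCollagen:
    def _collagen_image(self, frac, shape=(256, 256), seed=0):
        rng = np.random.default_rng(seed)
        conc = np.zeros(shape + (3,))
        conc[..., 1] = 0.2
        fld = ndi.gaussian_filter(rng.normal(size=shape), 10)
        k = int(frac * shape[0] * shape[1])
        if k:
            thr = np.partition(fld.ravel(), fld.size - k)[fld.size - k]
            mask = fld >= thr
            conc[mask, 2] = 0.75
            conc[mask, 1] = 0.1
        return compose_rgb(conc, REFERENCE_HEC)

    def test_planted_fraction_recovered(self):
        img = self._collagen_image(0.40)
        frac, fib = collagen_fraction(img, np.ones((256, 256), bool))
        assert abs(frac - 0.40) <= 0.05

    def test_zero_collagen(self):
        img = self._collagen_image(0.0)
        frac, fib = collagen_fraction(img, np.ones((256, 256), bool))
        assert frac == 0.0 and fib == 0.0

    def test_doubling_extent_doubles_fraction(self):
        f1, _ = collagen_fraction(self._collagen_image(0.10), np.ones((256, 256), bool))
        f2, _ = collagen_fraction(self._collagen_image(0.20), np.ones((256, 256), bool))
        assert abs(f2 / f1 - 2.0) < 0.3

    def test_fibrosis_score_saturates(self):
        img = self._collagen_image(0.6)
        frac, fib = collagen_fraction(img, np.ones((256, 256), bool))
        assert fib == 1.0


class TestNuclei:
    def _nuclei_image(self, ellipses, shape=(256, 256)):
        conc = np.zeros(shape + (3,))
        conc[..., 1] = 0.15
        for r, c, a, b, theta in ellipses:
            rr, cc = draw_ellipse(r, c, a, b, shape=shape, rotation=theta)
            conc[rr, cc, 0] = 1.2
        return compose_rgb(conc, REFERENCE_HEC)

    def test_analytic_ellipse_eccentricity(self):
        # a = 2b -> e = sqrt(3)/2
        ellipses = [(r, c, 12, 6, 0.2 * i) for i, (r, c) in enumerate((r, c) for r in range(30, 230, 50) for c in range(30, 230, 50))]
        img = self._nuclei_image(ellipses)
        out = nuclei_morphometry(
            img, np.zeros((256, 256), bool), np.ones((256, 256), bool), 2.0, max_nucleus_px=500
        )
        assert abs(out["nucleus_eccentricity_mean"] - np.sqrt(3) / 2) <= 0.01

    def test_circles_near_zero_eccentricity(self):
        ellipses = [(r, c, 8, 8, 0) for r in range(30, 230, 50) for c in range(30, 230, 50)]
        img = self._nuclei_image(ellipses)
        out = nuclei_morphometry(
            img, np.zeros((256, 256), bool), np.ones((256, 256), bool), 2.0, max_nucleus_px=500
        )
        assert out["nucleus_eccentricity_mean"] <= 0.35

    def test_no_nuclei_densities_zero_eccentricity_missing(self):
        img = self._nuclei_image([])
        out = nuclei_morphometry(img, np.zeros((256, 256), bool), np.ones((256, 256), bool), 2.0)
        assert out["nucleus_count"] == 0
        assert np.isnan(out["nucleus_eccentricity_mean"])
        assert out["inflammatory_cell_density_per_mm2"] == 0.0

    def test_planted_lacunae_density(self):
        # 50 lacunae punched in a solid bone block
        shape = (512, 512)
        conc = np.zeros(shape + (3,))
        conc[..., 1] = 0.95
        bone = np.ones(shape, dtype=bool)
        rng = np.random.default_rng(4)
        count = 0
        positions = []
        while count < 50:
            r, c = rng.integers(10, 500, 2)
            if all(abs(r - r0) + abs(c - c0) > 16 for r0, c0 in positions):
                rr, cc = draw_ellipse(r, c, 2.6, 1.8, shape=shape)
                conc[rr, cc, 1] = 0.0
                positions.append((r, c))
                count += 1
        img = compose_rgb(conc, REFERENCE_HEC)
        mpp = np.sqrt(2e6 / (512 * 512))  # bone area exactly 2 mm^2
        out = nuclei_morphometry(img, bone, np.zeros(shape, bool), mpp)
        assert abs(out["osteocyte_density_per_mm2"] - 25.0) <= 2.5


class TestFeatureTable:
    def test_three_cases_full_table(self, class_slides):
        cases = {}
        for cls, (img, gt) in class_slides.items():
            cases[f"case{cls}"] = compute_features(img, 2.0, gt.tissue_mask)
        df = feature_table(cases)
        assert df.shape == (3, 11)
        assert not df.isna().any().any()

    def test_empty_marrow_gives_na_not_zero(self):
        f = HistomorphometryFeatures(trabecular_bone_fraction=1.0)
        df = feature_table({"a": f})
        assert np.isnan(df.loc["a", "marrow_adiposity_fraction"])

    def test_duplicate_ids_rejected(self):
        pairs = [("a", HistomorphometryFeatures()), ("a", HistomorphometryFeatures())]
        with pytest.raises(ValueError, match="duplicate"):
            feature_table(pairs)

    def test_rerun_identical(self, class_slides):
        img, gt = class_slides[0]
        f1 = compute_features(img, 2.0, gt.tissue_mask)
        f2 = compute_features(img, 2.0, gt.tissue_mask)
        assert f1 == f2


@pytest.fixture(scope="module")
def cohort_features():
    feats = {cls: [] for cls in range(3)}
    for cls in range(3):
        for seed in range(8):
            img, gt = render_slide(spec_for_class(cls, seed=500 + 17 * seed + cls))
            feats[cls].append(compute_features(img, 2.0, gt.tissue_mask))
    return feats


class TestClassSeparation:
    def test_osteoporotic_thinnest_trabeculae(self, cohort_features):
        means = {
            cls: np.mean([f.trabecular_thickness_um for f in fs])
            for cls, fs in cohort_features.items()
        }
        assert means[0] < means[1] and means[0] < means[2]

    def test_neoplastic_highest_eccentricity(self, cohort_features):
        means = {
            cls: np.mean([f.nucleus_eccentricity_mean for f in fs])
            for cls, fs in cohort_features.items()
        }
        assert means[2] > means[0] and means[2] > means[1]

    def test_fractions_within_bounds(self, cohort_features):
        for fs in cohort_features.values():
            for f in fs:
                assert 0 <= f.trabecular_bone_fraction <= 1
                assert 0 <= f.marrow_adiposity_fraction <= 1
                assert 0 <= f.nucleus_eccentricity_mean < 1
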