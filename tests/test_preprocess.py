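import warnings

import numpy as np
import pytest

from spinepath.palette import REFERENCE_HE, compose_rgb
from spinepath.preprocess import (
    PreprocessConfig,
    StainProfile,
    detect_artifacts,
    estimate_stains,
    normalize_stains,
    otsu_threshold,
    reference_profile,
    segment_tissue,
    tile_slide,
    unmix_concentrations,
)


def brute_force_otsu(channel: np.ndarray) -> int:
    """Independent oracle: exhaustive between-class variance maximization."""
    vals = channel.ravel().astype(np.float64)
    best_t, best_var = -1, -1.0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            var = 0.0
        else:
            w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t if best_var > 0 else -1


class TestOtsu:
    def test_equals_exhaustive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            # bimodal-ish random 8-bit images
            a = rng.normal(rng.uniform(40, 100), 20, size=500)
            b = rng.normal(rng.uniform(150, 220), 25, size=500)
            img = np.clip(np.concatenate([a, b]), 0, 255).astype(np.uint8)
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_two_level_image_separates_exactly(self):
        img = np.full((50, 50), 230, dtype=np.uint8)  # background 0.9 * 255
        img[:20] = 51  # tissue 0.2 * 255, 40% of area
        t = otsu_threshold(img)
        assert 51 <= t < 230
        mask = img <= t
        assert mask.sum() == 20 * 50

    def test_uniform_image_returns_sentinel(self):
        assert otsu_threshold(np.full((10, 10), 77, dtype=np.uint8)) == -1

    def test_all_white_image_gives_empty_mask_with_warning(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning, match="uniform"):
            mask = segment_tissue(img)
        assert not mask.any()


class TestMacenko:
    def _mixture(self, seed=0, shape=(120, 120)):
        rng = np.random.default_rng(seed)
        conc = np.stack(
            [rng.uniform(0, 1.2, shape), rng.uniform(0, 1.0, shape)], axis=-1
        )
        return compose_rgb(conc, REFERENCE_HE), conc

    def test_recovers_known_vectors_within_5_degrees(self):
        img, _ = self._mixture()
        prof = estimate_stains(img)
        for j in range(2):
            cosang = float(prof.stain_matrix[:, j] @ REFERENCE_HE[:, j])
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 5.0

    def test_column_order_hematoxylin_first(self):
        img, _ = self._mixture(seed=3)
        prof = estimate_stains(img)
        assert prof.stain_matrix[2, 0] > prof.stain_matrix[2, 1]

    def test_single_stain_image_raises_rank_error(self):
        rng = np.random.default_rng(1)
        conc = np.stack([rng.uniform(0.2, 1.2, (80, 80)), np.zeros((80, 80))], axis=-1)
        img = compose_rgb(conc, REFERENCE_HE)
        with pytest.raises(ValueError, match="rank-deficient|single-stain"):
            estimate_stains(img)

    def test_too_few_tissue_pixels_raises(self):
        img = np.full((40, 40, 3), 255, dtype=np.uint8)
        with pytest.raises(ValueError, match="segment"):
            estimate_stains(img)

    def test_self_normalization_near_identity(self):
        img, _ = self._mixture(seed=7)
        prof = estimate_stains(img)
        out = normalize_stains(img, prof, prof)
        assert np.abs(out.astype(float) - img.astype(float)).mean() < 2.0

    def test_unmix_recovers_planted_concentrations(self):
        img, conc = self._mixture(seed=9)
        rec = unmix_concentrations(img, REFERENCE_HE)
        assert np.abs(rec - conc).mean() < 0.02

    def test_doubling_eosin_changes_only_eosin_channel(self):
        _, conc = self._mixture(seed=11)
        doubled = conc.copy()
        doubled[..., 1] = np.minimum(doubled[..., 1] * 2, 2.0)
        img2 = compose_rgb(doubled, REFERENCE_HE)
        rec2 = unmix_concentrations(img2, REFERENCE_HE)
        assert np.abs(rec2[..., 1] - doubled[..., 1]).mean() < 0.03
        assert np.abs(rec2[..., 0] - conc[..., 0]).mean() < 0.03

    def test_pure_white_pixels_stay_white(self):
        img = np.full((60, 60, 3), 255, dtype=np.uint8)
        img[:30, :30] = compose_rgb(np.full((30, 30, 2), 0.5), REFERENCE_HE)
        ref = reference_profile()
        src = StainProfile(REFERENCE_HE.copy(), np.array([0.8, 0.9]))
        out = normalize_stains(img, src, ref)
        assert (out[40:, 40:] >= 253).all()

    def test_stain_profile_validation(self):
        with pytest.raises(ValueError, match="unit-norm"):
            StainProfile(np.ones((3, 2)), np.ones(2))


def grid_count(extent: int, tile: int, stride: int) -> int:
    """Closed-form oracle: floor((W - T)/S) + 1, plus a shifted edge tile."""
    if extent < tile:
        return 0
    base = (extent - tile) // stride + 1
    covered_last = (base - 1) * stride + tile
    return base + (1 if covered_last < extent else 0)


class TestTiling:
    @pytest.mark.parametrize(
        "shape,tile,overlap",
        [
            ((1024, 1024), 512, 0.5),
            ((512, 512), 512, 0.5),
            ((1024, 768), 256, 0.5),
            ((700, 700), 128, 0.5),
            ((640, 384), 128, 0.25),
            ((512, 512), 256, 0.75),
            ((300, 300), 128, 0.5),
            ((1000, 600), 200, 0.5),
            ((256, 256), 128, 0.5),
            ((800, 800), 400, 0.5),
        ],
    )
    def test_tile_counts_match_grid_formula(self, shape, tile, overlap):
        img = np.full(shape + (3,), 100, dtype=np.uint8)
        mask = np.ones(shape, dtype=bool)
        cfg = PreprocessConfig(tile_size_px=tile, overlap_fraction=overlap)
        bag = tile_slide(img, mask, cfg, run_artifact_checks=False)
        stride = int(round(tile * (1 - overlap)))
        expected = grid_count(shape[0], tile, stride) * grid_count(shape[1], tile, stride)
        assert len(bag) == expected

    def test_1024_all_tissue_gives_9_tiles_at_expected_coords(self):
        img = np.full((1024, 1024, 3), 100, dtype=np.uint8)
        bag = tile_slide(img, np.ones((1024, 1024), bool), PreprocessConfig(), run_artifact_checks=False)
        assert len(bag) == 9
        assert sorted({c[0] for c in bag.coords}) == [0, 256, 512]
        assert sorted({c[1] for c in bag.coords}) == [0, 256, 512]

    def test_single_tile_for_exact_fit(self):
        img = np.full((512, 512, 3), 100, dtype=np.uint8)
        bag = tile_slide(img, np.ones((512, 512), bool), PreprocessConfig(), run_artifact_checks=False)
        assert len(bag) == 1
        assert bag.coords == [(0, 0)]

    def test_blank_tiles_dropped(self):
        img = np.full((512, 768, 3), 100, dtype=np.uint8)
        mask = np.ones((512, 768), dtype=bool)
        mask[:, 512:] = False  # right third background
        cfg = PreprocessConfig(tile_size_px=512, overlap_fraction=0.5)
        bag = tile_slide(img, mask, cfg, run_artifact_checks=False)
        # the tile at col=256 has 50% blank (kept); a hypothetical col=512 tile
        # would be 100% blank; shifted edge tile at 256 duplicates -> dedup via coords
        for (r, c), q in zip(bag.coords, bag.qc_flags):
            pass
        blanks = [q for q in bag.qc_flags if q["blank"]]
        kept = {c for c in bag.coords}
        assert all(q["blank_fraction"] <= 0.5 for q in bag.qc_flags if not q["blank"])
        for q in blanks:
            assert (q["row"], q["col"]) not in kept

    def test_60_percent_background_tile_dropped(self):
        img = np.full((512, 512, 3), 100, dtype=np.uint8)
        mask = np.ones((512, 512), dtype=bool)
        mask[:, : int(512 * 0.6)] = False
        cfg = PreprocessConfig(tile_size_px=512)
        bag = tile_slide(img, mask, cfg, run_artifact_checks=False)
        assert len(bag) == 0

    def test_coords_unique_and_in_bounds(self, bordered_slide):
        img, gt = bordered_slide
        mask = segment_tissue(img)
        cfg = PreprocessConfig(tile_size_px=128)
        bag = tile_slide(img, mask, cfg, run_artifact_checks=False)
        assert len(set(bag.coords)) == len(bag.coords)
        for r, c in bag.coords:
            assert 0 <= r <= img.shape[0] - 128
            assert 0 <= c <= img.shape[1] - 128

    def test_empty_mask_warns_and_returns_empty_bag(self):
        img = np.full((256, 256, 3), 100, dtype=np.uint8)
        with pytest.warns(UserWarning, match="empty"):
            bag = tile_slide(img, np.zeros((256, 256), bool), PreprocessConfig(tile_size_px=128))
        assert len(bag) == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(overlap_fraction=1.5)
        with pytest.raises(ValueError):
            PreprocessConfig(tile_size_px=32)


class TestArtifacts:
    def _clean_tile(self):
        rng = np.random.default_rng(0)
        conc = np.stack(
            [rng.uniform(0.2, 1.0, (64, 64)), rng.uniform(0.2, 0.8, (64, 64))], axis=-1
        )
        return compose_rgb(conc, REFERENCE_HE)

    def test_clean_tile_has_no_flags(self):
        flags = detect_artifacts(self._clean_tile())
        assert not any(flags.values())

    def test_gaussian_blurred_tile_flags_blur(self):
        from scipy.ndimage import gaussian_filter

        tile = self._clean_tile().astype(np.float64)
        blurred = np.clip(gaussian_filter(tile, sigma=(8, 8, 0)), 0, 255).astype(np.uint8)
        assert detect_artifacts(blurred)["blur"]
        assert not detect_artifacts(self._clean_tile())["blur"]

    def test_all_white_tile_flags_blank(self):
        tile = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert detect_artifacts(tile)["blank"]

    def test_dark_saturated_fold_flags_fold(self):
        tile = self._clean_tile()
        tile[:, :30] = (80, 20, 60)  # dark, saturated band
        assert detect_artifacts(tile)["fold"]


def test_segmentation_recovers_tissue_block(bordered_slide):
    img, gt = bordered_slide
    mask = segment_tissue(img)
    inter = (mask & gt.tissue_mask).sum()
    dice = 2 * inter / (mask.sum() + gt.tissue_mask.sum())
    assert dice > 0.9
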