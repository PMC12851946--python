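"""Slide preprocessing: tissue segmentation, stain normalization, tiling, QC.

The five-step workflow is: (1) Otsu tissue segmentation, (2) Macenko stain
normalization against a reference profile, (3) tiling with overlap,
(4) artifact/blank removal, (5) bag assembly for the classifier.

Coordinates are 0-based ``(row, col)`` top-left positions; a tile spans the
half-open range ``[row, row+T) x [col, col+T)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import nnls
from skimage.color import rgb2hsv
from skimage.morphology import disk

from .palette import REFERENCE_HE, od_to_rgb, rgb_to_od


@dataclass
class StainProfile:
    """Macenko stain profile: 3x2 unit-column OD matrix + max concentrations."""

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=np.float64)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=np.float64)
        if self.stain_matrix.shape[0] != 3:
            raise ValueError("stain_matrix must have 3 rows (RGB OD)")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must be unit-norm")
        if (self.stain_matrix < -1e-9).any():
            raise ValueError("stain_matrix entries must be nonnegative")


@dataclass
class PreprocessConfig:
    tile_size_px: int = 512
    overlap_fraction: float = 0.5
    blank_fraction_max: float = 0.5
    od_background_threshold: float = 0.15
    macenko_alpha: float = 1.0
    concentration_percentile: float = 99.0
    blur_variance_min: float = 3.0
    fold_fraction_max: float = 0.25
    reference_stain_profile: StainProfile | None = None

    def __post_init__(self):
        if not (0.0 < self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in (0, 1)")
        if self.tile_size_px < 64:
            raise ValueError("tile_size_px must be >= 64")


@dataclass
class TileBag:
    """All QC-passing tiles of one slide: the MIL bag."""

    slide_id: str
    tiles: list[np.ndarray]
    coords: list[tuple[int, int]]
    qc_flags: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)


def otsu_threshold(channel: np.ndarray) -> int:
    """Otsu threshold on an 8-bit channel.

    Returns the cut ``t`` maximizing between-class variance when pixels are
    split into ``value <= t`` vs ``value > t`` (ties: smallest ``t``).
    Returns -1 when the image has zero between-class variance everywhere.
    """
    hist = np.bincount(np.asarray(channel, dtype=np.uint8).ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    p = hist / n
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    denom = omega * (1.0 - omega)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(denom > 0, (mu_t * omega - mu) ** 2 / denom, 0.0)
    if sigma_b.max() <= 0:
        return -1
    return int(np.argmax(sigma_b))


def tissue_channel(image: np.ndarray) -> np.ndarray:
    """Scalar channel for tissue/background separation.

    Uses (1 - saturation) * value, which is ~1 for white background and
    lower for stained tissue even when the stain is faint eosin.
    """
    hsv = rgb2hsv(np.asarray(image, dtype=np.uint8))
    return np.clip((1.0 - hsv[..., 1]) * hsv[..., 2] * 255.0, 0, 255).astype(np.uint8)


def segment_tissue(
    image: np.ndarray, opening_radius: int = 2, closing_radius: int = 6
) -> np.ndarray:
    """Binary tissue mask via Otsu on the background channel + morphology."""
    channel = tissue_channel(image)
    t = otsu_threshold(channel)
    if t < 0:
        warnings.warn("uniform image: returning all-background mask")
        return np.zeros(image.shape[:2], dtype=bool)
    mask = channel <= t
    mask = ndi.binary_opening(mask, structure=disk(opening_radius))
    mask = ndi.binary_closing(mask, structure=disk(closing_radius))
    # pale marrow and clear vacuoles sit inside the stained lattice; fill them
    mask = ndi.binary_fill_holes(mask)
    return mask


def estimate_stains(
    image: np.ndarray,
    od_threshold: float = 0.15,
    alpha: float = 1.0,
    percentile: float = 99.0,
) -> StainProfile:
    """Macenko stain-vector estimation.

    Projects high-OD pixels onto the top-2 OD singular plane and takes the
    extreme-angle directions at the (alpha, 100-alpha) percentiles as the
    stain vectors.  Hematoxylin (larger blue-channel OD) is column 0.
    """
    od = rgb_to_od(image).reshape(-1, 3)
    keep = np.linalg.norm(od, axis=1) > od_threshold
    od_t = od[keep]
    if od_t.shape[0] < 100:
        raise ValueError(
            "too few high-OD pixels for stain estimation; segment tissue first"
        )
    _, s, vt = np.linalg.svd(od_t, full_matrices=False)
    # quantization noise leaves a tiny second singular value even for a
    # single-stain image; 2% of the leading one separates the cases cleanly
    if s[1] <= 0.02 * s[0]:
        raise ValueError("rank-deficient OD data: image appears single-stain")
    basis = vt[:2].T  # 3x2 plane
    # orient basis so projections are predominantly positive
    for j in range(2):
        if basis[:, j].sum() < 0:
            basis[:, j] = -basis[:, j]
    proj = od_t @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    vecs = np.column_stack([v1, v2])
    vecs = np.clip(vecs, 0.0, None)
    vecs /= np.linalg.norm(vecs, axis=0)
    # hematoxylin first: larger blue-channel OD
    if vecs[2, 0] < vecs[2, 1]:
        vecs = vecs[:, ::-1]
    conc = unmix_concentrations(image, vecs)
    max_c = np.percentile(conc.reshape(-1, 2), percentile, axis=0)
    return StainProfile(stain_matrix=vecs, max_concentrations=np.maximum(max_c, 1e-8))


def unmix_concentrations(image: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Per-pixel nonnegative stain concentrations for a 3xS stain matrix.

    Solves least squares via the pseudoinverse and refines the (few) pixels
    with negative components by true NNLS.
    """
    od = rgb_to_od(image)
    flat = od.reshape(-1, 3)
    conc = flat @ np.linalg.pinv(stain_matrix).T
    neg = (conc < -1e-6).any(axis=1)
    if neg.any():
        idx = np.flatnonzero(neg)
        if idx.size > 20000:  # refine a capped subset; clip the rest
            idx = idx[:: int(np.ceil(idx.size / 20000))]
        for i in idx:
            conc[i], _ = nnls(stain_matrix, flat[i])
    conc = np.maximum(conc, 0.0)
    return conc.reshape(image.shape[:2] + (stain_matrix.shape[1],))


def normalize_stains(
    image: np.ndarray, source: StainProfile, reference: StainProfile
) -> np.ndarray:
    """Map an image from its source stain profile onto the reference profile."""
    conc = unmix_concentrations(image, source.stain_matrix)
    scale = reference.max_concentrations / np.maximum(source.max_concentrations, 1e-8)
    conc = conc * scale[None, None, :]
    od = conc @ reference.stain_matrix.T
    return od_to_rgb(od)


def reference_profile() -> StainProfile:
    """The package's published reference H&E profile."""
    return StainProfile(stain_matrix=REFERENCE_HE.copy(), max_concentrations=np.array([1.2, 1.0]))


def _grid_positions(lo: int, hi: int, tile: int, stride: int) -> list[int]:
    """Start positions covering [lo, hi] with the last tile shifted inward."""
    if hi - lo + 1 < tile:
        return []
    positions = list(range(lo, hi - tile + 2, stride))
    last = hi - tile + 1
    if positions[-1] != last:
        positions.append(last)
    return positions


def detect_artifacts(
    tile: np.ndarray,
    blur_variance_min: float = 3.0,
    fold_fraction_max: float = 0.25,
    blank_fraction_max: float = 0.95,
) -> dict:
    """QC flags for one tile: blur, fold, blank.  Any set flag excludes it."""
    gray = np.asarray(tile, dtype=np.float64).mean(axis=-1)
    lap = ndi.laplace(gray)
    blur = float(lap.var()) < blur_variance_min
    hsv = rgb2hsv(np.asarray(tile, dtype=np.uint8))
    fold = float(((hsv[..., 1] > 0.55) & (hsv[..., 2] < 0.45)).mean()) > fold_fraction_max
    blank = float((gray > 235).mean()) > blank_fraction_max
    return {"blur": blur, "fold": fold, "blank": blank}


def tile_slide(
    image: np.ndarray,
    mask: np.ndarray,
    config: PreprocessConfig,
    slide_id: str = "slide",
    run_artifact_checks: bool = True,
) -> TileBag:
    """Tile the mask bounding box into overlapping tiles and QC-filter them."""
    if mask.shape != image.shape[:2]:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        warnings.warn("empty tissue mask: returning empty bag")
        return TileBag(slide_id=slide_id, tiles=[], coords=[], qc_flags=[])
    t = config.tile_size_px
    stride = max(1, int(round(t * (1.0 - config.overlap_fraction))))
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r_pos = _grid_positions(rows[0], rows[-1], t, stride)
    c_pos = _grid_positions(cols[0], cols[-1], t, stride)
    tiles, coords, qc = [], [], []
    for r in r_pos:
        for c in c_pos:
            sub = image[r : r + t, c : c + t]
            blank_fraction = 1.0 - float(mask[r : r + t, c : c + t].mean())
            flags = {"blank_fraction": blank_fraction, "blur": False, "fold": False, "blank": False}
            if blank_fraction > config.blank_fraction_max:
                flags["blank"] = True
            elif run_artifact_checks:
                flags.update(
                    detect_artifacts(
                        sub,
                        blur_variance_min=config.blur_variance_min,
                        fold_fraction_max=config.fold_fraction_max,
                    )
                )
            if not (flags["blank"] or flags["blur"] or flags["fold"]):
                tiles.append(sub)
                coords.append((r, c))
            qc.append({"row": int(r), "col": int(c), **flags})
    return TileBag(slide_id=slide_id, tiles=tiles, coords=coords, qc_flags=qc)
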