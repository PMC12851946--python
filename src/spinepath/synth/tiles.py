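"""Desk-scale synthetic tile bags for MIL training and Grad-CAM probes.

Renders small square H&E-like tiles with the same palette as the full
slide generator.  Traumatic and neoplastic bags carry their class signal in
a subset of *discriminative* tiles (fracture cleft, tumor cluster) whose
pixel masks are recorded; osteoporotic bags carry a diffuse signal (thin
trabeculae, fat-rich marrow) on every tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from ..palette import REFERENCE_HEC, compose_rgb
from .slides import FractureClass


@dataclass
class TileBagSample:
    label: int
    tiles: np.ndarray                 # (n, T, T, 3) uint8
    discriminative: np.ndarray        # (n,) bool
    masks: list[np.ndarray | None]    # per-tile planted mask (or None)
    bag_id: str = ""


def _base_concentrations(t: int, rng) -> tuple[np.ndarray, np.ndarray]:
    hema = np.zeros((t, t), dtype=np.float64)
    eosin = np.full((t, t), 0.18, dtype=np.float64)
    return hema, eosin


def _add_trabecula(eosin, width, rng):
    t = eosin.shape[0]
    pos = rng.uniform(0.2, 0.8) * t
    ang = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:t, 0:t]
    d = np.abs((yy - pos) * np.cos(ang) + (xx - t / 2) * np.sin(ang))
    eosin[d < width / 2] = 0.95


def _add_fat(eosin, hema, n, rng):
    t = eosin.shape[0]
    for _ in range(n):
        r, c = rng.uniform(6, t - 6, 2)
        rad = rng.uniform(5.0, 8.0)
        rr, cc = draw_disk((r, c), rad, shape=eosin.shape)
        eosin[rr, cc] = 0.02
        hema[rr, cc] = 0.0


def _add_nuclei(hema, n, ecc_mean, size_lo, size_hi, conc, rng, region=None):
    t = hema.shape[0]
    for _ in range(n):
        if region is None:
            r, c = rng.uniform(3, t - 3, 2)
        else:
            r0, c0, rad = region
            ang = rng.uniform(0, 2 * np.pi)
            rho = rad * np.sqrt(rng.random())
            r, c = r0 + rho * np.sin(ang), c0 + rho * np.cos(ang)
        a = rng.uniform(size_lo, size_hi)
        e = np.clip(rng.normal(ecc_mean, 0.04), 0.02, 0.97)
        b = max(1.0, a * np.sqrt(1 - e * e))
        rr, cc = draw_ellipse(r, c, a, b, shape=hema.shape, rotation=rng.uniform(0, np.pi))
        if rr.size:
            hema[rr, cc] = conc


def render_tile(
    label: int, discriminative: bool, tile_px: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    """One tile + its planted discriminative mask (None when not planted)."""
    t = tile_px
    hema, eosin = _base_concentrations(t, rng)
    mask = None
    if label == FractureClass.OSTEOPOROTIC:
        # diffuse signal: thin trabecula, abundant fat, sparse round nuclei
        _add_trabecula(eosin, rng.uniform(2.5, 4.0), rng)
        _add_fat(eosin, hema, rng.integers(6, 10), rng)
        _add_nuclei(hema, rng.integers(3, 7), 0.30, 2.5, 3.5, 1.1, rng)
    elif label == FractureClass.TRAUMATIC:
        _add_trabecula(eosin, rng.uniform(8.0, 12.0), rng)
        _add_fat(eosin, hema, rng.integers(0, 2), rng)
        _add_nuclei(hema, rng.integers(3, 7), 0.35, 2.5, 3.5, 1.1, rng)
        if discriminative:
            # fracture cleft band + inflammatory cells along it
            yy, xx = np.mgrid[0:t, 0:t]
            pos = rng.uniform(0.3, 0.7) * t
            ang = rng.uniform(0, np.pi)
            d = np.abs((yy - pos) * np.cos(ang) + (xx - t / 2) * np.sin(ang))
            half = rng.uniform(3.0, 5.0)
            cleft = d < half
            eosin[cleft] = 0.02
            hema[cleft] = 0.0
            band = (d >= half) & (d < half + 10)
            coords = np.argwhere(band)
            for _ in range(40):
                r, c = coords[rng.integers(0, len(coords))]
                rr, cc = draw_ellipse(r, c, 2.2, 2.0, shape=hema.shape, rotation=0)
                hema[rr, cc] = 1.35
            mask = ndi.binary_dilation(cleft, iterations=4)
    else:  # neoplastic
        _add_trabecula(eosin, rng.uniform(6.0, 9.0), rng)
        _add_nuclei(hema, rng.integers(3, 7), 0.35, 2.5, 3.5, 1.1, rng)
        if discriminative:
            rad = rng.uniform(0.16, 0.22) * t
            r0 = rng.uniform(rad + 2, t - rad - 2)
            c0 = rng.uniform(rad + 2, t - rad - 2)
            region = (r0, c0, rad)
            _add_nuclei(hema, int(1.2 * rad * rad / 4), 0.90, 3.5, 5.0, 1.25, rng, region=region)
            mask = np.zeros((t, t), dtype=bool)
            rr, cc = draw_disk((r0, c0), rad, shape=mask.shape)
            mask[rr, cc] = True
    noise = 1.0 + 0.05 * ndi.gaussian_filter(rng.normal(size=(t, t)), 1.5)
    conc = np.stack([hema * noise, eosin * noise, np.zeros_like(eosin)], axis=-1)
    image = compose_rgb(np.maximum(conc, 0.0), REFERENCE_HEC)
    return image, mask


def generate_bag(
    label: int,
    tiles_per_bag: int,
    tile_px: int,
    rng: np.random.Generator,
    n_discriminative: int | None = None,
    bag_id: str = "",
) -> TileBagSample:
    """One labeled bag; traumatic/neoplastic bags get >=1 discriminative tile."""
    if n_discriminative is None:
        if label == FractureClass.OSTEOPOROTIC:
            n_discriminative = 0
        else:
            n_discriminative = max(1, int(round(rng.uniform(0.25, 0.4) * tiles_per_bag)))
    flags = np.zeros(tiles_per_bag, dtype=bool)
    if n_discriminative > 0:
        flags[rng.choice(tiles_per_bag, size=n_discriminative, replace=False)] = True
    tiles = np.empty((tiles_per_bag, tile_px, tile_px, 3), dtype=np.uint8)
    masks: list[np.ndarray | None] = []
    for i in range(tiles_per_bag):
        img, mask = render_tile(label, bool(flags[i]), tile_px, rng)
        tiles[i] = img
        masks.append(mask)
    return TileBagSample(
        label=int(label), tiles=tiles, discriminative=flags, masks=masks, bag_id=bag_id
    )


def generate_mil_cohort(
    n_bags_per_class: int = 60,
    tiles_per_bag: int = 30,
    tile_px: int = 64,
    seed: int = 0,
    class_counts: tuple[int, int, int] | None = None,
) -> list[TileBagSample]:
    """Deterministic 3-class bag cohort (default 180 bags of 30 tiles)."""
    rng = np.random.default_rng(seed)
    counts = class_counts if class_counts is not None else (n_bags_per_class,) * 3
    bags = []
    for label, count in enumerate(counts):
        for j in range(count):
            bags.append(
                generate_bag(
                    label, tiles_per_bag, tile_px, rng, bag_id=f"bag_c{label}_{j:03d}"
                )
            )
    return bags
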