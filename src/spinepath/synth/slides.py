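"""Synthetic H&E-like slide rendering with planted ground truth.

Slides are composed in stain-concentration space from the fixed reference
palette (:mod:`spinepath.palette`) and rendered through Beer-Lambert, so
every downstream estimator (stain recovery, unmixing, morphometry) has an
exactly known answer.  All geometry is painted into binary masks first and
the ground-truth scalars are recomputed from those masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from ..palette import REFERENCE_HEC, compose_rgb


class FractureClass(IntEnum):
    OSTEOPOROTIC = 0
    TRAUMATIC = 1
    NEOPLASTIC = 2


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide; same spec + seed gives identical bytes."""

    fracture_class: FractureClass = FractureClass.OSTEOPOROTIC
    image_size: tuple[int, int] = (512, 512)
    trabecular_width_px: float = 8.0
    trabecular_spacing_px: float = 40.0
    bone_fraction_target: float | None = None
    adiposity_fraction_target: float = 0.2
    tumor_cluster_count: int = 0
    inflammatory_cell_density_target: float = 100.0  # cells per mm^2
    collagen_fraction_target: float = 0.05
    fracture_line: bool = False
    seed: int = 0
    microns_per_pixel: float = 2.0
    background_border_px: int = 0
    nucleus_eccentricity_mean: float = 0.35
    marrow_nucleus_density_per_mm2: float = 150.0
    lacunae_per_bone_mm2: float = 60.0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 256 or w < 256:
            raise ValueError("image_size must be at least 256x256")
        if self.trabecular_width_px <= 0 or self.trabecular_spacing_px <= 0:
            raise ValueError("trabecular geometry must be positive")
        bf = self.bone_fraction_target
        if bf is not None and not (0.0 < bf < 1.0):
            raise ValueError("bone_fraction_target must lie in (0, 1)")
        if not (0.0 <= self.adiposity_fraction_target < 1.0):
            raise ValueError("adiposity_fraction_target must lie in [0, 1)")
        if not (0.0 <= self.collagen_fraction_target < 1.0):
            raise ValueError("collagen_fraction_target must lie in [0, 1)")
        if self.tumor_cluster_count < 0:
            raise ValueError("tumor_cluster_count must be nonnegative")
        bone = bf if bf is not None else 0.0
        if bone + self.adiposity_fraction_target > 0.95:
            raise ValueError("bone + fat fraction targets exceed 0.95: infeasible")


#: Class-conditional default specs; classes differ on trabecular width,
#: adiposity, tumor clusters and the presence of a fracture cleft.
CLASS_DEFAULTS: dict[FractureClass, dict] = {
    FractureClass.OSTEOPOROTIC: dict(
        trabecular_width_px=5.0,
        trabecular_spacing_px=55.0,
        adiposity_fraction_target=0.35,
        tumor_cluster_count=0,
        inflammatory_cell_density_target=50.0,
        collagen_fraction_target=0.05,
        fracture_line=False,
        nucleus_eccentricity_mean=0.30,
    ),
    FractureClass.TRAUMATIC: dict(
        trabecular_width_px=14.0,
        trabecular_spacing_px=36.0,
        adiposity_fraction_target=0.08,
        tumor_cluster_count=0,
        inflammatory_cell_density_target=500.0,
        collagen_fraction_target=0.15,
        fracture_line=True,
        nucleus_eccentricity_mean=0.40,
    ),
    FractureClass.NEOPLASTIC: dict(
        trabecular_width_px=11.0,
        trabecular_spacing_px=40.0,
        adiposity_fraction_target=0.03,
        tumor_cluster_count=3,
        inflammatory_cell_density_target=100.0,
        collagen_fraction_target=0.28,
        fracture_line=False,
        nucleus_eccentricity_mean=0.85,
    ),
}


def spec_for_class(
    fracture_class: FractureClass | int, seed: int, image_size: tuple[int, int] = (512, 512), **overrides
) -> SlideSpec:
    """Default :class:`SlideSpec` for a fracture class, with overrides."""
    fc = FractureClass(fracture_class)
    params = dict(CLASS_DEFAULTS[fc])
    params.update(overrides)
    return SlideSpec(fracture_class=fc, image_size=image_size, seed=seed, **params)


@dataclass
class GroundTruth:
    """Planted truth for one rendered slide; scalars recomputed from masks."""

    fracture_class: FractureClass
    bone_mask: np.ndarray
    marrow_mask: np.ndarray
    fat_mask: np.ndarray
    collagen_mask: np.ndarray
    nuclei_mask: np.ndarray
    lacunae_mask: np.ndarray
    discriminative_mask: np.ndarray
    tissue_mask: np.ndarray
    bone_fraction: float = 0.0
    trabecular_width_px: float = 0.0
    adiposity_fraction: float = 0.0
    collagen_fraction: float = 0.0
    lacunae_count: int = 0
    inflammatory_count: int = 0
    nucleus_eccentricities: np.ndarray = field(default_factory=lambda: np.empty(0))
    microns_per_pixel: float = 2.0


def _stripe_mask(shape, period, width, axis, rng):
    """Wobbly stripes of the given width and period along one axis."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    coord = yy if axis == 0 else xx
    other = xx if axis == 0 else yy
    amp = min(period / 6.0, 8.0)
    phase = rng.uniform(0, 2 * np.pi)
    wav = rng.uniform(150.0, 260.0)
    wobble = amp * np.sin(2 * np.pi * other / wav + phase)
    offset = rng.uniform(0, period)
    return ((coord + wobble + offset) % period) < width


def _bone_lattice(shape, width, target_fraction, rng, base_period=None):
    """Cross-hatched trabecular lattice; period tuned to the area target."""

    # phases drawn once and reused, so period tuning does not shift geometry
    s1, s2 = rng.integers(2**31), rng.integers(2**31)

    def make(period):
        m1 = _stripe_mask(shape, period, width, 0, np.random.default_rng(s1))
        m2 = _stripe_mask(shape, period, width, 1, np.random.default_rng(s2))
        return m1 | m2

    if target_fraction is None:
        return make(base_period)
    # bisection on the stripe period to hit the target area fraction
    lo, hi = width * 1.05, width * 60.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        frac = make(mid).mean()
        if abs(frac - target_fraction) < 0.003:
            break
        if frac > target_fraction:
            lo = mid
        else:
            hi = mid
    return make(mid)


def _sample_in_mask(mask_dist, min_dist, rng, n_tries=400):
    """Sample a point whose distance-to-outside exceeds ``min_dist``."""
    h, w = mask_dist.shape
    for _ in range(n_tries):
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        if mask_dist[r, c] > min_dist:
            return r, c
    return None


def _paint_nucleus(hema, nuclei_mask, r, c, a, b, theta, conc, ecc_list):
    rr, cc = draw_ellipse(r, c, a, b, shape=hema.shape, rotation=theta)
    if rr.size == 0:
        return False
    hema[rr, cc] = conc
    nuclei_mask[rr, cc] = True
    ecc_list.append(np.sqrt(max(0.0, 1.0 - (min(a, b) / max(a, b)) ** 2)))
    return True


def render_slide(spec: SlideSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic slide and its ground truth.

    Returns an (H, W, 3) uint8 RGB image and a :class:`GroundTruth` whose
    masks align pixelwise with the image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    shape = (h, w)
    mpp = spec.microns_per_pixel
    mm2_per_px = (mpp / 1000.0) ** 2

    border = spec.background_border_px
    tissue = np.zeros(shape, dtype=bool)
    tissue[border : h - border if border else h, border : w - border if border else w] = True

    # --- trabecular bone lattice -------------------------------------------------
    base_period = spec.trabecular_width_px + spec.trabecular_spacing_px
    bone = _bone_lattice(
        shape, spec.trabecular_width_px, spec.bone_fraction_target, rng, base_period=base_period
    )
    bone &= tissue

    # --- fracture cleft (traumatic) ----------------------------------------------
    cleft = np.zeros(shape, dtype=bool)
    if spec.fracture_line:
        xs = np.arange(w)
        steps = rng.normal(0.0, 3.0, size=w)
        path = h / 2.0 + np.cumsum(steps)
        path = ndi.gaussian_filter1d(path, 15.0)
        path = np.clip(path, h * 0.2, h * 0.8)
        half = rng.uniform(5.0, 8.0)
        yy = np.arange(h)[:, None]
        cleft = np.abs(yy - path[None, :]) < half
        cleft &= tissue
        bone &= ~cleft

    # --- tumor clusters (neoplastic) ----------------------------------------------
    tumor_regions = np.zeros(shape, dtype=bool)
    centers = []
    if spec.tumor_cluster_count > 0:
        rmax = max(30.0, min(h, w) / 11.0)
        for _ in range(spec.tumor_cluster_count):
            placed = False
            for _try in range(500):
                radius = rng.uniform(0.75 * rmax, rmax)
                r = rng.uniform(radius + 6, h - radius - 6)
                c = rng.uniform(radius + 6, w - radius - 6)
                if all(np.hypot(r - r0, c - c0) > radius + rad0 + 18 for r0, c0, rad0 in centers):
                    centers.append((r, c, radius))
                    rr, cc = draw_disk((r, c), radius, shape=shape)
                    tumor_regions[rr, cc] = True
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place tumor clusters without overlap; reduce count")
        tumor_regions &= tissue
        bone &= ~tumor_regions

    marrow = tissue & ~bone & ~cleft
    marrow_area = int(marrow.sum())

    # --- adipocyte vacuoles --------------------------------------------------------
    fat = np.zeros(shape, dtype=bool)
    if spec.adiposity_fraction_target > 0 and marrow_area > 0:
        eligible = marrow & ~tumor_regions
        target_px = spec.adiposity_fraction_target * marrow_area
        dist = ndi.distance_transform_edt(eligible)
        painted = 0
        stall = 0
        while painted < target_px and stall < 600:
            radius = rng.uniform(7.0, 13.0)
            pt = _sample_in_mask(dist, radius + 1.0, rng, n_tries=60)
            if pt is None:
                stall += 1
                continue
            r, c = pt
            if fat[r, c]:
                stall += 1
                continue
            rr, cc = draw_disk((r, c), radius, shape=shape)
            keep = eligible[rr, cc]
            new = int((~fat[rr[keep], cc[keep]]).sum())
            fat[rr[keep], cc[keep]] = True
            painted += new
            stall = 0 if new > 0 else stall + 1

    # --- collagen / fibrosis texture ----------------------------------------------
    collagen = np.zeros(shape, dtype=bool)
    if spec.collagen_fraction_target > 0 and marrow_area > 0:
        fld = ndi.gaussian_filter(rng.normal(size=shape), 14.0)
        eligible = marrow & ~fat & ~tumor_regions
        k = int(spec.collagen_fraction_target * marrow_area)
        vals = fld[eligible]
        if k > 0 and vals.size > k:
            thr = np.partition(vals, vals.size - k)[vals.size - k]
            collagen = eligible & (fld >= thr)

    # --- nuclei --------------------------------------------------------------------
    hema = np.zeros(shape, dtype=np.float64)
    nuclei_mask = np.zeros(shape, dtype=bool)
    ecc_list: list[float] = []
    area_mm2 = tissue.sum() * mm2_per_px

    # marrow stromal nuclei
    n_stromal = rng.poisson(spec.marrow_nucleus_density_per_mm2 * marrow.sum() * mm2_per_px)
    eligible = marrow & ~fat
    coords = np.argwhere(eligible)
    e_mean = spec.nucleus_eccentricity_mean
    for _ in range(int(n_stromal)):
        idx = rng.integers(0, len(coords))
        r, c = coords[idx]
        a = rng.uniform(3.5, 5.5)
        e = np.clip(rng.normal(e_mean, 0.05), 0.02, 0.97)
        b = max(1.2, a * np.sqrt(1 - e * e))
        _paint_nucleus(hema, nuclei_mask, r, c, a, b, rng.uniform(0, np.pi), 1.1, ecc_list)

    # inflammatory cells: small round dark nuclei; near the cleft when present
    n_inf = rng.poisson(spec.inflammatory_cell_density_target * area_mm2)
    if spec.fracture_line and cleft.any():
        band = ndi.binary_dilation(cleft, iterations=25) & marrow
        inf_coords = np.argwhere(band & ~fat)
    else:
        inf_coords = coords
    n_painted_inf = 0
    if len(inf_coords) > 0:
        for _ in range(int(n_inf)):
            idx = rng.integers(0, len(inf_coords))
            r, c = inf_coords[idx]
            a = rng.uniform(2.2, 3.0)
            b = a * rng.uniform(0.9, 1.0)
            if _paint_nucleus(hema, nuclei_mask, r, c, a, b, rng.uniform(0, np.pi), 1.35, ecc_list):
                n_painted_inf += 1

    # tumor nuclei: dense elongated nuclei filling the cluster regions
    if tumor_regions.any():
        t_coords = np.argwhere(tumor_regions)
        n_tumor = int(0.45 * tumor_regions.sum() / 30.0)
        for _ in range(n_tumor):
            idx = rng.integers(0, len(t_coords))
            r, c = t_coords[idx]
            a = rng.uniform(4.5, 6.5)
            e = np.clip(rng.normal(0.91, 0.02), 0.6, 0.97)
            b = max(1.2, a * np.sqrt(1 - e * e))
            _paint_nucleus(hema, nuclei_mask, r, c, a, b, rng.uniform(0, np.pi), 1.25, ecc_list)

    # osteocyte lacunae: bright holes punched in bone
    lacunae = np.zeros(shape, dtype=bool)
    bone_dist = ndi.distance_transform_edt(bone)
    n_lac = rng.poisson(spec.lacunae_per_bone_mm2 * bone.sum() * mm2_per_px)
    lac_count = 0
    for _ in range(int(n_lac)):
        pt = _sample_in_mask(bone_dist, 3.5, rng, n_tries=80)
        if pt is None:
            continue
        r, c = pt
        if lacunae[max(0, r - 4) : r + 5, max(0, c - 4) : c + 5].any():
            continue
        rr, cc = draw_ellipse(r, c, 2.6, 1.8, shape=shape, rotation=rng.uniform(0, np.pi))
        lacunae[rr, cc] = True
        lac_count += 1

    # --- stain concentration maps --------------------------------------------------
    eosin = np.zeros(shape, dtype=np.float64)
    eosin[marrow] = 0.18
    eosin[bone] = 0.95
    eosin[collagen] = 0.10
    coll_conc = np.zeros(shape, dtype=np.float64)
    coll_conc[collagen] = 0.75
    # clear structures: vacuoles, cleft, lacunae, background
    for clear in (fat, cleft, lacunae):
        eosin[clear] = 0.02
        hema[clear] = np.minimum(hema[clear], 0.02)
        coll_conc[clear] = 0.0
    eosin[~tissue] = 0.0
    hema[~tissue] = 0.0
    coll_conc[~tissue] = 0.0
    hema[marrow & ~nuclei_mask & ~fat] += 0.04

    # mild multiplicative texture noise, smoothed so it does not break masks
    noise = 1.0 + 0.06 * ndi.gaussian_filter(rng.normal(size=shape), 2.0)
    conc = np.stack([hema * noise, eosin * noise, coll_conc * noise], axis=-1)
    conc = np.maximum(conc, 0.0)
    image = compose_rgb(conc, REFERENCE_HEC)

    # --- discriminative regions ----------------------------------------------------
    discriminative = tumor_regions.copy()
    if spec.fracture_line:
        discriminative |= ndi.binary_dilation(cleft, iterations=10) & tissue

    gt = GroundTruth(
        fracture_class=FractureClass(spec.fracture_class),
        bone_mask=bone,
        marrow_mask=marrow,
        fat_mask=fat,
        collagen_mask=collagen,
        nuclei_mask=nuclei_mask,
        lacunae_mask=lacunae,
        discriminative_mask=discriminative,
        tissue_mask=tissue,
        bone_fraction=float(bone.sum() / max(1, tissue.sum())),
        trabecular_width_px=spec.trabecular_width_px,
        adiposity_fraction=float(fat.sum() / max(1, marrow.sum())),
        collagen_fraction=float(collagen.sum() / max(1, marrow.sum())),
        lacunae_count=lac_count,
        inflammatory_count=n_painted_inf,
        nucleus_eccentricities=np.asarray(ecc_list),
        microns_per_pixel=mpp,
    )
    if spec.tumor_cluster_count > 0:
        n_comp = ndi.label(tumor_regions)[1]
        if n_comp != spec.tumor_cluster_count:
            warnings.warn("tumor cluster components differ from requested count")
    return image, gt
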