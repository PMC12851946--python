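"""Handcrafted bone/marrow histomorphometry and nuclear features.

Computes the per-case feature vector used by the risk model: trabecular
architecture (fraction, thickness, separation, disruption), marrow
composition (adiposity, collagen/fibrosis), and nuclear morphometry
(eccentricity, osteocyte lacunae, inflammatory cell density).

Thickness and separation use the standard surrogate: twice the mean
Euclidean distance-transform value sampled on the structure's skeleton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from .palette import REFERENCE_HEC
from .preprocess import otsu_threshold, segment_tissue, unmix_concentrations


@dataclass
class HistomorphometryFeatures:
    trabecular_bone_fraction: float = np.nan
    trabecular_thickness_um: float = np.nan
    trabecular_separation_um: float = np.nan
    osteocyte_density_per_mm2: float = np.nan
    marrow_adiposity_fraction: float = np.nan
    collagen_density_fraction: float = np.nan
    inflammatory_cell_density_per_mm2: float = np.nan
    nucleus_eccentricity_mean: float = np.nan
    trabecular_disruption_score: float = np.nan
    marrow_fibrosis_score: float = np.nan
    microns_per_pixel: float = np.nan

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def segment_bone(
    image: np.ndarray,
    tissue_mask: np.ndarray | None = None,
    min_object_px: int = 64,
    min_eosin_concentration: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment trabecular bone; returns (bone_mask, marrow_mask).

    Bone is eosin-dense: threshold the eosin concentration channel (3-stain
    unmix against the reference basis) by Otsu within tissue, then size
    filter.  Marrow is the complement of bone within tissue.
    """
    if tissue_mask is None:
        tissue_mask = segment_tissue(image)
    if not tissue_mask.any():
        empty = np.zeros(image.shape[:2], dtype=bool)
        return empty, empty
    conc = unmix_concentrations(image, REFERENCE_HEC)
    eosin = conc[..., 1]
    scaled = np.clip(eosin / max(eosin.max(), 1e-8) * 255.0, 0, 255).astype(np.uint8)
    t = otsu_threshold(scaled[tissue_mask])
    if t < 0:
        empty = np.zeros(image.shape[:2], dtype=bool)
        return empty, tissue_mask.copy()
    # the absolute floor keeps a marrow-only image (Otsu splitting noise)
    # from being called bone
    bone = (scaled > t) & (eosin > min_eosin_concentration) & tissue_mask
    bone = ndi.binary_closing(bone, structure=np.ones((3, 3)))
    lab, n = ndi.label(bone)
    if n:
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_object_px)
        bone &= ~np.isin(lab, small)
    marrow = tissue_mask & ~bone
    return bone, marrow


def _skeleton_endpoints(skel: np.ndarray) -> int:
    neigh = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3), dtype=np.uint8), mode="constant")
    return int(((neigh == 2) & skel).sum())


def trabecular_metrics(
    bone_mask: np.ndarray,
    microns_per_pixel: float,
    tissue_mask: np.ndarray | None = None,
) -> dict:
    """Bone fraction, thickness, separation and disruption score.

    disruption = (skeleton endpoints + connected components - 1) per mm^2 of
    bone; higher values mean a more fragmented lattice.
    """
    if tissue_mask is None:
        tissue_mask = np.ones_like(bone_mask, dtype=bool)
    tissue_px = int(tissue_mask.sum())
    bone_px = int(bone_mask.sum())
    out = {
        "bone_fraction": bone_px / tissue_px if tissue_px else 0.0,
        "thickness_um": np.nan,
        "separation_um": np.nan,
        "disruption_score": np.nan,
    }
    if bone_px == 0:
        return out
    skel = skeletonize(bone_mask)
    dist = ndi.distance_transform_edt(bone_mask)
    if skel.any():
        out["thickness_um"] = float(2.0 * dist[skel].mean() * microns_per_pixel)
    marrow = tissue_mask & ~bone_mask
    if marrow.any():
        mskel = skeletonize(marrow)
        mdist = ndi.distance_transform_edt(marrow)
        if mskel.any():
            out["separation_um"] = float(2.0 * mdist[mskel].mean() * microns_per_pixel)
    n_comp = ndi.label(bone_mask)[1]
    endpoints = _skeleton_endpoints(skel)
    bone_mm2 = bone_px * (microns_per_pixel / 1000.0) ** 2
    out["disruption_score"] = float((endpoints + n_comp - 1) / max(bone_mm2, 1e-9))
    return out


def marrow_adiposity(
    image: np.ndarray,
    marrow_mask: np.ndarray,
    circularity_min: float = 0.6,
    min_area_px: int = 30,
    white_level: int = 225,
    saturation_max: float = 0.12,
) -> float:
    """Area fraction of marrow occupied by round clear vacuoles (adipocytes)."""
    if not marrow_mask.any():
        return np.nan
    arr = np.asarray(image, dtype=np.float64)
    hsv = rgb2hsv(np.asarray(image, dtype=np.uint8))
    clear = (arr.min(axis=-1) > white_level) & (hsv[..., 1] < saturation_max) & marrow_mask
    clear = ndi.binary_opening(clear, structure=np.ones((3, 3)))
    # vacuoles are round and frequently touch; peak-marker watershed splits
    # them cleanly before the circularity filter
    lab = _split_round_touching(clear, min_distance=6)
    fat_px = 0
    for region in regionprops(lab):
        if region.area < min_area_px:
            continue
        circ = 4.0 * math.pi * region.area / max(region.perimeter, 1.0) ** 2
        if circ >= circularity_min:
            fat_px += region.area
    return float(fat_px / marrow_mask.sum())


def collagen_fraction(
    image: np.ndarray,
    marrow_mask: np.ndarray,
    min_concentration: float = 0.15,
    fibrosis_reference: float = 0.5,
) -> tuple[float, float]:
    """Collagen-dominant pixel fraction in marrow and the saturating fibrosis score."""
    if not marrow_mask.any():
        return np.nan, np.nan
    conc = unmix_concentrations(image, REFERENCE_HEC)
    dominant = (
        (conc[..., 2] > min_concentration)
        & (conc[..., 2] > conc[..., 0])
        & (conc[..., 2] > conc[..., 1])
        & marrow_mask
    )
    frac = float(dominant.sum() / marrow_mask.sum())
    return frac, min(1.0, frac / fibrosis_reference)


def _split_round_touching(mask: np.ndarray, min_distance: int = 6) -> np.ndarray:
    """Watershed split of touching round objects via distance-peak markers.

    Suited to convex round blobs (fat vacuoles); elongated objects would be
    cut along their EDT ridge, so nuclei use :func:`_split_touching`.
    """
    from skimage.feature import peak_local_max

    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        return label(mask).astype(np.int32)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


def _split_touching(mask: np.ndarray, min_distance: int = 4, level: float = 0.6) -> np.ndarray:
    """Watershed split of touching objects via distance-threshold markers.

    Markers are the connected regions where the distance transform exceeds
    ``level`` times its per-component maximum: a single convex object (even
    a long ellipse, whose EDT ridge is a plateau) yields one marker, while
    touching blobs separated by a shallower neck yield one marker each.
    """
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    comp = label(mask)
    comp_max = ndi.maximum(dist, labels=comp, index=np.arange(1, comp.max() + 1))
    thresh = np.zeros(mask.shape)
    thresh[mask] = level * np.asarray(comp_max)[comp[mask] - 1]
    markers = label(dist > thresh)
    if markers.max() == 0:
        return comp.astype(np.int32)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


def nuclei_morphometry(
    image: np.ndarray,
    bone_mask: np.ndarray,
    marrow_mask: np.ndarray,
    microns_per_pixel: float,
    min_nucleus_px: int = 12,
    max_nucleus_px: int = 150,
    inflammatory_area_max_px: int = 40,
    inflammatory_ecc_max: float = 0.7,
) -> dict:
    """Nuclear segmentation and per-nucleus ellipse statistics.

    Returns mean/90th-percentile eccentricity, osteocyte lacunae per bone
    mm^2 and inflammatory (small round) cell density per marrow mm^2.
    """
    mm2 = (microns_per_pixel / 1000.0) ** 2
    conc = unmix_concentrations(image, REFERENCE_HEC)
    hema = conc[..., 0]
    scaled = np.clip(hema / max(hema.max(), 1e-8) * 255.0, 0, 255).astype(np.uint8)
    t = otsu_threshold(scaled)
    nuc = scaled > max(t, 1) if t >= 0 else np.zeros_like(bone_mask)
    nuc = ndi.binary_opening(nuc, structure=np.ones((2, 2)))
    lab = _split_touching(nuc)
    eccs, areas, cents = [], [], []
    for region in regionprops(lab):
        if region.area < min_nucleus_px or region.area > max_nucleus_px:
            continue
        eccs.append(region.eccentricity)
        areas.append(region.area)
        cents.append(region.centroid)
    out = {
        "nucleus_eccentricity_mean": np.nan,
        "nucleus_eccentricity_p90": np.nan,
        "nucleus_count": len(eccs),
        "osteocyte_density_per_mm2": 0.0,
        "inflammatory_cell_density_per_mm2": 0.0,
    }
    if eccs:
        out["nucleus_eccentricity_mean"] = float(np.mean(eccs))
        out["nucleus_eccentricity_p90"] = float(np.percentile(eccs, 90))
        inflammatory = sum(
            1
            for e, a, (r, c) in zip(eccs, areas, cents)
            if a <= inflammatory_area_max_px
            and e <= inflammatory_ecc_max
            and marrow_mask[int(r), int(c)]
        )
        marrow_mm2 = marrow_mask.sum() * mm2
        if marrow_mm2 > 0:
            out["inflammatory_cell_density_per_mm2"] = float(inflammatory / marrow_mm2)
    # osteocyte lacunae: small bright (low total OD) holes inside bone
    bone_mm2 = bone_mask.sum() * mm2
    if bone_mm2 > 0:
        total = conc.sum(axis=-1)
        # lacunae are unstained holes enclosed by bone (whether or not the
        # supplied bone mask already excludes them)
        holes = (total < 0.15) & ndi.binary_fill_holes(bone_mask)
        lab_h, n_h = ndi.label(holes)
        count = 0
        for region in regionprops(lab_h):
            if 4 <= region.area <= 120:
                count += 1
        out["osteocyte_density_per_mm2"] = float(count / bone_mm2)
    return out


def compute_features(
    image: np.ndarray,
    microns_per_pixel: float = 2.0,
    tissue_mask: np.ndarray | None = None,
) -> HistomorphometryFeatures:
    """Full handcrafted feature vector for one stain-normalized image."""
    if tissue_mask is None:
        tissue_mask = segment_tissue(image)
    bone, marrow = segment_bone(image, tissue_mask)
    trab = trabecular_metrics(bone, microns_per_pixel, tissue_mask)
    adip = marrow_adiposity(image, marrow)
    coll, fib = collagen_fraction(image, marrow)
    nuc = nuclei_morphometry(image, bone, marrow, microns_per_pixel)
    return HistomorphometryFeatures(
        trabecular_bone_fraction=trab["bone_fraction"],
        trabecular_thickness_um=trab["thickness_um"],
        trabecular_separation_um=trab["separation_um"],
        osteocyte_density_per_mm2=nuc["osteocyte_density_per_mm2"],
        marrow_adiposity_fraction=adip,
        collagen_density_fraction=coll,
        inflammatory_cell_density_per_mm2=nuc["inflammatory_cell_density_per_mm2"],
        nucleus_eccentricity_mean=nuc["nucleus_eccentricity_mean"],
        trabecular_disruption_score=trab["disruption_score"],
        marrow_fibrosis_score=fib,
        microns_per_pixel=microns_per_pixel,
    )


def feature_table(cases) -> pd.DataFrame:
    """One row per case; missing values stay NA, never silent zeros.

    ``cases`` is a mapping of case id to features, or an iterable of
    (case_id, features) pairs.  Duplicate case ids are an error.
    """
    pairs = list(cases.items()) if hasattr(cases, "items") else list(cases)
    ids = [str(i) for i, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    rows = [f.as_dict() for _, f in pairs]
    return pd.DataFrame(rows, index=pd.Index(ids, name="case_id"))
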