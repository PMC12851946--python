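"""Synthetic patient cohorts with planted latent risk and censored survival.

Each patient gets a fracture class, clinical covariates, true morphometry
(drawn from class-conditional distributions in "fast mode", or measured
from a rendered slide otherwise), an expression vector whose immune and
inflammatory programs track a latent risk, and Weibull survival with
proportional hazards on that latent risk plus independent exponential
censoring.

The latent linear predictor (eta) is stored alongside its squashed [0, 1]
form; the hazard multiplier is exp(beta * standardized eta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .slides import FractureClass, render_slide, spec_for_class

IMMUNE_GENES = ["GZMB", "IFNG", "CD8A", "PRF1", "CXCL13"]
INFLAMMATORY_GENES = ["TNF", "IL1B", "NFKB1", "IL6", "CXCL8"]
RANKL_GENES = ["TNFSF11", "TNFRSF11B"]
STEROID_GENES = ["NR3C1", "TSC22D3", "FKBP5"]
CHEMO_GENES = ["MKI67", "TOP2A", "TYMS"]


@dataclass
class CohortSpec:
    n_patients: int = 150
    class_proportions: tuple[float, float, float] = (0.4, 1.0 / 3.0, 0.267)
    age_mean: float = 72.0
    age_sd: float = 10.0
    female_fraction: float = 0.62
    # latent risk linear predictor weights
    class_effects: tuple[float, float, float] = (-1.2, 0.0, 1.2)
    eccentricity_weight: float = 1.5   # dominant planted effect (3x the others)
    collagen_weight: float = 0.5
    thickness_weight: float = -0.5
    gene_program_weight: float = 0.8   # latent program only visible via expression
    # survival model
    hazard_beta: float = 1.5           # on the standardized latent predictor
    immune_protective_weight: float = 1.2  # hazard reduction per immune-specific sd
    weibull_shape: float = 1.5
    weibull_scale_months: float = 30.0
    complication_scale_months: float = 48.0
    censoring_rate: float = 0.3
    n_noise_genes: int = 35
    expression_fraction: float = 1.0   # fraction of patients with RNA
    fast_mode: bool = True
    image_size: tuple[int, int] = (512, 512)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        props = np.asarray(self.class_proportions, dtype=float)
        if (props < 0).any() or not np.isclose(props.sum(), 1.0, atol=1e-3):
            raise ValueError("class_proportions must be nonnegative and sum to 1")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass
class PatientRecord:
    patient_id: str
    fracture_class: int
    age: float
    sex: str
    fracture_level: str
    bmd_t: float
    features: dict
    class_probs: np.ndarray | None = None
    expression: pd.Series | None = None
    survival_time: float = np.nan
    survival_event: int = 0
    complication_time: float = np.nan
    complication_event: int = 0
    slide: np.ndarray | None = None
    slide_truth: object = None


# class-conditional true-morphometry distributions (fast mode), mirroring the
# slide defaults at 2 um/px; (mean, sd) per feature
_FAST_FEATURES = {
    FractureClass.OSTEOPOROTIC: dict(
        trabecular_bone_fraction=(0.16, 0.03),
        trabecular_thickness_um=(10.0, 1.5),
        trabecular_separation_um=(95.0, 12.0),
        marrow_adiposity_fraction=(0.35, 0.05),
        collagen_density_fraction=(0.05, 0.02),
        nucleus_eccentricity_mean=(0.36, 0.04),
        trabecular_disruption_score=(160.0, 40.0),
        osteocyte_density_per_mm2=(25.0, 10.0),
        inflammatory_cell_density_per_mm2=(60.0, 20.0),
    ),
    FractureClass.TRAUMATIC: dict(
        trabecular_bone_fraction=(0.46, 0.05),
        trabecular_thickness_um=(27.0, 2.5),
        trabecular_separation_um=(55.0, 8.0),
        marrow_adiposity_fraction=(0.10, 0.03),
        collagen_density_fraction=(0.15, 0.03),
        nucleus_eccentricity_mean=(0.50, 0.04),
        trabecular_disruption_score=(90.0, 25.0),
        osteocyte_density_per_mm2=(65.0, 15.0),
        inflammatory_cell_density_per_mm2=(300.0, 80.0),
    ),
    FractureClass.NEOPLASTIC: dict(
        trabecular_bone_fraction=(0.36, 0.05),
        trabecular_thickness_um=(22.0, 2.5),
        trabecular_separation_um=(60.0, 9.0),
        marrow_adiposity_fraction=(0.03, 0.015),
        collagen_density_fraction=(0.28, 0.04),
        nucleus_eccentricity_mean=(0.63, 0.04),
        trabecular_disruption_score=(140.0, 35.0),
        osteocyte_density_per_mm2=(60.0, 15.0),
        inflammatory_cell_density_per_mm2=(140.0, 40.0),
    ),
}

_LEVELS = np.array(["C", "T", "L", "P"])
_LEVEL_PROBS = np.array([0.10, 0.45, 0.40, 0.05])


def class_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder apportionment of n patients into classes."""
    props = np.asarray(proportions, dtype=float)
    raw = props / props.sum() * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _censor_scale_for_rate(t_event: np.ndarray, u: np.ndarray, rate: float) -> float:
    """Bisection on the exponential censor scale to hit the target rate."""
    if rate <= 0:
        return np.inf
    lo, hi = 1e-3, 1e5
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        censored = (-mid * np.log(u) < t_event).mean()
        if censored > rate:
            lo = mid
        else:
            hi = mid
    return mid


def generate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate the cohort; returns patient records and a ground-truth table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    counts = class_counts(n, spec.class_proportions)
    classes = np.repeat(np.arange(3), counts)
    rng.shuffle(classes)

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 35, 95)
    sex = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    level = rng.choice(_LEVELS, size=n, p=_LEVEL_PROBS)
    bmd_mu = np.array([-3.1, -0.8, -1.5])[classes]
    bmd_t = rng.normal(bmd_mu, 0.6)

    # morphometry
    feats: list[dict] = []
    slides = []
    if spec.fast_mode:
        for i in range(n):
            dist = _FAST_FEATURES[FractureClass(classes[i])]
            row = {k: float(rng.normal(m, s)) for k, (m, s) in dist.items()}
            row["trabecular_bone_fraction"] = float(np.clip(row["trabecular_bone_fraction"], 0.02, 0.9))
            row["marrow_adiposity_fraction"] = float(np.clip(row["marrow_adiposity_fraction"], 0.0, 0.9))
            row["collagen_density_fraction"] = float(np.clip(row["collagen_density_fraction"], 0.0, 0.9))
            row["nucleus_eccentricity_mean"] = float(np.clip(row["nucleus_eccentricity_mean"], 0.02, 0.98))
            row["marrow_fibrosis_score"] = min(1.0, row["collagen_density_fraction"] / 0.5)
            row["microns_per_pixel"] = 2.0
            feats.append(row)
            slides.append((None, None))
    else:
        from ..morphometry import compute_features

        for i in range(n):
            sspec = spec_for_class(int(classes[i]), seed=int(rng.integers(2**31)), image_size=spec.image_size)
            img, gt = render_slide(sspec)
            f = compute_features(img, sspec.microns_per_pixel, gt.tissue_mask)
            feats.append(f.as_dict())
            slides.append((img, gt))

    ecc = np.array([f["nucleus_eccentricity_mean"] for f in feats])
    coll = np.array([f["collagen_density_fraction"] for f in feats])
    thick = np.array([f["trabecular_thickness_um"] for f in feats])

    gene_program = rng.normal(size=n)  # latent axis only observable via expression
    eta = (
        np.asarray(spec.class_effects)[classes]
        + spec.eccentricity_weight * _standardize(ecc)
        + spec.collagen_weight * _standardize(coll)
        + spec.thickness_weight * _standardize(thick)
        + spec.gene_program_weight * gene_program
    )
    eta_std = _standardize(eta)
    latent_risk = 1.0 / (1.0 + np.exp(-eta_std * 1.2))

    # survival: Weibull PH with independent exponential censoring.  The linear
    # predictor combines the latent risk with a protective immune-specific
    # axis that is observable only through the immune gene program.
    eps_imm = rng.normal(size=n)
    k, lam = spec.weibull_shape, spec.weibull_scale_months
    lp = spec.hazard_beta * eta_std - spec.immune_protective_weight * eps_imm
    u = rng.random(n)
    t_death = lam * (-np.log(u) / np.exp(lp)) ** (1.0 / k)
    u2 = rng.random(n)
    t_comp = spec.complication_scale_months * (-np.log(u2) / np.exp(0.8 * lp)) ** (1.0 / k)
    u_c = rng.random(n)
    scale_c = _censor_scale_for_rate(t_death, u_c, spec.censoring_rate)
    t_censor = -scale_c * np.log(u_c) if np.isfinite(scale_c) else np.full(n, np.inf)
    t_censor = np.maximum(t_censor, 0.05)
    surv_time = np.minimum(t_death, t_censor)
    surv_event = (t_death <= t_censor).astype(int)
    comp_time = np.minimum(t_comp, t_censor)
    comp_event = (t_comp <= t_censor).astype(int)

    # expression: programs track eta_std; RANKL/chemo/steroid track class
    has_rna = rng.random(n) < spec.expression_fraction
    noise_genes = [f"GENE{i:04d}" for i in range(spec.n_noise_genes)]
    genes = IMMUNE_GENES + INFLAMMATORY_GENES + RANKL_GENES + STEROID_GENES + CHEMO_GENES + noise_genes
    expr = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(len(genes), n)),
        index=genes,
        columns=[f"P{i:04d}" for i in range(n)],
    )
    for g in IMMUNE_GENES:
        expr.loc[g] = 6.0 + 1.0 * eta_std + 0.65 * eps_imm + rng.normal(0, 0.5, n)
    for g in INFLAMMATORY_GENES:
        expr.loc[g] = 5.0 + 0.8 * eta_std + rng.normal(0, 0.6, n)
    for g in RANKL_GENES:
        expr.loc[g] = 5.0 + 1.2 * (classes == 0) - 0.3 * eta_std + rng.normal(0, 0.6, n)
    for g in STEROID_GENES:
        expr.loc[g] = 5.0 - 0.5 * eta_std + rng.normal(0, 0.6, n)
    for g in CHEMO_GENES:
        expr.loc[g] = 4.0 + 1.5 * (classes == 2) + rng.normal(0, 0.6, n)

    # noisy subtype probabilities standing in for the image classifier
    logits = np.full((n, 3), -1.5)
    logits[np.arange(n), classes] = 1.5
    logits += rng.normal(0, 0.5, size=(n, 3))
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)

    records = []
    for i in range(n):
        pid = f"P{i:04d}"
        records.append(
            PatientRecord(
                patient_id=pid,
                fracture_class=int(classes[i]),
                age=float(age[i]),
                sex=str(sex[i]),
                fracture_level=str(level[i]),
                bmd_t=float(bmd_t[i]),
                features=feats[i],
                class_probs=probs[i],
                expression=expr[pid] if has_rna[i] else None,
                survival_time=float(surv_time[i]),
                survival_event=int(surv_event[i]),
                complication_time=float(comp_time[i]),
                complication_event=int(comp_event[i]),
                slide=slides[i][0],
                slide_truth=slides[i][1],
            )
        )

    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "fracture_class": classes,
            "latent_eta": eta,
            "latent_eta_std": eta_std,
            "latent_risk": latent_risk,
            "gene_program": gene_program,
            "immune_axis": eps_imm,
            "death_time": t_death,
            "censor_time": t_censor,
            "survival_time": surv_time,
            "survival_event": surv_event,
        }
    ).set_index("patient_id")
    return records, truth


def clinical_table(records: list[PatientRecord]) -> pd.DataFrame:
    """Clinical CSV layout: one row per patient."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "level": [r.fracture_level for r in records],
            "bmd_t": [r.bmd_t for r in records],
            "time_months": [r.survival_time for r in records],
            "event": [r.survival_event for r in records],
            "complication_time_months": [r.complication_time for r in records],
            "complication_event": [r.complication_event for r in records],
        }
    ).set_index("patient_id")


def expression_table(records: list[PatientRecord]) -> pd.DataFrame:
    """Genes x samples matrix over the patients that have RNA."""
    cols = {r.patient_id: r.expression for r in records if r.expression is not None}
    if not cols:
        return pd.DataFrame()
    return pd.DataFrame(cols)
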