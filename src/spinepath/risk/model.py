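"""Fracture risk score: feature fusion, survival-boosted training, SHAP, ablation.

The model fuses (a) subtype probabilities, (b) handcrafted histomorphometry,
(c) clinical covariates and (d) transcriptomic markers into one matrix,
boosts a Cox partial-likelihood objective on the composite endpoint
(earliest of death or major complication), and maps the raw margin to a
[0, 1] risk score with a monotone logistic calibrated on training margins.
Missing transcriptomics is handled natively by tree default directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..survstats import bootstrap_ci, concordance
from .shapley import shap_interactions, shap_values
from .trees import BoostedCoxModel, fit_boosted_cox

_LEVEL_ORDER = {"C": 0, "T": 1, "L": 2, "P": 3}

FEATURE_BLOCKS = ("subtype", "histologic", "clinical", "transcriptomic")

_HISTO_COLS = [
    "trabecular_bone_fraction",
    "trabecular_thickness_um",
    "trabecular_separation_um",
    "osteocyte_density_per_mm2",
    "marrow_adiposity_fraction",
    "collagen_density_fraction",
    "inflammatory_cell_density_per_mm2",
    "nucleus_eccentricity_mean",
    "trabecular_disruption_score",
    "marrow_fibrosis_score",
]


@dataclass
class RiskConfig:
    n_trees: int = 160
    learning_rate: float = 0.08
    max_depth: int = 3
    min_samples_leaf: int = 15
    reg_lambda: float = 1.0
    subsample: float = 0.8
    n_folds: int = 5
    endpoint: str = "composite"  # composite | survival | complication
    seed: int = 0


@dataclass
class RiskModel:
    booster: BoostedCoxModel
    columns: list[str]
    blocks: dict[str, str]
    margin_location: float = 0.0
    margin_scale: float = 1.0
    tertiles: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    cv_cindex: float = np.nan
    cv_fold_cindex: list[float] = field(default_factory=list)
    config: RiskConfig = field(default_factory=RiskConfig)

    def margin(self, X: np.ndarray) -> np.ndarray:
        return self.booster.margin(X)

    def risk_score(self, X: np.ndarray) -> np.ndarray:
        m = self.margin(X)
        return 1.0 / (1.0 + np.exp(-(m - self.margin_location) / self.margin_scale))

    def risk_group(self, scores: np.ndarray) -> np.ndarray:
        lo, hi = self.tertiles
        return np.where(scores <= lo, "low", np.where(scores <= hi, "intermediate", "high"))


@dataclass
class RiskOutput:
    patient_id: str
    risk_score: float
    risk_group: str
    shap_values: pd.Series
    shap_base: float
    shap_interactions: pd.DataFrame


def fuse_features(records) -> tuple[pd.DataFrame, dict[str, str]]:
    """Numeric model matrix + column->block manifest.

    Sex is one-hot (``sex_F``); fracture level is ordinal C<T<L<P; missing
    transcriptomics stays missing (NaN), never zero-filled.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    rows = []
    gene_index = None
    for r in records:
        if r.expression is not None:
            gene_index = r.expression.index
            break
    for r in records:
        row: dict[str, float] = {}
        probs = r.class_probs if r.class_probs is not None else [np.nan] * 3
        for k, name in enumerate(("prob_osteoporotic", "prob_traumatic", "prob_neoplastic")):
            row[name] = float(probs[k])
        feats = r.features if isinstance(r.features, dict) else r.features.as_dict()
        for c in _HISTO_COLS:
            row[c] = float(feats.get(c, np.nan))
        row["age"] = float(r.age)
        row["sex_F"] = 1.0 if r.sex == "F" else 0.0
        row["level_ordinal"] = float(_LEVEL_ORDER.get(r.fracture_level, np.nan))
        row["bmd_t"] = float(r.bmd_t) if r.bmd_t is not None else np.nan
        if gene_index is not None:
            if r.expression is not None:
                for g in gene_index:
                    row[f"expr_{g}"] = float(r.expression[g])
            else:
                for g in gene_index:
                    row[f"expr_{g}"] = np.nan
        rows.append(row)
    X = pd.DataFrame(rows, index=pd.Index([r.patient_id for r in records], name="patient_id"))
    all_missing = X.columns[X.isna().all()]
    if len(all_missing):
        warnings.warn(f"dropping all-missing columns: {list(all_missing)}")
        X = X.drop(columns=all_missing)
    blocks = {}
    for c in X.columns:
        if c.startswith("prob_"):
            blocks[c] = "subtype"
        elif c in _HISTO_COLS:
            blocks[c] = "histologic"
        elif c.startswith("expr_"):
            blocks[c] = "transcriptomic"
        else:
            blocks[c] = "clinical"
    return X, blocks


def _endpoint(records, which: str):
    t_s = np.array([r.survival_time for r in records])
    e_s = np.array([r.survival_event for r in records])
    if which == "survival":
        return t_s, e_s
    t_c = np.array([r.complication_time for r in records])
    e_c = np.array([r.complication_event for r in records])
    if which == "complication":
        return t_c, e_c
    # composite: earliest of death or major complication
    time = np.minimum(t_s, t_c)
    event = np.where(t_s <= t_c, e_s, e_c)
    event = np.maximum(event, np.where((t_c < t_s) & (e_c == 1), 1, 0))
    return time, event


def _cv_folds(n, n_folds, seed):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return np.array_split(idx, n_folds)


def train_risk(records, config: RiskConfig | None = None) -> RiskModel:
    """Fit the boosted Cox risk model with 5-fold CV concordance reporting."""
    config = config or RiskConfig()
    X_df, blocks = fuse_features(records)
    X = X_df.to_numpy(dtype=np.float64)
    time, event = _endpoint(records, config.endpoint)
    if event.sum() < 2:
        raise ValueError("need at least 2 events in the training data")

    fold_c = []
    for k, test_idx in enumerate(_cv_folds(len(records), config.n_folds, config.seed)):
        train_idx = np.setdiff1d(np.arange(len(records)), test_idx)
        if event[train_idx].sum() < 2 or event[test_idx].sum() < 1:
            continue
        booster = fit_boosted_cox(
            X[train_idx], time[train_idx], event[train_idx],
            n_trees=config.n_trees,
            learning_rate=config.learning_rate,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            reg_lambda=config.reg_lambda,
            subsample=config.subsample,
            seed=config.seed + 1000 + k,
        )
        c = concordance(booster.margin(X[test_idx]), time[test_idx], event[test_idx])
        if not np.isnan(c):
            fold_c.append(float(c))

    booster = fit_boosted_cox(
        X, time, event,
        n_trees=config.n_trees,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        reg_lambda=config.reg_lambda,
        subsample=config.subsample,
        seed=config.seed,
    )
    margins = booster.margin(X)
    location = float(np.median(margins))
    iqr = float(np.subtract(*np.percentile(margins, [75, 25])))
    scale = iqr if iqr > 0 else 1.0
    scores = 1.0 / (1.0 + np.exp(-(margins - location) / scale))
    tertiles = tuple(np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0]))
    model = RiskModel(
        booster=booster,
        columns=list(X_df.columns),
        blocks=blocks,
        margin_location=location,
        margin_scale=scale,
        tertiles=tertiles,
        cv_cindex=float(np.mean(fold_c)) if fold_c else np.nan,
        cv_fold_cindex=fold_c,
        config=config,
    )
    return model


def _check_layout(model: RiskModel, X_df: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.columns if c not in X_df.columns]
    if missing:
        raise ValueError(f"record is missing model columns: {missing}")
    return X_df[model.columns].to_numpy(dtype=np.float64)


def score_risk(model: RiskModel, records, with_shap: bool = False) -> list[RiskOutput]:
    """Score records; risk group uses the training-set tertile cut points."""
    X_df, _ = fuse_features(records)
    X = _check_layout(model, X_df)
    scores = model.risk_score(X)
    groups = model.risk_group(scores)
    phi = inter = None
    base = np.nan
    if with_shap:
        phi, base = shap_values(model.booster, X)
        inter = shap_interactions(model.booster, X)
    outputs = []
    for i, r in enumerate(records):
        outputs.append(
            RiskOutput(
                patient_id=r.patient_id,
                risk_score=float(scores[i]),
                risk_group=str(groups[i]),
                shap_values=pd.Series(phi[i], index=model.columns) if phi is not None else None,
                shap_base=float(base) if phi is not None else np.nan,
                shap_interactions=(
                    pd.DataFrame(inter[i], index=model.columns, columns=model.columns)
                    if inter is not None
                    else None
                ),
            )
        )
    return outputs


def explain_shap(model: RiskModel, records, interactions: bool = False) -> dict:
    """Exact tree-SHAP report: per-record values, global mean-|SHAP| ranking."""
    X_df, _ = fuse_features(records)
    X = _check_layout(model, X_df)
    phi, base = shap_values(model.booster, X)
    values = pd.DataFrame(phi, index=X_df.index, columns=model.columns)
    ranking = values.abs().mean(axis=0).sort_values(ascending=False)
    report = {
        "values": values,
        "base": float(base),
        "margins": model.margin(X),
        "ranking": ranking,
    }
    if interactions:
        report["interactions"] = shap_interactions(model.booster, X)
    return report


def ablate(records, config: RiskConfig, drop_block: str, n_boot: int = 200) -> dict:
    """Paired CV concordance with vs. without one feature block."""
    if drop_block not in FEATURE_BLOCKS:
        raise ValueError(f"drop_block must be one of {FEATURE_BLOCKS}")
    X_df, blocks = fuse_features(records)
    keep_cols = [c for c in X_df.columns if blocks[c] != drop_block]
    if not keep_cols:
        raise ValueError("ablation would drop every feature")
    time, event = _endpoint(records, config.endpoint)
    X_full = X_df.to_numpy(dtype=np.float64)
    col_idx = [X_df.columns.get_loc(c) for c in keep_cols]
    X_drop = X_full[:, col_idx]

    pairs = []
    preds_full = np.zeros(len(records))
    preds_drop = np.zeros(len(records))
    for k, test_idx in enumerate(_cv_folds(len(records), config.n_folds, config.seed)):
        train_idx = np.setdiff1d(np.arange(len(records)), test_idx)
        kwargs = dict(
            n_trees=config.n_trees,
            learning_rate=config.learning_rate,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            reg_lambda=config.reg_lambda,
            subsample=config.subsample,
            seed=config.seed + 2000 + k,
        )
        m_full = fit_boosted_cox(X_full[train_idx], time[train_idx], event[train_idx], **kwargs)
        m_drop = fit_boosted_cox(X_drop[train_idx], time[train_idx], event[train_idx], **kwargs)
        preds_full[test_idx] = m_full.margin(X_full[test_idx])
        preds_drop[test_idx] = m_drop.margin(X_drop[test_idx])
        c_f = concordance(preds_full[test_idx], time[test_idx], event[test_idx])
        c_d = concordance(preds_drop[test_idx], time[test_idx], event[test_idx])
        pairs.append((c_f, c_d))

    c_full = concordance(preds_full, time, event)
    c_drop = concordance(preds_drop, time, event)
    data = pd.DataFrame(
        {"full": preds_full, "drop": preds_drop, "time": time, "event": event}
    )

    def diff_metric(d):
        return concordance(d["full"].to_numpy(), d["time"].to_numpy(), d["event"].to_numpy()) - concordance(
            d["drop"].to_numpy(), d["time"].to_numpy(), d["event"].to_numpy()
        )

    est, ci = bootstrap_ci(diff_metric, data, n_boot=n_boot, seed=config.seed)
    return {
        "block": drop_block,
        "cindex_full": float(c_full),
        "cindex_without": float(c_drop),
        "difference": float(c_full - c_drop),
        "difference_ci": ci,
        "fold_pairs": pairs,
    }
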