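"""Configuration, manifest-driven I/O and the end-to-end pipeline run.

All randomness flows from one global seed through per-stage derived seeds.
The run manifest records input/config hashes, per-stage timing and every
output file, and is written atomically at the end of the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("spinepath")

_STAGES = ("synth", "preprocess", "morphometry", "mil", "risk", "omics", "survival")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "spinepath_run"
    version: str = "0.1.0"
    # synth
    n_patients: int = 60
    n_rendered_slides: int = 6
    censoring_rate: float = 0.3
    hazard_beta: float = 1.5
    # preprocess
    tile_size_px: int = 128
    overlap_fraction: float = 0.5
    blank_fraction_max: float = 0.5
    # mil (desk scale)
    mil_bags_per_class: int = 12
    mil_tiles_per_bag: int = 12
    mil_tile_px: int = 64
    mil_epochs: int = 8
    # risk
    risk_trees: int = 80
    risk_depth: int = 3
    stages: tuple[str, ...] = _STAGES

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        # the run location must not affect the config hash (determinism checks)
        d["out_dir"] = "."
        Path(path).write_text(json.dumps(d, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute synth -> preprocess -> morphometry -> MIL -> risk -> omics ->
    survival on a synthetic cohort, writing all declared outputs.

    Returns the run manifest.  A stage failure aborts with the stage name;
    partial outputs are preserved.
    """
    from .mil import MILConfig, evaluate_classifier, train_mil
    from .morphometry import compute_features, feature_table
    from .omics import default_gene_sets, immune_activity_score, risk_immune_strata, signature_score
    from .preprocess import PreprocessConfig, segment_tissue, tile_slide
    from .risk import RiskConfig, score_risk, train_risk
    from .survstats import concordance, km_estimate, logrank_test
    from .synth.cohort import CohortSpec, clinical_table, expression_table, generate_cohort
    from .synth.slides import render_slide, spec_for_class
    from .synth.tiles import generate_mil_cohort

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": config.version,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }
    state: dict = {}

    def emit_csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path)
        manifest["outputs"].append(name)
        return path

    def run_stage(name, fn):
        if name not in config.stages:
            logger.info("stage %s skipped", name)
            manifest["stages"][name] = {"skipped": True}
            return
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            manifest["stages"][name] = {"failed": str(exc)}
            _write_manifest(out, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}

    # --- stages ----------------------------------------------------------------
    def stage_synth():
        spec = CohortSpec(
            n_patients=config.n_patients,
            censoring_rate=config.censoring_rate,
            hazard_beta=config.hazard_beta,
            seed=_stage_seed(config.seed, "synth"),
        )
        records, truth = generate_cohort(spec)
        state["records"], state["truth"] = records, truth
        emit_csv(clinical_table(records), "clinical.csv")
        emit_csv(truth, "ground_truth.csv")
        expr = expression_table(records)
        path = out / "expression.tsv"
        expr.to_csv(path, sep="\t")
        manifest["outputs"].append("expression.tsv")
        # a few rendered slides exercise the imaging stages
        rng = np.random.default_rng(_stage_seed(config.seed, "synth-slides"))
        slides = []
        for i in range(config.n_rendered_slides):
            cls = i % 3
            sspec = spec_for_class(cls, seed=int(rng.integers(2**31)), background_border_px=16)
            slides.append((f"S{i:03d}", cls) + render_slide(sspec))
        state["slides"] = slides

    def stage_preprocess():
        cfg = PreprocessConfig(
            tile_size_px=config.tile_size_px,
            overlap_fraction=config.overlap_fraction,
            blank_fraction_max=config.blank_fraction_max,
        )
        rows = []
        bags = {}
        for sid, cls, img, gt in state["slides"]:
            mask = segment_tissue(img)
            bag = tile_slide(img, mask, cfg, slide_id=sid)
            bags[sid] = bag
            for q in bag.qc_flags:
                rows.append({"slide_id": sid, **{k: q[k] for k in ("row", "col", "blank", "blur", "fold")}})
        state["bags"] = bags
        emit_csv(pd.DataFrame(rows).set_index("slide_id"), "tile_qc.csv")

    def stage_morphometry():
        feats = {}
        for sid, cls, img, gt in state["slides"]:
            feats[sid] = compute_features(img, gt.microns_per_pixel, gt.tissue_mask)
        emit_csv(feature_table(feats), "morphometry.csv")

    def stage_mil():
        seed = _stage_seed(config.seed, "mil")
        bags = generate_mil_cohort(
            n_bags_per_class=config.mil_bags_per_class,
            tiles_per_bag=config.mil_tiles_per_bag,
            tile_px=config.mil_tile_px,
            seed=seed,
        )
        n_train = 2 * len(bags) // 3
        rng = np.random.default_rng(seed + 1)
        order = rng.permutation(len(bags))
        train = [bags[i] for i in order[:n_train]]
        test = [bags[i] for i in order[n_train:]]
        model = train_mil(train, MILConfig(tile_px=config.mil_tile_px, epochs=config.mil_epochs, seed=seed))
        report = evaluate_classifier(model, test, n_boot=200, seed=seed)
        (out / "mil_metrics.json").write_text(json.dumps(report, indent=2))
        manifest["outputs"].append("mil_metrics.json")
        state["mil_model"] = model

    def stage_risk():
        records = state["records"]
        cfg = RiskConfig(
            n_trees=config.risk_trees,
            max_depth=config.risk_depth,
            seed=_stage_seed(config.seed, "risk"),
        )
        model = train_risk(records, cfg)
        outputs = score_risk(model, records)
        df = pd.DataFrame(
            {
                "patient_id": [o.patient_id for o in outputs],
                "risk_score": [o.risk_score for o in outputs],
                "risk_group": [o.risk_group for o in outputs],
            }
        ).set_index("patient_id")
        emit_csv(df, "risk.csv")
        state["risk_model"], state["risk"] = model, df
        manifest["cv_cindex"] = model.cv_cindex

    def stage_omics():
        expr_path = out / "expression.tsv"
        from .omics import load_expression

        expr = load_expression(expr_path)
        sets = default_gene_sets()
        scores = pd.DataFrame(index=expr.columns)
        scores["immune_activity"] = immune_activity_score(expr, sets["immune_activity"])
        for name in ("rankl_signaling", "steroid_sensitivity", "chemo_response"):
            scores[name] = signature_score(expr, sets[name])
        state["omics"] = scores
        emit_csv(scores, "omics_scores.csv")

    def stage_survival():
        records = state["records"]
        risk = state["risk"]["risk_score"]
        times = pd.Series({r.patient_id: r.survival_time for r in records})
        events = pd.Series({r.patient_id: r.survival_event for r in records})
        ids = risk.index
        km = km_estimate(times[ids].to_numpy(), events[ids].to_numpy())
        emit_csv(
            pd.DataFrame(
                {
                    "time": km.times,
                    "survival": km.survival,
                    "at_risk": km.at_risk,
                    "ci_lower": km.ci_lower,
                    "ci_upper": km.ci_upper,
                }
            ).set_index("time"),
            "km_curve.csv",
        )
        hi = risk > risk.median()
        chi2, p = logrank_test(
            times[ids][~hi].to_numpy(), events[ids][~hi].to_numpy(),
            times[ids][hi].to_numpy(), events[ids][hi].to_numpy(),
        )
        c = concordance(risk.to_numpy(), times[ids].to_numpy(), events[ids].to_numpy())
        strata = None
        if "omics" in state:
            common = risk.index.intersection(state["omics"].index)
            strata = risk_immune_strata(risk[common], state["omics"].loc[common, "immune_activity"])
            emit_csv(strata.to_frame(), "risk_immune_strata.csv")
        report = {"logrank_chi2": chi2, "logrank_p": p, "cindex_risk": c}
        (out / "survival_report.json").write_text(json.dumps(report, indent=2))
        manifest["outputs"].append("survival_report.json")

    stage_fns = {
        "synth": stage_synth,
        "preprocess": stage_preprocess,
        "morphometry": stage_morphometry,
        "mil": stage_mil,
        "risk": stage_risk,
        "omics": stage_omics,
        "survival": stage_survival,
    }
    for name in _STAGES:
        run_stage(name, stage_fns[name])

    config.to_json(out / "config.json")
    manifest["outputs"].append("config.json")
    manifest["config_hash"] = _sha256(out / "config.json")
    manifest["output_hashes"] = {
        name: _sha256(out / name) for name in manifest["outputs"] if (out / name).is_file()
    }
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    os.replace(tmp, out / "manifest.json")


def validate_inputs(
    clinical_csv=None, expression_tsv=None, gene_sets_json=None
) -> list[dict]:
    """Schema checks; returns a list of issues (empty means clean)."""
    issues: list[dict] = []

    def add(file, row, message):
        issues.append({"file": str(file), "row": row, "issue": message})

    if clinical_csv is not None:
        try:
            df = pd.read_csv(clinical_csv)
        except Exception as exc:
            add(clinical_csv, None, f"unreadable: {exc}")
            df = None
        if df is not None:
            for col in ("patient_id", "age", "sex", "time_months", "event"):
                if col not in df.columns:
                    add(clinical_csv, None, f"missing column {col!r}")
            if "time_months" in df.columns:
                for i, v in df["time_months"].items():
                    if not (pd.notna(v) and v > 0):
                        add(clinical_csv, int(i), f"non-positive survival time {v!r}")
            if "sex" in df.columns:
                for i, v in df["sex"].items():
                    if v not in ("M", "F"):
                        add(clinical_csv, int(i), f"sex value {v!r} outside M/F coding")
            if "event" in df.columns:
                for i, v in df["event"].items():
                    if v not in (0, 1):
                        add(clinical_csv, int(i), f"event flag {v!r} not in {{0,1}}")
    if expression_tsv is not None:
        from .omics import load_expression

        try:
            load_expression(expression_tsv)
        except Exception as exc:
            add(expression_tsv, None, str(exc))
    if gene_sets_json is not None:
        try:
            raw = json.loads(Path(gene_sets_json).read_text())
            for name, entry in raw.items():
                if not entry.get("genes"):
                    add(gene_sets_json, None, f"gene set {name!r} has no genes")
        except Exception as exc:
            add(gene_sets_json, None, f"unreadable: {exc}")
    return issues
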