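"""End-to-end orchestration: simulate/load -> preprocess -> select -> train ->
evaluate -> adjust -> nomogram, with every intermediate persisted as text and
a manifest recording seeds, stage parameters and content hashes.

The training cohort is the only cohort any parameter is ever fitted on;
validation cohorts pass through the frozen transforms and the trained model
only. Rerunning with an identical configuration reproduces identical
artifacts (the manifest carries content hashes to prove it).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from ._containers import ClinicalTable, ExpressionMatrix
from .evaluation import dichotomize_risk, evaluate_cohort
from .network import TrainConfig, predict_risk, save_model, train_deepcox
from .nomogram import build_nomogram, clinical_design, multivariable_adjustment
from .preprocess import apply_frozen, fit_preprocess
from .screening import build_signature
from .synthetic import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Hierarchical stage configuration; see ``from_dict`` for the schema."""

    seed: int = 0
    endpoint: str = "os"
    simulate: dict = field(default_factory=dict)  # {'train': {...}, 'validation': {name: {...}}}
    data: dict = field(default_factory=dict)  # {'train': {'expr':…, 'clinical':…}, 'validation': {…}}
    preprocess: dict = field(default_factory=dict)
    select: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)
    nomogram: dict = field(default_factory=dict)

    def validate(self):
        has_sim = bool(self.simulate.get("train"))
        has_data = bool(self.data.get("train"))
        if has_sim == has_data:
            raise ValueError(
                "exactly one training cohort must be given, either under "
                "'simulate' or under 'data'"
            )
        val = (self.simulate if has_sim else self.data).get("validation", {})
        if "train" in val:
            raise ValueError("a validation cohort may not be named 'train'")
        if has_data:
            tr = self.data["train"]
            for name, spec in val.items():
                if spec.get("expr") == tr.get("expr"):
                    raise ValueError(
                        f"validation cohort {name!r} reuses the training files"
                    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(spec: dict) -> tuple[ExpressionMatrix, ClinicalTable]:
    clinical = tio.read_clinical(spec["clinical"])
    expr = tio.read_expression(spec["expr"])
    # attach batch labels from the clinical table, aligned to expression
    aligned = clinical.aligned_to(expr.sample_ids)
    batch = (
        [str(b) for b in aligned.data["batch"]]
        if "batch" in aligned.data.columns
        else None
    )
    expr.batch = batch
    return expr, clinical


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage; returns the artifact dictionary.

    Persists: simulated cohorts (when simulating), frozen preprocessing
    parameters, the gene signature, the trained model, per-cohort risk
    scores and evaluation reports, the multivariable hazard-ratio table, the
    nomogram, and ``manifest.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    manifest: dict = {"seed": seed, "endpoint": config.endpoint, "stages": {}}
    written: list[Path] = []

    def _persist(path: Path):
        written.append(path)

    # ---- cohorts -----------------------------------------------------------
    cohorts: dict[str, tuple[ExpressionMatrix, ClinicalTable]] = {}
    if config.simulate.get("train"):
        sim_specs = {"train": config.simulate["train"]}
        sim_specs.update(config.simulate.get("validation", {}))
        for i, (name, params) in enumerate(sim_specs.items()):
            sim = SimulationConfig(
                **params, cohort=name, seed=seed * 100 + 11 + i
            )
            expr, clinical, truth = generate_cohort(sim)
            cohorts[name] = (expr, clinical)
            tio.write_expression(expr, out / f"expr_{name}.tsv")
            tio.write_clinical(clinical, out / f"clinical_{name}.csv")
            tio.write_truth(truth, out / f"truth_{name}.txt")
            _persist(out / f"expr_{name}.tsv")
            _persist(out / f"clinical_{name}.csv")
            _persist(out / f"truth_{name}.txt")
            manifest["stages"].setdefault("simulate", {})[name] = {
                "seed": sim.seed,
                "n_samples": sim.n_samples,
                "n_genes": sim.n_genes,
            }
    else:
        cohorts["train"] = _load_cohort(config.data["train"])
        for name, spec in config.data.get("validation", {}).items():
            cohorts[name] = _load_cohort(spec)

    train_expr, train_clinical = cohorts["train"]
    val_names = [n for n in cohorts if n != "train"]

    # ---- preprocess --------------------------------------------------------
    min_frac = float(config.preprocess.get("min_frac_expressed", 0.2))
    train_z, params = fit_preprocess(train_expr, min_frac)
    tio.write_params(params, out / "preprocess_params.json")
    _persist(out / "preprocess_params.json")
    manifest["stages"]["preprocess"] = {
        "min_frac_expressed": min_frac,
        "n_genes_kept": len(params.kept_gene_ids),
        "params_hash": params.content_hash(),
    }

    # ---- select ------------------------------------------------------------
    sel = dict(config.select)
    sig = build_signature(
        train_z,
        train_clinical,
        alpha=float(sel.get("alpha", 0.05)),
        target_size=sel.get("target_size", 100),
        seed=seed * 100 + 31,
        n_lambda=int(sel.get("n_lambda", 50)),
        lambda_min_ratio=float(sel.get("lambda_min_ratio", 0.01)),
    )
    tio.write_signature(sig, out / "signature.csv")
    _persist(out / "signature.csv")
    manifest["stages"]["select"] = {
        "n_selected": len(sig),
        "lambda": sig.lambda_used,
        **sig.meta,
    }

    # ---- train -------------------------------------------------------------
    tc_kwargs = dict(config.train)
    if "hidden" in tc_kwargs:
        tc_kwargs["hidden"] = tuple(tc_kwargs["hidden"])
    tconf = TrainConfig(**tc_kwargs)
    train_sig_expr = train_z.subset_genes(sig.gene_ids)
    aligned = train_clinical.aligned_to(train_sig_expr.sample_ids)
    model = train_deepcox(
        train_sig_expr, aligned.time, aligned.event, tconf, seed=seed * 100 + 41
    )
    save_model(model, out / "model.json")
    _persist(out / "model.json")
    manifest["stages"]["train"] = {
        "seed": model.seed,
        "hidden": list(model.hidden),
        "dropout": model.dropout,
        "best_epoch": model.train_log.get("best_epoch"),
    }

    # ---- evaluate ----------------------------------------------------------
    ev = dict(config.evaluate)
    horizons = [float(h) for h in ev.get("horizons", [36.0])]
    n_boot = int(ev.get("n_boot", 1000))
    train_scores = predict_risk(model, train_z)
    _, cutoff = dichotomize_risk(train_scores)
    reports = {}
    for name in ["train", *val_names]:
        expr_c, clin_c = cohorts[name]
        z = train_z if name == "train" else apply_frozen(expr_c, params)
        rep = evaluate_cohort(
            model,
            z,
            clin_c,
            horizons=horizons,
            seed=seed * 100 + 51,
            cutoff=cutoff,
            n_boot=n_boot,
            endpoint=config.endpoint,
            cohort=name,
        )
        reports[name] = rep
        scores = rep.extras["scores"]
        tio.write_scores(scores, out / f"scores_{name}.csv")
        (out / f"report_{name}.txt").write_text(rep.to_text())
        _persist(out / f"scores_{name}.csv")
        _persist(out / f"report_{name}.txt")
        manifest["stages"].setdefault("evaluate", {})[name] = {
            "c_index": rep.c_index,
            "logrank_p": rep.logrank_p,
            "auc": {f"{h:g}": a for h, a in rep.auc_by_horizon.items()},
        }

    # ---- multivariable adjustment + nomogram -------------------------------
    fit = multivariable_adjustment(train_scores, train_clinical)
    fit.summary().to_csv(out / "hr_table.csv", index=False, float_format="%.8g")
    _persist(out / "hr_table.csv")
    design = clinical_design(train_clinical.aligned_to(train_scores.sample_ids))
    ranges = {"risk_score": (float(train_scores.score.min()),
                             float(train_scores.score.max()))}
    for c in design.columns:
        ranges[c] = (float(design[c].min()), float(design[c].max()))
    nomo_horizons = [
        h for h in [float(x) for x in config.nomogram.get("horizons", horizons)]
        if len(fit.baseline_times) and h <= fit.baseline_times[-1]
    ]
    nomo = None
    if nomo_horizons:
        nomo = build_nomogram(fit, nomo_horizons, ranges)
        nomo.to_frame().to_csv(out / "nomogram_points.csv", index=False,
                               float_format="%.8g")
        _persist(out / "nomogram_points.csv")
        manifest["stages"]["nomogram"] = {
            "horizons": nomo_horizons,
            "scale_b": nomo.scale_b,
        }
    manifest["stages"]["adjustment"] = {
        "covariates": fit.names,
        "hr": [float(h) for h in fit.hr],
        "p": [float(p) for p in fit.p_values],
    }

    manifest["files"] = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "params": params,
        "signature": sig,
        "model": model,
        "reports": reports,
        "adjustment": fit,
        "nomogram": nomo,
        "cutoff": cutoff,
        "manifest": manifest,
        "out_dir": out,
    }
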