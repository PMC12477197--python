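"""End-to-end run: generate/load -> preprocess -> split/train -> stack ->
aggregate, driven by one YAML configuration.

Artifacts written to the output directory: QC report, peak-stats table,
embedding coordinates, per-model metric reports, per-sample decisions,
and a JSON run log with the master seed, a config hash and per-stage
record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import dataset_to_matrix
from .embed import embeddings_to_frame, lada_embed, oplsda_fit, tsne_embed
from .ensemble import decide_samples, fit_stack, sample_accuracy_distribution, select_top_k
from .models import (TRADITIONAL_MODELS, apply_split, cross_validate, evaluate,
                     smote_oversample, split_dataset, train_model)
from .peaks import build_peak_stats
from .preprocess import PreprocessConfig, preprocess_dataset
from .synth import (DEFAULT_PEAK_TABLE, BaselineConfig, GeneratorConfig,
                    default_peak_templates, generate_dataset)

logger = logging.getLogger(__name__)

REQUIRED_SECTIONS = ("input", "preprocess", "models", "ensemble")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    missing = [s for s in REQUIRED_SECTIONS if s not in config]
    if missing:
        raise ValueError(f"config missing section(s): {missing}")
    return config


def _build_dataset(section: dict, seed: int):
    if "manifest" in section:
        from .io import read_manifest
        return read_manifest(section["manifest"])
    synth = dict(section.get("synth", {}))
    sep = synth.pop("separability", 1.0)
    baseline = BaselineConfig(**synth.pop("baseline", {}))
    cfg = GeneratorConfig(seed=synth.pop("seed", seed), baseline=baseline, **{
        k: tuple(v) if isinstance(v, list) else v for k, v in synth.items()
    })
    templates = default_peak_templates(separability=sep)
    return generate_dataset(cfg, templates)


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the four study steps; returns the artifact directory."""
    t0 = time.time()
    config = load_config(config_path)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "artifacts"))
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": seed, "config_hash": _config_hash(config),
                 "version": __version__, "python": platform.python_version(),
                 "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("load")
        samples = _build_dataset(config["input"], seed)
        log["stages"]["load"] = {"samples": len(samples),
                                 "spectra": sum(r.n_spectra for r in samples)}

        name = stage("preprocess")
        pp_cfg = PreprocessConfig(**config.get("preprocess", {}) or {})
        processed, qc_reports = preprocess_dataset(samples, pp_cfg)
        qc_rows = []
        for sid, rep in qc_reports.items():
            for rec in rep.get("qc_excluded", []):
                qc_rows.append({"sample_id": sid, "replicate": rec[1], "reason": rec[2]})
        pd.DataFrame(qc_rows, columns=["sample_id", "replicate", "reason"]
                     ).to_csv(outdir / "qc_report.csv", index=False)
        log["stages"]["preprocess"] = {
            "samples": len(processed),
            "spectra": sum(r.n_spectra for r in processed)}

        name = stage("peaks")
        peaks_cfg = config.get("peaks", {}) or {}
        positions = peaks_cfg.get("positions") or [p for p, *_ in DEFAULT_PEAK_TABLE]
        stats = build_peak_stats(processed, positions,
                                 units=peaks_cfg.get("units", "spectrum"))
        stats.to_csv(outdir / "peak_stats.csv", index=False)
        log["stages"]["peaks"] = {"rows": len(stats)}

        name = stage("embed")
        X_all, y_all, _ = dataset_to_matrix(processed)
        emb_cfg = config.get("embed", {}) or {}
        results = []
        if emb_cfg.get("tsne", True):
            perplexity = min(30.0, max(2.0, (len(X_all) - 1) / 4))
            results.append(tsne_embed(X_all, y_all, perplexity=perplexity, seed=seed))
        if emb_cfg.get("oplsda", True):
            _, res = oplsda_fit(X_all, y_all)
            results.append(res)
        if emb_cfg.get("lada", True):
            results.append(lada_embed(np.clip(X_all, 0, None), y_all, seed=seed))
        if results:
            embeddings_to_frame(results).to_csv(outdir / "embeddings.csv", index=False)
        log["stages"]["embed"] = {"methods": [r.method for r in results]}

        name = stage("train")
        m_cfg = config["models"] or {}
        plan = split_dataset(processed, m_cfg.get("fraction", 0.8), seed)
        train, predict = apply_split(processed, plan)
        X_tr, y_tr, sid_tr = dataset_to_matrix(train)
        X_te, y_te, sid_te = dataset_to_matrix(predict)
        Xb, yb = smote_oversample(X_tr, y_tr,
                                  m_cfg.get("smote_k_neighbors", 5), seed)
        names = m_cfg.get("names") or list(TRADITIONAL_MODELS)
        reports = []
        for mn in names:
            hp = (m_cfg.get("hyperparams", {}) or {}).get(mn)
            cv = None
            if mn in TRADITIONAL_MODELS and m_cfg.get("cross_validate", False):
                cv = cross_validate(mn, X_tr, y_tr, sid_tr,
                                    m_cfg.get("k_folds", 5), seed)
                hp = {**(cv["best_params"]), **(hp or {})}
            est = train_model(mn, Xb, yb, hp, seed)
            rep = evaluate(est, X_te, y_te, name=mn)
            if cv:
                rep.cv_scores = cv["fold_scores"]
            reports.append(rep)
        report_df = pd.DataFrame([r.to_row() for r in reports]).sort_values(
            "accuracy", ascending=False, kind="stable").reset_index(drop=True)
        report_df.insert(0, "rank", np.arange(1, len(report_df) + 1))
        report_df.to_csv(outdir / "model_reports.csv", index=False)
        log["stages"]["train"] = {"train_samples": len(train),
                                  "predict_samples": len(predict),
                                  "train_spectra": len(y_tr),
                                  "smote_spectra": len(yb),
                                  "predict_spectra": len(y_te),
                                  "models": [r.name for r in reports]}

        name = stage("stack")
        e_cfg = config["ensemble"] or {}
        k = e_cfg.get("top_k", 4)
        base = e_cfg.get("base_names") or select_top_k(reports, min(k, len(reports)))
        ens = fit_stack(base, X_tr, y_tr, sid_tr, seed,
                        k_folds=e_cfg.get("k_folds", 5))
        stack_report = evaluate(ens, X_te, y_te, name="STACK")
        log["stages"]["stack"] = {"base": base,
                                  "accuracy": stack_report.accuracy}

        name = stage("aggregate")
        decisions = decide_samples(ens, predict)
        pd.DataFrame([{
            "sample_id": d.sample_id, "truth": d.truth, "prediction": d.final_label,
            "n_spectra": d.n_spectra, "fraction_correct": d.fraction_correct,
        } for d in decisions]).to_csv(outdir / "sample_decisions.csv", index=False)
        hist = sample_accuracy_distribution(decisions)
        sample_acc = float(np.mean([d.final_label == d.truth for d in decisions]))
        log["stages"]["aggregate"] = {"samples": len(decisions),
                                      "sample_accuracy": sample_acc,
                                      "share_above_half": hist["share_above_half"]}
        (outdir / "stack_summary.json").write_text(json.dumps({
            "base_models": base,
            "spectrum_accuracy": stack_report.accuracy,
            "spectrum_sensitivity": stack_report.sensitivity,
            "spectrum_specificity": stack_report.specificity,
            "sample_accuracy": sample_acc,
            "histogram": hist,
        }, indent=2))
    except Exception as exc:
        log["failed_stage"] = name
        log["error"] = str(exc)
        (outdir / "run.json").write_text(json.dumps(log, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}") from exc

    log["elapsed_s"] = round(time.time() - t0, 2)
    (outdir / "run.json").write_text(json.dumps(log, indent=2, default=str))
    return outdir
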