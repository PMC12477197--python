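"""Stack the four best models and aggregate per-sample decisions.

Reads the ranking from 05 (falls back to the four cheap linear/distance
families if 05 has not been run), fits the out-of-fold stacking ensemble
on the training spectra, evaluates per spectrum, then applies the
mode-vote per sample and reports the fraction-correct histogram.
"""

import importlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ramanembryo.datatypes import dataset_to_matrix
from ramanembryo.ensemble import (decide_samples, fit_stack,
                                  sample_accuracy_distribution)
from ramanembryo.models import evaluate

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    train_mod = importlib.import_module("05_train_models")
    train, predict = train_mod.desk_scale_split()
    X_tr, y_tr, sid_tr = dataset_to_matrix(train)
    X_te, y_te, _ = dataset_to_matrix(predict)

    report_path = RESULTS / "05_model_reports.csv"
    if report_path.exists():
        ranking = pd.read_csv(report_path)
        base = ranking["model"].head(4).tolist()
    else:
        base = ["LDA", "LR", "NB", "KNN"]
    print(f"stacking base models: {base}")

    ens = fit_stack(base, X_tr, y_tr, sid_tr, SEED)
    rep = evaluate(ens, X_te, y_te, name="STACK")
    decisions = decide_samples(ens, predict)
    hist = sample_accuracy_distribution(decisions)
    sample_acc = float(np.mean([d.final_label == d.truth for d in decisions]))

    pd.DataFrame([{
        "sample_id": d.sample_id, "truth": d.truth, "prediction": d.final_label,
        "n_spectra": d.n_spectra, "fraction_correct": d.fraction_correct,
    } for d in decisions]).to_csv(RESULTS / "06_sample_decisions.csv", index=False)

    summary = {
        "base_models": base,
        "spectrum_accuracy": rep.accuracy,
        "spectrum_sensitivity": rep.sensitivity,
        "spectrum_specificity": rep.specificity,
        "per_class_sensitivity": rep.per_class_sensitivity,
        "per_class_specificity": rep.per_class_specificity,
        "sample_accuracy": sample_acc,
        "share_samples_above_half_correct": hist["share_above_half"],
        "histogram_counts": hist["counts"],
    }
    (RESULTS / "06_stack_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
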