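"""Train and rank the 12 classifier families on the synthetic cohort.

Desk-scale version of the modelling protocol: the cohort is regenerated
on a 4 cm^-1 grid (776 points instead of 3101) to keep the full
12-family comparison in minutes on one CPU. Sample-level 80/20 split,
SMOTE on the training spectra, spectrum-level evaluation; traditional
families additionally get 5-fold sample-level CV scores.
"""

import time
from pathlib import Path

import numpy as np
import pandas as pd

from ramanembryo.datatypes import dataset_to_matrix
from ramanembryo.models import (ALL_MODELS, TRADITIONAL_MODELS, apply_split,
                                cross_validate, evaluate, smote_oversample,
                                split_dataset, train_model)
from ramanembryo.preprocess import PreprocessConfig, preprocess_dataset
from ramanembryo.synth import GeneratorConfig, default_peak_templates, generate_dataset

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 0
GRID = (300.0, 3400.0, 4.0)


def desk_scale_split():
    cfg = GeneratorConfig(grid=GRID, seed=SEED)
    cohort = generate_dataset(cfg, default_peak_templates())
    pp = PreprocessConfig(range=GRID[:2], step=GRID[2])
    processed, _ = preprocess_dataset(cohort, pp)
    plan = split_dataset(processed, 0.8, SEED)
    train, predict = apply_split(processed, plan)
    return train, predict


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    train, predict = desk_scale_split()
    X_tr, y_tr, sid_tr = dataset_to_matrix(train)
    X_te, y_te, _ = dataset_to_matrix(predict)
    print(f"{len(train)}/{len(predict)} samples, "
          f"{len(y_tr)}/{len(y_te)} spectra, {X_tr.shape[1]} points")
    Xb, yb = smote_oversample(X_tr, y_tr, 5, SEED)

    rows = []
    for name in ALL_MODELS:
        t0 = time.time()
        cv = None
        if name in TRADITIONAL_MODELS:
            cv = cross_validate(name, X_tr, y_tr, sid_tr, 5, SEED, grid={})
        est = train_model(name, Xb, yb, None, SEED)
        rep = evaluate(est, X_te, y_te, name=name)
        row = rep.to_row()
        row["cv_accuracy"] = cv["mean_score"] if cv else np.nan
        row["fit_seconds"] = round(time.time() - t0, 1)
        rows.append(row)
        print(f"{name:5s} acc={rep.accuracy:.3f} sens={rep.sensitivity:.3f} "
              f"spec={rep.specificity:.3f} ({row['fit_seconds']}s)")

    df = pd.DataFrame(rows).sort_values("accuracy", ascending=False,
                                        kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.to_csv(RESULTS / "05_model_reports.csv", index=False)
    print("\n", df[["rank", "model", "accuracy", "sensitivity",
                    "specificity"]].to_string(index=False))


if __name__ == "__main__":
    main()
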