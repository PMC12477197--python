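"""Dimensionality-reduction views of the preprocessed cohort.

t-SNE (on a fixed random subsample — quadratic cost), LDA topics, and
OPLS-DA, each summarized by how well k-means on the 2-D coordinates
agrees with the outcome groups (adjusted Rand index).
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from ramanembryo.embed import embeddings_to_frame, lada_embed, oplsda_fit, tsne_embed

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    import importlib
    peaks_mod = importlib.import_module("03_peak_patterns")
    samples = peaks_mod.processed_cohort()
    from ramanembryo.datatypes import dataset_to_matrix
    X, y, _ = dataset_to_matrix(samples)

    rng = np.random.default_rng(SEED)
    sub = rng.choice(len(X), size=min(1500, len(X)), replace=False)

    results = []
    results.append(tsne_embed(X[sub], y[sub], perplexity=30, seed=SEED))
    _, opls = oplsda_fit(X, y)
    results.append(opls)
    results.append(lada_embed(np.clip(X, 0, None), y, n_topics=3, seed=SEED))

    RESULTS.mkdir(exist_ok=True)
    # coordinates are exported for a small shared subsample only (keeps
    # the artifact small); summaries below use every embedded spectrum
    keep = sub[:500]
    keep_ts = np.arange(min(500, len(sub)))
    export = [type(results[0])(results[0].method,
                               results[0].coordinates[keep_ts], y[keep],
                               {}),
              type(results[1])(results[1].method,
                               results[1].coordinates[keep], y[keep], {}),
              type(results[2])(results[2].method,
                               results[2].coordinates[keep], y[keep], {})]
    embeddings_to_frame(export).to_csv(RESULTS / "04_embeddings.csv", index=False)

    rows = []
    for r in results:
        km = KMeans(n_clusters=3, n_init=10, random_state=SEED
                    ).fit_predict(r.coordinates)
        ari = adjusted_rand_score(r.labels, km)
        rows.append({"method": r.method, "n_spectra": len(r.labels),
                     "kmeans_ari": round(ari, 3),
                     **{k: round(v, 3) for k, v in r.diagnostics.items()
                        if isinstance(v, float)}})
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "04_embedding_summary.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
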