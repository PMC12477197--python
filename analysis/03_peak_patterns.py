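"""Core-peak statistics across groups and recovery of the encoded patterns.

Per-sample mean peak intensities (independent observations) feed pairwise
Mann-Whitney tests and the rule-based pattern classifier. The table is
compared against the patterns the generator encoded: the two single-pair
peaks (506, 2874) are expected to resolve to their full orderings at
cohort-level power.
"""

from pathlib import Path

import numpy as np

from ramanembryo.datatypes import RamanSpectrum, SampleRecord
from ramanembryo.peaks import build_peak_stats
from ramanembryo.preprocess import PreprocessConfig, preprocess_dataset
from ramanembryo.synth import (DEFAULT_PEAK_TABLE, GeneratorConfig, make_grid,
                               default_peak_templates, generate_dataset)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 0


def processed_cohort() -> list[SampleRecord]:
    cache = SCRATCH / "processed_cohort.npz"
    if cache.exists():
        data = np.load(cache)
        grid = make_grid()
        records: dict[str, SampleRecord] = {}
        for row, g, sid in zip(data["X"], data["y"].astype(str),
                               data["sids"].astype(str)):
            rec = records.setdefault(sid, SampleRecord(sid, g, "", []))
            rec.spectra.append(RamanSpectrum(grid, row))
        return list(records.values())
    cohort = generate_dataset(GeneratorConfig(seed=SEED), default_peak_templates())
    processed, _ = preprocess_dataset(cohort, PreprocessConfig())
    return processed


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    samples = processed_cohort()
    positions = [p for p, *_ in DEFAULT_PEAK_TABLE]
    encoded = {float(p): pat for p, _, _, pat in DEFAULT_PEAK_TABLE}

    stats = build_peak_stats(samples, positions, units="sample")
    stats["encoded"] = [encoded[float(p)] for p in stats["position"]]
    stats["recovered"] = stats["pattern"] == stats["encoded"]
    stats.to_csv(RESULTS / "03_peak_stats.csv", index=False)

    n_ok = int(stats["recovered"].sum())
    print(stats[["position", "encoded", "pattern", "recovered"]].to_string(index=False))
    print(f"\nrecovered {n_ok}/18 encoded patterns "
          f"(>=16 expected; 506 and 2874 resolve to full orderings)")


if __name__ == "__main__":
    main()
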