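"""Synthetic Raman spectra of spent Day 3 embryo-culture medium.

The study's raw spectra are not deposited, so every downstream stage is
exercised on generated data with the statistical structure the analysis
assumes: 18 core peaks at the reported positions, per-peak group-mean
orderings matching the reported intensity patterns, 30-40 replicate
spectra per sample, cohort sizes 58/25/89 for outcome groups A/B/C,
smooth baseline drift, additive shot noise, and sparse cosmic-ray spikes.

Peaks are Gaussian. Amplitudes are hierarchical-lognormal: one lognormal
random effect per (sample, peak) shared by all replicates of the sample,
times an independent per-replicate lognormal factor. This makes replicate
predictions within a sample positively correlated, which is what makes
per-sample mode voting worth testing.

Group-mean encodings use a single relative-gap knob ``separability``:
adjacent groups in a pattern differ by a factor ``1 +/- d/2`` around the
peak's base amplitude (d = 0.2 * separability by default). "approximately
equal" groups get exactly equal means, so any downstream significance on
such a pair is a type-I error by construction.

Base amplitudes are chosen so that the three groups have *identical total
spectral area*: area normalization to a fixed total then rescales all
groups identically and cannot manufacture spurious between-group
differences at equal-mean peaks. The amplitude table was solved once as
the minimum relative deviation from a hand-picked set subject to the
three zero-imbalance constraints.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import GROUPS, RamanSpectrum, SampleRecord

DEFAULT_GRID = (300.0, 3400.0, 1.0)

#: (position cm^-1, Gaussian sigma cm^-1, base amplitude, pattern)
#: Patterns follow the reported per-peak group orderings; "~" means equal
#: means by construction. 898 is included to reach the stated 18 peaks.
DEFAULT_PEAK_TABLE = [
    (506,  7, 0.486, "B>A"),
    (620,  6, 0.330, "B<A<C"),
    (642,  6, 0.150, "A~B<C"),
    (662,  6, 0.150, "A~B<C"),
    (750,  7, 1.093, "A>B>C"),
    (850,  7, 0.351, "B<A<C"),
    (898,  6, 0.260, "A>B~C"),
    (938,  6, 0.758, "A>B>C"),
    (1000, 5, 0.150, "A~B<C"),
    (1030, 6, 0.150, "A~B<C"),
    (1120, 8, 0.500, "A~B~C"),
    (1202, 7, 0.287, "A<B<C"),
    (1332, 8, 0.179, "A>B~C"),
    (1446, 9, 0.150, "A>B~C"),
    (1605, 9, 0.865, "A~C>B"),
    (1654, 10, 0.800, "A~B~C"),
    (2874, 12, 0.383, "C>B"),
    (2926, 12, 1.069, "A<C<B"),
]


def _pattern_multipliers(pattern: str, d: float) -> dict[str, float]:
    """Group-mean multipliers (around 1) realizing a peak-intensity pattern.

    Full orderings place the groups at 1-d, 1, 1+d; two-equal patterns put
    the equal pair at 1-d/2 and the singleton at 1+d/2 (gap d); single-pair
    patterns put the pair endpoints at 1 -/+ d/2 and the third group exactly
    between them.
    """
    half = d / 2.0
    table = {
        "A>B>C": {"A": 1 + d, "B": 1.0, "C": 1 - d},
        "A<B<C": {"A": 1 - d, "B": 1.0, "C": 1 + d},
        "B<A<C": {"A": 1.0, "B": 1 - d, "C": 1 + d},
        "A<C<B": {"A": 1 - d, "B": 1 + d, "C": 1.0},
        "A~B<C": {"A": 1 - half, "B": 1 - half, "C": 1 + half},
        "A>B~C": {"A": 1 + half, "B": 1 - half, "C": 1 - half},
        "A~C>B": {"A": 1 + half, "B": 1 - half, "C": 1 + half},
        "B>A":   {"A": 1 - half, "B": 1 + half, "C": 1.0},
        "C>B":   {"A": 1.0, "B": 1 - half, "C": 1 + half},
        "A~B~C": {"A": 1.0, "B": 1.0, "C": 1.0},
    }
    if pattern not in table:
        raise ValueError(f"unknown pattern {pattern!r}")
    return table[pattern]


@dataclass
class PeakTemplate:
    """One Gaussian peak: position/width plus per-group mean amplitudes."""

    position: float
    width: float
    group_means: dict[str, float]
    amplitude_cv: float = 0.10
    pattern: str = ""

    def __post_init__(self) -> None:
        if not (300.0 <= self.position <= 3400.0):
            raise ValueError(f"position {self.position} outside [300, 3400]")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if any(v < 0 for v in self.group_means.values()):
            raise ValueError("group_means must be non-negative")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((grid - self.position) / self.width) ** 2)


def default_peak_templates(separability: float = 1.0,
                           amplitude_cv: float = 0.10) -> list[PeakTemplate]:
    """The 18 core-peak templates with the reported group-intensity patterns.

    ``separability`` scales the relative gap between adjacent group means
    (1.0 -> 20% between adjacent groups); 0 collapses all patterns to
    equal means.
    """
    d = 0.2 * separability
    out = []
    for pos, sigma, amp, pattern in DEFAULT_PEAK_TABLE:
        mult = _pattern_multipliers(pattern, d)
        out.append(PeakTemplate(
            position=float(pos), width=float(sigma),
            group_means={g: amp * mult[g] for g in GROUPS},
            amplitude_cv=amplitude_cv, pattern=pattern,
        ))
    return out


@dataclass
class BaselineConfig:
    """Smooth background: quadratic drift plus one broad Gaussian hump."""

    poly: tuple[float, float, float] = (2.0, 1.0, -0.5)
    hump_amplitude: float = 2.0
    hump_center: float = 1400.0
    hump_sigma: float = 500.0
    jitter: float = 0.1  # relative per-spectrum variation of each coefficient

    def curve(self, grid: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        t = (grid - grid[0]) / max(grid[-1] - grid[0], 1.0)
        coefs = np.array([*self.poly, self.hump_amplitude], dtype=float)
        if rng is not None and self.jitter > 0:
            coefs = coefs * (1.0 + self.jitter * rng.standard_normal(4))
        c0, c1, c2, ah = coefs
        hump = ah * np.exp(-0.5 * ((grid - self.hump_center) / self.hump_sigma) ** 2)
        return c0 + c1 * t + c2 * t ** 2 + hump


@dataclass
class GeneratorConfig:
    group_sizes: tuple[int, int, int] = (58, 25, 89)
    spectra_per_sample: tuple[int, int] = (30, 40)
    noise_sd: float = 0.02
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    spike_rate: float = 0.3
    spike_amplitude: float = 8.0
    grid: tuple[float, float, float] = DEFAULT_GRID
    sample_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 1 for n in self.group_sizes):
            raise ValueError("group_sizes: need three counts, all >= 1")
        lo, hi = self.spectra_per_sample
        if lo < 1 or lo > hi:
            raise ValueError("spectra_per_sample: need 1 <= min <= max")
        start, stop, step = self.grid
        if step <= 0:
            raise ValueError("grid: step must be > 0")
        if start >= stop:
            raise ValueError("grid: start must be < stop")
        for name in ("noise_sd", "spike_rate", "spike_amplitude", "sample_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be non-negative")

    def grid_array(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)


def make_grid(grid: tuple[float, float, float] = DEFAULT_GRID) -> np.ndarray:
    start, stop, step = grid
    return start + step * np.arange(int(round((stop - start) / step)) + 1)


def noiseless_mean_spectrum(templates: list[PeakTemplate], group: str,
                            grid: np.ndarray | None = None) -> RamanSpectrum:
    """Baseline-free, noise-free sum of group-mean peak profiles.

    The analytic oracle for peak-recovery tests: its strict local maxima
    are the template positions (when peaks are resolved on the grid).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if grid is None:
        grid = make_grid()
    y = np.zeros_like(grid, dtype=float)
    for t in templates:
        y += t.group_means[group] * t.profile(grid)
    return RamanSpectrum(grid, y, meta={"group": group, "kind": "noiseless_mean"})


def generate_dataset(config: GeneratorConfig,
                     templates: list[PeakTemplate]) -> list[SampleRecord]:
    """Draw a labelled synthetic cohort.

    Deterministic for a fixed ``config.seed``: a master ``SeedSequence`` is
    spawned into one child per sample, and each sample spawns separate
    substreams for amplitudes, baseline, noise and spikes -- so switching
    spikes off reproduces the identical underlying spectra (spike-free
    truth for despiking tests).
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    grid = config.grid_array()
    profiles = np.vstack([t.profile(grid) for t in templates])  # (K, n)
    lo, hi = config.spectra_per_sample

    n_total = sum(config.group_sizes)
    master = np.random.SeedSequence(config.seed)
    sample_seeds = master.spawn(n_total)

    samples: list[SampleRecord] = []
    idx = 0
    for group, n_group in zip(GROUPS, config.group_sizes):
        for j in range(n_group):
            ss = sample_seeds[idx]
            ss_amp, ss_base, ss_noise, ss_spike = ss.spawn(4)
            rng_amp = np.random.default_rng(ss_amp)
            rng_base = np.random.default_rng(ss_base)
            rng_noise = np.random.default_rng(ss_noise)
            rng_spike = np.random.default_rng(ss_spike)

            n_spec = int(rng_amp.integers(lo, hi + 1))
            # per-(sample, peak) lognormal random effect shared by replicates
            sample_fx = np.exp(config.sample_cv * rng_amp.standard_normal(len(templates)))
            means = np.array([t.group_means[group] for t in templates])
            cvs = np.array([t.amplitude_cv for t in templates])

            sample_id = f"{group}{j:03d}"
            grade = "I-II" if rng_amp.random() < 0.5 else "III"
            spectra = []
            for r in range(n_spec):
                rep_fx = np.exp(cvs * rng_amp.standard_normal(len(templates)))
                amps = means * sample_fx * rep_fx
                signal = amps @ profiles
                base = config.baseline.curve(grid, rng_base)
                y = signal + base + config.noise_sd * rng_noise.standard_normal(len(grid))
                n_spikes = rng_spike.poisson(config.spike_rate)
                for _ in range(n_spikes):
                    pos = int(rng_spike.integers(0, len(grid)))
                    width = int(rng_spike.integers(1, 3))  # 1-2 points
                    boost = config.spike_amplitude * (1.0 + abs(signal[pos] + base[pos]))
                    boost *= rng_spike.uniform(0.5, 1.5)
                    y[pos:pos + width] += boost
                spectra.append(RamanSpectrum(
                    grid.copy(), y,
                    meta={"sample_id": sample_id, "group": group,
                          "site": r // 5, "replicate": r},
                ))
            samples.append(SampleRecord(sample_id, group, grade, spectra))
            idx += 1
    return samples


def write_dataset(samples: list[SampleRecord], outdir: str | Path) -> Path:
    """Write one two-column CSV per spectrum plus a manifest table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group", "grade", "path"])
        for rec in samples:
            for i, s in enumerate(rec.spectra):
                rel = f"{rec.sample_id}_{i:02d}.csv"
                np.savetxt(outdir / rel,
                           np.column_stack([s.wavenumbers, s.intensities]),
                           delimiter=",", fmt="%.9g")
                w.writerow([rec.sample_id, rec.group, rec.grade, rel])
    return manifest_path


def write_long_csv(samples: list[SampleRecord], path: str | Path) -> Path:
    """Single long-format CSV: sample_id, group, replicate, wavenumber, intensity."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group", "replicate", "wavenumber", "intensity"])
        for rec in samples:
            for i, s in enumerate(rec.spectra):
                for wn, it in zip(s.wavenumbers, s.intensities):
                    w.writerow([rec.sample_id, rec.group, i, f"{wn:.9g}", f"{it:.9g}"])
    return path
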