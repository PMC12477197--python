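"""Core containers for Raman spectra of spent embryo-culture medium.

A *sample* is the spent culture-medium droplet of one Day 3 embryo; each
sample is measured repeatedly (30-40 replicate acquisitions at several
sites on the air-dried drop), giving a set of :class:`RamanSpectrum`
replicates that share one extended-culture outcome label:

* ``A`` - morphologically good blastocyst,
* ``B`` - morphologically non-good blastocyst,
* ``C`` - clinically non-useful embryo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("A", "B", "C")


@dataclass
class RamanSpectrum:
    """One replicate acquisition: intensity vs Raman shift (cm^-1).

    ``wavenumbers`` must be strictly increasing and the same length as
    ``intensities``; both are stored as float arrays. ``meta`` carries
    provenance (sample id, site index, replicate index, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavenumbers) > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def copy_with(self, intensities: np.ndarray | None = None,
                  wavenumbers: np.ndarray | None = None) -> "RamanSpectrum":
        return RamanSpectrum(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=self.intensities if intensities is None else intensities,
            meta=dict(self.meta),
        )


@dataclass
class SampleRecord:
    """One embryo's spent-medium sample: outcome label, Day 3 grade, replicates."""

    sample_id: str
    group: str
    grade: str
    spectra: list[RamanSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)


def dataset_to_matrix(samples: list[SampleRecord]):
    """Stack every spectrum of a dataset into (X, y, sample_ids).

    All spectra must share a common grid. Returns the intensity matrix
    (n_spectra x n_wavenumbers), the per-spectrum group labels and the
    per-spectrum parent sample ids (for leakage-free sample-level splits).
    """
    rows, y, ids = [], [], []
    grid = None
    for rec in samples:
        for s in rec.spectra:
            if grid is None:
                grid = s.wavenumbers
            elif len(s.wavenumbers) != len(grid) or not np.allclose(s.wavenumbers, grid):
                raise ValueError(
                    f"sample {rec.sample_id}: spectra are not on a common grid; "
                    "run preprocessing (truncate/resample) first"
                )
            rows.append(s.intensities)
            y.append(rec.group)
            ids.append(rec.sample_id)
    if not rows:
        raise ValueError("empty dataset")
    return np.vstack(rows), np.asarray(y), np.asarray(ids)
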