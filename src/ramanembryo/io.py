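"""Spectrum and manifest readers/writers.

Supported spectrum formats: two-column CSV/TSV (wavenumber, intensity)
and a minimal JCAMP-DX subset (``##XYDATA=(X++(Y..Y))`` with
FIRSTX/DELTAX/XFACTOR/YFACTOR, and ``##XYPOINTS=(XY..XY)``). Proprietary
instrument formats are out of scope. Spectra with descending grids are
sorted ascending with a warning.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import RamanSpectrum, SampleRecord

logger = logging.getLogger(__name__)


def _finalize(wn: np.ndarray, inten: np.ndarray, path) -> RamanSpectrum:
    if len(wn) and np.all(np.diff(wn) < 0):
        logger.warning("%s: descending wavenumbers; sorting ascending", path)
        wn, inten = wn[::-1], inten[::-1]
    order = np.argsort(wn)
    if not np.array_equal(order, np.arange(len(wn))):
        wn, inten = wn[order], inten[order]
    return RamanSpectrum(wn, inten, meta={"path": str(path)})


def _read_columns(path: Path, delimiter: str | None) -> RamanSpectrum:
    wn, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = delimiter
            if sep is None:
                sep = "\t" if "\t" in line else ","
            parts = [p for p in re.split(rf"[{sep}\s]+" if sep == "\t"
                                         else re.escape(sep), line) if p]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: non-numeric cell in {line!r}") from exc
            wn.append(x)
            inten.append(y)
    if not wn:
        raise ValueError(f"{path}: no data rows")
    return _finalize(np.asarray(wn), np.asarray(inten), path)


def _read_jcamp(path: Path) -> RamanSpectrum:
    headers: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # "xydata" | "xypoints"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XYDATA":
                    mode = "xydata"
                elif key == "XYPOINTS":
                    mode = "xypoints"
                elif key == "END":
                    break
                else:
                    headers[key] = val
                continue
            if mode:
                data_lines.append((lineno, line))

    if mode is None:
        raise ValueError(f"{path}: no ##XYDATA or ##XYPOINTS block")
    xf = float(headers.get("XFACTOR", 1.0))
    yf = float(headers.get("YFACTOR", 1.0))

    if mode == "xypoints":
        wn, inten = [], []
        for lineno, line in data_lines:
            for pair in re.split(r"[;\s]+", line):
                if not pair:
                    continue
                try:
                    x, y = pair.split(",")
                    wn.append(float(x) * xf)
                    inten.append(float(y) * yf)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad XY pair {pair!r}") from exc
        return _finalize(np.asarray(wn), np.asarray(inten), path)

    # XYDATA=(X++(Y..Y)): each line starts with its x, followed by y values
    firstx = float(headers["FIRSTX"]) if "FIRSTX" in headers else None
    deltax = float(headers["DELTAX"]) if "DELTAX" in headers else None
    wn, inten = [], []
    for lineno, line in data_lines:
        vals = [v for v in re.split(r"[,\s]+", line) if v]
        try:
            nums = [float(v) for v in vals]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value in XYDATA") from exc
        if len(nums) < 2:
            raise ValueError(f"{path}:{lineno}: XYDATA line needs x plus y values")
        x0 = nums[0] * xf
        ys = nums[1:]
        if deltax is None:
            if "LASTX" in headers and "NPOINTS" in headers:
                npts = int(float(headers["NPOINTS"]))
                lastx = float(headers["LASTX"])
                deltax = (lastx - (firstx if firstx is not None else x0)) / max(npts - 1, 1)
            else:
                raise ValueError(f"{path}: DELTAX (or LASTX+NPOINTS) required for XYDATA")
        for k, yv in enumerate(ys):
            wn.append(x0 + k * deltax * xf)
            inten.append(yv * yf)
    return _finalize(np.asarray(wn), np.asarray(inten), path)


def read_spectrum(path: str | Path, format: str | None = None) -> RamanSpectrum:
    """Read one spectrum; format inferred from the suffix when omitted."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "csv",
                  ".jdx": "jcamp", ".dx": "jcamp"}.get(suffix)
        if format is None:
            raise ValueError(f"{path}: cannot infer format from suffix {suffix!r}")
    if format == "csv":
        return _read_columns(path, ",")
    if format == "tsv":
        return _read_columns(path, "\t")
    if format == "jcamp":
        return _read_jcamp(path)
    raise ValueError(f"unsupported format {format!r} (csv, tsv, jcamp)")


def write_spectrum(s: RamanSpectrum, path: str | Path,
                   format: str | None = None) -> Path:
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx") else "csv"
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        np.savetxt(path, np.column_stack([s.wavenumbers, s.intensities]),
                   delimiter=sep, fmt="%.12g")
    elif format == "jcamp":
        with open(path, "w") as fh:
            fh.write("##TITLE=Raman spectrum\n##JCAMP-DX=4.24\n")
            fh.write("##DATATYPE=RAMAN SPECTRUM\n##XUNITS=1/CM\n##YUNITS=ARBITRARY\n")
            fh.write("##XFACTOR=1\n##YFACTOR=1\n")
            fh.write(f"##FIRSTX={s.wavenumbers[0]:.12g}\n")
            fh.write(f"##LASTX={s.wavenumbers[-1]:.12g}\n")
            fh.write(f"##NPOINTS={len(s)}\n")
            fh.write("##XYPOINTS=(XY..XY)\n")
            for x, y in zip(s.wavenumbers, s.intensities):
                fh.write(f"{x:.12g},{y:.12g}\n")
            fh.write("##END=\n")
    else:
        raise ValueError(f"unsupported format {format!r}")
    return path


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Load a dataset from a manifest CSV (sample_id, group, grade, path).

    Spectrum paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"sample_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    records: dict[str, SampleRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        spath = path.parent / str(row["path"])
        if not spath.exists():
            raise FileNotFoundError(f"manifest references missing file {spath}")
        s = read_spectrum(spath)
        s.meta.update({"sample_id": sid, "group": row["group"]})
        if sid not in records:
            records[sid] = SampleRecord(sid, str(row["group"]),
                                        str(row.get("grade", "")), [])
        records[sid].spectra.append(s)
    return list(records.values())
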