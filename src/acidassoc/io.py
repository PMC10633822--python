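"""Plain-text file formats: umbrella windows, PMF tables, CSV tables.

Umbrella windows use the de facto interchange layout: one two-column file
per window (time ps, coordinate A) plus a metadata file whose lines read
``path center spring_constant`` with the spring in kcal/(mol A^2).  PMF
profiles are three-column text (r, W, W_error) with a unit-bearing header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_umbrella import UmbrellaDataset, UmbrellaWindow
from .wham import PMFProfile

__all__ = [
    "TableFormatError",
    "write_windows",
    "read_windows",
    "write_pmf_table",
    "read_pmf_table",
    "write_table",
    "read_table",
]


class TableFormatError(ValueError):
    """A tabular file does not match the expected schema."""


def write_windows(dataset: UmbrellaDataset, directory: str | Path,
                  metadata_name: str = "metadata.dat") -> Path:
    """Write one time-series file per window plus the metadata file.

    Returns the metadata file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_lines = []
    for i, w in enumerate(dataset.windows):
        name = f"window_{i:03d}.dat"
        t = np.arange(len(w.samples)) * w.sample_interval
        np.savetxt(
            directory / name,
            np.column_stack([t, w.samples]),
            fmt="%.4f %.6f",
            header="time_ps coordinate_A",
        )
        meta_lines.append(f"{name} {w.center:.6g} {w.spring_constant:.6g}")
    meta = directory / metadata_name
    meta.write_text(
        "# path center_A spring_kcal_per_mol_A2\n" + "\n".join(meta_lines) + "\n"
    )
    return meta


def read_windows(metadata_path: str | Path, temperature: float) -> UmbrellaDataset:
    """Read a window set from its metadata file; paths are relative to it."""
    metadata_path = Path(metadata_path)
    base = metadata_path.parent
    windows = []
    for ln, line in enumerate(metadata_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise TableFormatError(
                f"{metadata_path}:{ln}: expected 'path center spring', got {line!r}"
            )
        path, center, spring = parts[0], float(parts[1]), float(parts[2])
        data = np.loadtxt(base / path)
        if data.ndim != 2 or data.shape[1] != 2:
            raise TableFormatError(f"{base / path}: expected two columns (time, coordinate)")
        dt = float(data[1, 0] - data[0, 0]) if len(data) > 1 else 0.1
        windows.append(
            UmbrellaWindow(
                center=center,
                spring_constant=spring,
                temperature=temperature,
                samples=data[:, 1],
                sample_interval=dt,
            )
        )
    if not windows:
        raise TableFormatError(f"{metadata_path}: no windows listed")
    return UmbrellaDataset(windows=tuple(windows), temperature=temperature)


def write_pmf_table(pmf: PMFProfile, path: str | Path) -> Path:
    """Three-column plain text: r (A), W (kJ/mol), W_error (kJ/mol)."""
    path = Path(path)
    err = pmf.W_error if pmf.W_error is not None else np.full_like(pmf.W, np.nan)
    header = (
        f"r_A W_kJ_per_mol W_error_kJ_per_mol\n"
        f"temperature_K = {pmf.temperature}\n"
        f"zero_region_A = {pmf.zero_region[0]} {pmf.zero_region[1]}"
    )
    np.savetxt(path, np.column_stack([pmf.bin_centers, pmf.W, err]),
               fmt="%.6g", header=header)
    return path


def read_pmf_table(path: str | Path, temperature: float | None = None,
                   zero_region: tuple[float, float] | None = None) -> PMFProfile:
    """Read a PMF table written by :func:`write_pmf_table` (or compatible)."""
    path = Path(path)
    temp, zr = temperature, zero_region
    for line in path.read_text().splitlines():
        if line.startswith("#") and "temperature_K" in line and temp is None:
            temp = float(line.split("=")[1])
        if line.startswith("#") and "zero_region_A" in line and zr is None:
            lo, hi = line.split("=")[1].split()
            zr = (float(lo), float(hi))
    if temp is None:
        raise TableFormatError(f"{path}: temperature not in header and not given")
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise TableFormatError(f"{path}: expected columns r, W[, W_error]")
    err = data[:, 2] if data.shape[1] > 2 else None
    if zr is None:
        zr = (10.0, float(data[-1, 0]))
    return PMFProfile(
        bin_centers=data[:, 0], W=data[:, 1], temperature=temp,
        zero_region=zr, W_error=err,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with a header row; numeric cells only."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a CSV table, mapping columns by header name.

    ``schema`` maps required column names to types (float/int/str).  Missing
    columns and non-numeric cells are reported with their line and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise TableFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if schema is None:
        return df
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    out = pd.DataFrame()
    for col, typ in schema.items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise TableFormatError(
                    f"{path}: non-numeric value {df[col][row]!r} in column "
                    f"'{col}', line {row + 2}"  # +1 header, +1 one-based
                )
            out[col] = coerced.astype(typ)
        else:
            out[col] = df[col]
    return out
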