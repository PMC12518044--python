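"""Absorbance spectra: container, resampling, and CSV round-trips.

A :class:`Spectrum` is one absorbance-vs-wavelength record, optionally
timestamped (seconds since the start of an experiment).  Time-resolved
experiments are exchanged as *wide* CSV (first column ``wavelength_nm``,
one column per time point named ``t<seconds>``) or *long* CSV
(``time_s,wavelength_nm,absorbance``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "Spectrum",
    "resample",
    "read_spectra_csv",
    "write_spectra_csv",
    "validate_spectra_file",
]


@dataclass(frozen=True)
class Spectrum:
    """One absorbance record A(lambda).

    Parameters
    ----------
    wavelength_nm : array
        Strictly increasing wavelength grid in nanometres.
    absorbance : array
        Absorbance (AU) on the same grid; must be finite.
    time_s : float, optional
        Seconds since experiment start.
    path_length_cm : float
        Optical path length, default 1 cm.
    """

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    time_s: float | None = None
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise InvalidInputError(
                f"wavelength ({wl.shape}) and absorbance ({ab.shape}) must be "
                "1-D arrays of equal length"
            )
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ab)):
            raise InvalidInputError("wavelengths and absorbances must be finite")
        if self.path_length_cm <= 0:
            raise InvalidInputError("path_length_cm must be positive")

    def __len__(self) -> int:
        return self.wavelength_nm.size

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavelengths in [lo, hi] nm (inclusive)."""
        m = (self.wavelength_nm >= lo) & (self.wavelength_nm <= hi)
        if not np.any(m):
            raise InvalidInputError(f"window [{lo}, {hi}] nm contains no points")
        return replace(self, wavelength_nm=self.wavelength_nm[m],
                       absorbance=self.absorbance[m])


def resample(spec: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid.

    The grid must lie within the spectrum's extent (no extrapolation);
    values at shared grid points are unchanged.
    """
    grid = np.asarray(grid, dtype=float)
    wl = spec.wavelength_nm
    if grid.min() < wl[0] or grid.max() > wl[-1]:
        raise InvalidInputError(
            f"requested grid [{grid.min()}, {grid.max()}] nm extends beyond the "
            f"recorded range [{wl[0]}, {wl[-1]}] nm"
        )
    ab = np.interp(grid, wl, spec.absorbance)
    return replace(spec, wavelength_nm=grid, absorbance=ab)


_TIME_COL = re.compile(r"^t(\d+(\.\d*)?)$")


def read_spectra_csv(path: str | Path, path_length_cm: float = 1.0) -> list[Spectrum]:
    """Read a wide or long spectra CSV into time-ordered spectra."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:1] == ["wavelength_nm"]:
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        out = []
        for c in cols[1:]:
            m = _TIME_COL.match(str(c))
            if m is None:
                raise InvalidInputError(
                    f"column {c!r}: time columns must be named t<seconds>"
                )
            out.append(Spectrum(wl, df[c].to_numpy(dtype=float),
                                time_s=float(m.group(1)),
                                path_length_cm=path_length_cm))
        out.sort(key=lambda s: s.time_s)
        return out
    if set(cols) >= {"time_s", "wavelength_nm", "absorbance"}:
        out = []
        for t, grp in df.groupby("time_s"):
            grp = grp.sort_values("wavelength_nm")
            out.append(Spectrum(grp["wavelength_nm"].to_numpy(dtype=float),
                                grp["absorbance"].to_numpy(dtype=float),
                                time_s=float(t), path_length_cm=path_length_cm))
        out.sort(key=lambda s: s.time_s)
        return out
    raise InvalidInputError(
        "unrecognized spectra CSV: expected wide format (wavelength_nm,t0.0,...) "
        "or long format (time_s,wavelength_nm,absorbance)"
    )


def write_spectra_csv(spectra: list[Spectrum], path: str | Path) -> None:
    """Write time-ordered spectra as wide CSV (shared grid required)."""
    if not spectra:
        raise InvalidInputError("no spectra to write")
    wl = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelength_nm, wl):
            raise InvalidInputError("wide CSV output requires a shared wavelength grid")
    data = {"wavelength_nm": wl}
    for s in spectra:
        t = 0.0 if s.time_s is None else s.time_s
        data[f"t{t:g}"] = s.absorbance
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class FileValidationReport:
    path: str
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_spectra_file(path: str | Path) -> FileValidationReport:
    """Validate a spectra CSV without raising.

    Checks: parseable, numeric cells, monotone wavelength, consistent
    column lengths.  Returns a structured report listing every problem
    found (empty list means the file is well formed).
    """
    report = FileValidationReport(path=str(path))
    p = Path(path)
    if not p.exists():
        report.errors.append("file does not exist")
        return report
    try:
        df = pd.read_csv(p)
    except Exception as exc:  # malformed CSV
        report.errors.append(f"cannot parse CSV: {exc}")
        return report
    if df.empty:
        report.errors.append("file contains no rows")
        return report
    if "wavelength_nm" not in df.columns and not (
        {"time_s", "wavelength_nm", "absorbance"} <= set(df.columns)
    ):
        report.errors.append("missing wavelength_nm column")
        return report
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        for row in df.index[bad]:
            report.errors.append(
                f"non-numeric value {df.at[row, col]!r} at row {row}, column {col!r}"
            )
    if "wavelength_nm" in df.columns and "time_s" not in df.columns:
        wl = pd.to_numeric(df["wavelength_nm"], errors="coerce").to_numpy()
        if np.all(np.isfinite(wl)) and not np.all(np.diff(wl) > 0):
            report.errors.append("wavelength_nm is not strictly increasing")
    if df.isna().any().any():
        report.errors.append("file contains missing cells")
    return report
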