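"""Calibrated single-species reference spectra.

The unmixing step needs one molar-absorptivity curve per species —
free protochlorophyllide (S, Q-band peak 651 nm), the Pchlide:BchNB
enzyme–substrate complex (ES, 633 nm) and chlorophyllide (P, 670 nm).
Raw reference spectra recorded at known concentrations are spline
smoothed, converted to epsilon via Beer–Lambert, resampled onto a
common grid, and the ES curve may be rescaled by a conservation
argument: free + bound Pchlide must stay constant in a binding-only
experiment, which pins the otherwise poorly known ES extinction
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize_scalar

from .errors import CalibrationError, InvalidInputError
from .spectra import Spectrum, resample

__all__ = [
    "SmoothingConfig",
    "ReferenceSpectrum",
    "ReferenceSet",
    "smooth_reference",
    "to_epsilon",
    "calibrate_es_epsilon",
    "read_reference_csv",
    "write_reference_set",
    "read_reference_set",
]

SPECIES = ("S", "ES", "P")

#: default analysis window (nm): the red Q-band region, which is less
#: affected by scattering from precipitated components than the Soret region
DEFAULT_WINDOW = (600.0, 700.0)


@dataclass(frozen=True)
class SmoothingConfig:
    """Cubic smoothing-spline settings.

    ``lam`` is the roughness penalty passed to
    :func:`scipy.interpolate.make_smoothing_spline`; ``None`` selects it
    by generalized cross-validation.  ``lam = 0`` disables smoothing and
    returns the input unchanged.
    """

    lam: float | None = None

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise InvalidInputError("smoothing parameter must be >= 0")


def smooth_reference(raw: Spectrum, smoothing: SmoothingConfig | float | None = None
                     ) -> Spectrum:
    """Spline-smooth a raw reference spectrum.

    Accepts a :class:`SmoothingConfig`, a bare smoothing parameter, or
    ``None`` (GCV default).  Needs at least 20 points; a smoothing
    parameter of exactly 0 is the identity.
    """
    if not isinstance(smoothing, SmoothingConfig):
        smoothing = SmoothingConfig(lam=smoothing)
    if len(raw) < 20:
        raise InvalidInputError(
            f"need >= 20 points to smooth a reference, got {len(raw)}"
        )
    if smoothing.lam == 0:
        return raw
    spl = make_smoothing_spline(raw.wavelength_nm, raw.absorbance,
                                lam=smoothing.lam)
    return replace(raw, absorbance=spl(raw.wavelength_nm))


def to_epsilon(ref_raw: Spectrum, concentration_uM: float,
               path_length_cm: float | None = None) -> np.ndarray:
    """Beer–Lambert conversion A(lambda) -> epsilon(lambda) in mM^-1 cm^-1.

    ``epsilon = A / (c[mM] * l)``; concentration is given in uM.
    """
    if concentration_uM <= 0:
        raise InvalidInputError("reference concentration must be positive")
    l = ref_raw.path_length_cm if path_length_cm is None else path_length_cm
    if l <= 0:
        raise InvalidInputError("path length must be positive")
    c_mM = concentration_uM * 1e-3
    return ref_raw.absorbance / (c_mM * l)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """A single-species reference: raw record, known concentration, and
    the derived (smoothed) molar-absorptivity curve on the raw grid."""

    species: str
    raw: Spectrum
    concentration_uM: float
    epsilon_curve: np.ndarray  # mM^-1 cm^-1, on raw.wavelength_nm

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidInputError(f"species must be one of {SPECIES}")
        if self.concentration_uM <= 0:
            raise InvalidInputError("concentration must be positive")
        eps = np.asarray(self.epsilon_curve, dtype=float)
        object.__setattr__(self, "epsilon_curve", eps)
        if eps.size != len(self.raw) or not np.all(np.isfinite(eps)):
            raise InvalidInputError("epsilon curve must be finite on the raw grid")

    @classmethod
    def from_raw(cls, species: str, raw: Spectrum, concentration_uM: float,
                 smoothing: SmoothingConfig | float | None = None
                 ) -> "ReferenceSpectrum":
        smoothed = smooth_reference(raw, smoothing)
        eps = to_epsilon(smoothed, concentration_uM)
        return cls(species, raw, concentration_uM, eps)

    def peak(self, window: tuple[float, float] = DEFAULT_WINDOW
             ) -> tuple[float, float]:
        """(peak wavelength nm, peak epsilon) within the analysis window."""
        wl = self.raw.wavelength_nm
        m = (wl >= window[0]) & (wl <= window[1])
        if not np.any(m):
            raise InvalidInputError("analysis window contains no points")
        i = np.argmax(self.epsilon_curve[m])
        return float(wl[m][i]), float(self.epsilon_curve[m][i])


@dataclass(frozen=True)
class ReferenceSet:
    """The three calibrated epsilon curves on one common grid."""

    common_grid: np.ndarray  # nm
    eps_S: np.ndarray
    eps_ES: np.ndarray
    eps_P: np.ndarray
    ref_concentrations_uM: dict = field(
        default_factory=lambda: {"S": 8.0, "ES": 3.5, "P": 5.0})
    analysis_window: tuple[float, float] = DEFAULT_WINDOW
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.common_grid, dtype=float)
        object.__setattr__(self, "common_grid", grid)
        for name in ("eps_S", "eps_ES", "eps_P"):
            eps = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, eps)
            if eps.size != grid.size or not np.all(np.isfinite(eps)):
                raise InvalidInputError(f"{name} must be finite on the common grid")
        lo, hi = self.analysis_window
        if lo < grid[0] or hi > grid[-1]:
            raise InvalidInputError("analysis window must lie within the grid")

    def epsilon(self, species: str) -> np.ndarray:
        return {"S": self.eps_S, "ES": self.eps_ES, "P": self.eps_P}[species]

    def scaled_es(self, alpha: float) -> "ReferenceSet":
        """Return a copy with the ES epsilon curve multiplied by ``alpha``."""
        return replace(self, eps_ES=self.eps_ES * alpha)

    @classmethod
    def from_references(cls, refs: dict[str, ReferenceSpectrum],
                        common_grid: np.ndarray | None = None,
                        analysis_window: tuple[float, float] = DEFAULT_WINDOW
                        ) -> "ReferenceSet":
        """Assemble a set from per-species references, resampling each
        epsilon curve onto a common grid (default: the S grid)."""
        missing = set(SPECIES) - set(refs)
        if missing:
            raise InvalidInputError(f"missing reference spectra for {sorted(missing)}")
        if common_grid is None:
            common_grid = refs["S"].raw.wavelength_nm
        common_grid = np.asarray(common_grid, dtype=float)
        eps = {}
        for sp in SPECIES:
            r = refs[sp]
            carrier = Spectrum(r.raw.wavelength_nm, r.epsilon_curve,
                               path_length_cm=r.raw.path_length_cm)
            eps[sp] = resample(carrier, common_grid).absorbance
        return cls(common_grid, eps["S"], eps["ES"], eps["P"],
                   ref_concentrations_uM={sp: refs[sp].concentration_uM
                                          for sp in SPECIES},
                   analysis_window=analysis_window,
                   path_length_cm=refs["S"].raw.path_length_cm)


def calibrate_es_epsilon(series: list[Spectrum], refs: ReferenceSet,
                         total_pchlide_uM: float, *, rel_tol: float = 0.05,
                         bounds: tuple[float, float] = (0.2, 5.0)
                         ) -> float:
    """Conservation-based rescaling of the ES extinction coefficient.

    Given a binding-only series (no electron donor, so only S and ES are
    present and their sum must equal total Pchlide), find the scalar
    ``alpha`` multiplying the ES epsilon curve that minimizes the relative
    standard deviation of the unmixed total c_S + c_ES over the series.

    Returns ``alpha``; raises :class:`CalibrationError` if the optimum is
    at the search bounds or the calibrated total misses
    ``total_pchlide_uM`` by more than ``rel_tol`` (both signal references
    inconsistent with the data).
    """
    from .unmix import UnmixConfig, unmix_series  # cycle at import time

    if len(series) < 10:
        raise InvalidInputError(
            f"ES calibration needs >= 10 spectra, got {len(series)}"
        )
    if total_pchlide_uM <= 0:
        raise InvalidInputError("total_pchlide_uM must be positive")
    cfg = UnmixConfig()

    def objective(alpha: float) -> float:
        cs = unmix_series(series, refs.scaled_es(alpha), cfg)
        total = cs.total_uM
        return float(np.std(total) / np.mean(total))

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    if not res.success:
        raise CalibrationError(f"ES calibration failed: {res.message}")
    alpha = float(res.x)
    lo, hi = bounds
    if alpha <= lo * 1.01 or alpha >= hi * 0.99:
        raise CalibrationError(
            f"calibrated ES scale {alpha:.3f} sits at the search bound "
            f"[{lo}, {hi}]; references are inconsistent with the series"
        )
    cs = unmix_series(series, refs.scaled_es(alpha), UnmixConfig())
    mean_total = float(np.mean(cs.total_uM))
    if abs(mean_total - total_pchlide_uM) / total_pchlide_uM > rel_tol:
        raise CalibrationError(
            f"post-calibration total {mean_total:.3f} uM differs from the "
            f"stated {total_pchlide_uM} uM by more than {rel_tol:.0%}"
        )
    return alpha


# ---------------------------------------------------------------------------
# I/O

def read_reference_csv(csv_path: str | Path,
                       sidecar_path: str | Path | None = None,
                       smoothing: SmoothingConfig | float | None = None
                       ) -> ReferenceSpectrum:
    """Read one raw reference (CSV ``wavelength_nm,absorbance``) plus its
    YAML/JSON sidecar (species, concentration_uM, path_length_cm)."""
    csv_path = Path(csv_path)
    if sidecar_path is None:
        for ext in (".yaml", ".yml", ".json"):
            cand = csv_path.with_suffix(ext)
            if cand.exists():
                sidecar_path = cand
                break
        else:
            raise InvalidInputError(f"no sidecar config found for {csv_path}")
    meta = yaml.safe_load(Path(sidecar_path).read_text())
    df = pd.read_csv(csv_path)
    raw = Spectrum(df["wavelength_nm"].to_numpy(float),
                   df["absorbance"].to_numpy(float),
                   path_length_cm=float(meta.get("path_length_cm", 1.0)))
    return ReferenceSpectrum.from_raw(meta["species"], raw,
                                      float(meta["concentration_uM"]), smoothing)


def write_reference_set(refs: ReferenceSet, path: str | Path) -> None:
    """Serialize a calibrated set as ``wavelength_nm,eps_S,eps_ES,eps_P``
    with a ``#``-prefixed metadata block."""
    path = Path(path)
    meta = {
        "ref_concentrations_uM": refs.ref_concentrations_uM,
        "analysis_window_nm": list(refs.analysis_window),
        "path_length_cm": refs.path_length_cm,
        "units": "mM^-1 cm^-1",
    }
    with open(path, "w") as fh:
        fh.write("# dporkin ReferenceSet\n")
        for line in yaml.safe_dump(meta, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame({
            "wavelength_nm": refs.common_grid,
            "eps_S": refs.eps_S, "eps_ES": refs.eps_ES, "eps_P": refs.eps_P,
        }).to_csv(fh, index=False)


def read_reference_set(path: str | Path) -> ReferenceSet:
    lines = Path(path).read_text().splitlines()
    meta_lines = [l[2:] for l in lines if l.startswith("# ")]
    meta = yaml.safe_load("\n".join(meta_lines[1:])) if len(meta_lines) > 1 else {}
    df = pd.read_csv(path, comment="#")
    return ReferenceSet(
        df["wavelength_nm"].to_numpy(float), df["eps_S"].to_numpy(float),
        df["eps_ES"].to_numpy(float), df["eps_P"].to_numpy(float),
        ref_concentrations_uM=meta.get("ref_concentrations_uM",
                                       {"S": 8.0, "ES": 3.5, "P": 5.0}),
        analysis_window=tuple(meta.get("analysis_window_nm", DEFAULT_WINDOW)),
        path_length_cm=float(meta.get("path_length_cm", 1.0)))
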