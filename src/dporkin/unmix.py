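"""Multicomponent spectral unmixing.

Each recorded spectrum is modelled as a weighted sum of the three
reference spectra plus a baseline and a wavelength-power scattering term:

    f(lambda) = p1*S_S(lambda - p6) + p2*S_P(lambda - p7)
              + p3*S_ES(lambda - p8) + p4 + p5*lambda**e

S_S, S_P and S_ES are the smoothed reference spectra *at their known
recording concentrations*, so the proportionality factors p1-p3 convert
directly to concentrations (c_S = p1 * c_ref_S, etc. — equivalent to
amplitude over epsilon).  p4 absorbs baseline shift, p5 scattering from
precipitating material, and p6-p8 are instrument wavelength shifts,
fixed at 0 by default.  With shifts fixed the model is linear in the
remaining parameters; the solver is a bounded trust-region nonlinear
least-squares that, on noise-free input, must agree with a direct linear
solution to high precision (this is tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear

from .errors import InvalidInputError
from .references import ReferenceSet
from .spectra import Spectrum, resample

__all__ = [
    "UnmixConfig",
    "UnmixResult",
    "ConcentrationSeries",
    "ConservationReport",
    "model_spectrum",
    "unmix_spectrum",
    "unmix_series",
    "conservation_check",
    "read_series_csv",
    "write_series_csv",
]

#: supported scattering exponents: +3 is the literal model; -3/-4 are the
#: physically motivated turbidity forms
SCATTER_EXPONENTS = (-4, -3, 3)

#: wavelength used to scale the scatter basis column for conditioning
_LAMBDA0 = 650.0


@dataclass(frozen=True)
class UnmixConfig:
    """Solver options for spectral unmixing."""

    fix_shifts: bool = True
    scatter_exponent: int = 3
    nonneg_concentrations: bool = True
    max_shift_nm: float = 3.0
    ftol: float = 1e-10
    max_iter: int = 500
    window: tuple[float, float] | None = None  # overrides the ReferenceSet's

    def __post_init__(self) -> None:
        if self.scatter_exponent not in SCATTER_EXPONENTS:
            raise InvalidInputError(
                f"scatter_exponent must be one of {SCATTER_EXPONENTS}")
        if self.max_shift_nm < 0:
            raise InvalidInputError("max_shift_nm must be >= 0")


@dataclass(frozen=True)
class UnmixResult:
    """Per-spectrum decomposition into species concentrations."""

    c_S_uM: float
    c_ES_uM: float
    c_P_uM: float
    p4: float  # AU baseline offset
    p5: float  # AU * nm^(-exponent) scatter coefficient
    p6: float = 0.0  # nm shift of the S reference
    p7: float = 0.0  # nm shift of the P reference
    p8: float = 0.0  # nm shift of the ES reference
    residual_rms: float = 0.0
    converged: bool = True
    shift_clamped: bool = False
    time_s: float | None = None


def _window_mask(refs: ReferenceSet, config: UnmixConfig) -> np.ndarray:
    lo, hi = config.window if config.window is not None else refs.analysis_window
    m = (refs.common_grid >= lo) & (refs.common_grid <= hi)
    if not np.any(m):
        raise InvalidInputError("analysis window contains no grid points")
    return m


def _reference_bases(refs: ReferenceSet) -> dict[str, np.ndarray]:
    """Reference spectra in AU at their recording concentrations."""
    l = refs.path_length_cm
    c = refs.ref_concentrations_uM
    return {
        "S": refs.eps_S * (c["S"] * 1e-3) * l,
        "P": refs.eps_P * (c["P"] * 1e-3) * l,
        "ES": refs.eps_ES * (c["ES"] * 1e-3) * l,
    }


def _shifted(base: np.ndarray, grid: np.ndarray, shift: float) -> np.ndarray:
    # S(lambda - shift); outside the grid, clamp to the nearest edge value
    return np.interp(grid - shift, grid, base)


def model_spectrum(params, refs: ReferenceSet, exponent: int = 3,
                   window: tuple[float, float] | None = None) -> Spectrum:
    """Evaluate the unmixing model for parameters (p1..p8).

    ``params`` is a sequence of up to 8 values; missing trailing values
    default to 0.  Returned on the analysis window of the reference grid.
    """
    p = np.zeros(8)
    p[:len(params)] = params
    cfg = UnmixConfig(scatter_exponent=exponent,
                      window=window)
    m = _window_mask(refs, cfg)
    grid = refs.common_grid[m]
    bases = _reference_bases(refs)
    ab = (p[0] * _shifted(bases["S"][m], grid, p[5])
          + p[1] * _shifted(bases["P"][m], grid, p[6])
          + p[2] * _shifted(bases["ES"][m], grid, p[7])
          + p[3] + p[4] * grid ** exponent)
    return Spectrum(grid, ab, path_length_cm=refs.path_length_cm)


def unmix_spectrum(spec: Spectrum, refs: ReferenceSet,
                   config: UnmixConfig | None = None,
                   x0: np.ndarray | None = None) -> UnmixResult:
    """Fit the unmixing model to one spectrum.

    Deterministic for identical inputs.  ``x0`` optionally warm-starts
    the free parameters (used by :func:`unmix_series`); by default p1-p3
    start from a nonnegative linear pre-fit, p4 from the red-tail median
    and p5 from 0.  Never raises on non-convergence — the result carries
    ``converged=False``.
    """
    config = config or UnmixConfig()
    m = _window_mask(refs, config)
    grid = refs.common_grid[m]
    if not np.array_equal(spec.wavelength_nm, grid):
        spec = resample(spec, grid)
    A = spec.absorbance
    e = config.scatter_exponent
    bases = _reference_bases(refs)
    B = np.column_stack([
        bases["S"][m], bases["P"][m], bases["ES"][m],
        np.ones(grid.size), (grid / _LAMBDA0) ** e,
    ])

    lower = np.array([0.0, 0.0, 0.0, -np.inf, -np.inf])
    if not config.nonneg_concentrations:
        lower[:3] = -np.inf
    upper = np.full(5, np.inf)

    if x0 is None:
        p4_0 = float(np.median(A[-5:]))
        pre = lsq_linear(B[:, :3], A - p4_0,
                         bounds=(lower[:3], upper[:3]))
        x0 = np.concatenate([pre.x, [p4_0, 0.0]])
    else:
        x0 = np.asarray(x0, dtype=float).copy()
    x0 = np.clip(x0[:5], lower, upper)

    if config.fix_shifts:
        res = least_squares(
            lambda p: B @ p - A, x0, jac=lambda p: B,
            bounds=(lower, upper), method="trf",
            ftol=config.ftol, xtol=1e-13, gtol=1e-12,
            max_nfev=config.max_iter)
        shifts = np.zeros(3)
        clamped = False
    else:
        ms = config.max_shift_nm
        lower = np.concatenate([lower, [-ms] * 3])
        upper = np.concatenate([upper, [ms] * 3])
        x0 = np.concatenate([x0, np.zeros(3)])

        def fun(p):
            mod = (p[0] * _shifted(bases["S"][m], grid, p[5])
                   + p[1] * _shifted(bases["P"][m], grid, p[6])
                   + p[2] * _shifted(bases["ES"][m], grid, p[7])
                   + p[3] + p[4] * (grid / _LAMBDA0) ** e)
            return mod - A

        res = least_squares(fun, x0, bounds=(lower, upper), method="trf",
                            ftol=config.ftol, xtol=1e-13, gtol=1e-12,
                            max_nfev=10 * config.max_iter)
        shifts = res.x[5:8]
        span = grid[-1] - grid[0]
        clamped = bool(np.any(np.abs(shifts) > 0) and
                       np.any(np.abs(shifts) >= ms - 1e-12))

    p = res.x
    c = refs.ref_concentrations_uM
    return UnmixResult(
        c_S_uM=p[0] * c["S"], c_ES_uM=p[2] * c["ES"], c_P_uM=p[1] * c["P"],
        p4=p[3], p5=p[4] / _LAMBDA0 ** e,
        p6=float(shifts[0]), p7=float(shifts[1]), p8=float(shifts[2]),
        residual_rms=float(np.sqrt(np.mean(res.fun ** 2))),
        converged=bool(res.status > 0),
        shift_clamped=clamped,
        time_s=spec.time_s)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Aligned concentration traces from unmixing a time series."""

    time_s: np.ndarray
    c_S_uM: np.ndarray
    c_ES_uM: np.ndarray
    c_P_uM: np.ndarray
    residual_rms: np.ndarray
    converged: np.ndarray
    truncated_before_s: float = 0.0  # dead-time truncation applied, if any

    def __post_init__(self) -> None:
        n = self.time_s.size
        for name in ("c_S_uM", "c_ES_uM", "c_P_uM", "residual_rms", "converged"):
            if getattr(self, name).size != n:
                raise InvalidInputError("series arrays must be aligned")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def total_uM(self) -> np.ndarray:
        """c_S + c_ES + c_P, computed on demand (never stored)."""
        return self.c_S_uM + self.c_ES_uM + self.c_P_uM

    def species(self, name: str) -> np.ndarray:
        return {"S": self.c_S_uM, "ES": self.c_ES_uM, "P": self.c_P_uM}[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "c_S_uM": self.c_S_uM,
            "c_ES_uM": self.c_ES_uM, "c_P_uM": self.c_P_uM,
            "total_uM": self.total_uM, "residual_rms": self.residual_rms,
            "converged": self.converged})


def unmix_series(spectra: list[Spectrum], refs: ReferenceSet,
                 config: UnmixConfig | None = None) -> ConcentrationSeries:
    """Unmix a time-ordered series, warm-starting each fit from the
    previous solution.  Non-converged points are flagged, never dropped."""
    if not spectra:
        raise InvalidInputError("empty spectra list")
    times = [s.time_s for s in spectra]
    if any(t is None for t in times):
        times = list(range(len(spectra)))
    elif any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise InvalidInputError("spectra must be strictly time-ordered")
    config = config or UnmixConfig()
    results = []
    x0 = None
    c = refs.ref_concentrations_uM
    for spec in spectra:
        r = unmix_spectrum(spec, refs, config, x0=x0)
        results.append(r)
        x0 = np.array([r.c_S_uM / c["S"], r.c_P_uM / c["P"],
                       r.c_ES_uM / c["ES"], r.p4,
                       r.p5 * _LAMBDA0 ** config.scatter_exponent])
    arr = lambda f: np.array([f(r) for r in results])
    return ConcentrationSeries(
        time_s=np.array(times, dtype=float),
        c_S_uM=arr(lambda r: r.c_S_uM), c_ES_uM=arr(lambda r: r.c_ES_uM),
        c_P_uM=arr(lambda r: r.c_P_uM),
        residual_rms=arr(lambda r: r.residual_rms),
        converged=np.array([r.converged for r in results], dtype=bool))


@dataclass(frozen=True)
class ConservationReport:
    """Report-only diagnostic: does c_S + c_ES + c_P stay at the known
    total Pchlide throughout the experiment?"""

    expected_total_uM: float
    max_rel_deviation: float
    worst_time_s: float
    rel_tol: float
    passed: bool

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (f"conservation {verdict}: max |total - {self.expected_total_uM} uM| "
                f"/ expected = {self.max_rel_deviation:.2e} at "
                f"t={self.worst_time_s:g} s (tol {self.rel_tol:g})")


def conservation_check(series: ConcentrationSeries, expected_total_uM: float,
                       rel_tol: float = 1e-3) -> ConservationReport:
    if len(series) == 0:
        raise InvalidInputError("empty series")
    if expected_total_uM <= 0:
        raise InvalidInputError("expected total must be positive")
    dev = np.abs(series.total_uM - expected_total_uM) / expected_total_uM
    i = int(np.argmax(dev))
    return ConservationReport(
        expected_total_uM=expected_total_uM,
        max_rel_deviation=float(dev[i]),
        worst_time_s=float(series.time_s[i]),
        rel_tol=rel_tol,
        passed=bool(dev[i] <= rel_tol))


def write_series_csv(series: ConcentrationSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series_csv(path: str | Path) -> ConcentrationSeries:
    df = pd.read_csv(path)
    need = {"time_s", "c_S_uM", "c_ES_uM", "c_P_uM"}
    if not need <= set(df.columns):
        raise InvalidInputError(f"series CSV must contain columns {sorted(need)}")
    n = len(df)
    return ConcentrationSeries(
        time_s=df["time_s"].to_numpy(float),
        c_S_uM=df["c_S_uM"].to_numpy(float),
        c_ES_uM=df["c_ES_uM"].to_numpy(float),
        c_P_uM=df["c_P_uM"].to_numpy(float),
        residual_rms=(df["residual_rms"].to_numpy(float)
                      if "residual_rms" in df else np.zeros(n)),
        converged=(df["converged"].to_numpy(bool)
                   if "converged" in df else np.ones(n, dtype=bool)))
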