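"""Association-model fitting of concentration progress curves.

Complex-formation and product-formation traces are summarised by
exponential association models, fitted by unweighted least squares
(optionally inverse-variance weighted):

* one-phase: ``y(t) = y0 + (plateau - y0) * (1 - exp(-k t))``
* two-phase: ``y(t) = y0 + span_fast*(1 - exp(-k_fast t))
  + span_slow*(1 - exp(-k_slow t))`` with ``k_fast >= k_slow`` enforced
  by fitting the slow constant and a ratio >= 1 (no label switching)
* linear: initial-rate fit over a short window.

The first ~10 s of a run are unobservable (mixing dead time); traces are
truncated, not deconvolved, and ``y0`` is always fitted rather than
pinned to the first datum.  Model choice between one- and two-phase uses
AICc with a "prefer simpler within 2" tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .errors import FitFailureError, InvalidInputError
from .unmix import ConcentrationSeries

__all__ = [
    "KineticFit",
    "DeadTime",
    "ModelChoice",
    "fit_one_phase",
    "fit_two_phase",
    "fit_initial_rate",
    "select_model",
    "apply_dead_time",
]

#: default instrument dead time (s): the spectrometer cannot resolve the
#: first ~10 s after mixing
DEFAULT_DEAD_TIME_S = 10.0


@dataclass(frozen=True)
class DeadTime:
    t_dead_s: float = DEFAULT_DEAD_TIME_S

    def __post_init__(self) -> None:
        if self.t_dead_s < 0:
            raise InvalidInputError("dead time must be >= 0")


@dataclass(frozen=True)
class KineticFit:
    """A fitted kinetic model with uncertainties and selection scores."""

    model: str  # one_phase | two_phase | linear
    params: dict
    stderr: dict
    aicc: float
    r_squared: float
    n_points: int
    flags: tuple[str, ...] = ()
    data_fingerprint: tuple = ()

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "one_phase":
            return p["y0"] + (p["plateau"] - p["y0"]) * (1 - np.exp(-p["k"] * t))
        if self.model == "two_phase":
            return (p["y0"]
                    + p["span_fast"] * (1 - np.exp(-p["k_fast"] * t))
                    + p["span_slow"] * (1 - np.exp(-p["k_slow"] * t)))
        return p["intercept"] + p["rate"] * t


def _checks(t: np.ndarray, y: np.ndarray, min_points: int) -> tuple:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise InvalidInputError("t and y must have the same length")
    if t.size < min_points:
        raise InvalidInputError(
            f"need at least {min_points} points, got {t.size}")
    if not np.all(np.diff(t) > 0):
        raise InvalidInputError("t must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise InvalidInputError("t and y must be finite")
    return t, y


def _fingerprint(t: np.ndarray, y: np.ndarray) -> tuple:
    return (t.size, float(t[0]), float(t[-1]), float(np.sum(y)))


def _aicc(result: lmfit.minimizer.MinimizerResult, n: int, k: int) -> float:
    # lmfit's aic = n*log(chi2/n) + 2*k ; add the small-sample correction
    if n - k - 1 <= 0:
        return np.inf
    return float(result.aic + 2 * k * (k + 1) / (n - k - 1))


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


def _run_fit(model: lmfit.Model, params: lmfit.Parameters, t, y, weights):
    try:
        res = model.fit(y, params, t=t, weights=weights,
                        nan_policy="raise", max_nfev=20000,
                        fit_kws={"xtol": 1e-12, "ftol": 1e-12,
                                 "gtol": 1e-12})
    except Exception as exc:
        raise FitFailureError(f"kinetic fit failed: {exc}") from exc
    if not res.success:
        raise FitFailureError(f"kinetic fit did not converge: {res.message}")
    return res


def fit_one_phase(t, y, weights: np.ndarray | None = None) -> KineticFit:
    """Plateau-followed-by-one-phase-association fit.

    Requires >= 6 strictly increasing time points.  A flat trace has no
    identifiable rate constant and raises :class:`FitFailureError`.
    Parameter standard errors come from the fit covariance.
    """
    t, y = _checks(t, y, 6)
    span = float(np.ptp(y))
    if span < 1e-12 * max(1.0, abs(float(np.mean(y)))) or span == 0.0:
        raise FitFailureError("constant trace: rate constant unidentifiable")

    def f(t, y0, plateau, k):
        return y0 + (plateau - y0) * (1 - np.exp(-k * t))

    model = lmfit.Model(f)
    # crude k guess from time to half-rise
    yr = (y - y[0]) / (y[-1] - y[0]) if y[-1] != y[0] else np.zeros_like(y)
    ihalf = int(np.argmax(yr >= 0.5)) if np.any(yr >= 0.5) else t.size // 2
    t_half = max(t[ihalf] - t[0], (t[1] - t[0]))
    params = model.make_params(
        y0=float(y[0]), plateau=float(y[-1]),
        k={"value": float(np.log(2) / t_half), "min": 1e-9, "max": 1e3})
    res = _run_fit(model, params, t, y, weights)
    flags = []
    kval = res.params["k"].value
    if kval <= 2e-9 or kval >= 0.99e3:
        flags.append("k_at_bound")
    return KineticFit(
        model="one_phase",
        params={n: float(res.params[n].value) for n in ("y0", "plateau", "k")},
        stderr={n: (float(res.params[n].stderr)
                    if res.params[n].stderr is not None else np.nan)
                for n in ("y0", "plateau", "k")},
        aicc=_aicc(res, t.size, 3),
        r_squared=_r_squared(y, res.residual),
        n_points=t.size, flags=tuple(flags),
        data_fingerprint=_fingerprint(t, y))


def fit_two_phase(t, y, weights: np.ndarray | None = None) -> KineticFit:
    """Two-phase association fit with k_fast >= k_slow by construction.

    Fitted in (k_slow, ratio) space with ratio >= 1, which removes the
    fast/slow label ambiguity.  Span collapse (either span < 1e-6 of the
    total span) or a ratio pinned at 1 is flagged — the data are then
    effectively one-phase.
    """
    t, y = _checks(t, y, 8)
    span = float(np.ptp(y))
    if span == 0.0:
        raise FitFailureError("constant trace: rate constants unidentifiable")

    def f(t, y0, span_fast, span_slow, k_slow, ratio):
        k_fast = k_slow * ratio
        return (y0 + span_fast * (1 - np.exp(-k_fast * t))
                + span_slow * (1 - np.exp(-k_slow * t)))

    model = lmfit.Model(f)
    t_span = t[-1] - t[0]
    params = model.make_params(
        y0=float(y[0]),
        span_fast={"value": span / 2, "min": 0.0},
        span_slow={"value": span / 2, "min": 0.0},
        k_slow={"value": 1.0 / t_span, "min": 1e-9, "max": 1e3},
        ratio={"value": 10.0, "min": 1.0, "max": 1e6})
    res = _run_fit(model, params, t, y, weights)
    p = res.params
    k_slow = float(p["k_slow"].value)
    ratio = float(p["ratio"].value)
    k_fast = k_slow * ratio
    sf, ss = float(p["span_fast"].value), float(p["span_slow"].value)
    total_span = sf + ss
    flags = []
    if total_span > 0 and min(sf, ss) < 1e-6 * total_span:
        flags.append("span_collapse_suggest_one_phase")
    if ratio < 1.0 + 1e-6:
        flags.append("phases_degenerate_suggest_one_phase")

    # propagate stderr of k_fast = k_slow * ratio from the covariance
    kf_err = np.nan
    if res.covar is not None and p["k_slow"].stderr is not None:
        names = [n for n in res.var_names]
        try:
            i, j = names.index("k_slow"), names.index("ratio")
            var = (ratio ** 2 * res.covar[i, i]
                   + k_slow ** 2 * res.covar[j, j]
                   + 2 * ratio * k_slow * res.covar[i, j])
            kf_err = float(np.sqrt(max(var, 0.0)))
        except ValueError:
            pass
    err = lambda n: (float(p[n].stderr) if p[n].stderr is not None else np.nan)
    return KineticFit(
        model="two_phase",
        params={"y0": float(p["y0"].value), "span_fast": sf, "span_slow": ss,
                "k_fast": k_fast, "k_slow": k_slow},
        stderr={"y0": err("y0"), "span_fast": err("span_fast"),
                "span_slow": err("span_slow"), "k_fast": kf_err,
                "k_slow": err("k_slow")},
        aicc=_aicc(res, t.size, 5),
        r_squared=_r_squared(y, res.residual),
        n_points=t.size, flags=tuple(flags),
        data_fingerprint=_fingerprint(t, y))


def fit_initial_rate(t, y, window_s: float, volume_mL: float | None = None
                     ) -> KineticFit:
    """Ordinary linear fit over the initial window [t0, t0 + window_s].

    The rate is reported in uM/s; when ``volume_mL`` is given the fit
    also records the absolute rate in nmol/s (uM * mL = nmol).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    m = t <= t[0] + window_s
    if not np.any(m):
        raise InvalidInputError("window excludes all points")
    t_w, y_w = _checks(t[m], y[m], 4)
    coef, cov = np.polyfit(t_w, y_w, 1, cov=True)
    rate, intercept = float(coef[0]), float(coef[1])
    resid = y_w - (intercept + rate * t_w)
    params = {"intercept": intercept, "rate": rate}
    stderr = {"intercept": float(np.sqrt(cov[1, 1])),
              "rate": float(np.sqrt(cov[0, 0]))}
    if volume_mL is not None:
        if volume_mL <= 0:
            raise InvalidInputError("volume must be positive")
        params["rate_nmol_per_s"] = rate * volume_mL
        stderr["rate_nmol_per_s"] = stderr["rate"] * volume_mL
    n = t_w.size
    rss = float(np.sum(resid ** 2))
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 2
    return KineticFit(
        model="linear", params=params, stderr=stderr,
        aicc=float(aic + 2 * 2 * 3 / max(n - 3, 1)),
        r_squared=_r_squared(y_w, resid), n_points=n,
        data_fingerprint=_fingerprint(t_w, y_w))


@dataclass(frozen=True)
class ModelChoice:
    chosen: KineticFit
    delta_aicc: float  # aicc(two_phase) - aicc(one_phase)
    reason: str


def select_model(fit1: KineticFit, fit2: KineticFit) -> ModelChoice:
    """Pick between a one-phase and a two-phase fit of the same data.

    Lower AICc wins; within |delta| < 2 the simpler (one-phase) model is
    preferred.
    """
    if {fit1.model, fit2.model} != {"one_phase", "two_phase"}:
        raise InvalidInputError("need one one-phase and one two-phase fit")
    one = fit1 if fit1.model == "one_phase" else fit2
    two = fit2 if fit2.model == "two_phase" else fit1
    if one.data_fingerprint != two.data_fingerprint:
        raise InvalidInputError("fits were not computed on identical data")
    delta = two.aicc - one.aicc
    if delta < -2:
        return ModelChoice(two, delta, f"two_phase favored (dAICc={delta:.1f})")
    return ModelChoice(one, delta,
                       "one_phase preferred (simpler within 2 AICc)"
                       if abs(delta) <= 2 else
                       f"one_phase favored (dAICc={delta:.1f})")


def apply_dead_time(series: ConcentrationSeries,
                    dead: DeadTime | float = DeadTime()) -> ConcentrationSeries:
    """Drop series points recorded before the instrument dead time.

    ``t_dead = 0`` is the identity; removing every point is an error.
    The truncation is recorded on the returned series.
    """
    if not isinstance(dead, DeadTime):
        dead = DeadTime(float(dead))
    if dead.t_dead_s == 0:
        return series
    m = series.time_s >= dead.t_dead_s
    if not np.any(m):
        raise InvalidInputError(
            f"dead time {dead.t_dead_s} s removes every point "
            f"(series ends at {series.time_s[-1]} s)")
    return replace(series,
                   time_s=series.time_s[m], c_S_uM=series.c_S_uM[m],
                   c_ES_uM=series.c_ES_uM[m], c_P_uM=series.c_P_uM[m],
                   residual_rms=series.residual_rms[m],
                   converged=series.converged[m],
                   truncated_before_s=dead.t_dead_s)
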