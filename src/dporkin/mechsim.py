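"""Deterministic simulation of the DPOR kinetic scheme.

The core model is the two-step scheme

    E + S <-> ES -> E + P

where E is a Pchlide-binding site on BchNB (two per tetramer), S is free
protochlorophyllide, ES the spectroscopically distinct complex and P
chlorophyllide.  Without an electron donor k_cat = 0 and only the binding
step runs.  Two extensions cover behaviour seen in real progress curves:

* **pools** — the binding sites are split into classes with independent
  rate constants, a phenomenological route to biphasic ES formation or
  biphasic product formation (two catalytic classes).
* **two_site** — an explicit sequential (Adair-type) site-pair model:
  each enzyme carries two sites whose macroscopic first/second binding
  events have separate rate constants, giving biphasic complex formation
  from site-site communication rather than from distinct populations.

``release_product=False`` switches catalysis to single-turnover mode: a
site that converts its substrate keeps the product and is blocked.  This
reproduces stalled turnover — product plateaus while free substrate
remains and the ES population decays toward zero — and makes the product
trace follow the one-/two-phase association closed form exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegratorError, InvalidInputError

__all__ = [
    "SitePool",
    "MechanismParams",
    "Trajectory",
    "Stage",
    "simulate",
    "simulate_event_sequence",
    "pseudo_first_order_kobs",
    "binding_site_capacity",
    "equilibrium_es",
]

#: Pchlide-binding sites per BchNB tetramer (one per alpha-beta half)
SITES_PER_BCHNB = 2

RTOL = 1e-10
ATOL = 1e-13


def binding_site_capacity(bchnb_uM: float) -> float:
    """Expected ES capacity in uM: two binding sites per BchNB tetramer."""
    if bchnb_uM < 0:
        raise InvalidInputError("BchNB concentration must be nonnegative")
    return SITES_PER_BCHNB * bchnb_uM


@dataclass(frozen=True)
class SitePool:
    """A class of binding sites.

    ``fraction`` of E_total belongs to this pool; ``k_on``/``k_off``
    default to the mechanism-level constants when ``None``.
    """

    fraction: float
    k_cat: float = 0.0
    k_on: float | None = None
    k_off: float | None = None


@dataclass(frozen=True)
class MechanismParams:
    """Rate constants and initial amounts for one simulation stage.

    Units: k_on in uM^-1 s^-1, k_off and k_cat in s^-1, amounts in uM of
    binding *sites* (E_total) and substrate (S_total).
    """

    k_on: float
    E_total_uM: float
    S_total_uM: float
    k_off: float = 0.0
    k_cat: float = 0.0
    pools: tuple[SitePool, ...] | None = None
    site_model: str = "single"  # or "two_site"
    k_on1: float | None = None
    k_off1: float | None = None
    k_on2: float | None = None
    k_off2: float | None = None
    release_product: bool = True

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_cat"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")
        if self.E_total_uM < 0 or self.S_total_uM < 0:
            raise InvalidInputError("amounts must be nonnegative")
        if self.site_model not in ("single", "two_site"):
            raise InvalidInputError("site_model must be 'single' or 'two_site'")
        if self.pools is not None:
            object.__setattr__(self, "pools", tuple(self.pools))
            fr = sum(p.fraction for p in self.pools)
            if not np.isclose(fr, 1.0):
                raise InvalidInputError(f"pool fractions must sum to 1, got {fr}")
            if any(p.fraction < 0 for p in self.pools):
                raise InvalidInputError("pool fractions must be nonnegative")
        if self.site_model == "two_site" and self.pools is not None:
            raise InvalidInputError("pools and two_site are mutually exclusive")

    def effective_pools(self) -> tuple[SitePool, ...]:
        pools = self.pools or (SitePool(fraction=1.0, k_cat=self.k_cat),)
        return tuple(
            SitePool(p.fraction, p.k_cat,
                     self.k_on if p.k_on is None else p.k_on,
                     self.k_off if p.k_off is None else p.k_off)
            for p in pools)


@dataclass(frozen=True)
class Trajectory:
    """Concentration trajectories (uM) on a time grid (s)."""

    time_s: np.ndarray
    c_S: np.ndarray
    c_ES: np.ndarray
    c_P: np.ndarray
    c_Efree: np.ndarray
    stage_starts_s: tuple[float, ...] = (0.0,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "c_S_uM": self.c_S, "c_ES_uM": self.c_ES,
            "c_P_uM": self.c_P, "c_Efree_uM": self.c_Efree})

    def total_pchlide(self) -> np.ndarray:
        """S + ES + P — conserved for a closed system."""
        return self.c_S + self.c_ES + self.c_P


# ---------------------------------------------------------------------------
# state layout helpers

def _initial_state(params: MechanismParams) -> np.ndarray:
    if params.site_model == "two_site":
        # [S, N00, N10, N01, N20, N11, N02, P_free]; N_sp = pairs with
        # s substrates and p products bound
        pairs = params.E_total_uM / 2.0
        return np.array([params.S_total_uM, pairs, 0, 0, 0, 0, 0, 0], float)
    n = len(params.effective_pools())
    # [S, ES_1..n, B_1..n (blocked product-holding sites), P]
    y = np.zeros(2 * n + 2)
    y[0] = params.S_total_uM
    return y


def _rhs_pools(params: MechanismParams):
    pools = params.effective_pools()
    n = len(pools)
    E = np.array([p.fraction for p in pools]) * params.E_total_uM
    kon = np.array([p.k_on for p in pools])
    koff = np.array([p.k_off for p in pools])
    kcat = np.array([p.k_cat for p in pools])
    release = params.release_product

    def rhs(t, y):
        S = y[0]
        ES = y[1:1 + n]
        B = y[1 + n:1 + 2 * n]
        Efree = E - ES - B
        bind = kon * Efree * S
        dES = bind - (koff + kcat) * ES
        dS = -np.sum(bind) + np.sum(koff * ES)
        dP = np.sum(kcat * ES)
        dB = np.zeros(n) if release else kcat * ES
        return np.concatenate(([dS], dES, dB, [dP]))

    return rhs, n, E


def _rhs_two_site(params: MechanismParams):
    a1 = params.k_on1 if params.k_on1 is not None else params.k_on
    a2 = params.k_on2 if params.k_on2 is not None else params.k_on
    d1 = params.k_off1 if params.k_off1 is not None else params.k_off
    d2 = params.k_off2 if params.k_off2 is not None else params.k_off
    kcat = params.k_cat
    release = params.release_product

    def rhs(t, y):
        S, N00, N10, N01, N20, N11, N02, Pf = y
        dy = np.zeros(8)
        # macroscopic first/second binding events per pair
        flows = [
            (1, 2, a1 * S * N00, True),   # N00 + S -> N10
            (2, 1, d1 * N10, False),      # N10 -> N00 + S
            (2, 4, a2 * S * N10, True),   # N10 + S -> N20
            (4, 2, d2 * N20, False),      # N20 -> N10 + S
            (3, 5, a2 * S * N01, True),   # N01 + S -> N11
            (5, 3, d2 * N11, False),      # N11 -> N01 + S
        ]
        for i, j, rate, consumes_S in flows:
            dy[i] -= rate
            dy[j] += rate
            dy[0] += -rate if consumes_S else rate
        if kcat > 0:
            if release:
                for i, j, mult in ((2, 1, 1.0), (4, 2, 2.0)):
                    rate = mult * kcat * y[i]
                    dy[i] -= rate
                    dy[j] += rate
                    dy[7] += rate
            else:
                for i, j, mult in ((2, 3, 1.0), (4, 5, 2.0), (5, 6, 1.0)):
                    rate = mult * kcat * y[i]
                    dy[i] -= rate
                    dy[j] += rate
        return dy

    return rhs


def _observables(params: MechanismParams, y: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map integrator states (columns = time) to S, ES, P, E_free."""
    if params.site_model == "two_site":
        S, N00, N10, N01, N20, N11, N02, Pf = y
        ES = N10 + 2 * N20 + N11
        P = Pf + N01 + N11 + 2 * N02
        Efree = 2 * N00 + N10 + N01
        return S, ES, P, Efree
    n = len(params.effective_pools())
    S = y[0]
    ES = y[1:1 + n].sum(axis=0)
    B = y[1 + n:1 + 2 * n].sum(axis=0)
    P = y[-1]
    E = params.E_total_uM
    return S, ES, P, E - ES - B


def _integrate(params: MechanismParams, t_grid: np.ndarray, y0: np.ndarray
               ) -> np.ndarray:
    rhs = (_rhs_two_site(params) if params.site_model == "two_site"
           else _rhs_pools(params)[0])
    if t_grid[-1] == t_grid[0]:
        return np.tile(y0[:, None], (1, t_grid.size))
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA",
                    t_eval=t_grid, rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise IntegratorError(
            f"ODE integration failed: {sol.message} (nfev={sol.nfev})"
        )
    return sol.y


def simulate(params: MechanismParams, t_grid: np.ndarray) -> Trajectory:
    """Integrate the scheme on ``t_grid`` (seconds, increasing, from 0).

    Mass is conserved to integrator tolerance: c_S + c_ES + c_P stays at
    S_total, and sites (free + complexed + blocked) at E_total.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise InvalidInputError("t_grid must be a nonempty 1-D array")
    if t_grid[0] != 0 or (t_grid.size > 1 and not np.all(np.diff(t_grid) > 0)):
        raise InvalidInputError("t_grid must be increasing and start at 0")
    y = _integrate(params, t_grid, _initial_state(params))
    S, ES, P, Efree = _observables(params, y)
    clip = lambda a: np.clip(np.atleast_1d(a), 0.0, None)
    return Trajectory(t_grid, clip(S), clip(ES), clip(P), clip(Efree))


@dataclass(frozen=True)
class Stage:
    """One stage of an event sequence.

    ``params`` applies for ``duration_s``; at the stage start,
    ``inject_S_uM`` of substrate and/or ``inject_E_uM`` of empty sites
    appear as a step increase (e.g. reaction initiated by Pchlide or by
    BchNB; donor addition is expressed by a params patch with k_cat > 0).
    """

    duration_s: float
    params: MechanismParams
    inject_S_uM: float = 0.0
    inject_E_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidInputError("stage duration must be positive")
        if self.inject_S_uM < 0 or self.inject_E_uM < 0:
            raise InvalidInputError("injected amounts must be nonnegative")


def simulate_event_sequence(stages: list[Stage],
                            dt: float | list[float]) -> Trajectory:
    """Run contiguous stages, carrying concentrations across boundaries.

    Each stage is sampled at ``dt`` (a scalar, or one interval per stage)
    from its own start; the trajectory is continuous at boundaries apart
    from explicit injections, which step the injected species only.  All
    stages must share the same structural model (pool layout / site
    model).
    """
    if not stages:
        raise InvalidInputError("need at least one stage")
    dts = list(dt) if np.ndim(dt) else [float(dt)] * len(stages)
    if len(dts) != len(stages):
        raise InvalidInputError("need one sampling interval per stage")
    first = stages[0].params
    layout = (first.site_model, len(first.effective_pools()))
    times, states = [], []
    y = _initial_state(first)
    t0 = 0.0
    starts = []
    for st, dt_s in zip(stages, dts):
        p = st.params
        if (p.site_model, len(p.effective_pools())) != layout:
            raise InvalidInputError(
                "all stages must share the same pool/site structure")
        y = y.copy()
        y[0] += st.inject_S_uM
        if st.inject_E_uM:
            if p.site_model == "two_site":
                y[1] += st.inject_E_uM / 2.0
            # pools model: free sites are implicit (E_total - ES - B), so an
            # enzyme injection is expressed by the stage params carrying a
            # larger E_total; nothing to add to the state vector.
        starts.append(t0)
        grid = np.arange(0.0, st.duration_s + dt_s / 2, dt_s)
        ys = _integrate(p, grid, y)
        times.append(grid + t0)
        states.append(ys)
        y = ys[:, -1]
        t0 += st.duration_s
    # drop duplicated boundary samples (end of stage i == start of stage i+1)
    tt = [times[0]] + [t[1:] for t in times[1:]]
    yy = [states[0]] + [s[:, 1:] for s in states[1:]]
    t_all = np.concatenate(tt)
    y_all = np.concatenate(yy, axis=1)
    S, ES, P, Efree = _observables(stages[-1].params, y_all)
    clip = lambda a: np.clip(a, 0.0, None)
    return Trajectory(t_all, clip(S), clip(ES), clip(P), clip(Efree),
                      stage_starts_s=tuple(starts))


def pseudo_first_order_kobs(params: MechanismParams) -> float:
    """Observed binding rate constant k_on*S_total + k_off (s^-1).

    This is the expected one-phase association constant for the ES trace
    when substrate is in large excess (S >> E) and k_cat = 0.
    """
    if params.S_total_uM <= 0:
        raise InvalidInputError("S_total must be positive")
    return params.k_on * params.S_total_uM + params.k_off


def equilibrium_es(E_total_uM: float, S_total_uM: float, Kd_uM: float) -> float:
    """Closed-form equilibrium ES for single-class binding to E_total sites.

    Root of k_on(E-ES)(S-ES) = k_off*ES with Kd = k_off/k_on.
    """
    b = E_total_uM + S_total_uM + Kd_uM
    return (b - np.sqrt(b * b - 4 * E_total_uM * S_total_uM)) / 2.0
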