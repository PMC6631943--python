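"""Structural model: domain types, the site-dependent dissolved fraction,
Michaelis-Menten dissolution solvers, and the full absorption/disposition
ODE system.

State convention
----------------
Tablet, lumen and gut amounts are carried as *fractions of the dose* so that
the dose-normalized release parameters (``vmax`` in 1/h, ``am50`` unitless)
apply to every formulation; absorption into the central compartment converts
to mg, and plasma concentration is reported as ng/mL (mg/L x 1000).

The state vector ordering used throughout is
``(x_tablet, x_lumen, x_gut, x1, x2, x_elim)`` where ``x_elim`` is a
bookkeeping state (cumulative amount eliminated, mg) that makes mass
conservation testable: at any time

    x_tablet + x_lumen + x_gut + (x1 + x2 + x_elim)/dose == 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ._fastode import rk4_integrate

__all__ = [
    "FDissParams",
    "InVitroDissolutionParams",
    "InVivoDissolutionParams",
    "DispositionParams",
    "SubjectParameters",
    "StateVector",
    "PlasmaProfile",
    "DissolutionProfile",
    "SolverConfig",
    "f_diss_stomach",
    "f_diss_intestine",
    "f_diss_total",
    "dissolved_fraction_window",
    "solve_invitro_dissolution",
    "invitro_time_to_dissolve",
    "ode_rhs",
    "simulate_pk",
    "simulate_dense",
    "in_vivo_dissolved_pct",
]

MG_PER_L_TO_NG_PER_ML = 1000.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FDissParams:
    """Hill/transit parameters of the time-varying dissolved fraction.

    The dissolved fraction multiplies the Michaelis-Menten release rate and
    encodes where the tablet is along the gastrointestinal tract: high
    solubility in the acidic stomach, near-zero in the small intestine, and
    a moderate rebound in the colon.

    Parameters
    ----------
    imax : maximum fractional drop of the stomach term, in (0, 1].
    t_get : h, time of half-maximal drop (gastric emptying half-time).
    hill_stomach : Hill steepness of the gastric-emptying switch.
    diss_max : maximum fractional rebound of the intestinal/colonic term.
    t_itt : h, intestinal transit time.
    t_ctt : h, colon transit time.
    hill_intestine : Hill steepness of the intestinal rise/fall.
    """

    imax: float
    t_get: float
    hill_stomach: float
    diss_max: float
    t_itt: float
    t_ctt: float
    hill_intestine: float

    def __post_init__(self) -> None:
        _require(0.0 < self.imax <= 1.0, f"imax must be in (0, 1], got {self.imax}")
        for name in ("t_get", "hill_stomach", "t_itt", "t_ctt", "hill_intestine"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0.0, f"{name} must be > 0, got {v}")
        _require(self.diss_max >= 0.0, f"diss_max must be >= 0, got {self.diss_max}")

    @property
    def t_trans1(self) -> float:
        """h, half-maximal rise time of the intestinal term (t_get + t_itt)."""
        return self.t_get + self.t_itt

    @property
    def t_trans2(self) -> float:
        """h, half-maximal fall time of the intestinal term (t_get + t_itt + t_ctt)."""
        return self.t_get + self.t_itt + self.t_ctt


@dataclass(frozen=True)
class InVitroDissolutionParams:
    """Dose-normalized Michaelis-Menten release parameters fitted to
    dissolution-tester data: ``vmax_invitro`` (1/h) and ``am50_invitro``
    (fraction of dose at half-maximal rate)."""

    vmax_invitro: float
    am50_invitro: float

    def __post_init__(self) -> None:
        for name in ("vmax_invitro", "am50_invitro"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0.0, f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class InVivoDissolutionParams:
    """Dose-normalized Michaelis-Menten release parameters acting in the
    gastrointestinal tract (before modulation by the dissolved fraction)."""

    vmax_invivo: float
    am50_invivo: float

    def __post_init__(self) -> None:
        for name in ("vmax_invivo", "am50_invivo"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0.0, f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class DispositionParams:
    """First-order transfer/absorption and two-compartment disposition.

    k_lag : 1/h, lumen -> gut transfer rate constant.
    k_a : 1/h, gut -> central absorption rate constant.
    v1, v2 : L, central and peripheral volumes.
    cl, cld : L/h, systemic and distribution clearances.
    """

    k_lag: float
    k_a: float
    v1: float
    v2: float
    cl: float
    cld: float

    def __post_init__(self) -> None:
        for name in ("k_lag", "k_a", "v1", "v2", "cl", "cld"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0.0, f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class SubjectParameters:
    """One individual's full structural parameter set."""

    f_diss: FDissParams
    dissolution: InVivoDissolutionParams
    disposition: DispositionParams
    subject_id: str
    formulation_id: str
    dose: float  # mg

    def __post_init__(self) -> None:
        _require(self.dose > 0.0, f"dose must be > 0, got {self.dose}")


@dataclass(frozen=True)
class StateVector:
    """Model state at one time point (fractions of dose for the gut-lumen
    chain, mg for systemic amounts)."""

    x_tablet: float
    x_lumen: float
    x_gut: float
    x1: float
    x2: float
    x_elim: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_tablet, self.x_lumen, self.x_gut, self.x1, self.x2, self.x_elim]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "StateVector":
        return cls(*(float(v) for v in a))

    def mass_balance(self, dose: float) -> float:
        """Total drug accounted for, as a fraction of dose (1 when conserved)."""
        return self.x_tablet + self.x_lumen + self.x_gut + (self.x1 + self.x2 + self.x_elim) / dose


@dataclass(frozen=True)
class PlasmaProfile:
    """Observed or simulated concentration-time profile for one subject."""

    subject_id: str
    formulation_id: str
    dose: float  # mg
    times: np.ndarray  # h
    concentrations: np.ndarray  # ng/mL
    blq_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        if self.blq_flags is None:
            object.__setattr__(self, "blq_flags", np.zeros(times.shape, dtype=bool))
        else:
            object.__setattr__(self, "blq_flags", np.asarray(self.blq_flags, dtype=bool))
        _require(times.ndim == 1 and conc.shape == times.shape, "times/concentrations must be 1-D and equal length")
        _require(self.blq_flags.shape == times.shape, "blq_flags length mismatch")
        _require(times.size == 0 or times[0] >= 0.0, "times must be non-negative")
        _require(np.all(np.diff(times) > 0.0), "times must be strictly increasing")
        _require(np.all(conc >= 0.0), "concentrations must be non-negative")

    def quantifiable(self) -> "PlasmaProfile":
        """Profile restricted to observations at or above the assay LLOQ."""
        keep = ~self.blq_flags
        return PlasmaProfile(
            self.subject_id,
            self.formulation_id,
            self.dose,
            self.times[keep],
            self.concentrations[keep],
            np.zeros(int(keep.sum()), dtype=bool),
        )


@dataclass(frozen=True)
class DissolutionProfile:
    """One dissolution-vessel %-dissolved time course."""

    formulation_id: str
    ph_label: str
    vessel_id: str
    times: np.ndarray  # h
    pct_dissolved: np.ndarray  # %
    dose: float  # mg

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pct = np.asarray(self.pct_dissolved, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pct_dissolved", pct)
        _require(times.ndim == 1 and pct.shape == times.shape, "times/pct_dissolved must be 1-D and equal length")
        _require(np.all(np.diff(times) > 0.0), "times must be strictly increasing")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for the in-vivo simulator.

    ``method`` is either ``"lsoda"`` (stiff-capable, adaptive; the default)
    or ``"rk4"`` (fixed-step classical Runge-Kutta, compiled; used inside
    estimation loops where ~10^5 solves are needed).  The Hill exponents of
    the dissolved fraction (>13) make it nearly a switch in time, so the
    adaptive path caps the step size and the fixed-step path uses a small
    step.  RK4 preserves the linear mass invariant exactly.
    """

    method: str = "lsoda"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 0.05
    rk4_step: float = 0.005
    dense_dt: float = 0.01  # internal output grid for Cmax extraction

    def __post_init__(self) -> None:
        _require(self.method in ("lsoda", "radau", "rk4"), f"unknown solver method {self.method!r}")


# ---------------------------------------------------------------------------
# Time-varying dissolved fraction
# ---------------------------------------------------------------------------


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be non-negative")
    return t


def f_diss_stomach(t, p: FDissParams):
    """Gastric contribution to the dissolved fraction.

    Starts at 1 (full dissolution capacity at gastric pH) and drops by
    ``imax`` with Hill steepness ``hill_stomach`` around the gastric
    emptying half-time ``t_get``; 0**h is taken as 0 by continuity.
    Value lies in [1 - imax, 1].
    """
    t = _check_time(t)
    th = t**p.hill_stomach
    out = 1.0 - p.imax * th / (p.t_get**p.hill_stomach + th)
    return out if out.ndim else float(out)


def f_diss_intestine(t, p: FDissParams):
    """Intestinal/colonic rebound of the dissolved fraction: a Hill rise at
    ``t_trans1`` times a Hill fall at ``t_trans2``, scaled by ``diss_max``.
    Value lies in [0, diss_max]."""
    t = _check_time(t)
    h = p.hill_intestine
    th = t**h
    rise = th / (p.t_trans1**h + th)
    fall = 1.0 - th / (p.t_trans2**h + th)
    out = p.diss_max * rise * fall
    return out if out.ndim else float(out)


def f_diss_total(t, p: FDissParams):
    """Total dissolved fraction: stomach + intestine terms."""
    return f_diss_stomach(t, p) + f_diss_intestine(t, p)


def dissolved_fraction_window(
    p: FDissParams, level: float = 0.10, t_max: float = 12.0, dt: float = 0.001
) -> tuple[float, float]:
    """Endpoints of the post-gastric window where the total dissolved
    fraction is at or above ``level``.

    The trajectory starts at 1, falls below ``level`` after gastric
    emptying, rebounds above it in the colonic window and falls back; the
    returned pair is the (up-crossing, down-crossing) of that rebound,
    located on a uniform grid of spacing ``dt``.  Raises if the trajectory
    never re-crosses the level.
    """
    t = np.arange(0.0, t_max + dt / 2, dt)
    f = f_diss_total(t, p)
    above = f >= level
    # segments of consecutive "above" samples; skip the initial gastric one
    edges = np.flatnonzero(np.diff(above.astype(int)))
    ups = [i + 1 for i in edges if not above[i]]
    downs = [i for i in edges if above[i]]
    if not ups:
        raise ValueError(f"dissolved fraction never re-crosses level {level} on [0, {t_max}] h")
    t_lo = t[ups[0]]
    later_downs = [i for i in downs if t[i] >= t_lo]
    t_hi = t[later_downs[0]] if later_downs else t[-1]
    return float(t_lo), float(t_hi)


# ---------------------------------------------------------------------------
# In-vitro Michaelis-Menten dissolution
# ---------------------------------------------------------------------------


def _mm_undissolved(p: InVitroDissolutionParams, t: float, x0: float = 1.0) -> float:
    """Undissolved fraction at time t from the implicit integrated form

        vmax * t = am50 * ln(x0 / x) + (x0 - x),

    solved for x by bracketing.  Exact for autonomous Michaelis-Menten
    depletion, so it doubles as an oracle for the ODE route."""
    if t <= 0.0:
        return x0
    target = p.vmax_invitro * t

    def g(x: float) -> float:
        return p.am50_invitro * math.log(x0 / x) + (x0 - x) - target

    lo = 1e-300
    if g(x0) >= 0.0:  # numerically instantaneous release not reachable
        return x0
    if g(lo) <= 0.0:  # release complete beyond representable precision
        return lo
    return brentq(g, lo, x0, xtol=1e-15, rtol=1e-14)


def solve_invitro_dissolution(p: InVitroDissolutionParams, times) -> np.ndarray:
    """Fraction of dose dissolved at each requested time.

    Solves dX/dt = -vmax * X / (am50 + X) from X(0) = 1 via the implicit
    closed form and returns 1 - X(t).  ``times`` must be non-negative and
    strictly increasing.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0.0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) <= 0.0):
        raise ValueError("times must be strictly increasing")
    x = np.array([_mm_undissolved(p, float(t)) for t in times])
    return 1.0 - x


def invitro_time_to_dissolve(p: InVitroDissolutionParams, fraction: float) -> float:
    """Time (h) at which the given fraction of dose has dissolved, from the
    implicit integrated form (no root finding needed in this direction)."""
    _require(0.0 < fraction < 1.0, "fraction must be in (0, 1)")
    x = 1.0 - fraction
    return (p.am50_invitro * math.log(1.0 / x) + (1.0 - x)) / p.vmax_invitro


# ---------------------------------------------------------------------------
# In-vivo ODE system
# ---------------------------------------------------------------------------


def _param_vector(sp: SubjectParameters) -> np.ndarray:
    f, d, q = sp.f_diss, sp.dissolution, sp.disposition
    return np.array(
        [
            f.imax,
            f.t_get,
            f.hill_stomach,
            f.diss_max,
            f.t_itt,
            f.t_ctt,
            f.hill_intestine,
            d.vmax_invivo,
            d.am50_invivo,
            q.k_lag,
            q.k_a,
            q.v1,
            q.v2,
            q.cl,
            q.cld,
        ]
    )


def ode_rhs(state, t: float, sp: SubjectParameters) -> np.ndarray:
    """Time derivative of the six-state system.

    Release from the tablet follows Michaelis-Menten kinetics modulated by
    the time-varying dissolved fraction; dissolved drug transfers lumen ->
    gut -> central at first order, and disposition is a linear
    two-compartment model with clearances acting on concentrations
    C1 = x1/v1, C2 = x2/v2.
    """
    if isinstance(state, StateVector):
        state = state.as_array()
    x_tablet, x_lumen, x_gut, x1, x2, _ = state
    d, q = sp.dissolution, sp.disposition
    rel = d.vmax_invivo * x_tablet / (d.am50_invivo + x_tablet) * f_diss_total(t, sp.f_diss)
    c1 = x1 / q.v1
    c2 = x2 / q.v2
    return np.array(
        [
            -rel,
            rel - q.k_lag * x_lumen,
            q.k_lag * x_lumen - q.k_a * x_gut,
            q.k_a * x_gut * sp.dose - q.cld * c1 + q.cld * c2 - q.cl * c1,
            q.cld * c1 - q.cld * c2,
            q.cl * c1,
        ]
    )


def _integrate(sp: SubjectParameters, t_grid: np.ndarray, config: SolverConfig) -> np.ndarray:
    """States at the (increasing, starting at 0) grid times; shape (n, 6)."""
    y0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    if config.method == "rk4":
        return rk4_integrate(_param_vector(sp), sp.dose, t_grid, config.rk4_step)
    method = "LSODA" if config.method == "lsoda" else "Radau"
    sol = solve_ivp(
        lambda t, y: ode_rhs(y, t, sp),
        (float(t_grid[0]), float(t_grid[-1])),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed for subject {sp.subject_id!r} "
            f"({sp.formulation_id!r}, dose {sp.dose} mg): {sol.message}"
        )
    return sol.y.T


@dataclass(frozen=True)
class SimulationResult:
    """Dense-grid simulation output for one subject."""

    times: np.ndarray  # h
    states: np.ndarray  # (n, 6)
    subject: SubjectParameters

    @property
    def concentrations(self) -> np.ndarray:
        """Central-compartment concentration, ng/mL."""
        return self.states[:, 3] / self.subject.disposition.v1 * MG_PER_L_TO_NG_PER_ML

    @property
    def cmax(self) -> float:
        return float(self.concentrations.max())

    @property
    def tmax(self) -> float:
        return float(self.times[int(self.concentrations.argmax())])

    @property
    def dissolved_pct(self) -> np.ndarray:
        return 100.0 * (1.0 - self.states[:, 0])

    def conc_at(self, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.times, self.concentrations)


def simulate_dense(
    sp: SubjectParameters,
    t_end: float = 48.0,
    config: SolverConfig | None = None,
) -> SimulationResult:
    """Simulate on the internal dense grid (spacing ``config.dense_dt``).

    The dense grid keeps the Cmax extraction error below 0.5% given the
    model's absorption rate constants.
    """
    config = config or SolverConfig()
    t_grid = np.arange(0.0, t_end + config.dense_dt / 2, config.dense_dt)
    states = _integrate(sp, t_grid, config)
    return SimulationResult(t_grid, states, sp)


def simulate_pk(
    sp: SubjectParameters,
    times,
    config: SolverConfig | None = None,
) -> PlasmaProfile:
    """Plasma concentration (ng/mL) at the requested times.

    The initial condition is the whole dose in the tablet; the profile
    starts at 0 ng/mL.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0.0):
        raise ValueError("times must be strictly increasing")
    config = config or SolverConfig()
    t_end = max(float(times[-1]), config.dense_dt)
    res = simulate_dense(sp, t_end=t_end, config=config)
    conc = res.conc_at(times)
    return PlasmaProfile(sp.subject_id, sp.formulation_id, sp.dose, times, np.maximum(conc, 0.0))


def in_vivo_dissolved_pct(sp: SubjectParameters, t, config: SolverConfig | None = None):
    """Percent of dose dissolved in vivo at time(s) ``t``: 100*(1 - x_tablet)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    config = config or SolverConfig()
    res = simulate_dense(sp, t_end=float(t_arr.max()), config=config)
    out = np.interp(t_arr, res.times, res.dissolved_pct)
    return float(out[0]) if np.ndim(t) == 0 else out
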