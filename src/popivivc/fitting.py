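"""Parameter estimation: in-vitro Michaelis-Menten release fits
(per-formulation, or joint across formulations with a shared am50) and the
population PK model fitted by an importance-sampling Monte Carlo EM
(MC-PEM).

The population model is a nonlinear mixed-effects model: each structural
parameter theta has a log-normal between-subject distribution,
theta_i = theta * exp(eta_i), eta_i ~ N(0, omega^2) with a diagonal
covariance, and the residual error on plasma concentrations is proportional
(sd = sigma * prediction).  The E-step draws importance samples of eta per
subject from a defensive mixture proposal: a multivariate t centered at the
warm-started conditional mode with the Laplace (Gauss-Newton) covariance,
plus a wide prior-scale normal component that keeps weights bounded.  The
M-step updates theta by the (damped) weighted mean of the individual
log-parameters, omega^2 by their weighted spread, and sigma by the weighted
mean squared proportional residual.  All formulations
are fitted simultaneously; every parameter is shared across formulations
except the in-vivo release rate ``vmax_invivo``, which is estimated per
formulation (theta keys ``"vmax_invivo:<formulation>"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import log_ndtr, logsumexp

from .model_core import (
    DissolutionProfile,
    DispositionParams,
    FDissParams,
    InVitroDissolutionParams,
    InVivoDissolutionParams,
    PlasmaProfile,
    SubjectParameters,
    solve_invitro_dissolution,
)
from ._fastode import rk4_conc_batch, rk4_integrate

__all__ = [
    "PopulationModel",
    "FitResult",
    "FitOptions",
    "NonIdentifiableError",
    "fit_invitro_mm",
    "fit_invitro_mm_joint",
    "fit_popk",
    "conditional_mode",
    "visual_predictive_check",
]

GLOBAL_STRUCTURAL = (
    "k_lag",
    "k_a",
    "v1",
    "v2",
    "cl",
    "cld",
    "am50_invivo",
    "imax",
    "t_get",
    "hill_stomach",
    "diss_max",
    "t_itt",
    "t_ctt",
    "hill_intestine",
)

# _fastode parameter-vector ordering
_PVEC_ORDER = (
    "imax",
    "t_get",
    "hill_stomach",
    "diss_max",
    "t_itt",
    "t_ctt",
    "hill_intestine",
    "vmax_invivo",
    "am50_invivo",
    "k_lag",
    "k_a",
    "v1",
    "v2",
    "cl",
    "cld",
)

_CONC_SCALE = 1000.0  # mg/L -> ng/mL
_PVEC_INDEX = {k: i for i, k in enumerate(_PVEC_ORDER)}


class NonIdentifiableError(ValueError):
    """Raised when the data carry no information about the parameters."""


@dataclass
class PopulationModel:
    """Population means, between-subject variances and residual error.

    ``theta`` maps structural-parameter names to population means; the
    in-vivo release rate is per-formulation under keys
    ``"vmax_invivo:<formulation>"``.  ``omega2`` maps a subset of those
    names to log-scale between-subject variances (absent = no variability).
    ``sigma`` is the proportional residual CV; with
    ``error_model="combined"`` an additive component ``sigma_add`` (ng/mL)
    is included in the residual sd.
    """

    theta: dict[str, float]
    omega2: dict[str, float]
    sigma: float
    error_model: str = "proportional"
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        for k, v in self.theta.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"theta[{k!r}] must be positive, got {v}")
        for k, v in self.omega2.items():
            if v < 0:
                raise ValueError(f"omega2[{k!r}] must be >= 0, got {v}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.error_model not in ("proportional", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")

    def formulations(self) -> list[str]:
        return sorted(k.split(":", 1)[1] for k in self.theta if k.startswith("vmax_invivo:"))

    def structural_names(self, formulation: str) -> list[str]:
        key = f"vmax_invivo:{formulation}"
        if key not in self.theta:
            raise KeyError(f"no vmax_invivo entry for formulation {formulation!r}")
        return list(GLOBAL_STRUCTURAL) + [key]

    def residual_sd(self, pred: np.ndarray) -> np.ndarray:
        if self.error_model == "proportional":
            return self.sigma * pred
        return np.sqrt(self.sigma_add**2 + (self.sigma * pred) ** 2)

    def subject_parameters(
        self,
        formulation: str,
        dose: float,
        subject_id: str = "typical",
        eta: dict[str, float] | None = None,
    ) -> SubjectParameters:
        """Individual parameters theta * exp(eta) packed into the structural
        types (population-typical subject when ``eta`` is None)."""
        eta = eta or {}
        vals = {}
        for name in self.structural_names(formulation):
            short = "vmax_invivo" if name.startswith("vmax_invivo:") else name
            vals[short] = self.theta[name] * math.exp(eta.get(name, 0.0))
        return SubjectParameters(
            f_diss=FDissParams(
                imax=min(vals["imax"], 1.0),
                t_get=vals["t_get"],
                hill_stomach=vals["hill_stomach"],
                diss_max=vals["diss_max"],
                t_itt=vals["t_itt"],
                t_ctt=vals["t_ctt"],
                hill_intestine=vals["hill_intestine"],
            ),
            dissolution=InVivoDissolutionParams(vals["vmax_invivo"], vals["am50_invivo"]),
            disposition=DispositionParams(
                vals["k_lag"], vals["k_a"], vals["v1"], vals["v2"], vals["cl"], vals["cld"]
            ),
            subject_id=subject_id,
            formulation_id=formulation,
            dose=dose,
        )


@dataclass
class FitResult:
    """Outcome of an estimation run."""

    estimates: object  # PopulationModel or InVitroDissolutionParams
    objective: list[float] = field(default_factory=list)
    converged: bool = False
    seed: int | None = None
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)


@dataclass
class FitOptions:
    """MC-PEM settings.

    n_samples : importance samples per subject per iteration.
    max_iter / tol / tol_window : stop when every estimated parameter has
        relative change < tol over tol_window consecutive iterations.
    omega_floor : lower bound on omega^2 during estimation (keeps the
        importance proposal alive for parameters whose variability shrinks
        to zero).
    fix : theta names held at their initial values (no random effect).
    rk4_step : fixed integrator step (h) used for subject predictions.
    proposal_inflation : variance inflation of the adaptive proposal.
    """

    n_samples: int = 1000
    max_iter: int = 100
    tol: float = 1e-3
    tol_window: int = 10
    seed: int = 0
    omega_floor: float = 1e-4
    fix: frozenset = frozenset()
    rk4_step: float = 0.01
    proposal_inflation: float = 2.0
    sigma_hold: int = 2
    sigma_damping: float = 0.7
    conc_floor: float = 0.5  # ng/mL floor on model predictions in the likelihood
    mode_nfev_first: int = 200  # Gauss-Newton evaluation budget per start, first iteration
    mode_nfev: int = 60  # warm-started budget, later iterations
    mode_starts: int = 5  # multi-start count for the first-iteration mode search
    defensive_weight: float = 0.1  # mixture weight of the wide exploration component
    defensive_scale: float = 1.5  # sd multiplier (vs prior) of the wide component
    proposal_df: float = 4.0  # t-distribution degrees of freedom of the proposal
    max_step_log: float = 0.25  # per-iteration cap on |log theta| updates
    omega_damping: float = 0.5  # geometric damping of omega^2 updates
    omega_cap: float = 4.0  # upper bound on estimated omega^2
    average_last: int = 0  # >0: report the geometric mean of the last K iterates
    update_omega: bool = True  # False: hold omega^2 at its initial values
    blq: str = "M1"  # censoring handling: "M1" drop, "M3" censored likelihood
    lloq: float = 5.0  # ng/mL, used by the M3 likelihood
    trace: bool = False  # record per-iteration estimates in diagnostics


# ---------------------------------------------------------------------------
# In-vitro Michaelis-Menten fit
# ---------------------------------------------------------------------------


def fit_invitro_mm(
    profiles: list[DissolutionProfile],
    ph: str | None = "1.2",
) -> FitResult:
    """Least-squares Michaelis-Menten fit of pooled dissolution vessels for
    one formulation.

    Profiles are pooled across vessels (restricted to ``ph`` unless None),
    percent dissolved is normalized to fraction of dose, and
    (vmax_invitro, am50_invitro) are estimated in log space by multi-start
    least squares: vmax started from the maximal observed release slope,
    am50 from {0.1, 0.3, 0.5}; the start with the lowest SSE wins, ties
    broken by the smallest am50.
    """
    if not profiles:
        raise ValueError("no dissolution profiles supplied")
    use = [p for p in profiles if ph is None or p.ph_label == ph]
    if not use:
        raise ValueError(f"no profiles at pH {ph!r}")
    forms = {p.formulation_id for p in use}
    if len(forms) > 1:
        raise ValueError(f"profiles span multiple formulations: {sorted(forms)}")

    t = np.concatenate([p.times for p in use])
    y = np.concatenate([p.pct_dissolved for p in use]).astype(float)
    # accept either % or fraction-of-dose input
    if np.nanmax(y) > 1.5:
        y = y / 100.0
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    if np.nanmax(y) <= 1e-9 or np.ptp(y) <= 1e-9:
        raise NonIdentifiableError("flat dissolution profile: release parameters are not identifiable")
    if np.unique(t[t > 0]).size < 4:
        raise ValueError("need >= 4 distinct positive time points to fit the release model")

    # vmax start: maximal observed release slope (fraction/h) on the mean curve
    tm = np.unique(t)
    ym = np.array([y[t == ti].mean() for ti in tm])
    t0 = np.concatenate([[0.0], tm])
    y0 = np.concatenate([[0.0], ym])
    slopes = np.diff(y0) / np.diff(t0)
    vmax0 = max(float(slopes.max()), 1e-3)

    def resid(logp: np.ndarray) -> np.ndarray:
        p = InVitroDissolutionParams(*np.exp(logp))
        pred = np.interp(t, tm, solve_invitro_dissolution(p, tm))
        return pred - y

    starts = [(vmax0, a0) for a0 in (0.1, 0.3, 0.5)]
    best = None
    for v0, a0 in starts:
        sol = least_squares(resid, np.log([v0, a0]), method="lm", xtol=1e-12, ftol=1e-12)
        sse = float(2 * sol.cost)
        key = (round(sse, 12), float(np.exp(sol.x[1])))
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    est = InVitroDissolutionParams(*np.exp(sol.x))
    return FitResult(
        estimates=est,
        objective=[float(2 * sol.cost)],
        converged=bool(sol.success),
        n_iter=1,
        diagnostics={"sse": float(2 * sol.cost), "n_obs": int(t.size), "formulation": forms.pop()},
    )


def fit_invitro_mm_joint(
    profiles: list[DissolutionProfile],
    ph: str | None = "1.2",
) -> FitResult:
    """Joint Michaelis-Menten fit across formulations with a single shared
    ``am50_invitro`` and one ``vmax_invitro`` per formulation.

    This mirrors how multi-formulation dissolution runs are usually
    modelled (the half-rate amount is a drug/medium property, the maximum
    rate a formulation property) and resolves the vmax/am50 ridge of
    very fast tablets whose rising phase contains a single sample.
    Returns a FitResult whose ``estimates`` maps formulation ->
    InVitroDissolutionParams (sharing am50).
    """
    use = [p for p in profiles if ph is None or p.ph_label == ph]
    if not use:
        raise ValueError(f"no profiles at pH {ph!r}")
    forms = sorted({p.formulation_id for p in use})
    data = {}
    for form in forms:
        t = np.concatenate([p.times for p in use if p.formulation_id == form])
        y = np.concatenate([p.pct_dissolved for p in use if p.formulation_id == form]).astype(float)
        if np.nanmax(y) > 1.5:
            y = y / 100.0
        if np.nanmax(y) <= 1e-9 or np.ptp(y) <= 1e-9:
            raise NonIdentifiableError(f"flat dissolution profile for {form!r}")
        order = np.argsort(t, kind="stable")
        data[form] = (t[order], y[order])

    def resid(logp: np.ndarray) -> np.ndarray:
        am50 = math.exp(logp[0])
        out = []
        for j, form in enumerate(forms):
            p = InVitroDissolutionParams(math.exp(logp[1 + j]), am50)
            t, y = data[form]
            tm = np.unique(t)
            out.append(np.interp(t, tm, solve_invitro_dissolution(p, tm)) - y)
        return np.concatenate(out)

    vmax0 = []
    for form in forms:
        t, y = data[form]
        tm = np.unique(t)
        ym = np.array([y[t == ti].mean() for ti in tm])
        slopes = np.diff(np.concatenate([[0.0], ym])) / np.diff(np.concatenate([[0.0], tm]))
        vmax0.append(max(float(slopes.max()), 1e-3))
    best = None
    for a0 in (0.1, 0.3, 0.5):
        x0 = np.log(np.concatenate([[a0], vmax0]))
        sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    am50 = float(np.exp(best.x[0]))
    estimates = {
        form: InVitroDissolutionParams(float(np.exp(best.x[1 + j])), am50)
        for j, form in enumerate(forms)
    }
    return FitResult(
        estimates=estimates,
        objective=[float(2 * best.cost)],
        converged=bool(best.success),
        n_iter=1,
        diagnostics={"sse": float(2 * best.cost), "shared_am50": am50, "formulations": forms},
    )


# ---------------------------------------------------------------------------
# Population fit (importance-sampling MC-PEM)
# ---------------------------------------------------------------------------


@dataclass
class _Subject:
    profile: PlasmaProfile
    re_names: list[str]  # estimated parameter names, subject order
    times: np.ndarray  # quantifiable observation times
    y: np.ndarray  # quantifiable concentrations
    prop_mean: np.ndarray  # proposal center (eta space)
    prop_var: np.ndarray  # proposal variances
    blq_times: np.ndarray | None = None  # censored observation times (M3)


def _pvec_from_values(vals: dict[str, float]) -> np.ndarray:
    return np.array([vals[k] for k in _PVEC_ORDER])


def _predict_conc(pvec: np.ndarray, dose: float, times: np.ndarray, h: float) -> np.ndarray:
    states = rk4_integrate(pvec, dose, times, h)
    return states[:, 3] / pvec[11] * _CONC_SCALE


def _subject_loglik(y: np.ndarray, f: np.ndarray, model: PopulationModel, floor: float = 0.5) -> float:
    f = np.maximum(f, floor)
    sd = np.maximum(model.residual_sd(f), 1e-12)
    r = (y - f) / sd
    return float(-0.5 * np.sum(r * r) - np.sum(np.log(sd)) - 0.5 * y.size * math.log(2 * math.pi))


def _prepare_subjects(cohort: list[PlasmaProfile], model: PopulationModel, fix: frozenset) -> list[_Subject]:
    subjects = []
    for prof in cohort:
        q = prof.quantifiable()
        keep = q.concentrations > 0
        times, y = q.times[keep], q.concentrations[keep]
        if y.size == 0:
            warnings.warn(
                f"subject {prof.subject_id!r}: all observations below LLOQ; excluded from the fit"
            )
            continue
        names = [n for n in model.structural_names(prof.formulation_id) if n not in fix]
        if not names:
            raise ValueError("all parameters are fixed; nothing to estimate")
        om = np.array([max(model.omega2.get(n, 0.0), 1e-4) for n in names])
        blq_times = prof.times[prof.blq_flags & (prof.times > 0)]
        subjects.append(
            _Subject(prof, names, times, y, np.zeros(len(names)), om.copy(), blq_times)
        )
    if not subjects:
        raise ValueError("no usable subjects in the cohort")
    return subjects


def _base_pvec(model: PopulationModel, formulation: str) -> np.ndarray:
    vals = {}
    for name in model.structural_names(formulation):
        short = "vmax_invivo" if name.startswith("vmax_invivo:") else name
        vals[short] = model.theta[name]
    return _pvec_from_values(vals)


def _re_columns(re_names: list[str]) -> list[int]:
    return [
        _PVEC_INDEX["vmax_invivo" if n.startswith("vmax_invivo:") else n] for n in re_names
    ]


def _loglik_batch(y: np.ndarray, conc: np.ndarray, model: PopulationModel, floor: float = 0.5) -> np.ndarray:
    """Row-wise log-likelihood of observations for a (n_samples, n_obs)
    prediction matrix (predictions floored to keep the proportional error
    model defined where the model predicts ~0)."""
    f = np.maximum(conc, floor)
    sd = np.maximum(model.residual_sd(f), 1e-12)
    r = (y - f) / sd
    return -0.5 * np.sum(r * r, axis=1) - np.sum(np.log(sd), axis=1) - 0.5 * y.size * math.log(2 * math.pi)


def _eta_to_pvec(model: PopulationModel, sub: _Subject, eta: np.ndarray) -> np.ndarray:
    form = sub.profile.formulation_id
    vals = {}
    for name in model.structural_names(form):
        short = "vmax_invivo" if name.startswith("vmax_invivo:") else name
        v = model.theta[name]
        if name in sub.re_names:
            v *= math.exp(eta[sub.re_names.index(name)])
        vals[short] = v
    return _pvec_from_values(vals)


def _joint_residuals(
    model: PopulationModel,
    sub: _Subject,
    eta: np.ndarray,
    omega2: np.ndarray,
    h: float,
    floor: float,
) -> np.ndarray:
    """Stacked residual vector whose 0.5*||r||^2 is (up to the slowly
    varying log-determinant term) the negative per-subject joint density:
    scaled data residuals followed by prior-scaled random effects."""
    pvec = _eta_to_pvec(model, sub, eta)
    with np.errstate(invalid="ignore", over="ignore"):
        f = _predict_conc(pvec, sub.profile.dose, sub.times, h)
    f = np.nan_to_num(f, nan=1e9, posinf=1e9, neginf=0.0)  # overflowed integrations
    fc = np.maximum(f, floor)
    sd = np.maximum(model.residual_sd(fc), 1e-12)
    return np.concatenate([(sub.y - fc) / sd, eta / np.sqrt(omega2)])


def _laplace_mode(
    model: PopulationModel,
    sub: _Subject,
    omega2: np.ndarray,
    h: float,
    x0: np.ndarray,
    max_nfev: int,
    floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional mode by damped Gauss-Newton on the joint residuals and
    the Laplace covariance (inverse Gauss-Newton Hessian) at the mode."""
    d = len(omega2)
    sol = least_squares(
        lambda e: _joint_residuals(model, sub, e, omega2, h, floor),
        x0,
        method="lm",
        max_nfev=max_nfev,
        xtol=1e-10,
        ftol=1e-10,
    )
    mode = sol.x if np.all(np.isfinite(sol.x)) else x0
    hess = sol.jac.T @ sol.jac + 1e-9 * np.eye(d)
    try:
        cov = np.linalg.inv(hess)
        cov = 0.5 * (cov + cov.T)
        np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    except np.linalg.LinAlgError:
        cov = np.diag(omega2)
    return mode, cov


def conditional_mode(
    profile: PlasmaProfile,
    model: PopulationModel,
    rk4_step: float = 0.01,
    max_nfev: int = 600,
) -> SubjectParameters:
    """Empirical-Bayes estimate: the eta maximizing the per-subject joint
    density of data and random effects, packed into SubjectParameters.

    Parameters without between-subject variability stay at the population
    means; with all omega^2 == 0 the population-typical subject is
    returned.  Falls back to the population means with a warning if the
    optimizer fails.
    """
    q = profile.quantifiable()
    keep = q.concentrations > 0
    if int(keep.sum()) == 0:
        raise ValueError(f"subject {profile.subject_id!r} has no quantifiable observations")
    names = [
        n
        for n in model.structural_names(profile.formulation_id)
        if model.omega2.get(n, 0.0) > 1e-12
    ]
    if not names:
        return model.subject_parameters(profile.formulation_id, profile.dose, profile.subject_id)
    sub = _Subject(
        profile,
        names,
        q.times[keep],
        q.concentrations[keep],
        np.zeros(len(names)),
        np.zeros(len(names)),
    )
    omega2 = np.array([model.omega2[n] for n in names])
    try:
        eta, _ = _laplace_mode(model, sub, omega2, rk4_step, np.zeros(len(names)), max_nfev, 0.5)
        if not np.all(np.isfinite(eta)):
            raise RuntimeError("non-finite mode")
    except Exception:
        warnings.warn(
            f"conditional-mode search failed for subject {profile.subject_id!r}; "
            "falling back to population means"
        )
        eta = np.zeros(len(names))
    return model.subject_parameters(
        profile.formulation_id, profile.dose, profile.subject_id, dict(zip(names, eta))
    )


def fit_popk(
    cohort: list[PlasmaProfile],
    init: PopulationModel,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the population model to all formulations simultaneously by
    importance-sampling MC-PEM.

    Observations below the LLOQ are excluded from the likelihood (M1);
    subjects with no quantifiable observations are dropped with a warning.
    Deterministic given ``options.seed``.  A run that exhausts
    ``max_iter`` without meeting the tolerance returns with
    ``converged=False`` (never silently).
    """
    options = options or FitOptions()
    model = replace(init, theta=dict(init.theta), omega2=dict(init.omega2))
    subjects = _prepare_subjects(cohort, model, options.fix)
    est_names = sorted({n for s in subjects for n in s.re_names})
    rng = np.random.default_rng(options.seed)
    h = options.rk4_step

    objective: list[float] = []
    objective_se: list[float] = []
    trace: list[dict] = []
    theta_history: list[dict[str, float]] = []
    stable = 0
    converged = False
    n_iter = 0
    for it in range(options.max_iter):
        n_iter = it + 1
        prev_theta = dict(model.theta)
        prev_sigma = model.sigma

        post_mean: dict[str, list[float]] = {n: [] for n in est_names}
        post_var: dict[str, list[float]] = {n: [] for n in est_names}
        sub_post: list[tuple[_Subject, np.ndarray, np.ndarray]] = []
        ll_total = 0.0
        ll_var_total = 0.0
        sq_prop_resid = 0.0
        n_obs_total = 0
        ess_min = np.inf

        for sub in subjects:
            d = len(sub.re_names)
            omega2 = np.maximum(
                np.array([model.omega2.get(n, 0.0) for n in sub.re_names]), options.omega_floor
            )
            # proposal center: Laplace approximation at the conditional mode
            # (multi-start in the first iteration, warm-started afterwards)
            if it == 0 and options.mode_starts > 1:
                starts = [sub.prop_mean] + [
                    rng.standard_normal(d) * 0.5 for _ in range(options.mode_starts - 1)
                ]
                best = None
                for x0 in starts:
                    m_k, c_k = _laplace_mode(
                        model, sub, omega2, h, x0, options.mode_nfev_first, options.conc_floor
                    )
                    obj = 0.5 * float(
                        np.sum(_joint_residuals(model, sub, m_k, omega2, h, options.conc_floor) ** 2)
                    )
                    if best is None or obj < best[0]:
                        best = (obj, m_k, c_k)
                mode, cov = best[1], best[2]
            else:
                mode, cov = _laplace_mode(
                    model, sub, omega2, h, sub.prop_mean, options.mode_nfev, options.conc_floor
                )
            sub.prop_mean = mode
            prop_cov = cov * options.proposal_inflation
            try:
                chol = np.linalg.cholesky(prop_cov + 1e-12 * np.eye(d))
            except np.linalg.LinAlgError:
                chol = np.diag(np.sqrt(np.maximum(np.diag(prop_cov), 1e-8)))

            # defensive mixture: a heavy-tailed multivariate-t around the
            # mode plus a wide prior-scale component, so that importance
            # weights stay bounded and the sampler can escape local basins
            pd_w = options.defensive_weight
            df = options.proposal_df
            wide_sd = options.defensive_scale * np.sqrt(omega2)
            n_wide = int(round(pd_w * options.n_samples)) if pd_w > 0 else 0
            n_lap = options.n_samples - n_wide
            z = rng.standard_normal((n_lap, d))
            g = rng.chisquare(df, size=n_lap) / df
            etas_lap = mode + (z @ chol.T) / np.sqrt(g)[:, None]
            etas_wide = rng.standard_normal((n_wide, d)) * wide_sd
            etas = np.vstack([etas_lap, etas_wide])

            base = _base_pvec(model, sub.profile.formulation_id)
            pvecs = np.tile(base, (options.n_samples, 1))
            for j, col in enumerate(_re_columns(sub.re_names)):
                pvecs[:, col] = base[col] * np.exp(etas[:, j])
            use_m3 = options.blq == "M3" and sub.blq_times is not None and sub.blq_times.size
            if use_m3:
                eval_times = np.unique(np.concatenate([sub.times, sub.blq_times]))
                iq = np.searchsorted(eval_times, sub.times)
                ib = np.searchsorted(eval_times, sub.blq_times)
                conc_all = rk4_conc_batch(pvecs, sub.profile.dose, eval_times, h)
                conc = conc_all[:, iq]
            else:
                conc = rk4_conc_batch(pvecs, sub.profile.dose, sub.times, h)
            with np.errstate(invalid="ignore", over="ignore"):
                ll = _loglik_batch(sub.y, conc, model, options.conc_floor)
                if use_m3:
                    # censored contribution: P(observation < LLOQ | eta)
                    fb = np.maximum(conc_all[:, ib], options.conc_floor)
                    sdb = np.maximum(model.residual_sd(fb), 1e-12)
                    ll = ll + np.sum(log_ndtr((options.lloq - fb) / sdb), axis=1)
            # samples whose parameters overflow the integrator get zero weight
            ll = np.where(np.isfinite(ll), ll, -np.inf)
            if not np.any(np.isfinite(ll)):
                raise RuntimeError(
                    f"non-finite likelihood for every importance sample of "
                    f"subject {sub.profile.subject_id!r}"
                )
            log2pi = math.log(2 * math.pi)
            lp = -0.5 * (np.sum(etas**2 / omega2, axis=1) + np.sum(np.log(omega2)) + d * log2pi)
            # mixture proposal density (multivariate t + wide normal)
            dev = etas - mode
            sol_ = np.linalg.solve(chol, dev.T)
            maha = np.sum(sol_**2, axis=0)
            logq_lap = (
                math.lgamma((df + d) / 2)
                - math.lgamma(df / 2)
                - 0.5 * d * math.log(df * math.pi)
                - np.sum(np.log(np.diag(chol)))
                - 0.5 * (df + d) * np.log1p(maha / df)
            )
            logq_wide = (
                -0.5 * np.sum((etas / wide_sd) ** 2, axis=1)
                - np.sum(np.log(wide_sd))
                - 0.5 * d * log2pi
            )
            if n_wide > 0:
                lq = np.logaddexp(math.log(1 - pd_w) + logq_lap, math.log(pd_w) + logq_wide)
            else:
                lq = logq_lap
            logw = ll + lp - lq
            with np.errstate(invalid="ignore", over="ignore"):
                fc = np.maximum(conc, options.conc_floor)
                resid2 = np.sum(((sub.y - fc) / fc) ** 2, axis=1)
            resid2 = np.where(np.isfinite(resid2), resid2, 0.0)

            lse = float(logsumexp(logw))
            ll_total += lse - math.log(options.n_samples)
            w = np.exp(logw - lse)
            ess = 1.0 / float(np.sum(w * w))
            ess_min = min(ess_min, ess)
            # delta-method MC variance of the log importance-sampling mean:
            # Var(log Wbar) ~= sum(w_norm^2) - 1/n
            ll_var_total += max(float(np.sum(w * w)) - 1.0 / options.n_samples, 0.0)

            mu = w @ etas
            second = w @ (etas**2)
            var = np.maximum(second - mu**2, 0.0)
            sub_post.append((sub, mu, var))
            for j, n in enumerate(sub.re_names):
                post_mean[n].append(mu[j])
                post_var[n].append(var[j])
            sq_prop_resid += float(w @ resid2)
            n_obs_total += sub.y.size

        # ----- M-step (damped) -----
        deltas_used: dict[str, float] = {}
        for n in est_names:
            mus = np.array(post_mean[n])
            vars_ = np.array(post_var[n])
            delta = float(np.clip(mus.mean(), -options.max_step_log, options.max_step_log))
            deltas_used[n] = delta
            model.theta[n] *= math.exp(delta)
            if options.update_omega:
                om_mle = max(float((vars_ + (mus - delta) ** 2).mean()), options.omega_floor)
                g_om = options.omega_damping
                om_new = model.omega2.get(n, om_mle) ** (1 - g_om) * om_mle**g_om
                model.omega2[n] = float(np.clip(om_new, options.omega_floor, options.omega_cap))
        # damped residual-error update (held for the first iterations while
        # the proposals are still diffuse)
        if n_iter > options.sigma_hold:
            sigma_mle = math.sqrt(sq_prop_resid / n_obs_total)
            lo, hi = options.sigma_damping, 1.0 / options.sigma_damping
            model.sigma = max(min(sigma_mle, hi * prev_sigma), lo * prev_sigma, 1e-6)

        # shift warm-start modes: theta absorbed the (clipped) shift per parameter
        for sub, mu, var in sub_post:
            deltas = np.array([deltas_used[n] for n in sub.re_names])
            sub.prop_mean = sub.prop_mean - deltas
            sub.prop_var = np.maximum(var, 1e-8)

        theta_history.append(dict(model.theta))
        objective.append(ll_total)
        objective_se.append(math.sqrt(ll_var_total))
        if options.trace:
            trace.append(
                {
                    "theta": dict(model.theta),
                    "omega2": dict(model.omega2),
                    "sigma": model.sigma,
                    "ess_min": float(ess_min),
                    "post_mean": {n: list(post_mean[n]) for n in est_names},
                }
            )

        rel = max(
            abs(model.theta[n] - prev_theta[n]) / prev_theta[n] for n in est_names
        )
        # sigma assessed on a floored denominator so that a residual CV
        # collapsing toward zero (noise-free data) does not block convergence
        rel = max(rel, abs(model.sigma - prev_sigma) / max(prev_sigma, 0.01))
        stable = stable + 1 if rel < options.tol else 0
        if stable >= options.tol_window:
            converged = True
            break

    # iterate averaging: the geometric mean over the trailing window damps
    # the Monte Carlo jitter of the stochastic EM updates
    if options.average_last > 1 and len(theta_history) > 1:
        tail = theta_history[-options.average_last :]
        model.theta = {
            n: float(np.exp(np.mean([math.log(t[n]) for t in tail]))) for n in model.theta
        }
    diagnostics = {
        "trace": trace,
        "objective_se": objective_se,
        "ess_min": float(ess_min),
        "n_subjects": len(subjects),
        "conditional_modes": {
            s.profile.subject_id: dict(zip(s.re_names, s.prop_mean.tolist())) for s in subjects
        },
    }
    if not converged:
        warnings.warn(
            f"MC-PEM did not meet the convergence criterion in {options.max_iter} iterations"
        )
    return FitResult(
        estimates=model,
        objective=objective,
        converged=converged,
        seed=options.seed,
        n_iter=n_iter,
        diagnostics=diagnostics,
    )


def visual_predictive_check(
    model: PopulationModel,
    design,
    n_sim: int = 200,
    seed: int = 0,
):
    """Simulated 5th/50th/95th percentile concentration bands per
    formulation and sampling time (proportional residual noise included).

    ``design`` is a :class:`~popivivc.synthetic_data.StudyDesign`; returns a
    pandas DataFrame with columns formulation, time_h, p5, p50, p95.
    """
    import pandas as pd

    from .synthetic_data import sample_individual

    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable percentile bands")
    rng = np.random.default_rng(seed)
    times = np.asarray(design.plasma_times, dtype=float)
    rows = []
    for form, dose in design.formulations:
        sims = np.empty((n_sim, times.size))
        for i in range(n_sim):
            sp = sample_individual(model, form, rng, dose=dose, subject_id=f"vpc{i}")
            pvec = _pvec_from_values(
                {
                    "imax": sp.f_diss.imax,
                    "t_get": sp.f_diss.t_get,
                    "hill_stomach": sp.f_diss.hill_stomach,
                    "diss_max": sp.f_diss.diss_max,
                    "t_itt": sp.f_diss.t_itt,
                    "t_ctt": sp.f_diss.t_ctt,
                    "hill_intestine": sp.f_diss.hill_intestine,
                    "vmax_invivo": sp.dissolution.vmax_invivo,
                    "am50_invivo": sp.dissolution.am50_invivo,
                    "k_lag": sp.disposition.k_lag,
                    "k_a": sp.disposition.k_a,
                    "v1": sp.disposition.v1,
                    "v2": sp.disposition.v2,
                    "cl": sp.disposition.cl,
                    "cld": sp.disposition.cld,
                }
            )
            f = _predict_conc(pvec, dose, times, 0.01)
            noise = model.sigma * rng.standard_normal(times.size)
            sims[i] = np.maximum(f * (1.0 + noise), 0.0)
        p5, p50, p95 = np.percentile(sims, [5, 50, 95], axis=0)
        for j, t in enumerate(times):
            rows.append(
                {"formulation": form, "time_h": t, "p5": p5[j], "p50": p50[j], "p95": p95[j]}
            )
    return pd.DataFrame(rows)
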