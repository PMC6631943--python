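"""Non-compartmental analysis of plasma concentration-time profiles.

Exposure metrics are model-free: Cmax/Tmax read directly from the
observations, AUC by the linear trapezoidal rule to the last quantifiable
point (a log-linear-down variant is available), the terminal slope
lambda_z by log-linear regression on an automatically selected terminal
point set, and the derived t1/2, AUC_inf, CL/F and Vz/F.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import PlasmaProfile

__all__ = ["NCAResult", "auc_trapezoid", "compute_lambda_z", "compute_nca", "nca_summary_table"]


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental metrics for one profile.

    Units: cmax ng/mL; tmax h; lambda_z 1/h; t_half h; auc_all and auc_inf
    ng.h/mL; vz_f L; cl_f mL/min; relative_ba % (None without a reference).
    """

    cmax: float
    tmax: float
    lambda_z: float
    t_half: float
    auc_all: float
    auc_inf: float
    vz_f: float
    cl_f: float
    n_lambda_points: int
    r2_adj: float
    relative_ba: float | None = None
    extrapolation_warning: bool = False


def _adj_r2(x: np.ndarray, logy: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and adjusted r^2 of a log-linear regression."""
    n = x.size
    slope, intercept = np.polyfit(x, logy, 1)
    pred = slope * x + intercept
    sst = float(np.sum((logy - logy.mean()) ** 2))
    sse = float(np.sum((logy - pred) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else -np.inf
    r2a = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, intercept, r2a


def compute_lambda_z(profile: PlasmaProfile) -> tuple[float, int, float]:
    """Terminal elimination rate constant (1/h) with the number of points
    used and the adjusted r^2 of the log-linear regression.

    Candidate point sets are all suffixes (>= 3 points) of the positive
    quantifiable observations after Tmax, with the Cmax observation itself
    excluded; the suffix maximizing adjusted r^2 wins.  Raises when fewer
    than 3 usable points exist or the best regression has a non-negative
    slope (no terminal decline).
    """
    q = profile.quantifiable()
    keep = q.concentrations > 0
    t, c = q.times[keep], q.concentrations[keep]
    if c.size == 0:
        raise ValueError("no positive quantifiable concentrations")
    i_max = int(c.argmax())
    t_term, c_term = t[i_max + 1 :], c[i_max + 1 :]
    if t_term.size < 3:
        raise ValueError(
            f"need >= 3 post-Tmax points for lambda_z, have {t_term.size}"
        )
    logc = np.log(c_term)
    best = None
    for start in range(t_term.size - 2):
        slope, _, r2a = _adj_r2(t_term[start:], logc[start:])
        if best is None or r2a > best[0] + 1e-12:
            best = (r2a, slope, t_term.size - start)
    r2a, slope, npts = best
    if slope >= 0:
        raise ValueError("terminal phase is not declining; lambda_z undefined")
    return -slope, npts, r2a


def auc_trapezoid(t, c, method: str = "linear") -> float:
    """Area under a concentration-time polyline: ``"linear"`` trapezoids or
    ``"linlog"`` (linear up, logarithmic down) trapezoids."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if method == "linear":
        return float(np.trapezoid(c, t))
    # linear-up / log-down
    auc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def compute_nca(
    profile: PlasmaProfile,
    dose: float | None = None,
    reference: NCAResult | None = None,
    reference_dose: float | None = None,
    auc_method: str = "linear",
) -> NCAResult:
    """Full non-compartmental workup of one profile.

    Leading below-LLOQ observations are treated as zero for the AUC;
    below-LLOQ observations elsewhere are dropped.  ``auc_method`` is
    ``"linear"`` (default) or ``"linlog"`` (linear up, log down).
    AUC_inf = AUC_all + C_last/lambda_z; CL/F is reported in mL/min
    (dose[mg] * 1e6 / AUC_inf[ng.h/mL] / 60) and Vz/F in L.  When a
    reference result and dose are given, relative bioavailability is the
    ratio of dose-normalized AUC_inf in percent.
    """
    dose = profile.dose if dose is None else dose
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    if auc_method not in ("linear", "linlog"):
        raise ValueError(f"unknown AUC method {auc_method!r}")

    t_all, c_all, blq = profile.times, profile.concentrations, profile.blq_flags
    # leading BLQ (pre-absorption) contribute zeros; later BLQ are dropped
    first_q = np.flatnonzero(~blq & (c_all > 0))
    if first_q.size == 0:
        raise ValueError("profile has no positive quantifiable concentrations")
    lead = blq & (np.arange(t_all.size) < first_q[0])
    keep = (~blq & (c_all >= 0)) | lead
    t = t_all[keep]
    c = np.where(blq[keep], 0.0, c_all[keep])

    cmax = float(c.max())
    tmax = float(t[int(c.argmax())])
    last_pos = np.flatnonzero(c > 0)[-1]
    auc_all = auc_trapezoid(t, c, auc_method)  # to the last observation

    lambda_z, npts, r2a = compute_lambda_z(profile)
    t_half = math.log(2.0) / lambda_z
    c_last = float(c[last_pos])
    auc_extra = c_last / lambda_z
    auc_inf = auc_all + auc_extra
    extrap_warn = auc_extra / auc_inf > 0.5
    if extrap_warn:
        warnings.warn(
            f"AUC extrapolation is {100 * auc_extra / auc_inf:.0f}% of AUC_inf "
            f"for subject {profile.subject_id!r}"
        )
    cl_f = dose * 1e6 / auc_inf / 60.0  # mL/min
    vz_f = (cl_f * 60.0 / 1000.0) / lambda_z  # L
    rel_ba = None
    if reference is not None:
        if reference_dose is None or reference_dose <= 0:
            raise ValueError("reference_dose must be supplied with a reference result")
        rel_ba = 100.0 * (auc_inf / dose) / (reference.auc_inf / reference_dose)
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        lambda_z=lambda_z,
        t_half=t_half,
        auc_all=auc_all,
        auc_inf=auc_inf,
        vz_f=vz_f,
        cl_f=cl_f,
        n_lambda_points=npts,
        r2_adj=r2a,
        relative_ba=rel_ba,
        extrapolation_warning=extrap_warn,
    )


def nca_summary_table(profiles: list[PlasmaProfile], reference_formulation: str = "IR", auc_method: str = "linear"):
    """Per-subject NCA with group mean +/- SD rows, one formulation block
    at a time; relative bioavailability is computed against the mean
    dose-normalized AUC_inf of the reference formulation.

    Returns a pandas DataFrame (one row per subject plus ``mean``/``sd``
    rows per formulation).
    """
    import pandas as pd

    results = []
    for p in profiles:
        try:
            r = compute_nca(p, auc_method=auc_method)
            row = {
                "cmax_ng_ml": r.cmax,
                "tmax_h": r.tmax,
                "t_half_h": r.t_half,
                "auc_all": r.auc_all,
                "auc_inf": r.auc_inf,
                "vz_f_l": r.vz_f,
                "cl_f_ml_min": r.cl_f,
            }
        except ValueError as err:
            # terminal phase not estimable (too few points or no decline):
            # keep the model-free metrics, leave the lambda_z-derived ones out
            warnings.warn(f"subject {p.subject_id!r}: {err}; reporting partial NCA")
            q = p.quantifiable()
            keep = q.concentrations > 0
            t, c = q.times[keep], q.concentrations[keep]
            row = {
                "cmax_ng_ml": float(c.max()),
                "tmax_h": float(t[int(c.argmax())]),
                "t_half_h": np.nan,
                "auc_all": auc_trapezoid(p.times, np.where(p.blq_flags, 0.0, p.concentrations), auc_method),
                "auc_inf": np.nan,
                "vz_f_l": np.nan,
                "cl_f_ml_min": np.nan,
            }
        row.update(
            {"formulation_id": p.formulation_id, "subject_id": p.subject_id, "dose_mg": p.dose}
        )
        results.append(row)
    df = pd.DataFrame(results)
    ref = df[df.formulation_id == reference_formulation]
    ref_dn_auc = (ref.auc_inf / ref.dose_mg).mean() if len(ref) else np.nan
    df["relative_ba_pct"] = 100.0 * (df.auc_inf / df.dose_mg) / ref_dn_auc
    metric_cols = df.columns.drop(["formulation_id", "subject_id"])
    blocks = []
    for form, g in df.groupby("formulation_id", sort=False):
        blocks.append(g)
        for stat, row in (("mean", g[metric_cols].mean()), ("sd", g[metric_cols].std(ddof=1))):
            srow = row.to_dict()
            srow.update({"formulation_id": form, "subject_id": stat})
            blocks.append(pd.DataFrame([srow]))
    return pd.concat(blocks, ignore_index=True)[df.columns]
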