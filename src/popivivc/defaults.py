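"""Reference parameter values and study design constants.

These are published population estimates for sildenafil immediate-release
(IR, 20 mg) and sustained-release (SR, 60 mg) tablets in fasted Beagle
dogs, together with the dissolution-tester and blood-sampling schedules of
that study.  They serve as the defaults of the synthetic-data generator and
as the worked-example inputs throughout the package.

``BSV`` entries are between-subject variances of log-scale random effects
(exponential variability model, theta_i = theta * exp(eta)).
"""

from __future__ import annotations

import numpy as np

from .model_core import (
    DispositionParams,
    FDissParams,
    InVitroDissolutionParams,
    InVivoDissolutionParams,
    SubjectParameters,
)

FORMULATIONS: tuple[str, ...] = ("IR", "SR_fast", "SR_medium", "SR_slow")

#: Label dose in mg per formulation.
DOSES: dict[str, float] = {"IR": 20.0, "SR_fast": 60.0, "SR_medium": 60.0, "SR_slow": 60.0}

#: Blood sampling schedule, h (19 samples over 48 h).
PLASMA_TIMES: np.ndarray = np.array(
    [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0, 12.0, 24.0, 36.0, 48.0]
)

#: Dissolution-tester sampling schedule, h (14 samples over 24 h).
DISSOLUTION_TIMES: np.ndarray = np.array(
    [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0]
)

#: Assay lower limit of quantification, ng/mL.
LLOQ: float = 5.0

#: Hill/transit parameters of the dissolved fraction (population means).
FDISS = FDissParams(
    imax=0.992,
    t_get=0.73,
    hill_stomach=16.7,
    diss_max=0.115,
    t_itt=2.18,
    t_ctt=4.1,
    hill_intestine=13.1,
)

#: Two-compartment disposition population means.
DISPOSITION = DispositionParams(k_lag=3.13, k_a=4.37, v1=22.0, v2=31.0, cl=49.2, cld=9.97)

#: Dose-normalized in-vitro Michaelis-Menten release rate (1/h) per formulation.
VMAX_INVITRO: dict[str, float] = {"IR": 6.58, "SR_fast": 1.40, "SR_medium": 0.358, "SR_slow": 0.124}

#: Shared dose-normalized in-vitro half-rate amount (fraction of dose).
AM50_INVITRO: float = 0.395

#: Dose-normalized in-vivo release rate (1/h) per formulation.
VMAX_INVIVO: dict[str, float] = {"IR": 4.42, "SR_fast": 1.71, "SR_medium": 0.781, "SR_slow": 0.219}

#: Shared dose-normalized in-vivo half-rate amount (fraction of dose).
AM50_INVIVO: float = 0.315

#: Between-subject variances (log scale) of the population model.
BSV: dict[str, float] = {
    "v1": 0.157,
    "v2": 0.751,
    "cl": 0.379,
    "cld": 0.2,
    "k_lag": 0.497,
    "k_a": 0.952,
    "t_get": 0.385,
    "imax": 0.0027,
    "hill_stomach": 0.0316,
    "t_itt": 0.434,
    "t_ctt": 0.11,
    "diss_max": 0.359,
    "hill_intestine": 0.0316,
    "am50_invivo": 0.105,
    "vmax_invivo:IR": 0.416,
    "vmax_invivo:SR_fast": 0.145,
    "vmax_invivo:SR_medium": 0.295,
    "vmax_invivo:SR_slow": 0.255,
}

#: Between-vessel variability reported with the in-vitro fits.
BSV_INVITRO: dict[str, float] = {
    "am50_invitro": 0.0316,
    "vmax_invitro:IR": 0.0283,
    "vmax_invitro:SR_fast": 0.147,
    "vmax_invitro:SR_medium": 0.0247,
    "vmax_invitro:SR_slow": 0.0333,
}

#: Default proportional residual-error CV of the synthetic cohorts (the
#: source study does not report one; see docs/methods.md).
SIGMA_PROP: float = 0.15


def invitro_params(formulation: str) -> InVitroDissolutionParams:
    """Reference in-vitro release parameters for one formulation."""
    return InVitroDissolutionParams(VMAX_INVITRO[formulation], AM50_INVITRO)


def typical_subject(formulation: str, subject_id: str = "typical") -> SubjectParameters:
    """Population-typical individual for one formulation at its label dose."""
    return SubjectParameters(
        f_diss=FDISS,
        dissolution=InVivoDissolutionParams(VMAX_INVIVO[formulation], AM50_INVIVO),
        disposition=DISPOSITION,
        subject_id=subject_id,
        formulation_id=formulation,
        dose=DOSES[formulation],
    )


def reference_population():
    """Reference :class:`~popivivc.fitting.PopulationModel` (Table of
    population means and BSVs above, proportional residual CV
    :data:`SIGMA_PROP`)."""
    from .fitting import PopulationModel  # deferred: fitting imports model_core

    theta = {
        "k_lag": DISPOSITION.k_lag,
        "k_a": DISPOSITION.k_a,
        "v1": DISPOSITION.v1,
        "v2": DISPOSITION.v2,
        "cl": DISPOSITION.cl,
        "cld": DISPOSITION.cld,
        "am50_invivo": AM50_INVIVO,
        "imax": FDISS.imax,
        "t_get": FDISS.t_get,
        "hill_stomach": FDISS.hill_stomach,
        "diss_max": FDISS.diss_max,
        "t_itt": FDISS.t_itt,
        "t_ctt": FDISS.t_ctt,
        "hill_intestine": FDISS.hill_intestine,
    }
    theta.update({f"vmax_invivo:{f}": v for f, v in VMAX_INVIVO.items()})
    return PopulationModel(theta=theta, omega2=dict(BSV), sigma=SIGMA_PROP)
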