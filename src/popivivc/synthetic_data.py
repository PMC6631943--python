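"""Synthetic study generator.

Emulates the crossover-free parallel design of the source study: four
formulations (IR 20 mg, three SR at 60 mg), three subjects per
formulation, 19 blood samples over 48 h with a 5 ng/mL LLOQ, and 6-vessel
dissolution runs sampled 14 times over 24 h.  Individual parameters follow
the exponential (log-normal) between-subject model, plasma observations
carry proportional residual noise, and dissolution observations carry
additive noise in percent points.  Every generator is a pure function of
(parameters, design, seed), and cohorts are returned together with their
ground-truth individual parameters so that estimation can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .model_core import (
    DissolutionProfile,
    InVitroDissolutionParams,
    PlasmaProfile,
    SolverConfig,
    SubjectParameters,
    simulate_dense,
    solve_invitro_dissolution,
)

__all__ = ["StudyDesign", "sample_individual", "generate_cohort", "generate_invitro_dataset"]


@dataclass(frozen=True)
class StudyDesign:
    """Study layout: formulations with label doses, group size, sampling
    schedules, assay LLOQ and vessel count."""

    formulations: tuple = tuple((f, defaults.DOSES[f]) for f in defaults.FORMULATIONS)
    n_subjects: int = 3
    plasma_times: np.ndarray = field(default_factory=lambda: defaults.PLASMA_TIMES.copy())
    dissolution_times: np.ndarray = field(default_factory=lambda: defaults.DISSOLUTION_TIMES.copy())
    lloq: float = defaults.LLOQ
    n_vessels: int = 6

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_vessels <= 0:
            raise ValueError("counts must be positive")
        for name in ("plasma_times", "dissolution_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, t)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_individual(
    pop,
    formulation: str,
    seed,
    dose: float | None = None,
    subject_id: str = "sim",
) -> SubjectParameters:
    """Draw one individual from the population model: theta_i =
    theta * exp(eta), eta ~ N(0, omega^2) independently per parameter.

    ``seed`` may be an integer or an existing numpy Generator (the latter
    advances the stream, which is how cohort generation stays
    deterministic).
    """
    rng = _as_rng(seed)
    dose = defaults.DOSES.get(formulation, 60.0) if dose is None else dose
    eta = {}
    for name in pop.structural_names(formulation):
        om2 = pop.omega2.get(name, 0.0)
        eta[name] = rng.normal(0.0, math.sqrt(om2)) if om2 > 0 else 0.0
    return pop.subject_parameters(formulation, dose, subject_id, eta)


def generate_cohort(
    pop,
    design: StudyDesign | None = None,
    seed: int = 0,
    config: SolverConfig | None = None,
) -> tuple[list[PlasmaProfile], dict[str, SubjectParameters]]:
    """Simulate a full plasma study.

    Each subject is drawn from the population model, simulated with the
    structural model at the design's sampling times, perturbed with
    proportional residual noise (sd = sigma * prediction) and censored at
    the LLOQ (censored observations keep value 0 and set ``blq_flags``).
    Returns the profiles and a map subject_id -> true individual
    parameters.
    """
    design = design or StudyDesign()
    rng = _as_rng(seed)
    cfg = config or SolverConfig(method="rk4")
    times = design.plasma_times
    profiles: list[PlasmaProfile] = []
    truth: dict[str, SubjectParameters] = {}
    for form, dose in design.formulations:
        for i in range(design.n_subjects):
            sid = f"{form}_{i + 1:02d}"
            sp = sample_individual(pop, form, rng, dose=dose, subject_id=sid)
            sim = simulate_dense(sp, t_end=float(times[-1]), config=cfg)
            pred = sim.conc_at(times)
            noise = rng.standard_normal(times.size)
            obs = np.maximum(pred * (1.0 + pop.sigma * noise), 0.0)
            blq = obs < design.lloq
            obs = np.where(blq, 0.0, obs)
            profiles.append(PlasmaProfile(sid, form, dose, times, obs, blq))
            truth[sid] = sp
    return profiles, truth


def generate_invitro_dataset(
    p: InVitroDissolutionParams,
    design: StudyDesign | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    formulation_id: str = "test",
    ph_label: str = "1.2",
    dose: float = 60.0,
) -> list[DissolutionProfile]:
    """Simulate a multi-vessel dissolution run.

    The mean curve is the closed-form Michaelis-Menten release; each
    vessel observes it plus additive Gaussian noise of ``noise_sd``
    percent points, clipped to [0, 105]%.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    design = design or StudyDesign()
    rng = _as_rng(seed)
    times = design.dissolution_times
    mean_pct = 100.0 * solve_invitro_dissolution(p, times)
    out = []
    for v in range(design.n_vessels):
        pct = mean_pct + noise_sd * rng.standard_normal(times.size)
        pct = np.clip(pct, 0.0, 105.0)
        out.append(
            DissolutionProfile(formulation_id, ph_label, f"V{v + 1}", times.copy(), pct, dose)
        )
    return out
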