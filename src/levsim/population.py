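"""Virtual-patient generation for the dosing simulations.

Each simulated cohort fixes creatinine clearance at the scenario value and
realises inter-individual variability (IIV) as independent lognormal
multipliers on clearance and central volume:

    CL_i = TVCL(CrCl) * exp(eta1_i),   eta1 ~ N(0, omega_cl^2)
    V1_i = V1_pop    * exp(eta2_i),    eta2 ~ N(0, omega_v1^2)

Q and V2 carry no IIV and are identical across subjects.  The reported
IIV percentages are interpreted as 100 * omega (SD of the log-scale random
effect).  Proportional residual error is available separately
(:func:`apply_residual_error`) but is excluded from trough-based target
attainment by default: attainment is judged on individual-predicted
concentrations, which back-calculates to the published grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .pkmodel import (
    IndividualParameters,
    PopulationParameters,
    Regimen,
    typical_clearance,
    typical_clearance_power_only,
)

__all__ = ["Scenario", "Cohort", "sample_cohort", "sample_individuals", "apply_residual_error"]

_CLEARANCE_MODELS = {
    "additive": typical_clearance,
    "power-only": typical_clearance_power_only,
}


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: a CrCl level, a regimen, cohort size, seed."""

    crcl: float
    regimen: Regimen
    n_subjects: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crcl <= 0:
            raise ValueError("crcl must be strictly positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


class Cohort(NamedTuple):
    """Structure-of-arrays view of a sampled cohort (vector per parameter)."""

    cl: np.ndarray
    v1: np.ndarray
    q: np.ndarray
    v2: np.ndarray


def sample_cohort(
    pop: PopulationParameters,
    crcl: float,
    n: int,
    seed,
    clearance_model: str = "additive",
) -> Cohort:
    """Draw ``n`` virtual subjects at fixed CrCl; vectorised parameter arrays.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a ``Generator``.
    Draw order is fixed (eta on CL first, then eta on V1) so results are
    bitwise reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    try:
        tvcl = _CLEARANCE_MODELS[clearance_model](crcl, pop)
    except KeyError:
        raise ValueError(f"unknown clearance_model: {clearance_model!r}") from None
    rng = np.random.default_rng(seed)
    eta_cl = rng.normal(0.0, pop.omega_cl, n)
    eta_v1 = rng.normal(0.0, pop.omega_v1, n)
    return Cohort(
        cl=tvcl * np.exp(eta_cl),
        v1=pop.v1_pop * np.exp(eta_v1),
        q=np.full(n, pop.q_pop),
        v2=np.full(n, pop.v2_pop),
    )


def sample_individuals(
    pop: PopulationParameters,
    crcl: float,
    n: int,
    seed,
    clearance_model: str = "additive",
) -> list[IndividualParameters]:
    """As :func:`sample_cohort` but returning one object per subject."""
    c = sample_cohort(pop, crcl, n, seed, clearance_model)
    return [
        IndividualParameters(cl=float(c.cl[i]), v1=float(c.v1[i]),
                             q=float(c.q[i]), v2=float(c.v2[i]))
        for i in range(n)
    ]


def apply_residual_error(conc, sigma_prop: float, rng: np.random.Generator):
    """Proportional residual error: conc * (1 + eps), eps ~ N(0, sigma^2).

    Observations are truncated below at zero (at sigma = 0.223 the truncation
    probability is < 4e-6).  Accepts scalars or arrays.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("conc must be non-negative")
    if sigma_prop == 0.0:
        return float(conc) if conc.ndim == 0 else conc.copy()
    eps = rng.normal(0.0, sigma_prop, conc.shape)
    out = np.maximum(conc * (1.0 + eps), 0.0)
    return float(out) if out.ndim == 0 else out
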