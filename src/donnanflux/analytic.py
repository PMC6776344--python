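"""Closed-form approximate solutions for the two-domain transport problem.

For a trace ion diffusing between two semi-infinite half-spaces joined by a
quasi-steady interfacial jump, the concentration field is an error-function
profile in each domain with *time-independent* interface values:

    c(z, t) = C_p(0-) * (1 + erf(z / sqrt(4 D_p t)))            z <= 0
    c(z, t) = C_s(0+) + (C_s0 - C_s(0+)) * erf(z / sqrt(4 D_s t))   z >= 0

Flux continuity at the interface fixes the salt-side value,

    C_s(0+) = C_s0 / (1 + sqrt(D_p / D_s) * ratio),

with ratio = C_p(0-)/C_s(0+) the Donnan partition ratio of the ion. The
solution holds while the container boundaries are out of reach, roughly
t < 0.1 L_p^2 / D_p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import erf

from .io import ProfileSeries

__all__ = [
    "ErfSolution",
    "interface_concentrations",
    "erf_profile",
    "erf_solution",
    "validity_time",
    "bounded_corrected_profile",
]


@dataclass(frozen=True)
class ErfSolution:
    """Parameters of the coupled semi-infinite erf solution."""

    c_s_initial: float  # mM, salt concentration at t = 0
    c_s_interface: float  # mM, C_s(0+), time-independent
    c_p_interface: float  # mM, C_p(0-), time-independent
    d_poly: float  # m^2/s
    d_salt_region: float  # m^2/s

    def __post_init__(self) -> None:
        if min(self.c_s_initial, self.d_poly, self.d_salt_region) <= 0:
            raise ValueError("concentrations and diffusivities must be "
                             "positive")
        if self.c_s_interface > self.c_s_initial * (1 + 1e-12):
            raise ValueError("C_s(0+) cannot exceed the initial salt "
                             "concentration")

    @property
    def ratio(self) -> float:
        return self.c_p_interface / self.c_s_interface


def interface_concentrations(c_s_initial: float, ratio: float, d_poly: float,
                             d_salt_region: float) -> tuple[float, float]:
    """Time-independent interface values (C_s(0+), C_p(0-)) from flux
    matching of the two erf branches."""
    if c_s_initial <= 0 or ratio < 0 or min(d_poly, d_salt_region) <= 0:
        raise ValueError("inputs must be positive (ratio may be zero)")
    c_s0p = c_s_initial / (1.0 + np.sqrt(d_poly / d_salt_region) * ratio)
    return c_s0p, ratio * c_s0p


def erf_solution(c_s_initial: float, ratio: float, d_poly: float,
                 d_salt_region: float) -> ErfSolution:
    """Build the full :class:`ErfSolution` from the partition ratio."""
    c_s0p, c_p0m = interface_concentrations(c_s_initial, ratio, d_poly,
                                            d_salt_region)
    return ErfSolution(c_s_initial, c_s0p, c_p0m, d_poly, d_salt_region)


def erf_profile(solution: ErfSolution, z, t: float):
    """Evaluate the two-branch erf profile at positions ``z`` (m), time
    ``t`` (s > 0). The profile jumps by C_p(0-) - C_s(0+) at z = 0; z = 0
    itself is assigned the polyelectrolyte branch value."""
    if t <= 0:
        raise ValueError("t must be positive")
    z = np.asarray(z, dtype=float)
    poly = solution.c_p_interface * (
        1.0 + erf(z / np.sqrt(4.0 * solution.d_poly * t)))
    salt = solution.c_s_interface + (
        (solution.c_s_initial - solution.c_s_interface)
        * erf(z / np.sqrt(4.0 * solution.d_salt_region * t)))
    return np.where(z > 0, salt, poly)


def validity_time(l_poly: float, d_poly: float) -> float:
    """Order-of-magnitude time 0.1 * L_p^2 / D_p before the finite container
    starts to distort the semi-infinite solution."""
    if l_poly <= 0 or d_poly <= 0:
        raise ValueError("inputs must be positive")
    return 0.1 * l_poly**2 / d_poly


def bounded_corrected_profile(solution: ErfSolution, z, t: float,
                              salt_mode: str = "semi-infinite",
                              c_salt_of_t: Callable[[float], float] | None = None,
                              l_poly: float | None = None):
    """Erf profile with a correction for a stirred (convective) salt side.

    In ``'convection-flat'`` mode the salt compartment is well mixed, so the
    salt-side interface value is re-evaluated at each time from the supplied
    (measured or simulated) mixed salt concentration ``c_salt_of_t`` and the
    polyelectrolyte branch uses that time-dependent interface value with the
    fixed partition ratio. This is a reconstruction of the bounded/convective
    correction to the semi-infinite solution, not a closed-form result.

    ``'semi-infinite'`` reduces to :func:`erf_profile`; if ``l_poly`` is
    given, evaluation past the validity window only emits a warning.
    """
    if salt_mode == "semi-infinite":
        if l_poly is not None and t > validity_time(l_poly, solution.d_poly):
            warnings.warn(
                f"t = {t:.3g} s exceeds the semi-infinite validity window "
                f"{validity_time(l_poly, solution.d_poly):.3g} s; boundary "
                "effects may be significant", stacklevel=2)
        return erf_profile(solution, z, t)
    if salt_mode != "convection-flat":
        raise ValueError(f"unknown salt_mode {salt_mode!r}")
    if c_salt_of_t is None:
        raise ValueError("convection-flat mode requires c_salt_of_t")
    if t <= 0:
        raise ValueError("t must be positive")
    z = np.asarray(z, dtype=float)
    c_mixed = float(c_salt_of_t(t))
    c_p0m = solution.ratio * c_mixed
    poly = c_p0m * (1.0 + erf(z / np.sqrt(4.0 * solution.d_poly * t)))
    return np.where(z > 0, c_mixed, poly)


def erf_profile_series(solution: ErfSolution, z: np.ndarray,
                       times: np.ndarray,
                       species: str = "Gd(DTPA)2-") -> ProfileSeries:
    """Tabulate the analytic solution on the shared ProfileSeries schema."""
    times = np.asarray(times, dtype=float)
    conc = np.vstack([erf_profile(solution, z, t) for t in times])
    return ProfileSeries(species, times, np.asarray(z, dtype=float), conc)
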