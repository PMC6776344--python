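"""1-D electro-diffusive transport across polyelectrolyte / membrane / salt.

Two solver tiers share the geometry:

* A **resolved-interface** tier that solves the steady nonlinear
  Poisson-Boltzmann problem for the background Na+/Cl- ions and the electric
  potential on a geometrically graded mesh (sub-nm spacing at the interface),
  then integrates the trace contrast agent's drift-diffusion equation on the
  frozen potential. The non-ideal chemical-potential step is smoothed over a
  nanometre with an erf, and the flux is discretized in Slotboom form
  J = -(D/w) d(c w)/dz with w = exp(mu_corr/RT + z_i psi), which is exact at
  equilibrium and strictly conservative.

* A **macroscopic jump-condition** tier for multi-day, full-length runs:
  pure diffusion per region, with the nanometre double layer replaced by a
  partition jump c_p(0-) = ratio * c(0+) embedded in the interface
  transmissibility, plus flux continuity. The two tiers agree to a fraction
  of a percent once the double layer is quasi-steady.

Both are linear method-of-lines systems integrated with an implicit BDF
scheme (adaptive step, deterministic, no randomness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.special import erf

from .donnan import solve_donnan_equilibrium
from .io import ProfileSeries
from .parameters import (EPSILON_0, EPSILON_R, FARADAY, GAS_CONSTANT,
                         BathComposition, IonSpecies, debye_length)

__all__ = [
    "Geometry1D",
    "FieldState",
    "InterfaceCondition",
    "smoothed_mu_corr",
    "resolved_mesh",
    "solve_background_steady",
    "solve_gd_transport",
    "jump_interface_solver",
    "step_size_timeseries",
    "time_to_fraction",
    "equilibrium_poly_concentration",
    "bulk_migration_flux_fraction",
]

#: default width (m) of the erf smoothing of the chemical-potential step
MU_SMOOTHING_WIDTH = 1e-9


@dataclass(frozen=True)
class Geometry1D:
    """1-D sample geometry: polyelectrolyte at z < 0, then an uncharged
    membrane of ``membrane_thickness``, then salt solution truncated at
    ``d_salt`` (measured from the interface at z = 0)."""

    z_poly_bottom: float = -10e-3  # m
    membrane_thickness: float = 100e-6  # m
    d_salt: float = 3e-3  # m

    def __post_init__(self) -> None:
        if self.z_poly_bottom >= 0:
            raise ValueError("z_poly_bottom must be negative")
        if self.membrane_thickness < 0 or self.d_salt < 0:
            raise ValueError("membrane_thickness and d_salt must be >= 0")
        if 0 < self.d_salt <= self.membrane_thickness:
            raise ValueError("d_salt must exceed membrane_thickness")

    @property
    def l_poly(self) -> float:
        return -self.z_poly_bottom

    @property
    def l_salt(self) -> float:
        return self.d_salt - self.membrane_thickness

    def region_of(self, z: np.ndarray) -> np.ndarray:
        """'poly' / 'membrane' / 'salt' per position."""
        z = np.asarray(z)
        out = np.where(z < 0, "poly",
                       np.where(z < self.membrane_thickness, "membrane",
                                "salt"))
        return out

    def d_of(self, ion: IonSpecies, z: np.ndarray) -> np.ndarray:
        """Per-position diffusion coefficient for ``ion``."""
        z = np.asarray(z, dtype=float)
        d = np.full(z.shape, ion.d_salt_region)
        d[z < 0] = ion.d_poly
        if self.membrane_thickness > 0:
            d[(z >= 0) & (z < self.membrane_thickness)] = ion.d_membrane
        return d


@dataclass
class FieldState:
    """Steady background state on the resolved mesh (node-based)."""

    time: float
    z: np.ndarray  # node positions, m (these are the FV faces for Gd)
    psi: np.ndarray  # dimensionless potential at nodes
    conc: dict  # species name -> mM at nodes
    geometry: Geometry1D
    bath: BathComposition
    mu_width: float
    debye: float
    newton_iterations: int = 0


@dataclass(frozen=True)
class InterfaceCondition:
    """Macroscopic interface contract for the jump-condition tier."""

    ratio_gd: float  # c_p(0-)/c(0+), dimensionless
    flux_continuity: bool = True

    def __post_init__(self) -> None:
        if self.ratio_gd <= 0:
            raise ValueError("partition ratio must be positive")


def smoothed_mu_corr(z, ion: IonSpecies, width: float = MU_SMOOTHING_WIDTH,
                     mu_s_corr: float = 0.0):
    """Erf-smoothed chemical-potential correction profile (units of RT).

    Steps from mu_p^corr = mu_s_corr + delta_mu_corr (z -> -inf) to
    mu_s_corr (z -> +inf) over ``width``; at z = 0 it equals the midpoint.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    z = np.asarray(z, dtype=float)
    mu_p = mu_s_corr + ion.delta_mu_corr
    return (-0.5 * erf(z / width) * ion.delta_mu_corr
            + 0.5 * (mu_p + mu_s_corr))


# -- resolved-interface tier -------------------------------------------------


def _march(z_start: float, z_end: float, dz0: float, growth: float,
           dz_max: float) -> tuple[np.ndarray, float]:
    """Geometrically graded face positions from z_start (exclusive) to
    z_end (inclusive), growing from dz0; returns (faces, final dz)."""
    faces = []
    z, dz = z_start, dz0
    while z + dz < z_end - 1e-15:
        z += dz
        faces.append(z)
        dz = min(dz * growth, dz_max)
    # merge a dangling sliver into the last step
    if faces and (z_end - faces[-1]) < 0.25 * dz:
        faces[-1] = z_end
    else:
        faces.append(z_end)
    return np.array(faces), dz


def resolved_mesh(geometry: Geometry1D, dz_min: float = 2e-10,
                  growth: float = 1.15, dz_max: float = 1e-4) -> np.ndarray:
    """Graded face positions resolving the nm interface within the mm domain.

    Faces grow geometrically away from z = 0 on both sides; the membrane/salt
    boundary and both domain ends are snapped to faces exactly.
    """
    pos = [np.array([0.0])]
    if geometry.membrane_thickness > 0:
        seg, dz = _march(0.0, geometry.membrane_thickness, dz_min, growth,
                         dz_max)
        pos.append(seg)
        if geometry.l_salt > 0:
            seg2, _ = _march(geometry.membrane_thickness, geometry.d_salt,
                             dz, growth, dz_max)
            pos.append(seg2)
    elif geometry.d_salt > 0:
        seg, _ = _march(0.0, geometry.d_salt, dz_min, growth, dz_max)
        pos.append(seg)
    neg, _ = _march(0.0, geometry.l_poly, dz_min, growth, dz_max)
    pos.append(-neg)
    faces = np.unique(np.concatenate(pos))
    return faces


def solve_background_steady(geometry: Geometry1D, bath: BathComposition,
                            na: IonSpecies, cl: IonSpecies,
                            width: float = MU_SMOOTHING_WIDTH,
                            faces: np.ndarray | None = None,
                            dz_min: float = 2e-10, growth: float = 1.15,
                            dz_max: float = 1e-4, max_iter: int = 60,
                            tol: float = 1e-10) -> FieldState:
    """Steady Poisson-Boltzmann solve for the background ions and potential.

    At zero flux each background ion follows its Boltzmann distribution on
    the (unknown) potential; substituting into Poisson's equation gives a
    single nonlinear equation in psi(z), solved by damped Newton iteration
    on the graded mesh. Boundary conditions: dpsi/dz = 0 at the
    polyelectrolyte bottom, psi = 0 at d_salt. The fixed charge density
    steps from FCD (z < 0) to zero with the same erf smoothing as the
    chemical-potential corrections.
    """
    if faces is None:
        faces = resolved_mesh(geometry, dz_min, growth, dz_max)
    z = faces
    n = z.size
    h = np.diff(z)

    c_s = bath.c_nacl_salt  # mM == mol/m^3
    coeff = FARADAY**2 / (EPSILON_0 * EPSILON_R * GAS_CONSTANT
                          * bath.temperature)
    lam_d = debye_length(c_s, bath.temperature)

    mu_na = smoothed_mu_corr(z, na, width)
    mu_cl = smoothed_mu_corr(z, cl, width)
    fcd = bath.fcd * 0.5 * (1.0 - erf(z / width))

    def charges(psi):
        c_na = c_s * np.exp(-mu_na - psi)
        c_cl = c_s * np.exp(-mu_cl + psi)
        return c_na, c_cl

    # initial guess: Donnan plateau relaxing over a Debye length
    donnan = solve_donnan_equilibrium(bath, na, cl)
    psi = donnan.psi * 0.5 * (1.0 - erf(z / lam_d))

    def residual(psi):
        c_na, c_cl = charges(psi)
        res = np.empty(n)
        lap = (2.0 / (h[:-1] + h[1:])
               * ((psi[2:] - psi[1:-1]) / h[1:]
                  - (psi[1:-1] - psi[:-2]) / h[:-1]))
        res[1:-1] = lap + coeff * (c_na[1:-1] - c_cl[1:-1] + fcd[1:-1])
        res[0] = (psi[1] - psi[0]) / h[0]  # Neumann
        res[-1] = psi[-1]  # Dirichlet, reference potential
        return res

    scale = coeff * c_s
    res = residual(psi)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(res)) / scale < tol:
            break
        c_na, c_cl = charges(psi)
        # tridiagonal Jacobian in banded form
        ab = np.zeros((3, n))
        w2 = 2.0 / (h[:-1] + h[1:])
        ab[0, 2:] = w2 / h[1:]  # super-diagonal for rows 1..n-2
        ab[2, :-2] = w2 / h[:-1]  # sub-diagonal
        ab[1, 1:-1] = (-w2 * (1.0 / h[1:] + 1.0 / h[:-1])
                       + coeff * (-c_na[1:-1] - c_cl[1:-1]))
        ab[1, 0] = -1.0 / h[0]
        ab[0, 1] = 1.0 / h[0]
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        step = solve_banded((1, 1), ab, -res)
        alpha, norm0 = 1.0, np.max(np.abs(res))
        while alpha > 1e-6:
            trial = psi + alpha * step
            res_t = residual(trial)
            if np.max(np.abs(res_t)) < norm0:
                psi, res = trial, res_t
                break
            alpha *= 0.5
        else:  # pragma: no cover - PB Newton is globally well behaved here
            raise RuntimeError(
                "Poisson-Boltzmann Newton iteration stalled: residual "
                f"{norm0 / scale:.3g} after {it} iterations")
    else:
        raise RuntimeError(
            "Poisson-Boltzmann iteration did not converge in "
            f"{max_iter} iterations (residual {np.max(np.abs(res)) / scale:.3g})")

    c_na, c_cl = charges(psi)
    return FieldState(time=0.0, z=z, psi=psi,
                      conc={na.name: c_na, cl.name: c_cl},
                      geometry=geometry, bath=bath, mu_width=width,
                      debye=lam_d, newton_iterations=it)


def _as_callable(value) -> Callable[[float], float]:
    if callable(value):
        return value
    return lambda t, v=float(value): v


def _bdf_integrate(a_mat, b_of_t, c0, times, rtol=1e-8, atol=1e-12):
    """Integrate dc/dt = A c + b(t) with BDF and the exact (constant) Jacobian."""
    a_csr = a_mat.tocsr()

    def rhs(t, c):
        return a_csr @ c + b_of_t(t)

    sol = solve_ivp(rhs, (0.0, times[-1]), c0, method="BDF", t_eval=times,
                    jac=a_mat.tocsc(), rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"implicit time integration failed: {sol.message}")
    if np.any(sol.y < -1e-6 * max(1.0, np.max(np.abs(c0)))):
        raise RuntimeError(
            "transport produced significantly negative concentrations; "
            "refine the mesh or tolerances (clipping is not performed)")
    return sol.y.T  # (T, N)


def solve_gd_transport(geometry: Geometry1D, bath: BathComposition,
                       gd: IonSpecies, background: FieldState,
                       t_end: float, dt_out: float | None = None,
                       times: np.ndarray | None = None,
                       salt_boundary: str = "dirichlet",
                       boundary_value=None,
                       c_init: np.ndarray | None = None,
                       rtol: float = 1e-6) -> ProfileSeries:
    """Time-dependent contrast-agent transport on the resolved mesh.

    The potential and chemical-potential profiles are frozen at the
    background steady state (trace-ion approximation). Finite-volume cells
    sit between the background nodes; the flux through each face is
    J = (u_L - u_R)/Rf with u = c*w, w = exp(mu_corr + z_i*psi) and Rf the
    integrated resistance of the two half-cells, so the scheme conserves
    mass exactly and its stationary point is the Boltzmann distribution.

    ``salt_boundary``: 'dirichlet' clamps the concentration at d_salt to
    ``boundary_value`` (scalar or callable of t; default the bath's initial
    concentration); 'closed' makes the system mass-tight for conservation
    and equilibrium-limit studies.
    """
    zf = background.z
    n = zf.size - 1  # cells
    dz = np.diff(zf)
    zc = 0.5 * (zf[:-1] + zf[1:])

    mu_f = smoothed_mu_corr(zf, gd, background.mu_width)
    mu_c = smoothed_mu_corr(zc, gd, background.mu_width)
    psi_f = background.psi
    psi_c = np.interp(zc, zf, psi_f)
    w_f = np.exp(mu_f + gd.valence * psi_f)
    w_c = np.exp(mu_c + gd.valence * psi_c)
    d_c = geometry.d_of(gd, zc)

    # face resistances (interior faces 1..n-1)
    dl = zf[1:-1] - zc[:-1]
    dr = zc[1:] - zf[1:-1]
    r_face = (dl * 0.5 * (w_c[:-1] + w_f[1:-1]) / d_c[:-1]
              + dr * 0.5 * (w_f[1:-1] + w_c[1:]) / d_c[1:])

    # assemble dc/dt = A c + b(t)
    a_coef = w_c[:-1] / r_face  # J_k = a_k c_{k-1} - b_k c_k
    b_coef = w_c[1:] / r_face
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    main[:-1] -= a_coef / dz[:-1]
    upper += b_coef / dz[:-1]
    main[1:] -= b_coef / dz[1:]
    lower += a_coef / dz[1:]

    b_vec = np.zeros(n)
    if salt_boundary == "dirichlet":
        cb = _as_callable(bath.c_gd_salt_initial if boundary_value is None
                          else boundary_value)
        d_edge = zf[-1] - zc[-1]
        r_edge = d_edge * 0.5 * (w_c[-1] + w_f[-1]) / d_c[-1]
        main[-1] -= w_c[-1] / (r_edge * dz[-1])

        def b_of_t(t, base=b_vec):
            b = base.copy()
            b[-1] += w_f[-1] * cb(t) / (r_edge * dz[-1])
            return b
    elif salt_boundary == "closed":
        def b_of_t(t, base=b_vec):
            return base
    else:
        raise ValueError(f"unknown salt_boundary mode {salt_boundary!r}")

    a_mat = sparse.diags_array((lower, main, upper), offsets=(-1, 0, 1))

    if c_init is None:
        c0 = np.where(zc > geometry.membrane_thickness,
                      bath.c_gd_salt_initial, 0.0)
    else:
        c0 = np.asarray(c_init, dtype=float)
    if times is None:
        if dt_out is None:
            dt_out = t_end / 20.0
        times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    times = np.asarray(times, dtype=float)

    conc = _bdf_integrate(a_mat, b_of_t, c0, times, rtol=rtol)
    series = ProfileSeries(gd.name, times, zc, conc)
    series.cell_dz = dz
    return series


# -- macroscopic jump-condition tier ----------------------------------------


def _macro_mesh(geometry: Geometry1D, dz: float, convection_flat: bool,
                include_salt: bool) -> tuple[np.ndarray, list[str]]:
    """Uniform-per-region face positions for the macroscopic tier."""
    faces = [np.linspace(geometry.z_poly_bottom, 0.0,
                         max(8, round(geometry.l_poly / dz)) + 1)]
    if geometry.membrane_thickness > 0:
        faces.append(np.linspace(0.0, geometry.membrane_thickness,
                                 max(4, round(geometry.membrane_thickness
                                              / (dz / 2))) + 1))
    if include_salt and geometry.l_salt > 0 and not convection_flat:
        faces.append(np.linspace(geometry.membrane_thickness, geometry.d_salt,
                                 max(8, round(geometry.l_salt / dz)) + 1))
    return np.unique(np.concatenate(faces)), faces


def jump_interface_solver(geometry: Geometry1D, gd: IonSpecies,
                          ratio: InterfaceCondition | float,
                          t_end: float | None = None,
                          dt_out: float | None = None,
                          times: np.ndarray | None = None,
                          c_salt_initial: float = 0.33,
                          boundary: str = "dirichlet",
                          boundary_value=None,
                          convection_flat: bool = False,
                          dz: float = 5e-5,
                          rtol: float = 1e-8) -> ProfileSeries:
    """Pure-diffusion transport with the double layer as a partition jump.

    The concentration is discontinuous at z = 0: c_p(0-) = ratio * c(0+),
    with equal flux on both sides, folded into the transmissibility of the
    interface face so the discrete system stays linear and conservative.

    Boundary modes at the salt end:

    * ``'dirichlet'`` — clamp c(d_salt, t) to ``boundary_value`` (scalar or
      callable; default ``c_salt_initial``), the d_salt truncation used when
      convection stirs the far salt region;
    * ``'closed'`` — zero flux (finite reservoir / conservation tests);
    * ``'interface_dirichlet'`` — no membrane or salt region is meshed; the
      salt-side interface concentration itself is prescribed, so the
      polyelectrolyte fills against c_p(0-) = ratio * boundary_value(t).

    ``convection_flat`` replaces the salt region by a single well-mixed
    compartment with zero internal resistance (instantaneous thermal-
    convection mixing); its concentration then evolves by mass balance, or
    is clamped if combined with 'dirichlet'.
    """
    if isinstance(ratio, InterfaceCondition):
        r = ratio.ratio_gd
    else:
        r = float(ratio)
    if r <= 0:
        raise ValueError("partition ratio must be positive")

    include_salt = boundary != "interface_dirichlet"
    faces, _ = _macro_mesh(geometry, dz, convection_flat, include_salt)
    mixed_salt = (convection_flat and include_salt and geometry.l_salt > 0
                  and boundary != "dirichlet")
    if mixed_salt:
        # append the well-mixed salt compartment as one full-width cell
        faces = np.append(faces, geometry.d_salt)
    n = faces.size - 1
    dzs = np.diff(faces)
    zc = 0.5 * (faces[:-1] + faces[1:])
    d_c = geometry.d_of(gd, zc)

    # partition ratio per interior face: r at z=0, 1 elsewhere; in
    # interface_dirichlet mode z=0 is the boundary face and the jump is
    # applied through the boundary term instead
    r_face = np.ones(n - 1)
    if faces[0] < 0.0 < faces[-1]:
        iface = np.argmin(np.abs(faces[1:-1] - 0.0))
        if abs(faces[1 + iface]) > 1e-12:  # pragma: no cover
            raise RuntimeError("interface face not on the macroscopic mesh")
        r_face[iface] = r

    dl = faces[1:-1] - zc[:-1]
    dr = zc[1:] - faces[1:-1]
    if mixed_salt:
        dr[-1] = 0.0  # stirred compartment: no salt-side resistance
    a_half = d_c[:-1] / dl
    with np.errstate(divide="ignore"):
        b_half = np.where(dr > 0, d_c[1:] / dr, np.inf)
    # J = T * (c_L - r_f * c_R); T from the series resistances with the jump;
    # with zero right-side resistance (stirred compartment) T -> a
    t_face = np.empty(n - 1)
    fin = np.isfinite(b_half)
    t_face[~fin] = a_half[~fin]
    t_face[fin] = (a_half[fin] * b_half[fin]
                   / (a_half[fin] * r_face[fin] + b_half[fin]))

    a_coef = t_face
    b_coef = t_face * r_face
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    main[:-1] -= a_coef / dzs[:-1]
    upper += b_coef / dzs[:-1]
    main[1:] -= b_coef / dzs[1:]
    lower += a_coef / dzs[1:]

    b_vec = np.zeros(n)
    if boundary == "dirichlet":
        cb = _as_callable(c_salt_initial if boundary_value is None
                          else boundary_value)
        if convection_flat:
            # stirred region clamped: Dirichlet right at the last meshed face
            t_edge = d_c[-1] / (faces[-1] - zc[-1])
        else:
            t_edge = d_c[-1] / (faces[-1] - zc[-1])
        main[-1] -= t_edge / dzs[-1]

        def b_of_t(t):
            b = b_vec.copy()
            b[-1] += t_edge * cb(t) / dzs[-1]
            return b
    elif boundary == "interface_dirichlet":
        cb = _as_callable(c_salt_initial if boundary_value is None
                          else boundary_value)
        t_edge = d_c[-1] / (faces[-1] - zc[-1])
        main[-1] -= t_edge / dzs[-1]

        def b_of_t(t):
            b = b_vec.copy()
            b[-1] += t_edge * r * cb(t) / dzs[-1]
            return b
    elif boundary == "closed":
        def b_of_t(t):
            return b_vec
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")

    a_mat = sparse.diags_array((lower, main, upper), offsets=(-1, 0, 1))

    c0 = np.where(zc > geometry.membrane_thickness, c_salt_initial, 0.0)
    if not include_salt:
        c0[:] = 0.0
    if times is None:
        if t_end is None:
            raise ValueError("provide t_end or times")
        if dt_out is None:
            dt_out = t_end / 20.0
        times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    times = np.asarray(times, dtype=float)

    conc = _bdf_integrate(a_mat, b_of_t, c0, times, rtol=rtol)
    if mixed_salt:
        # render the stirred compartment as a flat profile over its extent
        start = faces[-2]
        n_extra = max(2, int(round((geometry.d_salt - start) / dz)))
        z_extra = np.linspace(start, geometry.d_salt, n_extra + 1)
        zc_extra = 0.5 * (z_extra[:-1] + z_extra[1:])
        zc = np.concatenate([zc[:-1], zc_extra])
        conc = np.hstack([conc[:, :-1],
                          np.repeat(conc[:, -1:], n_extra, axis=1)])
        dzs = np.concatenate([dzs[:-1], np.diff(z_extra)])
    series = ProfileSeries(gd.name, times, zc, conc)
    series.cell_dz = dzs
    series.interface_ratio = r
    return series


# -- derived quantities ------------------------------------------------------


def _extrapolate_to_interface(z: np.ndarray, c: np.ndarray, side: int,
                              exclusion: float, n_fit: int = 3) -> float:
    """Linear extrapolation of the macroscopic profile to z = 0 from one side
    (side=-1 poly, +1 salt/membrane), skipping the nm transition zone."""
    if side < 0:
        mask = z <= -exclusion
        pts = np.argsort(-z[mask])[:n_fit]
    else:
        mask = z >= exclusion
        pts = np.argsort(z[mask])[:n_fit]
    zz, cc = z[mask][pts], c[mask][pts]
    if zz.size < 2:
        raise ValueError("insufficient near-interface nodes for "
                         "extrapolation; refine the mesh")
    coeff = np.polyfit(zz, cc, 1)
    return float(np.polyval(coeff, 0.0))


def step_size_timeseries(series: ProfileSeries, exclusion: float = 5e-8):
    """Concentration step and ratio at z = 0 per frame.

    Extrapolates the macroscopic profiles on both sides of the interface to
    0- and 0+ (excluding the nanometre transition zone, ``exclusion``) and
    returns a DataFrame with columns (time_s, c_poly_interface_mM,
    c_salt_interface_mM, step_mM, ratio). The step is polyelectrolyte minus
    salt side.
    """
    import pandas as pd

    rows = []
    for t, prof in zip(series.times, series.conc):
        cp = _extrapolate_to_interface(series.z, prof, -1, exclusion)
        cs = _extrapolate_to_interface(series.z, prof, +1, exclusion)
        rows.append((t, cp, cs, cp - cs,
                     cp / cs if cs != 0 else np.nan))
    return pd.DataFrame(rows, columns=[
        "time_s", "c_poly_interface_mM", "c_salt_interface_mM", "step_mM",
        "ratio"])


def equilibrium_poly_concentration(geometry: Geometry1D, ratio: float,
                                   c_salt_initial: float,
                                   boundary: str = "dirichlet") -> float:
    """Long-time polyelectrolyte concentration implied by mass balance.

    With a clamped salt boundary (or prescribed interface concentration) the
    polyelectrolyte equilibrates at ratio * c_salt; in a closed system the
    initial salt-side inventory redistributes over salt + membrane (both
    salt-like) and the partitioned polyelectrolyte volume.
    """
    if boundary in ("dirichlet", "interface_dirichlet"):
        return ratio * c_salt_initial
    if boundary == "closed":
        m0 = c_salt_initial * geometry.l_salt
        c_salt_eq = m0 / (geometry.l_salt + geometry.membrane_thickness
                          + ratio * geometry.l_poly)
        return ratio * c_salt_eq
    raise ValueError(f"unknown boundary mode {boundary!r}")


def time_to_fraction(series: ProfileSeries, fraction: float,
                     equilibrium_value: float,
                     z_range: tuple[float, float] | None = None) -> float:
    """First time the polyelectrolyte-average concentration reaches
    ``fraction`` of ``equilibrium_value`` (linear interpolation in t)."""
    if fraction < 0 or fraction > 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0:
        return 0.0
    if z_range is None:
        z_range = (series.z[0], 0.0)
    avg = series.average(*z_range)
    target = fraction * equilibrium_value
    above = avg >= target
    if not above.any():
        raise ValueError(
            f"fraction {fraction} of equilibrium never reached within "
            f"{series.times[-1]:.3g} s (max {avg.max() / equilibrium_value:.3f})")
    i = int(np.argmax(above))
    if i == 0:
        return float(series.times[0])
    t0, t1 = series.times[i - 1], series.times[i]
    a0, a1 = avg[i - 1], avg[i]
    return float(t0 + (target - a0) / (a1 - a0) * (t1 - t0))


def bulk_migration_flux_fraction(background: FieldState, gd: IonSpecies,
                                 series: ProfileSeries, t: float,
                                 bulk_margin: float = 1e-6) -> float:
    """Ratio of the electro-migration+non-ideality drift flux to the Fickian
    flux for the contrast agent, away from the interface double layer.

    The background potential is flat outside the nanometre double layer, so
    this is small at the trace concentrations of the experiment; it
    quantifies why the macroscopic tier may drop the drift term entirely.
    """
    prof = series.frame(t)
    z = series.z
    mu = smoothed_mu_corr(z, gd, background.mu_width)
    psi = np.interp(z, background.z, background.psi)
    g = mu + gd.valence * psi
    dgdz = np.gradient(g, z)
    dcdz = np.gradient(prof, z)
    bulk = np.abs(z) > bulk_margin
    drift = np.abs(prof * dgdz)[bulk]
    fick = np.max(np.abs(dcdz[bulk]))
    return float(np.max(drift) / fick)
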