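"""Parameter estimation from concentration-profile time series.

* ``fit_d_poly`` — the contrast agent's diffusion coefficient in the
  polyelectrolyte from the erf-shaped early/intermediate-time profiles,
  fitted jointly over all (z, t) in a window chosen so that membrane
  artifacts have decayed but the far wall is still out of reach
  (2.5-6 h by default).
* ``fit_delta_mu_gd_dynamic`` — the contrast agent's non-ideality
  correction by matching forward-simulated profiles to observed ones.
* ``estimate_d_salt`` — where convective stirring takes over in the salt
  compartment, i.e. where observed and diffusion-only simulated salt
  profiles part ways; used to place the truncation boundary.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import erf

from .donnan import solve_donnan_equilibrium
from .io import ProfileSeries
from .parameters import BathComposition, IonSpecies
from .transport import Geometry1D, jump_interface_solver

__all__ = [
    "FitWindow",
    "DPolyFit",
    "fit_d_poly",
    "d_ratio_to_salt",
    "fit_delta_mu_gd_dynamic",
    "estimate_d_salt",
]


@dataclass(frozen=True)
class FitWindow:
    """Spatio-temporal window for the diffusion-coefficient fit.

    Defaults: 2.5-6 h, polyelectrolyte side only, excluding a two-voxel
    (174 um) band next to the membrane where the imaging data are
    unreliable.
    """

    t_min: float = 2.5 * 3600.0  # s
    t_max: float = 6.0 * 3600.0  # s
    z_lo: float | None = None  # m; default: bottom of the series
    z_hi: float = -174e-6  # m; exclude the near-membrane band

    def __post_init__(self) -> None:
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.z_hi > 0:
            raise ValueError("z_hi must be on the polyelectrolyte side")


@dataclass
class DPolyFit:
    d_poly: float  # m^2/s
    c_p_interface: float  # mM (at the first window time in scaled mode)
    stderr_d: float
    stderr_c: float
    n_points: int
    window: FitWindow
    rms_residual: float
    flags: list

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = dataclasses.asdict(self.window)
        return d


def _window_points(series: ProfileSeries, window: FitWindow):
    t_mask = (series.times >= window.t_min) & (series.times <= window.t_max)
    if t_mask.sum() < 3:
        raise ValueError(
            f"degenerate window: only {int(t_mask.sum())} time points in "
            f"[{window.t_min}, {window.t_max}] s")
    z_lo = series.z[0] if window.z_lo is None else window.z_lo
    z_mask = (series.z >= z_lo) & (series.z <= window.z_hi)
    if series.z[z_mask].size < 5:
        raise ValueError("window contains fewer than 5 spatial points")
    span = series.z[z_mask].max() - series.z[z_mask].min()
    if span < 3e-3:
        warnings.warn(
            f"polyelectrolyte window spans only {span * 1e3:.1f} mm; the "
            "diffusion fit may be poorly conditioned", stacklevel=3)
    return t_mask, z_mask


def fit_d_poly(series: ProfileSeries, window: FitWindow = FitWindow(),
               interface_model: str = "analytic",
               c_salt_of_t: Callable[[float], float] | None = None,
               weights: bool = True) -> DPolyFit:
    """Fit (D_p, interface scale) to polyelectrolyte-side profiles.

    The model is the semi-infinite erf branch
    c(z, t) = C_p(0-; t) * (1 + erf(z / sqrt(4 D_p t))). With
    ``interface_model='analytic'`` the interface value is one free constant
    (the semi-infinite regime, where it is time-independent); with
    ``'numeric'`` (convection-corrected mode) its time dependence is taken
    proportional to the supplied well-mixed salt concentration
    ``c_salt_of_t`` and only the proportionality is free.

    Per-point standard errors stored on the series weight the residuals
    when available and ``weights`` is True.
    """
    t_mask, z_mask = _window_points(series, window)
    times = series.times[t_mask]
    zz = series.z[z_mask]
    obs = series.conc[np.ix_(t_mask, z_mask)]
    if interface_model == "numeric":
        if c_salt_of_t is None:
            raise ValueError("interface_model='numeric' requires c_salt_of_t")
        shape_t = np.array([c_salt_of_t(t) for t in times])
        shape_t = shape_t / shape_t[0]
    elif interface_model == "analytic":
        shape_t = np.ones(times.size)
    else:
        raise ValueError(f"unknown interface_model {interface_model!r}")

    sig = None
    if weights and series.stderr is not None:
        sig = series.stderr[np.ix_(t_mask, z_mask)]
        good = np.isfinite(sig) & (sig > 0)
        if good.any():
            sig = np.where(good, sig, np.median(sig[good]))
        else:  # noiseless data: unweighted
            sig = None

    d_scale = 1e-10
    c_scale = max(float(obs.max()), 1e-6)

    def model(p):
        d, c0 = p[0] * d_scale, p[1] * c_scale
        args = zz[None, :] / np.sqrt(4.0 * d * times[:, None])
        return c0 * shape_t[:, None] * (1.0 + erf(args))

    def resid(p):
        r = model(p) - obs
        if sig is not None:
            r = r / sig
        return r.ravel()

    p0 = np.array([4.0, 0.5 * obs.max() / c_scale if obs.max() > 0 else 0.5])
    sol = least_squares(resid, p0, bounds=([1e-3, 0.0], [1e3, np.inf]),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"diffusion fit failed: {sol.message}")
    d_fit = sol.x[0] * d_scale
    c_fit = sol.x[1] * c_scale

    # covariance from the Jacobian at the solution
    _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
    dof = max(sol.fun.size - 2, 1)
    s2 = np.sum(sol.fun**2) / dof
    cov = (vt.T / s**2) @ vt * s2
    stderr = np.sqrt(np.diag(cov))

    flags = []
    if not (1e-11 < d_fit < 1e-8):
        flags.append(f"D = {d_fit:.3e} m^2/s outside the plausible "
                     "(1e-11, 1e-8) range")
        warnings.warn(flags[-1], stacklevel=2)
    return DPolyFit(
        d_poly=d_fit, c_p_interface=c_fit,
        stderr_d=float(stderr[0] * d_scale),
        stderr_c=float(stderr[1] * c_scale),
        n_points=sol.fun.size, window=window,
        rms_residual=float(np.sqrt(np.mean(sol.fun**2))), flags=flags)


def interface_scale_from_series(series: ProfileSeries,
                                z_band: tuple[float, float] = (-8e-4, -1.5e-4),
                                ) -> Callable[[float], float]:
    """Time-dependent interface concentration extracted from the data.

    Linear extrapolation of the polyelectrolyte-side profile in ``z_band``
    to z = 0- per frame, linearly interpolated in time. Feeding this into
    :func:`fit_d_poly` (``interface_model='numeric'``) reproduces the
    convection/finite-reservoir-corrected fitting mode, where only the
    profile *shape* constrains the diffusion coefficient and the measured
    interface value carries its own time dependence.
    """
    mask = (series.z >= z_band[0]) & (series.z <= z_band[1])
    if mask.sum() < 2:
        raise ValueError("z_band contains fewer than 2 points")
    vals = np.array([
        np.polyval(np.polyfit(series.z[mask], frame[mask], 1), 0.0)
        for frame in series.conc])
    times = series.times

    def c_of_t(t: float) -> float:
        return float(np.interp(t, times, vals))

    return c_of_t


def d_ratio_to_salt(d_poly: float, d_salt: float = 4.5e-10) -> float:
    """D in the polyelectrolyte relative to the salt solution."""
    if d_poly <= 0 or d_salt <= 0:
        raise ValueError("diffusivities must be positive")
    return d_poly / d_salt


def fit_delta_mu_gd_dynamic(observed: ProfileSeries, bath: BathComposition,
                            na: IonSpecies, cl: IonSpecies, gd: IonSpecies,
                            geometry: Geometry1D,
                            bounds: tuple[float, float] = (-1.0, 0.5),
                            c_salt_initial: float | None = None,
                            boundary: str = "dirichlet",
                            convection_flat: bool = False,
                            dz: float = 1e-4,
                            xatol: float = 1e-4) -> dict:
    """Estimate delta_mu_Gd by matching simulated to observed profiles.

    The background Donnan state is held fixed; only the contrast agent's
    correction (hence its partition ratio) varies. For each candidate value
    the macroscopic jump solver reproduces the observed times and the sum of
    squared differences on the observed grid is minimized (bounded scalar
    search, deterministic). ``gd`` supplies the transport coefficients; its
    own ``delta_mu_corr`` is only used to report the search displacement.
    """
    state = solve_donnan_equilibrium(bath, na, cl)
    if c_salt_initial is None:
        c_salt_initial = bath.c_gd_salt_initial
    times = observed.times[observed.times > 0]

    def misfit(dmu: float) -> float:
        ratio = float(np.exp(-dmu - gd.valence * state.psi))
        sim = jump_interface_solver(
            geometry, gd, ratio, times=np.concatenate([[0.0], times]),
            c_salt_initial=c_salt_initial, boundary=boundary,
            convection_flat=convection_flat, dz=dz)
        sim_i = sim.interp(observed.z)
        obs = observed.conc[observed.times > 0]
        return float(np.sum((sim_i.conc[1:] - obs) ** 2))

    res = minimize_scalar(misfit, bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    f_opt = res.fun
    f_edges = min(misfit(bounds[0]), misfit(bounds[1]))
    if f_edges - f_opt < 1e-9 * max(f_opt, 1e-30):
        warnings.warn(
            "objective is flat over the delta_mu_Gd search interval; the "
            "estimate is ill-conditioned", stacklevel=2)
    return {
        "delta_mu_gd": float(res.x),
        "objective": float(f_opt),
        "psi_background": state.psi,
        "ratio": float(np.exp(-res.x - gd.valence * state.psi)),
        "converged": bool(res.success),
    }


def estimate_d_salt(observed_salt: ProfileSeries,
                    simulated_no_convection: ProfileSeries,
                    threshold: float = 0.05,
                    clamp: tuple[float, float] = (1e-3, 5e-3)) -> float:
    """Salt-side truncation distance from convection onset.

    Compares observed salt-region profiles with a diffusion-only simulation
    on a common grid and returns the smallest z > 0 beyond which their
    relative difference (normalized by the largest observed salt
    concentration) exceeds ``threshold`` at any common time. If the curves
    never diverge the domain end is returned with a note; the result is
    clamped to the 1-5 mm range used in practice, with a warning.
    """
    z_obs = observed_salt.z[observed_salt.z > 0]
    if z_obs.size == 0:
        raise ValueError("observed series has no salt-side points")
    sim = simulated_no_convection.interp(observed_salt.z)
    common_t = np.intersect1d(observed_salt.times,
                              simulated_no_convection.times)
    if common_t.size == 0:
        raise ValueError("series share no time points")
    it_obs = np.isin(observed_salt.times, common_t)
    it_sim = np.isin(simulated_no_convection.times, common_t)
    zmask = observed_salt.z > 0
    dev = np.abs(observed_salt.conc[it_obs][:, zmask]
                 - sim.conc[it_sim][:, zmask])
    scale = np.max(np.abs(observed_salt.conc[it_obs][:, zmask]))
    rel = dev.max(axis=0) / scale
    exceeding = np.nonzero(rel > threshold)[0]
    if exceeding.size == 0:
        warnings.warn(
            "observed and simulated salt profiles never diverge beyond "
            f"{threshold:.0%}; returning the domain end", stacklevel=2)
        d = float(z_obs[-1])
    else:
        d = float(z_obs[exceeding[0]])
    if not clamp[0] <= d <= clamp[1]:
        warnings.warn(
            f"estimated d_salt = {d * 1e3:.2f} mm clamped to "
            f"[{clamp[0] * 1e3:.0f}, {clamp[1] * 1e3:.0f}] mm", stacklevel=2)
        d = float(np.clip(d, *clamp))
    return d
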