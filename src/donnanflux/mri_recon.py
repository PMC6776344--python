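"""Inversion-recovery T1 mapping and relaxivity-based concentration maps.

Voxel-wise magnitude IR model |I| = I0 |1 - A exp(-tau/T1)| fitted by
nonlinear least squares (the absolute value folds the recovery curve at the
null point, so the fit is multi-started across the fold), Monte-Carlo
parameter errors, conversion to contrast-agent concentration through the
relaxivity calibration 1/T1 = 1/T1pre + R*c, Gaussian map smoothing, and
collapse of 2-D maps to 1-D profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.stats import linregress

from .parameters import CalibrationModel

__all__ = [
    "IRSeries",
    "T1Map",
    "IRFit",
    "default_tau_grid",
    "ir_signal",
    "fit_ir_magnitude",
    "mc_error_t1",
    "fit_t1_map",
    "concentration_from_t1",
    "fit_relaxivity",
    "smooth_map",
    "profile_from_maps",
]

#: FWHM -> sigma conversion for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_tau_grid(n: int = 32, tau_min: float = 0.0017,
                     tau_max: float = 15.0) -> np.ndarray:
    """Logarithmic recovery-delay grid (s), 32 points from 1.7 ms to 15 s."""
    return np.geomspace(tau_min, tau_max, n)


@dataclass
class IRSeries:
    """Inversion-recovery magnitude stack over (tau, z, y)."""

    signal: np.ndarray  # (n_tau, n_z, n_y), magnitudes >= 0
    tau_list: np.ndarray  # s, strictly increasing
    voxel_size: tuple[float, float] = (87e-6, 100e-6)  # (z, y) in m
    z: np.ndarray | None = None  # voxel-centre z coordinates, m

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.tau_list = np.asarray(self.tau_list, dtype=float)
        if self.signal.ndim != 3:
            raise ValueError("signal must be (tau, z, y)")
        if self.signal.shape[0] != self.tau_list.size:
            raise ValueError("tau_list length must match signal axis 0")
        if np.any(np.diff(self.tau_list) <= 0):
            raise ValueError("tau_list must be strictly increasing")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and non-negative")


@dataclass
class T1Map:
    """Voxel-wise fit results of the magnitude IR model."""

    t1: np.ndarray  # s
    i0: np.ndarray
    a_factor: np.ndarray
    stderr_t1: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.a_factor[np.isfinite(self.a_factor)] > 2.0):
            warnings.warn(
                "fitted A factor exceeds 2 in some voxels (perfect inversion "
                "bound); inspect those fits", stacklevel=2)


@dataclass
class IRFit:
    """Single-voxel IR fit."""

    t1: float
    i0: float
    a_factor: float
    residuals: np.ndarray
    cost: float


def ir_signal(tau, t1: float, i0: float, a: float):
    """Magnitude inversion-recovery model |I0 (1 - A exp(-tau/T1))|."""
    return i0 * np.abs(1.0 - a * np.exp(-np.asarray(tau, dtype=float) / t1))


def _residual_and_jac(p, tau, y):
    t1, i0, a = p
    e = np.exp(-tau / t1)
    f = 1.0 - a * e
    s = np.sign(f)
    s[s == 0] = 1.0
    r = i0 * np.abs(f) - y
    jac = np.empty((tau.size, 3))
    jac[:, 0] = i0 * s * (-a * e * tau / t1**2)
    jac[:, 1] = np.abs(f)
    jac[:, 2] = i0 * s * (-e)
    return r, jac


def fit_ir_magnitude(signal_voxel: np.ndarray, tau_list: np.ndarray,
                     a_max: float = 2.2, extra_starts: bool = True) -> IRFit:
    """Fit the magnitude IR model to one voxel's recovery curve.

    The absolute value makes the least-squares surface fold at the null
    point tau = T1 ln A, so the fit is initialized from the observed signal
    minimum (T1 ~ tau_null / ln 2) and, if the first solution is poor,
    restarted from a log-spaced T1 grid spanning the tau range.

    Raises
    ------
    RuntimeError
        If no start converges, or if the recovery is not sampled (fitted T1
        far beyond the largest tau, i.e. the parameters are unidentifiable).
    """
    y = np.asarray(signal_voxel, dtype=float)
    tau = np.asarray(tau_list, dtype=float)
    if y.size != tau.size or y.size < 5:
        raise ValueError("need >= 5 (tau, signal) samples")

    i0_init = float(np.max(y))
    if i0_init <= 0:
        raise RuntimeError("voxel signal is identically zero")
    tau_null = tau[int(np.argmin(y))]
    t1_starts = [max(tau_null / np.log(2.0), tau[0])]
    if extra_starts:
        t1_starts += list(np.geomspace(tau[1], tau[-1], 4))

    lb = [tau[0] * 1e-3, i0_init * 1e-3, 0.0]
    ub = [tau[-1] * 30.0, i0_init * 10.0, a_max]
    best = None
    # a start whose residuals are already at the few-percent level has
    # escaped the |.| fold; the remaining grid cannot do better
    accept_cost = (0.05 * i0_init) ** 2 * tau.size
    for t1_0 in t1_starts:
        p0 = np.array([t1_0, i0_init, 2.0])
        try:
            sol = least_squares(
                lambda p: _residual_and_jac(p, tau, y)[0], p0,
                jac=lambda p: _residual_and_jac(p, tau, y)[1],
                bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14,
                gtol=1e-14)
        except Exception:  # pragma: no cover - least_squares rarely raises
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < accept_cost:
            break
    if best is None:  # pragma: no cover
        raise RuntimeError("IR magnitude fit failed from all starts")
    t1, i0, a = best.x
    if t1 > 3.0 * tau[-1]:
        raise RuntimeError(
            f"fitted T1 = {t1:.3g} s is unconstrained by the tau grid "
            f"(max tau {tau[-1]:.3g} s): recovery not sampled")
    if np.min(y) > 0.5 * np.max(y):
        # with A ~ 2 the recovery null must be visible; a flat magnitude
        # curve is equally well fitted by T1 -> 0 and T1 -> inf
        raise RuntimeError(
            "recovery null not sampled by the tau grid (signal never drops "
            "below half its maximum): T1 is unidentifiable")
    return IRFit(t1=float(t1), i0=float(i0), a_factor=float(a),
                 residuals=best.fun, cost=float(best.cost))


def mc_error_t1(signal_voxel: np.ndarray, tau_list: np.ndarray, fit: IRFit,
                n_mc: int = 500, seed: int = 0) -> dict:
    """Monte-Carlo one-standard-deviation errors of the IR fit parameters.

    Synthetic datasets are the fitted model plus Gaussian noise with sigma
    equal to the RMS fit residual; each is refitted (initialized at the
    original solution) and the parameter standard deviations are returned.
    Deterministic for a fixed seed.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    tau = np.asarray(tau_list, dtype=float)
    model = ir_signal(tau, fit.t1, fit.i0, fit.a_factor)
    sigma = float(np.sqrt(np.mean(fit.residuals**2)))
    if sigma == 0.0:
        zero = {"t1": 0.0, "i0": 0.0, "a_factor": 0.0}
        return zero
    rng = np.random.default_rng(seed)
    params = np.empty((n_mc, 3))
    p0 = np.array([fit.t1, fit.i0, fit.a_factor])
    lb = [tau[0] * 1e-3, fit.i0 * 1e-3, 0.0]
    ub = [tau[-1] * 30.0, fit.i0 * 10.0, 2.5]
    p0 = np.clip(p0, lb, ub)
    for i in range(n_mc):
        y = np.abs(model + rng.normal(0.0, sigma, tau.size))
        sol = least_squares(
            lambda p: _residual_and_jac(p, tau, y)[0], p0,
            jac=lambda p: _residual_and_jac(p, tau, y)[1],
            bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
        params[i] = sol.x
    std = params.std(axis=0, ddof=1)
    return {"t1": float(std[0]), "i0": float(std[1]),
            "a_factor": float(std[2])}


def fit_t1_map(ir: IRSeries, mask: np.ndarray | None = None,
               with_errors: bool = False, n_mc: int = 100,
               seed: int = 0) -> T1Map:
    """Voxel-by-voxel IR fit over a stack; non-converged voxels become NaN."""
    n_tau, n_z, n_y = ir.signal.shape
    t1 = np.full((n_z, n_y), np.nan)
    i0 = np.full((n_z, n_y), np.nan)
    a = np.full((n_z, n_y), np.nan)
    err = np.full((n_z, n_y), np.nan) if with_errors else None
    ok = np.zeros((n_z, n_y), dtype=bool)
    for iz in range(n_z):
        for iy in range(n_y):
            if mask is not None and not mask[iz, iy]:
                continue
            try:
                fit = fit_ir_magnitude(ir.signal[:, iz, iy], ir.tau_list)
            except (RuntimeError, ValueError):
                continue
            t1[iz, iy], i0[iz, iy], a[iz, iy] = fit.t1, fit.i0, fit.a_factor
            ok[iz, iy] = True
            if with_errors:
                err[iz, iy] = mc_error_t1(
                    ir.signal[:, iz, iy], ir.tau_list, fit, n_mc=n_mc,
                    seed=seed + iz * n_y + iy)["t1"]
    return T1Map(t1=t1, i0=i0, a_factor=a, stderr_t1=err, converged=ok)


def concentration_from_t1(t1, calib: CalibrationModel):
    """Contrast-agent concentration c = (1/T1 - 1/T1pre)/R in mM.

    Noise can push 1/T1 slightly below 1/T1pre; the resulting small negative
    concentrations are preserved (clipping would bias averages) and a
    warning is emitted when they occur.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1[np.isfinite(t1)] <= 0):
        raise ValueError("T1 values must be positive")
    c = (1.0 / t1 - 1.0 / calib.t1_pre) / calib.relaxivity
    neg = c[np.isfinite(c)] < 0
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} voxel(s) map to negative concentration "
            "(noise about zero); preserved unclipped", stacklevel=2)
    return c if c.ndim else float(c)


def fit_relaxivity(t1_series) -> CalibrationModel:
    """Relaxivity calibration from (concentration mM, T1 s) pairs.

    Linear regression of the relaxation rate 1/T1 on concentration; the
    slope is the relaxivity R in (mM s)^-1 and the intercept is 1/T1pre.
    """
    arr = np.asarray(t1_series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, T1) pairs")
    conc, t1 = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("rank-deficient design: need >= 2 distinct "
                         "concentrations")
    if not np.any(conc == 0):
        warnings.warn("calibration series does not include c = 0; T1pre is "
                      "an extrapolation", stacklevel=2)
    res = linregress(conc, 1.0 / t1)
    if res.slope <= 0 or res.intercept <= 0:
        raise ValueError("calibration produced non-physical slope/intercept")
    return CalibrationModel(relaxivity=float(res.slope),
                            t1_pre=float(1.0 / res.intercept))


def smooth_map(map2d: np.ndarray, fwhm: float,
               voxel_size: tuple[float, float]) -> np.ndarray:
    """Gaussian smoothing of a (z, y) map with the stated FWHM (m).

    The kernel width is interpreted as full width at half maximum
    (sigma = FWHM / 2.355); reflective borders preserve the image sum.
    """
    sigma_vox = [fwhm * FWHM_TO_SIGMA / v for v in voxel_size]
    return ndimage.gaussian_filter(np.asarray(map2d, dtype=float), sigma_vox,
                                   mode="reflect")


def profile_from_maps(conc_map: np.ndarray, roi: slice | tuple | None = None):
    """Collapse a (z, y) concentration map to a 1-D profile.

    Averages over the y range ``roi`` (slice or (start, stop) tuple; default
    all columns) and returns (mean, standard error) arrays over z. NaN
    voxels (non-converged fits) are excluded per row.
    """
    m = np.asarray(conc_map, dtype=float)
    if roi is None:
        roi = slice(None)
    elif isinstance(roi, tuple):
        roi = slice(*roi)
    sub = m[:, roi]
    if sub.size == 0 or sub.shape[1] == 0:
        raise ValueError("empty ROI")
    n = np.sum(np.isfinite(sub), axis=1)
    mean = np.full(sub.shape[0], np.nan)
    sem = np.full(sub.shape[0], np.nan)
    rows = n > 0
    mean[rows] = np.nanmean(sub[rows], axis=1)
    rows2 = n > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sem[rows2] = (np.nanstd(sub[rows2], axis=1, ddof=1)
                      / np.sqrt(n[rows2]))
    if sub.shape[1] == 1:
        sem = np.where(rows, 0.0, np.nan)
    return mean, sem
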