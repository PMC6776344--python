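"""End-to-end synthetic experiments: transport truth -> T1 fields ->
noisy inversion-recovery stacks -> packaged fixture trees.

The generator emulates the muMRI experiment on the cartilage-model system:
a polyelectrolyte solution (FCD -73/-92/-108 mM) against 150 mM NaCl with
0.33 mM of the divalent contrast agent added to the salt side at t = 0,
imaged at 87 x 100 um resolution with a 32-point logarithmic recovery-delay
grid. Every random element flows from one integer seed, so regeneration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .analytic import erf_profile, erf_solution
from .donnan import solve_donnan_equilibrium
from .io import ProfileSeries
from .mri_recon import (IRSeries, concentration_from_t1, default_tau_grid,
                        fit_t1_map, ir_signal, profile_from_maps)
from .parameters import CalibrationModel, ParameterSet, get_parameter_set
from .transport import Geometry1D, jump_interface_solver

__all__ = [
    "ExperimentConfig",
    "generate_truth",
    "render_ir_stack",
    "reconstruct_profile",
    "reconstruct_series",
    "make_fixture_suite",
    "run_full_loop",
]

DEFAULT_OUTPUT_TIMES = tuple(3600.0 * h for h in (1.0, 2.5, 3.5, 4.5, 6.0))


@dataclass
class ExperimentConfig:
    """Everything needed to regenerate one synthetic experiment."""

    parameter_set: str = "fcd-108"
    #: experimental column: 10 mm polyelectrolyte, 0.1 mm membrane, and the
    #: full ~13 mm salt column of the sample holder (finite reservoir)
    geometry: Geometry1D = field(
        default_factory=lambda: Geometry1D(-10e-3, 100e-6, 13e-3))
    truth_model: str = "numeric"  # 'numeric' (jump solver) | 'analytic' (erf)
    boundary: str = "closed"
    convection: str = "off"  # 'off' | 'flat-salt'
    output_times: tuple = DEFAULT_OUTPUT_TIMES  # s
    tau_list: tuple = tuple(default_tau_grid())
    snr: float = 50.0  # np.inf for noiseless
    noise_model: str = "gaussian"  # 'gaussian' | 'rician'
    seed: int = 0
    voxel_size: tuple = (87e-6, 100e-6)  # (z, y), m
    n_y: int = 8
    i0: float = 100.0
    a_factor: float = 2.0
    t1_pre_salt: float = 3.2  # s
    t1_pre_poly: float = 2.8  # s
    dz_solver: float = 5e-5  # m, macroscopic mesh target

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def parameter_values(self) -> ParameterSet:
        return get_parameter_set(self.parameter_set)

    def calibrations(self) -> tuple[CalibrationModel, CalibrationModel]:
        """(poly, salt) relaxivity calibrations."""
        pset = self.parameter_values()
        r_poly = pset.relaxivity_poly or pset.relaxivity_salt
        return (CalibrationModel(r_poly, self.t1_pre_poly),
                CalibrationModel(pset.relaxivity_salt, self.t1_pre_salt))

    def voxel_grid(self) -> np.ndarray:
        """Voxel-centre z coordinates covering the full sample."""
        vz = self.voxel_size[0]
        return np.arange(self.geometry.z_poly_bottom + vz / 2,
                         self.geometry.d_salt, vz)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["output_times"] = list(self.output_times)
        d["tau_list"] = [float(x) for x in self.tau_list]
        d["snr"] = float(self.snr) if np.isfinite(self.snr) else "inf"
        return d


def generate_truth(config: ExperimentConfig):
    """Forward-simulate the ground-truth concentration fields.

    Returns (ProfileSeries on the voxel grid, DonnanState, truth record).
    The truth record carries every generator parameter an estimator might
    try to recover.
    """
    pset = config.parameter_values()
    state = solve_donnan_equilibrium(pset.bath, pset.na, pset.cl, pset.gd)
    ratio = state.partition_ratio_gd
    times = np.asarray(config.output_times, dtype=float)
    zg = config.voxel_grid()
    if config.truth_model == "numeric":
        sim = jump_interface_solver(
            config.geometry, pset.gd, ratio,
            times=np.concatenate([[0.0], times]),
            c_salt_initial=pset.bath.c_gd_salt_initial,
            boundary=config.boundary,
            convection_flat=(config.convection == "flat-salt"),
            dz=config.dz_solver)
        series = sim.interp(zg)
        series = ProfileSeries(sim.species, times, zg, series.conc[1:])
    elif config.truth_model == "analytic":
        if np.any(times <= 0):
            raise ValueError("analytic truth requires strictly positive "
                             "output times")
        sol = erf_solution(pset.bath.c_gd_salt_initial, ratio,
                           pset.gd.d_poly, pset.gd.d_salt_region)
        conc = np.vstack([erf_profile(sol, zg, t) for t in times])
        series = ProfileSeries(pset.gd.name, times, zg, conc)
    else:
        raise ValueError(f"unknown truth_model {config.truth_model!r}")
    truth = {
        "parameter_set": config.parameter_set,
        "d_poly": pset.gd.d_poly,
        "delta_mu_gd": pset.gd.delta_mu_corr,
        "partition_ratio_gd": ratio,
        "psi": state.psi,
        "c_salt_initial": pset.bath.c_gd_salt_initial,
        "truth_model": config.truth_model,
    }
    return series, state, truth


def _t1_field(profile: np.ndarray, z: np.ndarray,
              config: ExperimentConfig) -> np.ndarray:
    calib_poly, calib_salt = config.calibrations()
    t1 = np.where(z < 0, calib_poly.t1_of(profile), calib_salt.t1_of(profile))
    return t1


def render_ir_stack(profile: np.ndarray, z: np.ndarray,
                    config: ExperimentConfig,
                    rng: np.random.Generator | None = None) -> IRSeries:
    """Render one concentration frame into a noisy IR magnitude stack.

    T1 per voxel follows the per-region relaxivity calibration; the y axis
    replicates the 1-D profile with independent noise per voxel. Gaussian
    noise is added to the magnitude (high-SNR limit); 'rician' adds complex
    Gaussian noise before taking the magnitude, producing the characteristic
    signal floor at the recovery nulls.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tau = np.asarray(config.tau_list, dtype=float)
    t1 = _t1_field(np.asarray(profile, dtype=float), z, config)
    clean = config.i0 * np.abs(
        1.0 - config.a_factor * np.exp(-tau[:, None] / t1[None, :]))
    clean = np.repeat(clean[:, :, None], config.n_y, axis=2)
    if np.isinf(config.snr):
        signal = clean
    else:
        sigma = config.i0 / config.snr
        if config.noise_model == "gaussian":
            signal = np.abs(clean + rng.normal(0.0, sigma, clean.shape))
        else:  # rician
            re = clean + rng.normal(0.0, sigma, clean.shape)
            im = rng.normal(0.0, sigma, clean.shape)
            signal = np.hypot(re, im)
    return IRSeries(signal=signal, tau_list=tau,
                    voxel_size=config.voxel_size, z=z)


def reconstruct_profile(ir: IRSeries, config: ExperimentConfig,
                        membrane_band_voxels: int = 2):
    """Stack -> T1 map -> concentration -> y-averaged profile (+ sem).

    Voxels within ``membrane_band_voxels`` of z = 0 (membrane artifacts) and
    inside the membrane itself are masked out (NaN in the output).
    """
    z = ir.z
    tmap = fit_t1_map(ir)
    calib_poly, calib_salt = config.calibrations()
    conc = np.where(
        (z < 0)[:, None],
        concentration_from_t1(np.where(np.isfinite(tmap.t1), tmap.t1,
                                       calib_poly.t1_pre), calib_poly),
        concentration_from_t1(np.where(np.isfinite(tmap.t1), tmap.t1,
                                       calib_salt.t1_pre), calib_salt))
    conc[~tmap.converged] = np.nan
    vz = config.voxel_size[0]
    band = (np.abs(z) < membrane_band_voxels * vz) | (
        (z >= 0) & (z < config.geometry.membrane_thickness))
    conc[band] = np.nan
    mean, sem = profile_from_maps(conc)
    return mean, sem


def reconstruct_series(stacks: list, times, config: ExperimentConfig,
                       membrane_band_voxels: int = 2) -> ProfileSeries:
    """Assemble reconstructed frames into a ProfileSeries (NaN-masked
    voxels dropped column-wise only if masked at all times)."""
    profs, sems = [], []
    for ir in stacks:
        mean, sem = reconstruct_profile(ir, config, membrane_band_voxels)
        profs.append(mean)
        sems.append(sem)
    conc = np.vstack(profs)
    sems = np.vstack(sems)
    z = stacks[0].z
    keep = np.all(np.isfinite(conc), axis=0)
    return ProfileSeries("Gd(DTPA)2-", np.asarray(times, dtype=float),
                         z[keep], conc[:, keep], sems[:, keep])


def run_full_loop(config: ExperimentConfig, fit_z_max: float = 1e-3) -> dict:
    """Generator -> IR stacks -> T1 fitting -> concentration -> D_p fit.

    Returns the truth record plus the recovered diffusion coefficient, for
    closed-loop validation of the whole pipeline. Voxels beyond
    ``fit_z_max`` on the salt side are not reconstructed (the diffusion fit
    uses only the polyelectrolyte side and the near-interface band).
    """
    from .fitting import FitWindow, fit_d_poly, interface_scale_from_series

    series, state, truth = generate_truth(config)
    rng = np.random.default_rng(config.seed)
    stacks = [render_ir_stack(series.conc[i], series.z, config, rng)
              for i in range(series.times.size)]
    keep = series.z <= fit_z_max
    stacks = [IRSeries(signal=ir.signal[:, keep, :], tau_list=ir.tau_list,
                       voxel_size=ir.voxel_size, z=ir.z[keep])
              for ir in stacks]
    recon = reconstruct_series(stacks, series.times, config)
    t_lo = float(max(series.times.min(), 2.5 * 3600.0))
    t_hi = float(min(series.times.max(), 6.0 * 3600.0))
    window = FitWindow(t_min=t_lo - 1.0, t_max=t_hi + 1.0)
    if config.truth_model == "numeric":
        fit = fit_d_poly(recon, window, interface_model="numeric",
                         c_salt_of_t=interface_scale_from_series(recon))
    else:
        fit = fit_d_poly(recon, window)
    out = dict(truth)
    out.update({
        "d_poly_fit": fit.d_poly,
        "d_poly_stderr": fit.stderr_d,
        "relative_error": fit.d_poly / truth["d_poly"] - 1.0,
        "n_points": fit.n_points,
    })
    return out


FIXTURE_SETS = ("fcd-73", "fcd-92", "fcd-108", "ideal", "fcd-150-stress")


def make_fixture_suite(out_dir, seed: int = 0,
                       sets: tuple = FIXTURE_SETS,
                       base_config: ExperimentConfig | None = None) -> dict:
    """Write a complete synthetic fixture tree.

    One directory per parameter set containing config.yaml, truth.csv, one
    IR stack per output time (TIFF + JSON sidecar) and a manifest.json
    listing every file with its SHA-256 checksum. Regeneration with the same
    seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_all = {}
    for k, name in enumerate(sets):
        cfg = dataclasses.replace(
            base_config or ExperimentConfig(
                geometry=Geometry1D(-10e-3, 100e-6, 2e-3),
                boundary="dirichlet",
                output_times=(3600.0 * 2.5, 3600.0 * 4.0, 3600.0 * 5.5),
                n_y=2),
            parameter_set=name, seed=int(np.random.default_rng(
                [seed, k]).integers(0, 2**31 - 1)))
        set_dir = out_dir / name
        set_dir.mkdir(exist_ok=True)
        series, state, truth = generate_truth(cfg)
        dio.save_config(cfg.to_dict(), set_dir / "config.yaml")
        series.to_csv(set_dir / "truth.csv")
        rng = np.random.default_rng(cfg.seed)
        files = ["config.yaml", "truth.csv"]
        for i, t in enumerate(series.times):
            ir = render_ir_stack(series.conc[i], series.z, cfg, rng)
            stem = f"stack_t{i:02d}"
            dio.save_ir_stack(set_dir / f"{stem}.tiff", ir.signal,
                              ir.tau_list, ir.voxel_size,
                              {"time_s": float(t), "z_m": series.z.tolist()})
            files += [f"{stem}.tiff", f"{stem}.json"]
        manifest = {
            "parameter_set": name,
            "seed": cfg.seed,
            "truth": {k: float(v) if isinstance(v, (int, float)) else v
                      for k, v in truth.items()},
            "files": {f: dio.file_sha256(set_dir / f) for f in sorted(files)},
        }
        (set_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        manifest_all[name] = manifest
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest_all, indent=2, sort_keys=True))
    return manifest_all
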