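"""Containers and file formats: tidy profile tables, image stacks, configs
and run manifests.

``ProfileSeries`` is the common currency between the transport solvers, the
analytic solutions, the image-reconstruction pipeline and the fitting
routines: concentration of one species on a fixed spatial grid at a set of
times. Serialized as tidy CSV (columns time_s, z_m, species, conc_mM) and,
for image-pipeline interop, as multi-frame TIFF with a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


@dataclass
class ProfileSeries:
    """Concentration vs position vs time for one species.

    Attributes
    ----------
    times : (T,) array, s
    z : (N,) array, m — strictly increasing; interface at z = 0,
        polyelectrolyte at z < 0.
    conc : (T, N) array, mM
    stderr : optional (T, N) array of per-point standard errors, mM
    """

    species: str
    times: np.ndarray
    z: np.ndarray
    conc: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.z = np.asarray(self.z, dtype=float)
        self.conc = np.atleast_2d(np.asarray(self.conc, dtype=float))
        if self.conc.shape != (self.times.size, self.z.size):
            raise ValueError(
                f"conc shape {self.conc.shape} != "
                f"(n_times={self.times.size}, n_z={self.z.size})")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")

    # -- access helpers ------------------------------------------------------

    def frame(self, t: float) -> np.ndarray:
        """Profile at the stored time nearest to ``t`` (must match closely)."""
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t, rtol=1e-6, atol=1e-9):
            raise KeyError(f"time {t} not in series (nearest {self.times[i]})")
        return self.conc[i]

    def interp(self, z_new: np.ndarray) -> "ProfileSeries":
        """Linear resampling onto a new spatial grid."""
        z_new = np.asarray(z_new, dtype=float)
        conc = np.vstack([np.interp(z_new, self.z, row) for row in self.conc])
        return ProfileSeries(self.species, self.times.copy(), z_new, conc)

    def average(self, z_lo: float, z_hi: float) -> np.ndarray:
        """Spatial (trapezoidal) mean of each frame over [z_lo, z_hi]."""
        mask = (self.z >= z_lo) & (self.z <= z_hi)
        if mask.sum() < 2:
            raise ValueError("averaging window contains fewer than 2 nodes")
        zz = self.z[mask]
        return np.trapezoid(self.conc[:, mask], zz, axis=1) / (zz[-1] - zz[0])

    def total_mass(self) -> np.ndarray:
        """Line integral of concentration per frame (mM * m)."""
        return np.trapezoid(self.conc, self.z, axis=1)

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        t_col = np.repeat(self.times, self.z.size)
        z_col = np.tile(self.z, self.times.size)
        df = pd.DataFrame({
            "time_s": t_col,
            "z_m": z_col,
            "species": self.species,
            "conc_mM": self.conc.ravel(),
        })
        if self.stderr is not None:
            df["stderr_mM"] = self.stderr.ravel()
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 species: str | None = None) -> "ProfileSeries":
        df = pd.read_csv(path)
        if species is not None:
            df = df[df["species"] == species]
        else:
            species = str(df["species"].iloc[0])
            df = df[df["species"] == species]
        times = np.sort(df["time_s"].unique())
        z = np.sort(df["z_m"].unique())
        pivot = df.pivot_table(index="time_s", columns="z_m",
                               values="conc_mM").sort_index()
        conc = pivot.to_numpy()
        stderr = None
        if "stderr_mM" in df.columns:
            stderr = df.pivot_table(index="time_s", columns="z_m",
                                    values="stderr_mM").sort_index().to_numpy()
        return cls(species, times, z, conc, stderr)

    def to_tiff(self, path: str | Path) -> None:
        """Write frames as a multi-page float32 TIFF plus a JSON sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.conc[:, None, :].astype(np.float32),
                         photometric="minisblack")
        sidecar = {
            "species": self.species,
            "times_s": self.times.tolist(),
            "z_m": self.z.tolist(),
            "units": "mM",
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ProfileSeries":
        import tifffile

        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        conc = data.reshape(len(meta["times_s"]), len(meta["z_m"]))
        return cls(meta["species"], np.array(meta["times_s"]),
                   np.array(meta["z_m"]), conc)


def save_ir_stack(path: str | Path, signal: np.ndarray, tau_list: np.ndarray,
                  voxel_size: tuple[float, float],
                  extra_meta: dict | None = None) -> None:
    """Write an inversion-recovery stack (tau, z, y) as TIFF + JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(signal, dtype=np.float32),
                     photometric="minisblack")
    meta = {
        "tau_s": np.asarray(tau_list, dtype=float).tolist(),
        "voxel_size_m": list(voxel_size),
        "axes": "tau,z,y",
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_ir_stack(path: str | Path):
    """Read an IR stack written by :func:`save_ir_stack`.

    Returns (signal array (tau, z, y), tau array, voxel_size tuple, meta dict).
    """
    import tifffile

    path = Path(path)
    signal = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return (signal, np.asarray(meta["tau_s"], dtype=float),
            tuple(meta["voxel_size_m"]), meta)


# -- configuration and manifests ---------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written by every CLI run."""

    command: str
    config_hash: str
    seed: int | None
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started_unix: float = field(default_factory=_time.time)
    elapsed_s: float = 0.0
    versions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.versions:
            import numpy
            import scipy

            from . import __version__

            self.versions = {
                "donnanflux": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "python": platform.python_version(),
            }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
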