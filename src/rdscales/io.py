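"""Serialisation of fields and runs: plain-text CSV matrices, 16-bit PNGs,
and a self-describing run directory.

Layout of a run directory::

    run.json          parameters, lattice, dt, snapshot times, fingerprint
    u_t<k>.csv        activator grid at snapshot k (row-major, full precision)
    v_t<k>.csv        inhibitor grid at snapshot k
    u_t<k>.png        16-bit grayscale rendering (min-max scaled)
    u_t<k>.png.json   the scaling used for the PNG
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .kinetics import KineticParams
from .solver import FieldState, LatticeSpec, SimulationResult

__all__ = [
    "save_field_csv",
    "load_field_csv",
    "save_field_png",
    "save_run",
    "load_run",
]

_CSV_FMT = "%.17g"  # 17 significant digits round-trips float64 exactly


def save_field_csv(grid: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(grid), fmt=_CSV_FMT, delimiter=",")


def load_field_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def save_field_png(grid: np.ndarray, path) -> None:
    """Min-max scaled 16-bit grayscale PNG with a JSON sidecar for the scale."""
    g = np.asarray(grid, dtype=float)
    lo, hi = float(g.min()), float(g.max())
    scaled = np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 65535).round().astype(np.uint16))
    Path(str(path) + ".json").write_text(
        json.dumps({"min": lo, "max": hi, "dtype": "uint16"}, indent=2)
    )


def save_run(result: SimulationResult, out_dir, write_png: bool = True) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": result.params.to_dict(),
        "lattice": result.lattice.to_dict(),
        "dt": result.dt,
        "seed": result.seed,
        "times": result.times,
        "fingerprint": result.fingerprint,
    }
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    for k, snap in enumerate(result.snapshots):
        save_field_csv(snap.u, out / f"u_t{k}.csv")
        save_field_csv(snap.v, out / f"v_t{k}.csv")
        if write_png:
            save_field_png(snap.u, out / f"u_t{k}.png")
    return out


def load_run(run_dir) -> SimulationResult:
    run_dir = Path(run_dir)
    meta = json.loads((run_dir / "run.json").read_text())
    params = KineticParams.from_dict(meta["params"])
    lattice = LatticeSpec.from_dict(meta["lattice"])
    snapshots = []
    for k, t in enumerate(meta["times"]):
        u = load_field_csv(run_dir / f"u_t{k}.csv")
        v = load_field_csv(run_dir / f"v_t{k}.csv")
        snapshots.append(FieldState(u=u, v=v, t=float(t)))
    result = SimulationResult(
        snapshots=snapshots,
        params=params,
        lattice=lattice,
        dt=float(meta["dt"]),
        seed=meta.get("seed"),
        fingerprint=meta.get("fingerprint", ""),
    )
    return result
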