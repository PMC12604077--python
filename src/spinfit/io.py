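"""Plain-text persistence for spectra, FIDs and basis sets.

Spectra travel as a CSV (``ppm,real,imag`` — or ``time_s,real,imag`` for
FIDs) plus a JSON sidecar with acquisition metadata; a basis set is a
directory of such pairs listed in a ``manifest.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_sim import AcquisitionGrid, BasisSet, FID, Spectrum

__all__ = [
    "save_spectrum",
    "load_spectrum",
    "save_fid",
    "load_fid",
    "save_basis",
    "load_basis",
]

_FLOAT_FMT = "%.10g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_spectrum(spec: Spectrum, path: str | Path, truth: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"ppm": spec.ppm, "real": spec.values.real, "imag": spec.values.imag}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = dict(spec.meta)
    if truth is not None:
        meta["truth"] = truth
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=float)


def load_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
    return Spectrum(
        ppm=df["ppm"].to_numpy(),
        values=df["real"].to_numpy() + 1j * df["imag"].to_numpy(),
        meta=meta,
    )


def save_fid(fid: FID, path: str | Path) -> None:
    path = Path(path)
    t = fid.grid.time_axis_s
    df = pd.DataFrame(
        {"time_s": t, "real": fid.samples.real, "imag": fid.samples.imag}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = dict(fid.meta)
    meta["grid"] = {
        "f0_mhz": fid.grid.f0_mhz,
        "sweep_width_hz": fid.grid.sweep_width_hz,
        "n_points": fid.grid.n_points,
        "ref_ppm": fid.grid.ref_ppm,
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=float)


def load_fid(path: str | Path) -> FID:
    path = Path(path)
    df = pd.read_csv(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    g = meta.pop("grid")
    grid = AcquisitionGrid(
        f0_mhz=g["f0_mhz"],
        sweep_width_hz=g["sweep_width_hz"],
        n_points=int(g["n_points"]),
        ref_ppm=g["ref_ppm"],
    )
    return FID(
        samples=df["real"].to_numpy() + 1j * df["imag"].to_numpy(),
        grid=grid,
        meta=meta,
    )


def save_basis(basis: BasisSet, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, spec in basis.spectra.items():
        fname = f"{name}.csv"
        save_spectrum(spec, out / fname)
        files[name] = fname
    manifest = {"meta": dict(basis.meta), "spectra": files}
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    return mpath


def load_basis(dir_path: str | Path) -> BasisSet:
    d = Path(dir_path)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    spectra = {
        name: load_spectrum(d / fname)
        for name, fname in manifest["spectra"].items()
    }
    return BasisSet(spectra=spectra, meta=manifest.get("meta", {}))
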