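"""Configuration files, snapshot containers, and run artifacts.

Configs are flat INI key-value files with one section per module
(``[sideview]``, ``[confined]``, ``[analysis]``, ``[synth]``, ``[run]``).
Every run echoes its fully-resolved configuration and seed into the output
directory, snapshots go to HDF5, scalar time series to CSV, and field
renders to PNG.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .confined import ConfinedParams, ConfinedSeries, ConfinedState
from .sideview import DropSpec, SideViewParams, SideViewState, StateSeries

__all__ = [
    "load_config",
    "params_from_config",
    "echo_config",
    "write_side_series",
    "read_side_series",
    "write_confined_series",
    "read_confined_series",
    "write_series_csv",
    "render_side_state",
    "render_confined_state",
]


def load_config(path) -> dict[str, dict[str, str]]:
    """Parse a flat INI config into {section: {key: value}} (strings)."""
    cp = configparser.ConfigParser()
    cp.optionxform = str          # keys are case-sensitive (Nx vs nx)
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    return {s: dict(cp.items(s)) for s in cp.sections()}


def _coerce(fields: dict, raw: dict[str, str]) -> dict:
    """Coerce string config values onto dataclass field types."""
    out = {}
    for key, value in raw.items():
        if key not in fields:
            raise ValueError(f"unknown parameter {key!r}")
        ftype = fields[key]
        if ftype is bool:
            out[key] = value.lower() in ("1", "true", "yes", "on")
        elif ftype is int:
            out[key] = int(value)
        else:
            try:
                out[key] = float(value)
            except ValueError:
                out[key] = value
    return out


def _field_types(cls) -> dict:
    types = {}
    for f in dataclasses.fields(cls):
        t = f.type
        if isinstance(t, str):
            t = {"int": int, "float": float, "bool": bool,
                 "float | None": float, "int | None": int}.get(t, str)
        types[f.name] = t
    return types


def params_from_config(config: dict, overrides: dict | None = None):
    """Build (SideViewParams, DropSpec) and/or ConfinedParams from a config."""
    out = {}
    overrides = overrides or {}
    if "sideview" in config or any(k in overrides for k in ("c0", "eta")):
        raw = dict(config.get("sideview", {}))
        drop_keys = {f.name for f in dataclasses.fields(DropSpec)}
        drop_raw = {k: raw.pop(k) for k in list(raw) if k in drop_keys}
        raw.update({k: str(v) for k, v in overrides.items()
                    if k in _field_types(SideViewParams)})
        drop_raw.update({k: str(v) for k, v in overrides.items()
                         if k in drop_keys})
        out["sideview"] = SideViewParams(
            **_coerce(_field_types(SideViewParams), raw))
        out["drop"] = DropSpec(**_coerce(_field_types(DropSpec), drop_raw))
    if "confined" in config:
        raw = dict(config["confined"])
        raw.update({k: str(v) for k, v in overrides.items()
                    if k in _field_types(ConfinedParams)})
        out["confined"] = ConfinedParams(
            **_coerce(_field_types(ConfinedParams), raw))
    return out


def echo_config(out_dir, params, extra: dict | None = None) -> Path:
    """Write the fully-resolved parameters (and seed) as JSON + INI echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {}
    for name, obj in params.items():
        if dataclasses.is_dataclass(obj):
            payload[name] = dataclasses.asdict(obj)
        else:
            payload[name] = obj
    if extra:
        payload.update(extra)
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# HDF5 snapshot containers

_SIDE_FIELDS = ("rho", "c", "omega", "psi", "vx", "vz")


def write_side_series(path, series: StateSeries) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["model"] = "sideview"
        for key, value in dataclasses.asdict(series.params).items():
            f.attrs[f"param_{key}"] = -1 if value is None else value
        f.create_dataset("times", data=series.times)
        for k, state in enumerate(series):
            g = f.create_group(f"snap{k:05d}")
            g.attrs["t"] = state.t
            g.attrs["clipped_mass"] = state.clipped_mass
            for name in _SIDE_FIELDS:
                g.create_dataset(name, data=getattr(state, name),
                                 compression="gzip", compression_opts=4)


def read_side_series(path) -> StateSeries:
    with h5py.File(path, "r") as f:
        kwargs = {}
        for key in f.attrs:
            if key.startswith("param_"):
                kwargs[key[6:]] = f.attrs[key]
        if kwargs.get("dt", -1) == -1:
            kwargs["dt"] = None
        for name in ("Nx", "Nz", "seed"):
            kwargs[name] = int(kwargs[name])
        params = SideViewParams(**kwargs)
        states = []
        for key in sorted(k for k in f.keys() if k.startswith("snap")):
            g = f[key]
            fields = {name: g[name][...] for name in _SIDE_FIELDS}
            states.append(SideViewState(t=float(g.attrs["t"]),
                                        clipped_mass=float(
                                            g.attrs["clipped_mass"]),
                                        **fields))
    return StateSeries(states=states, params=params)


def write_confined_series(path, series: ConfinedSeries) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["model"] = "confined"
        for key, value in dataclasses.asdict(series.params).items():
            f.attrs[f"param_{key}"] = value
        f.create_dataset("times", data=series.times)
        for k, state in enumerate(series):
            g = f.create_group(f"snap{k:05d}")
            g.attrs["t"] = state.t
            g.create_dataset("rho", data=state.rho,
                             compression="gzip", compression_opts=4)
            g.create_dataset("c", data=state.c,
                             compression="gzip", compression_opts=4)


def read_confined_series(path) -> ConfinedSeries:
    with h5py.File(path, "r") as f:
        kwargs = {key[6:]: f.attrs[key] for key in f.attrs
                  if key.startswith("param_")}
        for name in ("N", "seed"):
            kwargs[name] = int(kwargs[name])
        params = ConfinedParams(**kwargs)
        states = []
        for key in sorted(k for k in f.keys() if k.startswith("snap")):
            g = f[key]
            states.append(ConfinedState(t=float(g.attrs["t"]),
                                        rho=g["rho"][...], c=g["c"][...]))
    return ConfinedSeries(states=states, params=params)


def write_series_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# renders

def render_side_state(path, state: SideViewState, params: SideViewParams,
                      quiver_stride: int = 16) -> None:
    """Density with velocity arrows, the side-view visualisation style."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 2.5))
    im = ax.imshow(state.rho.T, origin="lower", aspect="auto",
                   extent=(0, params.Lx, 0, params.Lz), cmap="turbo")
    s = quiver_stride
    x = np.arange(params.Nx)[::s] * params.dx
    z = np.linspace(0, params.Lz, params.Nz)[::s]
    ax.quiver(x, z, state.vx[::s, ::s].T, state.vz[::s, ::s].T,
              color="white", scale_units="xy")
    fig.colorbar(im, ax=ax, label="rho")
    ax.set_xlabel("x")
    ax.set_ylabel("z")
    ax.set_title(f"t = {state.t:.2f}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_confined_state(path, state: ConfinedState,
                          params: ConfinedParams) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(state.rho.T, origin="lower",
                   extent=(0, params.L, 0, params.L), cmap="turbo")
    fig.colorbar(im, ax=ax, label="rho")
    ax.set_title(f"t = {state.t:.2f}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
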