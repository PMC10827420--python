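"""Snapshot, trajectory and geometry export.

States and link tables are columnar (CSV or HDF5, chosen by extension);
trajectories are HDF5 with one group per frame plus the fully resolved
parameters; fibres can be exported as legacy-VTK polylines (with the local
alignment indicator as point data) for 3D viewing.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .crosslinking import LinkTable
from .geometry import DomainBox, FibreGeometry, FibreState, ModelParams, canonical_orientations

__all__ = [
    "save_state",
    "load_state",
    "save_links",
    "load_links",
    "save_events",
    "save_trajectory",
    "load_trajectory",
    "export_vtk_polylines",
    "export_frames",
    "params_to_dict",
    "params_from_dict",
]

_STATE_COLUMNS = ["fibre_id", "x", "y", "z", "ux", "uy", "uz", "t"]
_LINK_COLUMNS = ["link_id", "fibre_a", "fibre_b", "s_a", "s_b", "t_created"]


def _state_frame(state: FibreState) -> pd.DataFrame:
    om = canonical_orientations(state.omega)
    return pd.DataFrame(
        {
            "fibre_id": np.arange(state.n_fib),
            "x": state.X[:, 0],
            "y": state.X[:, 1],
            "z": state.X[:, 2],
            "ux": om[:, 0],
            "uy": om[:, 1],
            "uz": om[:, 2],
            "t": state.t,
        }
    )


def _links_frame(links: LinkTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "link_id": np.arange(len(links)),
            "fibre_a": links.fibre_a,
            "fibre_b": links.fibre_b,
            "s_a": links.s_a,
            "s_b": links.s_b,
            "t_created": links.t_created,
        }
    )


def save_state(state: FibreState, path: str | Path) -> None:
    path = Path(path)
    df = _state_frame(state)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for col in _STATE_COLUMNS:
                f.create_dataset(col, data=df[col].to_numpy())
    else:
        df.to_csv(path, index=False)


def load_state(path: str | Path) -> FibreState:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            df = pd.DataFrame({col: f[col][...] for col in _STATE_COLUMNS})
    else:
        df = pd.read_csv(path)
    X = df[["x", "y", "z"]].to_numpy()
    om = df[["ux", "uy", "uz"]].to_numpy()
    t = float(df["t"].iloc[0]) if len(df) else 0.0
    return FibreState(X, om, t)


def save_links(links: LinkTable, path: str | Path) -> None:
    path = Path(path)
    df = _links_frame(links)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for col in _LINK_COLUMNS:
                f.create_dataset(col, data=df[col].to_numpy())
    else:
        df.to_csv(path, index=False)


def load_links(path: str | Path) -> LinkTable:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            df = pd.DataFrame({col: f[col][...] for col in _LINK_COLUMNS})
    else:
        df = pd.read_csv(path)
    return LinkTable(
        df["fibre_a"].to_numpy(), df["fibre_b"].to_numpy(),
        df["s_a"].to_numpy(), df["s_b"].to_numpy(), df["t_created"].to_numpy(),
    )


def save_events(traj, path: str | Path) -> None:
    """Write the link/unlink event log as CSV (t, event, fibre_a, fibre_b)."""
    pd.DataFrame(
        traj.events, columns=["t", "event", "fibre_a", "fibre_b"]
    ).to_csv(path, index=False)


def params_to_dict(params: ModelParams) -> dict:
    d = dataclasses.asdict(params)
    return d


def params_from_dict(d: dict) -> ModelParams:
    d = dict(d)
    geom = d.pop("geometry", {})
    return ModelParams(geometry=FibreGeometry(**geom), **d)


def save_trajectory(traj, path: str | Path) -> None:
    """Write frames, link tables, events and resolved parameters to HDF5."""
    with h5py.File(path, "w") as f:
        if traj.params is not None:
            f.attrs["params"] = json.dumps(params_to_dict(traj.params))
        if traj.box is not None:
            f.attrs["box"] = json.dumps([traj.box.L_x, traj.box.L_y, traj.box.L_z])
        if traj.seed is not None:
            f.attrs["seed"] = int(traj.seed)
        frames = f.create_group("frames")
        for i, fr in enumerate(traj.frames):
            g = frames.create_group(f"{i:05d}")
            g.attrs["t"] = fr.state.t
            g.create_dataset("X", data=fr.state.X)
            g.create_dataset("omega", data=canonical_orientations(fr.state.omega))
            g.create_dataset("link_a", data=fr.links.fibre_a)
            g.create_dataset("link_b", data=fr.links.fibre_b)
            g.create_dataset("link_sa", data=fr.links.s_a)
            g.create_dataset("link_sb", data=fr.links.s_b)
            g.create_dataset("link_t", data=fr.links.t_created)
            if fr.summary is not None:
                g.attrs["al_sim"] = fr.summary.al_sim
                g.attrs["n_link_per_fib"] = fr.summary.n_link_per_fib
                g.attrs["a_max"] = fr.summary.a_max
                g.attrs["state_label"] = fr.summary.state_label
        if traj.events:
            ev = f.create_group("events")
            ev.create_dataset("t", data=np.array([e[0] for e in traj.events]))
            ev.create_dataset(
                "kind",
                data=np.array([e[1] for e in traj.events], dtype=h5py.string_dtype()),
            )
            ev.create_dataset("fibre_a", data=np.array([e[2] for e in traj.events]))
            ev.create_dataset("fibre_b", data=np.array([e[3] for e in traj.events]))


def load_trajectory(path: str | Path):
    from .integrator import Frame, Trajectory
    from .quantifiers import OrderSummary

    traj = Trajectory()
    with h5py.File(path, "r") as f:
        if "params" in f.attrs:
            traj.params = params_from_dict(json.loads(f.attrs["params"]))
        if "box" in f.attrs:
            traj.box = DomainBox(*json.loads(f.attrs["box"]))
        if "seed" in f.attrs:
            traj.seed = int(f.attrs["seed"])
        for name in sorted(f["frames"]):
            g = f["frames"][name]
            state = FibreState(g["X"][...], g["omega"][...], float(g.attrs["t"]))
            links = LinkTable(
                g["link_a"][...], g["link_b"][...],
                g["link_sa"][...], g["link_sb"][...], g["link_t"][...],
            )
            summary = None
            if "al_sim" in g.attrs:
                summary = OrderSummary(
                    t=state.t,
                    al_sim=float(g.attrs["al_sim"]),
                    n_link_per_fib=float(g.attrs["n_link_per_fib"]),
                    a_max=float(g.attrs["a_max"]),
                    state_label=str(g.attrs["state_label"]),
                )
            traj.frames.append(Frame(state, links, summary))
        if "events" in f:
            ev = f["events"]
            kinds = [k.decode() if isinstance(k, bytes) else k for k in ev["kind"][...]]
            traj.events = list(
                zip(ev["t"][...].tolist(), kinds, ev["fibre_a"][...].tolist(),
                    ev["fibre_b"][...].tolist())
            )
    return traj


def export_vtk_polylines(
    state: FibreState,
    geom: FibreGeometry,
    path: str | Path,
    al: np.ndarray | None = None,
) -> None:
    """Write fibres as legacy-VTK ASCII polylines (one segment per fibre).

    ``al`` attaches the local alignment indicator as point data for colouring;
    NaN values are written as 0.
    """
    n = state.n_fib
    h = geom.half_length
    p0 = state.X - h * state.omega
    p1 = state.X + h * state.omega
    pts = np.empty((2 * n, 3))
    pts[0::2] = p0
    pts[1::2] = p1
    lines = []
    lines.append("# vtk DataFile Version 3.0")
    lines.append("fibre network snapshot")
    lines.append("ASCII")
    lines.append("DATASET POLYDATA")
    lines.append(f"POINTS {2 * n} float")
    lines.extend(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in pts)
    lines.append(f"LINES {n} {3 * n}")
    lines.extend(f"2 {2 * i} {2 * i + 1}" for i in range(n))
    if al is not None:
        vals = np.nan_to_num(np.asarray(al, float), nan=0.0)
        lines.append(f"POINT_DATA {2 * n}")
        lines.append("SCALARS Al float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.6g}\n{v:.6g}" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


def export_frames(traj, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
    """Export every frame of a trajectory as CSV tables or VTK geometry."""
    from .quantifiers import alignment_field

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("csv", "vtk"):
        raise ValueError(f"unknown export format {fmt!r}")
    geom = traj.params.geometry if traj.params is not None else FibreGeometry()
    written: list[Path] = []
    for i, fr in enumerate(traj.frames):
        if fmt == "csv":
            p_state = out_dir / f"frame_{i:05d}_fibres.csv"
            save_state(fr.state, p_state)
            p_links = out_dir / f"frame_{i:05d}_links.csv"
            save_links(fr.links, p_links)
            written += [p_state, p_links]
        else:
            al = None
            if traj.params is not None and traj.box is not None and fr.state.n_fib > 1:
                al = alignment_field(fr.state, geom, traj.params.d_link_max, traj.box)
            p = out_dir / f"frame_{i:05d}.vtk"
            export_vtk_polylines(fr.state, geom, p, al=al)
            written.append(p)
    return written
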