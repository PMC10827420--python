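"""Run configuration: schema, validation and file round-trip.

A run configuration resolves to the default parameter set (the reference
values: L_fib = 6, R_fib = 0.5, alpha_rep = 12.5, alpha_rest = 5.0,
alpha_align = 2.0, d_link_max = d_link_eq = 1, cubic box of side 30,
T_final = 5e4) with any subset of fields overridden.  YAML, TOML and JSON are
accepted; unknown keys are rejected by name.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import DomainBox, FibreGeometry, ModelParams
from .integrator import StepControl

__all__ = ["SweepGrid", "RunConfig", "load_config", "save_config", "config_to_dict"]

#: admissible sweep ranges of the reference parameter study
SWEEP_RANGES = {"nu_link": (0.0, 10.0), "chi_link": (0.1, 0.9), "n_fib": (1500, 3000)}


@dataclass(frozen=True)
class SweepGrid:
    """Grid of (nu_link, chi_link, N_fib) cells for a parameter sweep."""

    nu_link: tuple[float, ...] = (0.1,)
    chi_link: tuple[float, ...] = (0.5,)
    n_fib: tuple[int, ...] = (3000,)
    allow_outside_reference_ranges: bool = False

    def __post_init__(self) -> None:
        if not self.allow_outside_reference_ranges:
            for name in ("nu_link", "chi_link", "n_fib"):
                lo, hi = SWEEP_RANGES[name]
                for v in getattr(self, name):
                    if not (lo <= v <= hi):
                        raise ValueError(
                            f"sweep.{name} value {v} outside reference range "
                            f"[{lo}, {hi}]; set allow_outside_reference_ranges "
                            "to override"
                        )

    def cells(self) -> list[tuple[float, float, int]]:
        return [
            (nu, chi, n)
            for nu in self.nu_link
            for chi in self.chi_link
            for n in self.n_fib
        ]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of a run (or sweep of runs)."""

    params: ModelParams = field(default_factory=ModelParams)
    box: DomainBox = field(default_factory=lambda: DomainBox.cube(30.0))
    ctrl: StepControl = field(default_factory=StepControl)
    replicates: int = 1
    n_frames: int = 25
    sweep: SweepGrid | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {where}: {sorted(unknown)}")


def _build(d: dict) -> RunConfig:
    _check_keys(d, {"params", "box", "ctrl", "replicates", "n_frames", "sweep"}, "config")
    pd_ = dict(d.get("params", {}))
    geom_fields = {f.name for f in dataclasses.fields(FibreGeometry)}
    par_fields = {f.name for f in dataclasses.fields(ModelParams)} | geom_fields
    _check_keys(pd_, par_fields, "params")
    geom_kwargs = {k: pd_.pop(k) for k in list(pd_) if k in geom_fields}
    if "geometry" in pd_:
        geom_kwargs = {**pd_.pop("geometry"), **geom_kwargs}
    try:
        params = ModelParams(geometry=FibreGeometry(**geom_kwargs), **pd_)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid params: {exc}") from exc

    bd = d.get("box", {})
    if isinstance(bd, (int, float)):
        box = DomainBox.cube(float(bd))
    else:
        _check_keys(dict(bd), {"L_x", "L_y", "L_z", "L"}, "box")
        if "L" in bd:
            box = DomainBox.cube(float(bd["L"]))
        elif bd:
            box = DomainBox(**{k: float(v) for k, v in bd.items()})
        else:
            box = DomainBox.cube(30.0)

    cd = dict(d.get("ctrl", {}))
    _check_keys(cd, {f.name for f in dataclasses.fields(StepControl)}, "ctrl")
    ctrl = StepControl(**cd)

    sweep = None
    if "sweep" in d and d["sweep"] is not None:
        sd = dict(d["sweep"])
        _check_keys(
            sd,
            {"nu_link", "chi_link", "n_fib", "allow_outside_reference_ranges"},
            "sweep",
        )
        for k in ("nu_link", "chi_link", "n_fib"):
            if k in sd:
                sd[k] = tuple(sd[k])
        sweep = SweepGrid(**sd)

    return RunConfig(
        params=params,
        box=box,
        ctrl=ctrl,
        replicates=int(d.get("replicates", 1)),
        n_frames=int(d.get("n_frames", 25)),
        sweep=sweep,
    )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/TOML/JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text) or {}
    elif path.suffix == ".toml":
        import tomllib

        d = tomllib.loads(text)
    elif path.suffix == ".json":
        d = json.loads(text)
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    if not isinstance(d, dict):
        raise ValueError("configuration root must be a mapping")
    return _build(d)


def config_to_dict(cfg: RunConfig) -> dict:
    d: dict = {
        "params": dataclasses.asdict(cfg.params),
        "box": {"L_x": cfg.box.L_x, "L_y": cfg.box.L_y, "L_z": cfg.box.L_z},
        "ctrl": dataclasses.asdict(cfg.ctrl),
        "replicates": cfg.replicates,
        "n_frames": cfg.n_frames,
    }
    geom = d["params"].pop("geometry")
    d["params"].update(geom)
    if cfg.sweep is not None:
        d["sweep"] = {
            "nu_link": list(cfg.sweep.nu_link),
            "chi_link": list(cfg.sweep.chi_link),
            "n_fib": list(cfg.sweep.n_fib),
            "allow_outside_reference_ranges": cfg.sweep.allow_outside_reference_ranges,
        }
    return d


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
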