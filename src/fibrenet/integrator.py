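"""Time integration of the coupled overdamped ODE / jump system.

Translation and rotation follow the overdamped equations

    mu_fib L_fib   dX_k/dt = sum_m (F_rep + p_km F_rest)
    mu_fib L_fib^3 dw_k/dt = sum_m (T_rep + p_km (T_rest + T_align)) ^ w_k

integrated with an explicit (forward) Euler scheme whose step is chosen
adaptively so that no fibre moves more than ``dx_max`` or rotates more than
``dth_max`` per step.  Directions are renormalized after every step.  Each
step is followed by Bernoulli-thinned link creation and deletion events
(fixed operator order: move, link, unlink).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, quantifiers
from .crosslinking import (
    LinkTable,
    bernoulli_initial_links,
    eligible_pairs,
    sample_link_events,
    sample_unlink_events,
)
from .fixtures import (
    ALIGN_CRITERION_ANGLE,
    ALIGN_START_OFFSET,
    make_orientation_field,
    make_two_fibre_fixture,
)
from .geometry import (
    DomainBox,
    FibreState,
    ModelParams,
    candidate_pairs,
    wrap_position,
)
from .interactions import accumulate_forces

__all__ = [
    "StepControl",
    "StiffConfigurationError",
    "Frame",
    "Trajectory",
    "euler_step",
    "run_simulation",
    "two_fibre_characteristic_time",
    "characteristic_time_closed_form",
    "ALIGN_CRITERION_ANGLE",
    "ALIGN_START_OFFSET",
]

class StiffConfigurationError(RuntimeError):
    """Raised when the adaptive step would fall below ``dt_min``."""


@dataclass(frozen=True)
class StepControl:
    """Adaptive-step parameters.

    ``dt = clamp(min(dx_max/max|v|, dth_max/max|dw/dt|), dt_min, dt_max)``;
    defaults cap the per-step displacement at a fifth of a fibre radius and
    the per-step rotation at 0.05 rad.
    """

    dt_init: float = 0.01
    dx_max: float = 0.05
    dth_max: float = 0.05
    dt_min: float = 1e-10
    dt_max: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.dt_min <= self.dt_init <= self.dt_max):
            raise ValueError("need dt_min <= dt_init <= dt_max with dt_min > 0")
        if self.dx_max <= 0 or self.dth_max <= 0:
            raise ValueError("dx_max and dth_max must be positive")


@dataclass
class Frame:
    state: FibreState
    links: LinkTable
    summary: "quantifiers.OrderSummary | None" = None


@dataclass
class Trajectory:
    frames: list[Frame] = field(default_factory=list)
    events: list[tuple[float, str, int, int]] = field(default_factory=list)
    params: ModelParams | None = None
    box: DomainBox | None = None
    seed: int | None = None
    n_steps: int = 0
    dt_min_seen: float = float("inf")
    dt_max_seen: float = 0.0

    @property
    def final(self) -> Frame:
        return self.frames[-1]

    def times(self) -> np.ndarray:
        return np.array([f.state.t for f in self.frames])


def euler_step(
    state: FibreState,
    links: LinkTable | None,
    params: ModelParams,
    ctrl: StepControl,
    box: DomainBox,
    pairs: np.ndarray | None = None,
    pair_geom=None,
    t_stop: float | None = None,
) -> tuple[FibreState, float]:
    """One adaptive forward-Euler step of the overdamped dynamics.

    Returns the new state and the step actually taken.  The realized per-fibre
    displacement is at most ``ctrl.dx_max`` and the rotation at most
    ``ctrl.dth_max``.
    """
    F, T = accumulate_forces(state, links, params, box, pairs=pairs, pair_geom=pair_geom)
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(T))):
        raise FloatingPointError("non-finite forces or torques")
    geom = params.geometry
    mu_L = params.mu_fib * geom.L_fib
    v = F / mu_L
    wdot = np.cross(T, state.omega) / (mu_L * geom.L_fib**2)
    vmax = float(np.max(np.linalg.norm(v, axis=1))) if state.n_fib else 0.0
    wmax = float(np.max(np.linalg.norm(wdot, axis=1))) if state.n_fib else 0.0
    dt = ctrl.dt_max
    if vmax > 0:
        dt = min(dt, ctrl.dx_max / vmax)
    if wmax > 0:
        dt = min(dt, ctrl.dth_max / wmax)
    if dt < ctrl.dt_min:
        raise StiffConfigurationError(
            f"adaptive step {dt:.3e} below dt_min={ctrl.dt_min:.3e} at t={state.t:.6g} "
            f"(max speed {vmax:.3g}, max rotation rate {wmax:.3g})"
        )
    if t_stop is not None:
        dt = min(dt, t_stop - state.t)
    disp = dt * v
    moved = np.any(disp != 0.0, axis=1)
    new_X = state.X.copy()
    if np.any(moved):  # wrapping an unmoved coordinate could disturb its last ulp
        new_X[moved] = wrap_position(state.X[moved] + disp[moved], box)
    new_om = state.omega + dt * wdot
    new_om /= np.linalg.norm(new_om, axis=1, keepdims=True)
    return FibreState(new_X, new_om, state.t + dt), dt


def _frame_times(t_final: float, n_frames: int) -> np.ndarray:
    """Logarithmically spaced frame times (the observables grow on log scales)."""
    if n_frames <= 1:
        return np.array([t_final])
    t0 = t_final / 10 ** max(2, n_frames // 8)
    return np.geomspace(max(t0, 1e-6), t_final, n_frames)


def run_simulation(
    params: ModelParams,
    box: DomainBox,
    ctrl: StepControl | None = None,
    seed: int | None = None,
    initial_state: FibreState | None = None,
    initial_links: LinkTable | str = "bernoulli",
    n_frames: int = 25,
    quantify: bool = True,
    record_events: bool = True,
    t_final: float | None = None,
) -> Trajectory:
    """Run the full model from random insemination (or a given state).

    Initial centres are uniform in the box and directions uniform on the
    half-sphere; the initial link set is Bernoulli(``chi_link``) over eligible
    pairs unless ``initial_links`` is ``"none"`` or an explicit table.
    Frames (state, links, order summary) are recorded at log-spaced times.
    Fully reproducible from ``seed``.
    """
    geom = params.geometry
    geom.check_box(box)
    ctrl = ctrl or StepControl()
    t_final = params.T_final if t_final is None else t_final
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)

    if initial_state is None:
        state = make_orientation_field("uniform", n=params.n_fib, box=box, rng=rng)
    else:
        state = initial_state.copy()
    state.validate(box)

    L = box.lengths
    h = geom.half_length
    cutoff = geom.L_fib + max(2.0 * geom.R_fib, params.d_link_max)
    skin = 1.0

    thresh = max(2.0 * geom.R_fib, params.d_link_max)
    pairs = candidate_pairs(state.X, box, cutoff + skin)
    geom_data = _kernels.pair_geometry(state.X, state.omega, pairs, L, h, thresh)
    ref_X = state.X.copy()

    if isinstance(initial_links, LinkTable):
        links = initial_links.copy()
    elif initial_links == "none":
        links = LinkTable()
    elif initial_links == "bernoulli":
        links = bernoulli_initial_links(
            state, geom, params.d_link_max, params.chi_link, box, rng
        )
    else:
        raise ValueError(f"unknown initial_links mode {initial_links!r}")

    traj = Trajectory(params=params, box=box, seed=seed)
    frame_times = _frame_times(t_final, n_frames)
    next_frame = 0

    def record(st: FibreState, lk: LinkTable) -> None:
        summ = (
            quantifiers.order_summary(st, lk, geom, params.d_link_max, box)
            if quantify and st.n_fib > 1
            else None
        )
        traj.frames.append(Frame(st.copy(), lk.copy(), summ))

    record(state, links)
    nu_unlink = params.nu_unlink

    while state.t < t_final:
        state, dt = euler_step(
            state, links, params, ctrl, box,
            pairs=pairs, pair_geom=geom_data, t_stop=t_final,
        )
        traj.n_steps += 1
        traj.dt_min_seen = min(traj.dt_min_seen, dt)
        traj.dt_max_seen = max(traj.dt_max_seen, dt)
        # refresh the candidate list when anything moved more than half the skin
        disp = np.abs(wrap_position(state.X - ref_X, box)).max(initial=0.0)
        if 2.0 * disp > skin:
            pairs = candidate_pairs(state.X, box, cutoff + skin)
            ref_X = state.X.copy()
        geom_data = _kernels.pair_geometry(state.X, state.omega, pairs, L, h, thresh)

        if params.nu_link > 0.0:
            elig, es1, es2 = eligible_pairs(
                state, geom, params.d_link_max, box,
                links=links, pairs=pairs, pair_geom=geom_data,
            )
            new_pairs, ns1, ns2 = sample_link_events(
                elig, es1, es2, params.nu_link, dt, rng
            )
            if new_pairs.shape[0]:
                links = links.add(new_pairs[:, 0], new_pairs[:, 1], ns1, ns2, state.t)
                if record_events:
                    traj.events.extend(
                        (state.t, "link", int(a), int(b)) for a, b in new_pairs
                    )
        if nu_unlink > 0.0 and len(links):
            gone = sample_unlink_events(links, nu_unlink, dt, rng)
            if np.any(gone):
                if record_events:
                    traj.events.extend(
                        (state.t, "unlink", int(a), int(b))
                        for a, b in zip(links.fibre_a[gone], links.fibre_b[gone])
                    )
                links = links.delete(gone)

        while next_frame < len(frame_times) and state.t >= frame_times[next_frame]:
            record(state, links)
            next_frame += 1

    if not traj.frames or traj.frames[-1].state.t < state.t:
        record(state, links)
    return traj


def two_fibre_characteristic_time(
    interaction: str,
    params: ModelParams,
    box: DomainBox | None = None,
    dt_max: float | None = None,
    tilt: float = ALIGN_START_OFFSET,
    t_cap: float | None = None,
) -> float:
    """Characteristic interaction time from the worst-case two-fibre system.

    ``rep``: fully overlapped unlinked pair separating under repulsion alone to
    99% of the equilibrium distance ``2 R_fib``.  ``rest``: fully overlapped
    pair crosslinked at their centres reaching 99% of the unloaded link length
    under the spring alone.  ``align``: near-perpendicular centre-crosslinked
    pair relaxing under the alignment torque alone to relative angle 0.9 deg
    (exactly perpendicular is a stationary point; the start is offset by
    ``tilt``).
    """
    if interaction not in ("rep", "rest", "align"):
        raise ValueError("interaction must be one of 'rep', 'rest', 'align'")
    geom = params.geometry
    box = box or DomainBox.cube(5.0 * (geom.L_fib + 2.0 * geom.R_fib))
    only = {
        "rep": dict(alpha_rest=0.0, alpha_align=0.0),
        "rest": dict(alpha_rep=0.0, alpha_align=0.0),
        "align": dict(alpha_rep=0.0, alpha_rest=0.0),
    }[interaction]
    p = params.with_(nu_link=0.0, **only)
    relevant = {"rep": p.alpha_rep, "rest": p.alpha_rest, "align": p.alpha_align}
    if relevant[interaction] <= 0:
        raise ValueError(f"alpha for {interaction!r} must be positive")
    state, links = make_two_fibre_fixture(interaction, geom, tilt=tilt)
    if dt_max is None:
        dt_max = 1e-3 if interaction in ("rep", "rest") else 0.1
    ctrl = StepControl(dt_init=dt_max, dt_max=dt_max, dt_min=1e-12)
    if t_cap is None:
        length = geom.L_fib**3 if interaction == "align" else geom.L_fib
        t_cap = 100.0 * p.mu_fib * length / relevant[interaction]

    def done(st: FibreState) -> bool:
        if interaction == "align":
            c = abs(float(st.omega[0] @ st.omega[1]))
            return math.acos(min(1.0, c)) <= ALIGN_CRITERION_ANGLE
        d = np.linalg.norm(wrap_position(st.X[1] - st.X[0], box))
        target = 0.99 * (2.0 * geom.R_fib if interaction == "rep" else p.d_link_eq)
        return d >= target

    while not done(state):
        state, _ = euler_step(state, links, p, ctrl, box)
        if state.t > t_cap:
            raise RuntimeError(
                f"99% criterion not reached within t_cap={t_cap:.3g} for {interaction!r}"
            )
    return state.t


def characteristic_time_closed_form(interaction: str, params: ModelParams) -> float:
    """Closed-form characteristic times of the two-fibre relaxation ODEs.

    rep:   9 mu L / alpha_rep          (Hertz 3/2 force law, 99% of 2R)
    rest:  ln(10) mu L / alpha_rest    (linear spring, 99% of d_eq)
    align: (mu L^3 / 2 alpha) ln((4/pi) cot^2(0.9 deg))   (nematic torque)
    """
    geom = params.geometry
    mu, L = params.mu_fib, geom.L_fib
    if interaction == "rep":
        return 9.0 * mu * L / params.alpha_rep
    if interaction == "rest":
        return math.log(10.0) * mu * L / params.alpha_rest
    if interaction == "align":
        tc = math.tan(ALIGN_CRITERION_ANGLE)
        return mu * L**3 / (2.0 * params.alpha_align) * math.log(4.0 / (math.pi * tc * tc))
    raise ValueError("interaction must be one of 'rep', 'rest', 'align'")
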