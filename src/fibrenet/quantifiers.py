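"""Quantifiers of emergent order in fibre networks.

Local order is measured per fibre by the alignment indicator ``Al_k``: the
square root of the eigenvalue gap ``lambda_1 - lambda_3`` of the second-moment
tensor ``<w w^T>`` of the directions in fibre ``k``'s neighbourhood (the fibre
itself included).  This score is 0 in expectation for uniformly random
neighbour directions, ``sqrt(1/2) ~ 0.7`` for directions uniform in a plane
and 1 when all neighbours share one direction, and is invariant under global
rotations and per-fibre sign flips.  ``Al_sim`` is its mean over fibres.

Global order is measured on the stereographic projection of all directions:
each direction is flipped to the upper half-sphere around a data-driven
reference axis (the principal nematic eigenvector) and mapped onto the unit
disk by the equal-area projection ``r = sqrt(2) sin(theta/2)``, so uniform
directions cover the disk uniformly.  ``A_max`` is the semi-major axis of the
2-sigma covariance ellipse of the projected cloud (``~1`` for the uniform
disk).  Simulation outcomes are classified from ``(Al_sim, A_max)`` with
thresholds 0.7 and 0.45 into aligned / curved / unorganized states.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._kernels import pair_geometry
from .geometry import DomainBox, FibreGeometry, FibreState, candidate_pairs

__all__ = [
    "OrderSummary",
    "EnsembleSummary",
    "fibre_density",
    "density_regime",
    "links_per_fibre",
    "local_alignment",
    "alignment_field",
    "mean_alignment",
    "nematic_tensor",
    "principal_axis",
    "stereographic_projection",
    "covariance_ellipse_semi_major",
    "classify_state",
    "order_summary",
    "ensemble_summary",
    "fit_tau_al",
    "fit_log_law",
    "TauFit",
    "LogLawFit",
]

#: spherocylinder packing densities: random (amorphous) and ordered
PHI_RANDOM = 0.4
PHI_ORDER = 0.89
#: classification thresholds on (Al_sim, A_max)
AL_THRESHOLD = 0.7
AMAX_THRESHOLD = 0.45


@dataclass(frozen=True)
class OrderSummary:
    """Per-frame quantifiers of one simulation snapshot."""

    t: float
    al_sim: float
    n_link_per_fib: float
    a_max: float
    state_label: str


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate statistics (population SD over the replicate set)."""

    al_mean: float
    al_std: float
    nlinkperfib_mean: float
    nlinkperfib_std: float
    n_replicates: int


def fibre_density(n_fib: int, geom: FibreGeometry, box: DomainBox) -> float:
    """Volume fraction ``N V_fib / |box|`` of N non-overlapping spherocylinders."""
    if box.volume <= 0:
        raise ValueError("box volume must be positive")
    v_fib = math.pi * geom.R_fib**2 * geom.L_fib + 4.0 / 3.0 * math.pi * geom.R_fib**3
    return n_fib * v_fib / box.volume


def density_regime(phi: float) -> str:
    """'sparse' below random packing, 'hyperdense' above ordered packing."""
    if phi < PHI_RANDOM:
        return "sparse"
    if phi > PHI_ORDER:
        return "hyperdense"
    return "dense"


def links_per_fibre(links, n_fib: int) -> float:
    """``N_links / N_fib`` (0.5 when every fibre is in exactly one link)."""
    if n_fib <= 0:
        raise ValueError("n_fib must be positive")
    return len(links) / n_fib


def local_alignment(omega_k: np.ndarray, neighbour_omegas: np.ndarray) -> float:
    """Alignment indicator ``Al_k`` of one fibre against its neighbours.

    Returns NaN when the fibre has no neighbours (the score is undefined and
    the fibre is excluded from ``Al_sim``).
    """
    neighbour_omegas = np.asarray(neighbour_omegas, float).reshape(-1, 3)
    if neighbour_omegas.shape[0] == 0:
        return float("nan")
    omegas = np.vstack([np.asarray(omega_k, float).reshape(1, 3), neighbour_omegas])
    M = omegas.T @ omegas / omegas.shape[0]
    ev = np.linalg.eigvalsh(M)
    return float(np.sqrt(max(0.0, ev[-1] - ev[0])))


def alignment_field(
    state: FibreState,
    geom: FibreGeometry,
    d_link_max: float,
    box: DomainBox,
    radius: float | None = None,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """``Al_k`` for every fibre; NaN where a fibre has no neighbours.

    The neighbourhood of fibre ``k`` is every fibre within segment-segment
    distance ``2 R_fib + d_link_max`` (contact plus perception shell) unless
    ``radius`` overrides it.
    """
    radius = radius if radius is not None else 2.0 * geom.R_fib + d_link_max
    n = state.n_fib
    if pairs is None:
        pairs = candidate_pairs(state.X, box, geom.L_fib + radius)
    if pairs.shape[0]:
        _, _, dist = pair_geometry(
            state.X, state.omega, pairs, box.lengths, geom.half_length, radius
        )
        pairs = pairs[dist <= radius]
    # accumulate the neighbourhood second-moment tensor of every fibre
    outer = state.omega[:, :, None] * state.omega[:, None, :]
    M = outer.copy()  # each fibre counts itself
    counts = np.ones(n)
    if pairs.shape[0]:
        np.add.at(M, pairs[:, 0], outer[pairs[:, 1]])
        np.add.at(M, pairs[:, 1], outer[pairs[:, 0]])
        np.add.at(counts, pairs[:, 0], 1.0)
        np.add.at(counts, pairs[:, 1], 1.0)
    M /= counts[:, None, None]
    ev = np.linalg.eigvalsh(M)
    al = np.sqrt(np.clip(ev[:, -1] - ev[:, 0], 0.0, None))
    al[counts < 2] = np.nan  # no neighbours: indicator undefined
    return al


def mean_alignment(al_k: np.ndarray) -> float:
    """``Al_sim``: unweighted mean of the defined per-fibre indicators."""
    al_k = np.asarray(al_k, float)
    if not np.any(np.isfinite(al_k)):
        raise ValueError("no fibre has a defined alignment indicator")
    return float(np.nanmean(al_k))


def nematic_tensor(omegas: np.ndarray) -> np.ndarray:
    """``Q = <w w^T> - I/3`` (traceless; zero for isotropic directions)."""
    omegas = np.asarray(omegas, float).reshape(-1, 3)
    return omegas.T @ omegas / omegas.shape[0] - np.eye(3) / 3.0


def principal_axis(omegas: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the nematic tensor (the dominant direction)."""
    _, vecs = np.linalg.eigh(nematic_tensor(omegas))
    return vecs[:, -1]


def stereographic_projection(
    omegas: np.ndarray, axis: np.ndarray | None = None
) -> np.ndarray:
    """Project nematic directions onto the unit disk around a reference axis.

    Directions are flipped to the hemisphere around ``axis`` (default: the
    principal nematic eigenvector) and mapped with the equal-area projection
    ``r = sqrt(2) sin(theta/2)``: the axis maps to the disk centre, equatorial
    directions to the rim, and uniform directions cover the disk uniformly.
    """
    omegas = np.asarray(omegas, float).reshape(-1, 3)
    axis = principal_axis(omegas) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    z = omegas @ axis
    flip = np.where(z < 0, -1.0, 1.0)
    z = np.abs(np.clip(z, -1.0, 1.0))
    u = (omegas * flip[:, None]) @ e1
    v = (omegas * flip[:, None]) @ e2
    theta = np.arccos(z)
    r = math.sqrt(2.0) * np.sin(0.5 * theta)
    rho = np.hypot(u, v)
    safe = np.where(rho > 1e-300, rho, 1.0)
    return np.column_stack([r * u / safe, r * v / safe])


def covariance_ellipse_semi_major(points: np.ndarray) -> float:
    """Semi-major axis of the 2-sigma covariance ellipse of a planar cloud.

    ``A_max = 2 sqrt(lambda_max)`` of the 2x2 covariance matrix; points
    uniform on the unit disk give ``A_max ~ 1``; identical points give 0.
    """
    points = np.asarray(points, float).reshape(-1, 2)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points for a covariance ellipse")
    if np.all(points == points[0]):
        return 0.0
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred / points.shape[0]
    lam = float(np.linalg.eigvalsh(cov)[-1])
    return 2.0 * math.sqrt(max(lam, 0.0))


def classify_state(al_sim: float, a_max: float) -> str:
    """Three-state classification from the local and global quantifiers."""
    if not (np.isfinite(al_sim) and np.isfinite(a_max)):
        raise ValueError("quantifiers must be finite")
    if al_sim >= AL_THRESHOLD:
        return "aligned" if a_max <= AMAX_THRESHOLD else "curved"
    return "unnamed" if a_max <= AMAX_THRESHOLD else "unorganized"


def order_summary(
    state: FibreState,
    links,
    geom: FibreGeometry,
    d_link_max: float,
    box: DomainBox,
) -> OrderSummary:
    """All per-frame quantifiers of one snapshot."""
    al = mean_alignment(alignment_field(state, geom, d_link_max, box))
    a_max = covariance_ellipse_semi_major(stereographic_projection(state.omega))
    return OrderSummary(
        t=state.t,
        al_sim=al,
        n_link_per_fib=links_per_fibre(links, state.n_fib),
        a_max=a_max,
        state_label=classify_state(al, a_max),
    )


def ensemble_summary(summaries: list[OrderSummary]) -> EnsembleSummary:
    """Mean/SD of ``Al_sim`` and ``N_linkperfib`` over replicate runs."""
    if len(summaries) < 2:
        raise ValueError("ensemble statistics need at least 2 replicates")
    al = np.array([s.al_sim for s in summaries])
    nl = np.array([s.n_link_per_fib for s in summaries])
    return EnsembleSummary(
        al_mean=float(al.mean()),
        al_std=float(al.std(ddof=0)),
        nlinkperfib_mean=float(nl.mean()),
        nlinkperfib_std=float(nl.std(ddof=0)),
        n_replicates=len(summaries),
    )


@dataclass(frozen=True)
class TauFit:
    """Saturating-growth fit ``A(t) = A0 + (Ainf - A0)(1 - exp(-t/tau))``."""

    tau_al: float
    tau: float
    a0: float
    a_inf: float


def fit_tau_al(t: np.ndarray, al: np.ndarray) -> TauFit:
    """Time constant ``tau_Al``: when the fitted curve reaches 63% of its asymptote.

    Raises ``ValueError`` for a series that has not begun to saturate within
    its time span (the asymptote would be extrapolation).
    """
    t = np.asarray(t, float)
    al = np.asarray(al, float)
    ok = np.isfinite(t) & np.isfinite(al)
    t, al = t[ok], al[ok]
    if t.size < 4:
        raise ValueError("need at least 4 points to fit a time constant")
    span = float(t.max() - t.min())
    if float(np.ptp(al)) < 1e-12:  # constant series: already at its asymptote
        return TauFit(0.0, 0.0, float(al[0]), float(al[0]))

    def model(tt, a0, ainf, tau):
        return a0 + (ainf - a0) * (1.0 - np.exp(-tt / tau))

    p0 = (float(al[0]), float(al[-1]), max(span / 5.0, 1e-9))
    popt, _ = curve_fit(model, t, al, p0=p0, maxfev=20000)
    a0, ainf, tau = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if tau > 0.75 * span or not np.isfinite(tau):
        raise ValueError(
            f"series does not saturate within its span (fitted tau={tau:.3g}, span={span:.3g})"
        )
    # solve A(t) = 0.63 * Ainf
    ratio = (ainf - 0.63 * ainf) / (ainf - a0) if ainf != a0 else 1.0
    if ratio >= 1.0:  # already above 63% of the asymptote at t = 0
        return TauFit(0.0, tau, a0, ainf)
    if ratio <= 0.0:
        raise ValueError("fitted asymptote inconsistent with a 63% crossing")
    return TauFit(-tau * math.log(ratio), tau, a0, ainf)


@dataclass(frozen=True)
class LogLawFit:
    """Logarithmic law ``Al_mean ~ alpha log(N_linkperfib) + beta`` below a drop."""

    alpha: float
    beta: float
    r_squared: float
    n_critic: float  # NaN when no drop is detected


def fit_log_law(
    n_link_per_fib: np.ndarray,
    al_mean: np.ndarray,
    min_points: int = 4,
    drop_frac: float = 0.1,
) -> LogLawFit:
    """Fit the below-threshold logarithmic branch and locate the drop.

    Points are sorted by link count; an expanding-window least-squares fit on
    ``(log N, Al)`` flags the first point falling more than ``drop_frac``
    (relative) below the running prediction as the critical link count
    ``N_critic``; the final fit uses only points below it.
    """
    x = np.asarray(n_link_per_fib, float)
    y = np.asarray(al_mean, float)
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points")
    if np.any(x <= 0):
        raise ValueError("link counts must be positive for a log fit")
    order = np.argsort(x)
    x, y = x[order], y[order]
    lx = np.log(x)

    def _ls(k: int) -> tuple[float, float]:
        A = np.column_stack([lx[:k], np.ones(k)])
        coef, *_ = np.linalg.lstsq(A, y[:k], rcond=None)
        return float(coef[0]), float(coef[1])

    n_critic = float("nan")
    upper = x.size
    for k in range(min_points, x.size):
        a, b = _ls(k)
        pred = a * lx[k] + b
        if pred > 0 and (pred - y[k]) / pred > drop_frac:
            n_critic = float(x[k])
            upper = k
            break
    a, b = _ls(upper)
    resid = y[:upper] - (a * lx[:upper] + b)
    ss_tot = float(np.sum((y[:upper] - y[:upper].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LogLawFit(alpha=a, beta=b, r_squared=r2, n_critic=n_critic)
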