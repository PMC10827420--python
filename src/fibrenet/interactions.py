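"""Pairwise forces and torques of the overdamped fibre dynamics.

Three elementary interactions act between fibre pairs:

* **Hertzian repulsion** between overlapping spherocylinders, with magnitude
  ``alpha_rep * (2R - d)^{3/2} / sqrt(2R)`` for closest-point distance
  ``d < 2R``, applied at the closest points.
* **Crosslink spring**: a linear spring of stiffness ``alpha_rest`` and
  unloaded length ``d_link_eq`` between two material points fixed at link
  creation.
* **Nematic alignment torque** at each crosslink, deriving from the potential
  ``V = -(alpha_align/2) (w1 . w2)^2``; it vanishes for aligned fibres,
  is invariant under ``w -> -w`` of either fibre and carries no force.

Repulsion and spring obey action-reaction, so internal forces sum to zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import (
    DomainBox,
    FibreGeometry,
    FibreState,
    ModelParams,
    candidate_pairs,
    periodic_displacement,
    segment_closest_points,
)

__all__ = [
    "PairForceTorque",
    "repulsion_force_torque",
    "spring_force_torque",
    "alignment_torque",
    "accumulate_forces",
]


@dataclass(frozen=True)
class PairForceTorque:
    """Force and torque on each member of an interacting fibre pair."""

    F_on_1: np.ndarray
    F_on_2: np.ndarray
    T_on_1: np.ndarray
    T_on_2: np.ndarray

    @classmethod
    def zero(cls) -> "PairForceTorque":
        z = np.zeros(3)
        return cls(z.copy(), z.copy(), z.copy(), z.copy())


def _fallback_direction(k: int, m: int, omega: np.ndarray) -> np.ndarray:
    return np.asarray(_kernels._pair_unit_perp(k, m, np.asarray(omega, float)))


def repulsion_force_torque(
    X1, omega1, X2, omega2,
    geom: FibreGeometry,
    alpha_rep: float,
    box: DomainBox,
    indices: tuple[int, int] = (0, 1),
) -> PairForceTorque:
    """Hertzian repulsion between two spherocylinders (zero when not in contact)."""
    s1, s2, dist = segment_closest_points(X1, omega1, X2, omega2, geom, box)
    two_R = 2.0 * geom.R_fib
    if dist >= two_R:
        return PairForceTorque.zero()
    r = periodic_displacement(X1, X2, box)
    if dist > 1e-12:
        n = (r + s2 * np.asarray(omega2, float) - s1 * np.asarray(omega1, float)) / dist
    else:
        n = _fallback_direction(indices[0], indices[1], omega1)
    mag = alpha_rep * (two_R - dist) ** 1.5 / np.sqrt(two_R)
    F1 = -mag * n
    T1 = np.cross(s1 * np.asarray(omega1, float), F1)
    T2 = np.cross(s2 * np.asarray(omega2, float), -F1)
    return PairForceTorque(F1, -F1, T1, T2)


def spring_force_torque(
    X1, omega1, X2, omega2,
    s_a: float,
    s_b: float,
    geom: FibreGeometry,
    alpha_rest: float,
    d_link_eq: float,
    box: DomainBox,
    indices: tuple[int, int] = (0, 1),
) -> PairForceTorque:
    """Linear restoring force between the two attachment points of a crosslink."""
    h = geom.half_length
    if not (-h <= s_a <= h and -h <= s_b <= h):
        raise ValueError("attachment abscissae must lie within the fibre")
    omega1 = np.asarray(omega1, float)
    omega2 = np.asarray(omega2, float)
    delta = periodic_displacement(X1, X2, box) + s_b * omega2 - s_a * omega1
    dist = float(np.linalg.norm(delta))
    if dist > 1e-12:
        u = delta / dist
    else:
        u = _fallback_direction(indices[0], indices[1], omega1)
    F1 = alpha_rest * (dist - d_link_eq) * u
    T1 = np.cross(s_a * omega1, F1)
    T2 = np.cross(s_b * omega2, -F1)
    return PairForceTorque(F1, -F1, T1, T2)


def alignment_torque(omega1, omega2, alpha_align: float) -> PairForceTorque:
    """Nematic alignment torque of a crosslinked pair (pure torque).

    Derived from ``V = -(alpha_align/2)(w1.w2)^2``:
    ``T_on_1 = alpha_align (w1.w2) (w1 x w2)`` and ``T_on_2 = -T_on_1``.
    Zero for parallel fibres; perpendicular fibres sit at the (unstable)
    maximum of ``V`` where the torque is exactly zero as well.
    """
    omega1 = np.asarray(omega1, float)
    omega2 = np.asarray(omega2, float)
    c = float(omega1 @ omega2)
    T1 = alpha_align * c * np.cross(omega1, omega2)
    z = np.zeros(3)
    return PairForceTorque(z, z.copy(), T1, -T1)


def accumulate_forces(
    state: FibreState,
    links,
    params: ModelParams,
    box: DomainBox,
    pairs: np.ndarray | None = None,
    pair_geom: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total force and torque on every fibre (the double sums of the dynamics).

    ``pairs`` may carry a precomputed candidate pair list (any superset of the
    pairs in repulsion range); the result is independent of the search
    structure used.  Returns ``(F, T)`` with shapes ``(N, 3)``.
    """
    geom = params.geometry
    n = state.n_fib
    F = np.zeros((n, 3))
    T = np.zeros((n, 3))
    if n == 0:
        return F, T
    L = box.lengths
    h = geom.half_length
    two_R = 2.0 * geom.R_fib
    if pairs is None:
        pairs = candidate_pairs(state.X, box, geom.L_fib + two_R)
    if pairs.shape[0]:
        if pair_geom is None:
            s1, s2, dist = _kernels.pair_geometry(
                state.X, state.omega, pairs, L, h, two_R
            )
        else:
            s1, s2, dist = pair_geom
        _kernels.accumulate_repulsion(
            state.X, state.omega, pairs, s1, s2, dist, L, two_R, params.alpha_rep, F, T
        )
    if links is not None and len(links):
        _kernels.accumulate_link_forces(
            state.X,
            state.omega,
            links.fibre_a,
            links.fibre_b,
            links.s_a,
            links.s_b,
            L,
            params.alpha_rest,
            params.d_link_eq,
            params.alpha_align,
            F,
            T,
        )
    return F, T
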