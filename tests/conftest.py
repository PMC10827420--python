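"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from fibrenet import DomainBox, FibreGeometry, FibreState, ModelParams


@pytest.fixture(scope="session")
def geom() -> FibreGeometry:
    return FibreGeometry(L_fib=6.0, R_fib=0.5)


@pytest.fixture(scope="session")
def box() -> DomainBox:
    return DomainBox.cube(30.0)


@pytest.fixture(scope="session")
def params(geom) -> ModelParams:
    return ModelParams(geometry=geom)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240131)


def random_state(n: int, box: DomainBox, seed: int) -> FibreState:
    g = np.random.default_rng(seed)
    X = g.uniform(-0.5, 0.5, size=(n, 3)) * box.lengths
    om = g.normal(size=(n, 3))
    om /= np.linalg.norm(om, axis=1, keepdims=True)
    return FibreState(X, om)


def min_image(d: np.ndarray, box: DomainBox) -> np.ndarray:
    L = box.lengths
    return d - L * np.floor(d / L + 0.5)


def grid_min_distance(
    X1, w1, X2, w2, geom: FibreGeometry, box: DomainBox, n_coarse=81, n_fine=81
) -> float:
    """Dense-grid minimization of the segment-segment distance (oracle).

    Two-stage: coarse grid over the full abscissa square, then a fine grid in
    a window around the coarse minimum.  Independent of the analytic
    closest-point computation under test.
    """
    h = geom.half_length
    r = min_image(np.asarray(X2, float) - np.asarray(X1, float), box)
    w1 = np.asarray(w1, float)
    w2 = np.asarray(w2, float)

    def scan(lo1, hi1, lo2, hi2, n):
        s1 = np.linspace(lo1, hi1, n)
        s2 = np.linspace(lo2, hi2, n)
        P1 = s1[:, None, None] * w1[None, None, :]
        P2 = r[None, None, :] + s2[None, :, None] * w2[None, None, :]
        D = np.linalg.norm(P2 - P1, axis=2)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        return s1[i], s2[j], D[i, j], (s1[1] - s1[0]), (s2[1] - s2[0])

    a, b, d, da, db = scan(-h, h, -h, h, n_coarse)
    for _ in range(3):
        a, b, d, da, db = scan(
            max(-h, a - da), min(h, a + da), max(-h, b - db), min(h, b + db), n_fine
        )
    return d


def naive_force_sum(state: FibreState, links, params: ModelParams, box: DomainBox):
    """All-pairs O(N^2) force/torque sums using the scalar pair functions."""
    from fibrenet import alignment_torque, repulsion_force_torque, spring_force_torque

    n = state.n_fib
    F = np.zeros((n, 3))
    T = np.zeros((n, 3))
    geom = params.geometry
    for k in range(n):
        for m in range(k + 1, n):
            ft = repulsion_force_torque(
                state.X[k], state.omega[k], state.X[m], state.omega[m],
                geom, params.alpha_rep, box, indices=(k, m),
            )
            F[k] += ft.F_on_1
            F[m] += ft.F_on_2
            T[k] += ft.T_on_1
            T[m] += ft.T_on_2
    if links is not None:
        for a, b, sa, sb in zip(links.fibre_a, links.fibre_b, links.s_a, links.s_b):
            ft = spring_force_torque(
                state.X[a], state.omega[a], state.X[b], state.omega[b],
                sa, sb, geom, params.alpha_rest, params.d_link_eq, box, indices=(a, b),
            )
            F[a] += ft.F_on_1
            F[b] += ft.F_on_2
            T[a] += ft.T_on_1
            T[b] += ft.T_on_2
            al = alignment_torque(state.omega[a], state.omega[b], params.alpha_align)
            T[a] += al.T_on_1
            T[b] += al.T_on_2
    return F, T
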