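"""Seeded generators of fibre configurations and link topologies.

These synthetic states have known ground truth (orientation statistics, link
counts, two-fibre worst cases), so every quantifier and force operation can be
tested without running full simulations.  Identical spec + seed always yields
an identical fixture.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crosslinking import LinkTable, eligible_pairs
from .geometry import (
    DomainBox,
    FibreGeometry,
    FibreState,
    canonical_orientations,
    segment_closest_points,
)

__all__ = [
    "ALIGN_CRITERION_ANGLE",
    "ALIGN_START_OFFSET",
    "FixtureSpec",
    "make_fixture",
    "make_orientation_field",
    "make_two_fibre_fixture",
    "make_link_topology",
]

#: criterion angle of the alignment characteristic time (1% of a right angle)
ALIGN_CRITERION_ANGLE = math.radians(0.9)
#: regularizing offset from exactly perpendicular used by the alignment
#: characteristic time: tan(offset) = (pi/4) tan(0.9 deg); see docs/methods.md
ALIGN_START_OFFSET = math.atan(0.25 * math.pi * math.tan(ALIGN_CRITERION_ANGLE))

_ORIENTATION_KINDS = ("uniform", "unidirectional", "planar", "concentration")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    kind: str
    n: int = 0
    seed: int = 0
    kappa: float | None = None
    chi: float | None = None
    box: DomainBox = field(default_factory=lambda: DomainBox.cube(30.0))
    geometry: FibreGeometry = field(default_factory=FibreGeometry)


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    if spec.kind in _ORIENTATION_KINDS:
        return make_orientation_field(
            spec.kind, spec.n, seed=spec.seed, box=spec.box, kappa=spec.kappa
        )
    if spec.kind.startswith("two_fibre"):
        return make_two_fibre_fixture(spec.kind.split(":")[-1], spec.geometry)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def _sample_watson(n: int, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Axially symmetric directions with density ~ exp(kappa (w.z)^2).

    kappa = 0 is the uniform sphere; kappa -> inf concentrates on +-z
    (a nematic one-parameter family, monotone in order parameter).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    out = np.empty(n)
    got = 0
    while got < n:
        m = max(64, 2 * (n - got))
        u = rng.uniform(-1.0, 1.0, size=m)
        acc = u[rng.random(m) < np.exp(kappa * (u * u - 1.0))]
        take = min(n - got, acc.size)
        out[got : got + take] = acc[:take]
        got += take
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(np.clip(1.0 - out * out, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), out])


def make_orientation_field(
    kind: str,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    box: DomainBox | None = None,
    axis=(0.0, 0.0, 1.0),
    kappa: float | None = None,
) -> FibreState:
    """Fibre state with positions uniform in the box and prescribed directions.

    ``uniform``: uniform on the projective (half-) sphere; ``unidirectional``:
    all parallel to ``axis``; ``planar``: uniform in the plane perpendicular to
    ``axis``; ``concentration``: Watson family with parameter ``kappa``.
    """
    if kind not in _ORIENTATION_KINDS:
        raise ValueError(f"unknown orientation kind {kind!r}")
    box = box or DomainBox.cube(30.0)
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = box.lengths
    X = rng.uniform(-0.5, 0.5, size=(n, 3)) * L
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    if kind == "uniform":
        om = rng.normal(size=(n, 3))
        om /= np.linalg.norm(om, axis=1, keepdims=True)
    elif kind == "unidirectional":
        om = np.tile(axis, (n, 1))
    elif kind == "planar":
        # orthonormal in-plane frame perpendicular to axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(axis @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        om = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
    else:  # concentration
        if kappa is None:
            raise ValueError("concentration family needs kappa")
        om = _sample_watson(n, kappa, rng)
        if abs(axis[2] - 1.0) > 1e-12:  # rotate +z onto the requested axis
            z = np.array([0.0, 0.0, 1.0])
            v = np.cross(z, axis)
            s = np.linalg.norm(v)
            if s > 1e-12:
                vx = np.array(
                    [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
                )
                R = np.eye(3) + vx + vx @ vx * ((1 - z @ axis) / s**2)
                om = om @ R.T
            elif axis[2] < 0:
                om = -om
    return FibreState(X, canonical_orientations(om), t=0.0)


def make_two_fibre_fixture(
    interaction: str, geom: FibreGeometry | None = None, tilt: float = 0.0
) -> tuple[FibreState, LinkTable]:
    """Worst-case two-fibre initial conditions of the characteristic times.

    ``rep``: fully overlapped parallel pair, no link.  ``rest``: fully
    overlapped pair crosslinked at their centres.  ``align``: perpendicularly
    crossing pair crosslinked at their centres; ``tilt`` reduces the relative
    angle below 90 degrees (0 gives the exactly perpendicular, stationary
    configuration).
    """
    if interaction not in ("rep", "rest", "align"):
        raise ValueError("interaction must be one of 'rep', 'rest', 'align'")
    X = np.zeros((2, 3))
    e_x = np.array([1.0, 0.0, 0.0])
    if interaction == "align":
        om2 = np.array([math.sin(tilt), math.cos(tilt), 0.0])
        omega = np.vstack([e_x, om2])
    else:
        omega = np.vstack([e_x, e_x])
    state = FibreState(X, omega, t=0.0)
    if interaction == "rep":
        links = LinkTable()
    else:
        links = LinkTable().add([0], [1], [0.0], [0.0], 0.0)
    return state, links


def make_link_topology(
    state: FibreState,
    kind: str,
    parameter: float | None = None,
    seed: int | None = None,
    geom: FibreGeometry | None = None,
    box: DomainBox | None = None,
    d_link_max: float = 1.0,
) -> LinkTable:
    """Link tables with known statistics.

    ``perfect_matching``: every fibre in exactly one link (N/2 links,
    attachments at current closest points; N must be even).
    ``bernoulli``: each eligible pair linked independently with probability
    ``parameter``.
    """
    geom = geom or FibreGeometry()
    box = box or DomainBox.cube(30.0)
    if kind == "perfect_matching":
        n = state.n_fib
        if n % 2:
            raise ValueError("perfect matching needs an even number of fibres")
        a = np.arange(0, n, 2)
        b = a + 1
        s_a = np.empty(n // 2)
        s_b = np.empty(n // 2)
        for i, (k, m) in enumerate(zip(a, b)):
            s_a[i], s_b[i], _ = segment_closest_points(
                state.X[k], state.omega[k], state.X[m], state.omega[m], geom, box
            )
        return LinkTable().add(a, b, s_a, s_b, state.t)
    if kind == "bernoulli":
        if parameter is None or not (0.0 <= parameter <= 1.0):
            raise ValueError("bernoulli topology needs a link probability in [0, 1]")
        pairs, s1, s2 = eligible_pairs(state, geom, d_link_max, box)
        if pairs.shape[0] == 0 or parameter == 0.0:
            return LinkTable()
        rng = np.random.default_rng(seed)
        hit = rng.random(pairs.shape[0]) < parameter
        return LinkTable().add(pairs[hit, 0], pairs[hit, 1], s1[hit], s2[hit], state.t)
    raise ValueError(f"unknown link topology {kind!r}")
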