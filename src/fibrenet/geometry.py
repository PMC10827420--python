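"""Domain geometry and fibre state containers.

Fibres are rigid spherocylinders of length ``L_fib`` and radius ``R_fib``
living in a periodic cuboid centred on the origin.  A fibre is described by
its centre ``X_k`` and a *non-oriented* unit direction ``omega_k`` (a nematic
direction: ``omega`` and ``-omega`` denote the same fibre).  All pairwise
geometry uses the minimum-image convention, which is unambiguous as long as
``L_fib + 2 R_fib < min(L_x, L_y, L_z) / 2``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import closest_point_pair

__all__ = [
    "DomainBox",
    "FibreGeometry",
    "FibreState",
    "ModelParams",
    "wrap_position",
    "periodic_displacement",
    "segment_closest_points",
    "canonical_orientations",
    "candidate_pairs",
]


@dataclass(frozen=True)
class DomainBox:
    """Periodic cuboid ``[-L_x/2, L_x/2) x [-L_y/2, L_y/2) x [-L_z/2, L_z/2)``."""

    L_x: float
    L_y: float
    L_z: float

    def __post_init__(self) -> None:
        if not (self.L_x > 0 and self.L_y > 0 and self.L_z > 0):
            raise ValueError("box side lengths must be strictly positive")

    @classmethod
    def cube(cls, L: float) -> "DomainBox":
        return cls(L, L, L)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.L_x, self.L_y, self.L_z], dtype=float)

    @property
    def volume(self) -> float:
        return self.L_x * self.L_y * self.L_z


@dataclass(frozen=True)
class FibreGeometry:
    """Spherocylinder dimensions (aspect ratio ``L_fib / (2 R_fib)``)."""

    L_fib: float = 6.0
    R_fib: float = 0.5

    def __post_init__(self) -> None:
        if not (self.L_fib > 0 and self.R_fib > 0):
            raise ValueError("fibre length and radius must be strictly positive")

    @property
    def half_length(self) -> float:
        return 0.5 * self.L_fib

    @property
    def aspect_ratio(self) -> float:
        return self.L_fib / (2.0 * self.R_fib)

    def check_box(self, box: DomainBox) -> None:
        """Minimum-image unambiguity: a fibre must fit in half the box."""
        if self.L_fib + 2.0 * self.R_fib >= 0.5 * min(box.L_x, box.L_y, box.L_z):
            raise ValueError(
                "L_fib + 2 R_fib must be smaller than half the shortest box side "
                "for the minimum-image convention to be unambiguous"
            )


@dataclass
class FibreState:
    """Centres, nematic unit directions and current time of all fibres."""

    X: np.ndarray  # (N, 3) centres
    omega: np.ndarray  # (N, 3) unit directions, omega == -omega
    t: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float).reshape(-1, 3)
        self.omega = np.ascontiguousarray(self.omega, dtype=float).reshape(-1, 3)
        if self.X.shape != self.omega.shape:
            raise ValueError("X and omega must have matching shapes")

    @property
    def n_fib(self) -> int:
        return self.X.shape[0]

    def validate(self, box: DomainBox | None = None, tol: float = 1e-9) -> None:
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.omega)):
            raise ValueError("non-finite coordinates in fibre state")
        norms = np.linalg.norm(self.omega, axis=1)
        if self.n_fib and np.max(np.abs(norms - 1.0)) > tol:
            raise ValueError("fibre directions must be unit vectors")
        if box is not None and self.n_fib:
            half = 0.5 * box.lengths
            if np.any(self.X < -half) or np.any(self.X >= half):
                raise ValueError("fibre centres must lie in the half-open box")

    def copy(self) -> "FibreState":
        return FibreState(self.X.copy(), self.omega.copy(), self.t)


@dataclass(frozen=True)
class ModelParams:
    """All model parameters.

    ``chi_link = nu_link / (nu_link + nu_unlink)`` is the stationary probability
    that an eligible (close enough) fibre pair is linked; ``nu_unlink`` is derived
    from it.  ``mu_fib`` is the friction coefficient of the overdamped dynamics;
    with ``mu_fib = 1`` the characteristic interaction times of the default
    parameter set are 4.32, 2.76 and 462 time units for repulsion, spring and
    alignment respectively.
    """

    n_fib: int = 3000
    geometry: FibreGeometry = field(default_factory=FibreGeometry)
    alpha_rep: float = 12.5
    alpha_rest: float = 5.0
    alpha_align: float = 2.0
    d_link_max: float = 1.0
    d_link_eq: float = 1.0
    nu_link: float = 0.1
    chi_link: float = 0.5
    mu_fib: float = 1.0
    T_final: float = 5.0e4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_fib < 0:
            raise ValueError("n_fib must be non-negative")
        if self.nu_link < 0:
            raise ValueError("nu_link must be non-negative")
        if not (0.0 <= self.chi_link <= 1.0):
            raise ValueError("chi_link must lie in [0, 1]")
        for name in ("alpha_rep", "alpha_rest", "alpha_align"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mu_fib <= 0:
            raise ValueError("mu_fib must be strictly positive")

    @property
    def nu_unlink(self) -> float:
        """Unlinking frequency derived from chi_link = nu/(nu + nu_unlink)."""
        if self.chi_link == 0.0:
            if self.nu_link == 0.0:
                return 0.0
            return np.inf
        return self.nu_link * (1.0 - self.chi_link) / self.chi_link

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def wrap_position(x: np.ndarray, box: DomainBox) -> np.ndarray:
    """Wrap point(s) into the half-open box ``[-L_i/2, L_i/2)`` per axis."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input coordinates")
    L = box.lengths
    return (x + 0.5 * L) % L - 0.5 * L


def periodic_displacement(a: np.ndarray, b: np.ndarray, box: DomainBox) -> np.ndarray:
    """Minimum-image vector from ``a`` to ``b``; components in ``[-L_i/2, L_i/2)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite input coordinates")
    return wrap_position(b - a, box)


def segment_closest_points(
    X1: np.ndarray,
    omega1: np.ndarray,
    X2: np.ndarray,
    omega2: np.ndarray,
    geom: FibreGeometry,
    box: DomainBox,
) -> tuple[float, float, float]:
    """Mutually closest points of two fibre segments under minimum image.

    Returns ``(s1, s2, distance)`` where ``s_i`` are abscissae along each fibre
    axis in ``[-L_fib/2, L_fib/2]``.  For parallel segments with a continuum of
    closest pairs the midpoint of the overlap interval is returned
    (deterministic tie-break).
    """
    r = periodic_displacement(np.asarray(X1, float), np.asarray(X2, float), box)
    s1, s2, dist = closest_point_pair(
        r, np.asarray(omega1, float), np.asarray(omega2, float), geom.half_length
    )
    return float(s1), float(s2), float(dist)


def canonical_orientations(omega: np.ndarray) -> np.ndarray:
    """Flip each nematic direction so its first nonzero component is positive.

    Used only at I/O time; the internal dynamics keeps the evolving sign.
    """
    omega = np.asarray(omega, dtype=float).reshape(-1, 3)
    out = omega.copy()
    for j in range(3):
        # flip rows whose leading nonzero component is at column j and negative
        lead = np.all(np.abs(out[:, :j]) == 0.0, axis=1) if j else np.ones(len(out), bool)
        flip = lead & (out[:, j] < 0)
        out[flip] *= -1.0
    return out


def candidate_pairs(X: np.ndarray, box: DomainBox, cutoff: float) -> np.ndarray:
    """Unordered index pairs with centre-to-centre periodic distance <= cutoff.

    Deterministic ordering: rows sorted lexicographically with ``i < j``.
    Two segments can be within surface distance ``d`` of each other only if
    their centres are within ``L_fib + d``, so a centre cutoff of
    ``L_fib + max(2 R_fib, d_link_max)`` covers every interacting pair.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    L = box.lengths
    pos = np.mod(X + 0.5 * L, L)
    pos[pos >= L] = 0.0  # guard against round-up to the box edge
    tree = cKDTree(pos, boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray").astype(np.int64)
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]
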