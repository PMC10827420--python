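"""Stochastic crosslink remodelling.

Linking and unlinking are independent Poisson processes with frequencies
``nu_link`` and ``nu_unlink``.  Over a step of length ``dt`` each eligible
unlinked pair links with probability ``1 - exp(-nu_link dt)`` and each
existing link is removed with probability ``1 - exp(-nu_unlink dt)``
(Bernoulli thinning of the Poisson clocks).  The stationary probability for a
pair that stays eligible is ``chi_link = nu_link / (nu_link + nu_unlink)``.

Attachment abscissae are the closest-point abscissae at creation time and
stay fixed for the life of the link; links are *not* broken by distance, only
by the unlinking process.
"""
from __future__ import annotations

import numpy as np

from ._kernels import pair_geometry
from .geometry import DomainBox, FibreGeometry, FibreState, candidate_pairs

__all__ = [
    "LinkTable",
    "eligible_pairs",
    "sample_link_events",
    "sample_unlink_events",
    "equilibrium_linked_fraction",
    "bernoulli_initial_links",
]


class LinkTable:
    """Columnar table of crosslinks (canonical ordering ``fibre_a < fibre_b``)."""

    __slots__ = ("fibre_a", "fibre_b", "s_a", "s_b", "t_created")

    def __init__(self, fibre_a=None, fibre_b=None, s_a=None, s_b=None, t_created=None):
        self.fibre_a = np.asarray(fibre_a if fibre_a is not None else [], dtype=np.int64)
        self.fibre_b = np.asarray(fibre_b if fibre_b is not None else [], dtype=np.int64)
        self.s_a = np.asarray(s_a if s_a is not None else [], dtype=float)
        self.s_b = np.asarray(s_b if s_b is not None else [], dtype=float)
        self.t_created = np.asarray(t_created if t_created is not None else [], dtype=float)
        if np.any(self.fibre_a >= self.fibre_b):
            raise ValueError("links must satisfy fibre_a < fibre_b")
        if np.unique(self.keys()).size != len(self):
            raise ValueError("duplicate link for the same unordered pair")

    def __len__(self) -> int:
        return self.fibre_a.shape[0]

    def keys(self) -> np.ndarray:
        """Pack each unordered pair into one sortable int64 key."""
        return self.fibre_a * np.int64(2**31) + self.fibre_b

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.fibre_a.tolist(), self.fibre_b.tolist()))

    def copy(self) -> "LinkTable":
        return LinkTable(
            self.fibre_a.copy(), self.fibre_b.copy(), self.s_a.copy(),
            self.s_b.copy(), self.t_created.copy(),
        )

    def add(self, fibre_a, fibre_b, s_a, s_b, t) -> "LinkTable":
        """Return a new table with the given links appended."""
        fibre_a = np.asarray(fibre_a, dtype=np.int64)
        return LinkTable(
            np.concatenate([self.fibre_a, fibre_a]),
            np.concatenate([self.fibre_b, np.asarray(fibre_b, dtype=np.int64)]),
            np.concatenate([self.s_a, np.asarray(s_a, dtype=float)]),
            np.concatenate([self.s_b, np.asarray(s_b, dtype=float)]),
            np.concatenate([self.t_created, np.full(len(fibre_a), float(t))]),
        )

    def delete(self, mask: np.ndarray) -> "LinkTable":
        """Return a new table without the rows where ``mask`` is True."""
        keep = ~np.asarray(mask, dtype=bool)
        return LinkTable(
            self.fibre_a[keep], self.fibre_b[keep], self.s_a[keep],
            self.s_b[keep], self.t_created[keep],
        )


def eligible_pairs(
    state: FibreState,
    geom: FibreGeometry,
    d_link_max: float,
    box: DomainBox,
    links: LinkTable | None = None,
    pairs: np.ndarray | None = None,
    pair_geom: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unlinked pairs with segment-segment distance <= ``d_link_max``.

    Returns ``(pairs, s1, s2)`` where ``s1, s2`` are the current closest-point
    abscissae (the attachment points if the pair links now).  A spatial
    search prunes candidates but the result equals the all-pairs answer.
    """
    if pairs is None:
        pairs = candidate_pairs(state.X, box, geom.L_fib + d_link_max)
    if pairs.shape[0] == 0:
        e = np.empty(0)
        return np.empty((0, 2), dtype=np.int64), e, e.copy()
    if pair_geom is None:
        s1, s2, dist = pair_geometry(
            state.X, state.omega, pairs, box.lengths, geom.half_length, d_link_max
        )
    else:
        s1, s2, dist = pair_geom
    close = dist <= d_link_max
    if links is not None and len(links) and np.any(close):
        keys = pairs[close, 0] * np.int64(2**31) + pairs[close, 1]
        still_free = ~np.isin(keys, links.keys())
        idx = np.flatnonzero(close)[still_free]
        mask = np.zeros_like(close)
        mask[idx] = True
        close = mask
    return pairs[close], s1[close], s2[close]


def sample_link_events(
    eligible: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    nu_link: float,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli thinning of the linking Poisson clock over one step.

    Each eligible pair links independently with probability
    ``1 - exp(-nu_link dt)``; selected pairs attach at their current closest
    points.  Returns the selected ``(pairs, s1, s2)``.
    """
    if nu_link < 0:
        raise ValueError("nu_link must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eligible.shape[0] == 0 or nu_link == 0.0:
        e = np.empty(0)
        return np.empty((0, 2), dtype=np.int64), e, e.copy()
    p = -np.expm1(-nu_link * dt)
    hit = rng.random(eligible.shape[0]) < p
    return eligible[hit], s1[hit], s2[hit]


def sample_unlink_events(
    links: LinkTable, nu_unlink: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Mask of links removed this step (probability ``1 - exp(-nu_unlink dt)``).

    Removal is independent of spring extension: no force-dependent unbinding.
    """
    if nu_unlink < 0:
        raise ValueError("nu_unlink must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(links) == 0 or nu_unlink == 0.0:
        return np.zeros(len(links), dtype=bool)
    p = -np.expm1(-nu_unlink * dt)
    return rng.random(len(links)) < p


def equilibrium_linked_fraction(nu_link: float, nu_unlink: float) -> float:
    """Stationary linked probability ``nu_link / (nu_link + nu_unlink)``."""
    if nu_link < 0 or nu_unlink < 0:
        raise ValueError("rates must be non-negative")
    if nu_link + nu_unlink == 0:
        raise ValueError("equilibrium fraction undefined when both rates are zero")
    if np.isinf(nu_unlink):
        return 0.0
    return nu_link / (nu_link + nu_unlink)


def bernoulli_initial_links(
    state: FibreState,
    geom: FibreGeometry,
    d_link_max: float,
    chi_link: float,
    box: DomainBox,
    rng: np.random.Generator,
) -> LinkTable:
    """Initial link set: each eligible pair linked with probability ``chi_link``.

    This seeds the network at its stationary linked fraction, and gives
    non-dynamical networks (``nu_link = 0``) a fixed, nontrivial link set.
    """
    pairs, s1, s2 = eligible_pairs(state, geom, d_link_max, box)
    if pairs.shape[0] == 0 or chi_link == 0.0:
        return LinkTable()
    hit = rng.random(pairs.shape[0]) < chi_link
    return LinkTable().add(pairs[hit, 0], pairs[hit, 1], s1[hit], s2[hit], state.t)
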