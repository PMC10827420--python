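"""Numba-compiled inner loops: segment geometry and pair force accumulation.

Everything here operates on plain arrays; the public API lives in
:mod:`fibrenet.geometry` and :mod:`fibrenet.interactions`.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

_PAR_EPS = 1e-12


@njit(cache=True)
def _min_image(d, L):
    out = np.empty(3)
    for i in range(3):
        out[i] = d[i] - L[i] * math.floor(d[i] / L[i] + 0.5)
    return out


@njit(cache=True)
def closest_point_pair(r, w1, w2, h):
    """Closest points of segments ``s1*w1`` and ``r + s2*w2``, ``s in [-h, h]``.

    ``r`` is the (already minimum-imaged) vector between the two centres.
    Returns ``(s1, s2, dist)``.  Parallel segments use the midpoint of the
    overlap interval as a deterministic tie-break.
    """
    b = w1[0] * w2[0] + w1[1] * w2[1] + w1[2] * w2[2]
    d = w1[0] * r[0] + w1[1] * r[1] + w1[2] * r[2]
    e = w2[0] * r[0] + w2[1] * r[1] + w2[2] * r[2]
    denom = 1.0 - b * b
    if denom > _PAR_EPS:
        s1 = (d - b * e) / denom
        if s1 > h:
            s1 = h
        elif s1 < -h:
            s1 = -h
        s2 = b * s1 - e
        if s2 > h:
            s2 = h
        elif s2 < -h:
            s2 = -h
        # re-optimize s1 for the clamped s2
        s1 = b * s2 + d
        if s1 > h:
            s1 = h
        elif s1 < -h:
            s1 = -h
    else:
        # parallel: s1 values facing segment 2 span [d - h, d + h]
        lo = d - h
        hi = d + h
        if lo < -h:
            lo = -h
        if hi > h:
            hi = h
        if lo <= hi:
            s1 = 0.5 * (lo + hi)
        else:
            s1 = h if d > 0.0 else -h
        s2 = b * s1 - e
        if s2 > h:
            s2 = h
        elif s2 < -h:
            s2 = -h
    vx = r[0] + s2 * w2[0] - s1 * w1[0]
    vy = r[1] + s2 * w2[1] - s1 * w1[1]
    vz = r[2] + s2 * w2[2] - s1 * w1[2]
    dist = math.sqrt(vx * vx + vy * vy + vz * vz)
    return s1, s2, dist


@njit(cache=True)
def pair_geometry(X, W, pairs, L, h, thresh=1.0e30):
    """Closest-point abscissae and distances for an array of index pairs.

    Allocation-free inner loop (this runs once per time step over every
    candidate pair and dominates the step cost).  When ``thresh`` is given,
    pairs whose segment distance provably exceeds it are skipped and receive
    the (rigorous) lower bound instead of the exact distance; every consumer
    only compares distances against thresholds at or below ``thresh``.
    """
    n = pairs.shape[0]
    s1 = np.zeros(n)
    s2 = np.zeros(n)
    dist = np.empty(n)
    for i in range(n):
        k = pairs[i, 0]
        m = pairs[i, 1]
        rx = X[m, 0] - X[k, 0]
        ry = X[m, 1] - X[k, 1]
        rz = X[m, 2] - X[k, 2]
        # centres lie in the box, so one conditional wrap suffices per axis
        if rx > 0.5 * L[0]:
            rx -= L[0]
        elif rx < -0.5 * L[0]:
            rx += L[0]
        if ry > 0.5 * L[1]:
            ry -= L[1]
        elif ry < -0.5 * L[1]:
            ry += L[1]
        if rz > 0.5 * L[2]:
            rz -= L[2]
        elif rz < -0.5 * L[2]:
            rz += L[2]
        w1x, w1y, w1z = W[k, 0], W[k, 1], W[k, 2]
        w2x, w2y, w2z = W[m, 0], W[m, 1], W[m, 2]
        cd = math.sqrt(rx * rx + ry * ry + rz * rz)
        if cd - 2.0 * h > thresh:
            dist[i] = cd - 2.0 * h
            continue
        if cd > thresh:
            # |v| >= |v . r_hat| >= cd - h(|w1.r_hat| + |w2.r_hat|)
            p1 = abs(w1x * rx + w1y * ry + w1z * rz)
            p2 = abs(w2x * rx + w2y * ry + w2z * rz)
            bound = cd - h * (p1 + p2) / cd
            if bound > thresh:
                dist[i] = bound
                continue
        b = w1x * w2x + w1y * w2y + w1z * w2z
        d = w1x * rx + w1y * ry + w1z * rz
        e = w2x * rx + w2y * ry + w2z * rz
        denom = 1.0 - b * b
        if denom > _PAR_EPS:
            sa = (d - b * e) / denom
            if sa > h:
                sa = h
            elif sa < -h:
                sa = -h
            sb = b * sa - e
            if sb > h:
                sb = h
            elif sb < -h:
                sb = -h
            sa = b * sb + d
            if sa > h:
                sa = h
            elif sa < -h:
                sa = -h
        else:
            lo = d - h
            hi = d + h
            if lo < -h:
                lo = -h
            if hi > h:
                hi = h
            if lo <= hi:
                sa = 0.5 * (lo + hi)
            else:
                sa = h if d > 0.0 else -h
            sb = b * sa - e
            if sb > h:
                sb = h
            elif sb < -h:
                sb = -h
        vx = rx + sb * w2x - sa * w1x
        vy = ry + sb * w2y - sa * w1y
        vz = rz + sb * w2z - sa * w1z
        s1[i] = sa
        s2[i] = sb
        dist[i] = math.sqrt(vx * vx + vy * vy + vz * vz)
    return s1, s2, dist


@njit(cache=True)
def _pair_unit_perp(k, m, w):
    """Deterministic pseudo-random unit vector perpendicular to ``w``.

    Used as the force direction when two closest points coincide exactly and
    the true direction is undefined; seeding by the index pair keeps runs
    reproducible.
    """
    u1 = math.sin(12.9898 * (k + 1) + 78.233 * (m + 1)) * 43758.5453
    u1 -= math.floor(u1)
    u2 = math.sin(39.3468 * (k + 1) + 11.135 * (m + 1)) * 24634.6345
    u2 -= math.floor(u2)
    phi = 2.0 * math.pi * u1
    z = 2.0 * u2 - 1.0
    s = math.sqrt(max(0.0, 1.0 - z * z))
    v = np.empty(3)
    v[0] = s * math.cos(phi)
    v[1] = s * math.sin(phi)
    v[2] = z
    # orthogonalize against w
    p = v[0] * w[0] + v[1] * w[1] + v[2] * w[2]
    for i in range(3):
        v[i] -= p * w[i]
    nrm = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if nrm < 1e-8:
        # v happened to be (anti)parallel to w: pick any perpendicular
        if abs(w[0]) < 0.9:
            v[0], v[1], v[2] = 0.0, -w[2], w[1]
        else:
            v[0], v[1], v[2] = -w[2], 0.0, w[0]
        nrm = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    for i in range(3):
        v[i] /= nrm
    return v


@njit(cache=True)
def accumulate_repulsion(X, W, pairs, s1, s2, dist, L, two_R, a_rep, F, T):
    """Add Hertzian repulsion ``F = a_rep (2R - d)^{3/2} (2R)^{-1/2}`` in place."""
    inv_sqrt = 1.0 / math.sqrt(two_R)
    for i in range(pairs.shape[0]):
        dd = dist[i]
        if dd >= two_R:
            continue
        k = pairs[i, 0]
        m = pairs[i, 1]
        u = two_R - dd
        mag = a_rep * u * math.sqrt(u) * inv_sqrt
        r = _min_image(X[m] - X[k], L)
        if dd > _PAR_EPS:
            nx = (r[0] + s2[i] * W[m, 0] - s1[i] * W[k, 0]) / dd
            ny = (r[1] + s2[i] * W[m, 1] - s1[i] * W[k, 1]) / dd
            nz = (r[2] + s2[i] * W[m, 2] - s1[i] * W[k, 2]) / dd
        else:
            v = _pair_unit_perp(k, m, W[k])
            nx, ny, nz = v[0], v[1], v[2]
        # n points from fibre k towards fibre m: push k along -n, m along +n
        fx = -mag * nx
        fy = -mag * ny
        fz = -mag * nz
        F[k, 0] += fx
        F[k, 1] += fy
        F[k, 2] += fz
        F[m, 0] -= fx
        F[m, 1] -= fy
        F[m, 2] -= fz
        # torque about each centre from the force applied at the closest point
        ax = s1[i] * W[k, 0]
        ay = s1[i] * W[k, 1]
        az = s1[i] * W[k, 2]
        T[k, 0] += ay * fz - az * fy
        T[k, 1] += az * fx - ax * fz
        T[k, 2] += ax * fy - ay * fx
        bx = s2[i] * W[m, 0]
        by = s2[i] * W[m, 1]
        bz = s2[i] * W[m, 2]
        T[m, 0] += by * (-fz) - bz * (-fy)
        T[m, 1] += bz * (-fx) - bx * (-fz)
        T[m, 2] += bx * (-fy) - by * (-fx)


@njit(cache=True)
def accumulate_link_forces(
    X, W, link_a, link_b, link_sa, link_sb, L, a_rest, d_eq, a_align, F, T
):
    """Add crosslink spring forces/torques and nematic alignment torques in place.

    The spring connects material points fixed at creation (abscissae
    ``link_sa``, ``link_sb``); the alignment torque derives from the nematic
    potential ``V = -(a_align/2) (w_a . w_b)^2`` and is a pure torque.
    """
    for i in range(link_a.shape[0]):
        a = link_a[i]
        b = link_b[i]
        r = _min_image(X[b] - X[a], L)
        dx = r[0] + link_sb[i] * W[b, 0] - link_sa[i] * W[a, 0]
        dy = r[1] + link_sb[i] * W[b, 1] - link_sa[i] * W[a, 1]
        dz = r[2] + link_sb[i] * W[b, 2] - link_sa[i] * W[a, 2]
        dd = math.sqrt(dx * dx + dy * dy + dz * dz)
        if dd > _PAR_EPS:
            ux, uy, uz = dx / dd, dy / dd, dz / dd
        else:
            v = _pair_unit_perp(a, b, W[a])
            ux, uy, uz = v[0], v[1], v[2]
        mag = a_rest * (dd - d_eq)  # attractive when stretched, repulsive when short
        fx = mag * ux
        fy = mag * uy
        fz = mag * uz
        F[a, 0] += fx
        F[a, 1] += fy
        F[a, 2] += fz
        F[b, 0] -= fx
        F[b, 1] -= fy
        F[b, 2] -= fz
        ax = link_sa[i] * W[a, 0]
        ay = link_sa[i] * W[a, 1]
        az = link_sa[i] * W[a, 2]
        T[a, 0] += ay * fz - az * fy
        T[a, 1] += az * fx - ax * fz
        T[a, 2] += ax * fy - ay * fx
        bx = link_sb[i] * W[b, 0]
        by = link_sb[i] * W[b, 1]
        bz = link_sb[i] * W[b, 2]
        T[b, 0] += by * (-fz) - bz * (-fy)
        T[b, 1] += bz * (-fx) - bx * (-fz)
        T[b, 2] += bx * (-fy) - by * (-fx)
        # nematic alignment: T_a = a_align (w_a . w_b) (w_a x w_b), T_b = -T_a
        c = W[a, 0] * W[b, 0] + W[a, 1] * W[b, 1] + W[a, 2] * W[b, 2]
        cx = W[a, 1] * W[b, 2] - W[a, 2] * W[b, 1]
        cy = W[a, 2] * W[b, 0] - W[a, 0] * W[b, 2]
        cz = W[a, 0] * W[b, 1] - W[a, 1] * W[b, 0]
        T[a, 0] += a_align * c * cx
        T[a, 1] += a_align * c * cy
        T[a, 2] += a_align * c * cz
        T[b, 0] -= a_align * c * cx
        T[b, 1] -= a_align * c * cy
        T[b, 2] -= a_align * c * cz
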