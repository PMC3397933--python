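"""Internal-coordinate geometry: angles and dihedrals with analytic gradients.

Shared by the bead-chain force field and the dihedral-based collective
variables. All gradient formulas are the standard ones used by MD engines and
are pinned against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "cross3",
    "angle_value_grad",
    "dihedral_value_grad",
    "angles_batch",
    "dihedrals_batch",
    "dihedrals_batch_reference",
]


class DegenerateGeometryError(ValueError):
    """Raised when an angle/dihedral is undefined (collinear or coincident atoms)."""


def angle_value_grad(r_i: np.ndarray, r_j: np.ndarray, r_k: np.ndarray):
    """Angle i-j-k in radians and its gradient w.r.t. the three positions."""
    u = r_i - r_j
    v = r_k - r_j
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("coincident atoms in angle")
    eu = u / nu
    ev = v / nv
    c = float(np.clip(eu @ ev, -1.0, 1.0))
    s = np.sqrt(max(1.0 - c * c, 0.0))
    if s < 1e-10:
        raise DegenerateGeometryError("collinear atoms in angle")
    theta = np.arccos(c)
    dth_di = -(ev - c * eu) / (nu * s)
    dth_dk = -(eu - c * ev) / (nv * s)
    dth_dj = -(dth_di + dth_dk)
    return theta, (dth_di, dth_dj, dth_dk)


def dihedral_value_grad(r1: np.ndarray, r2: np.ndarray, r3: np.ndarray, r4: np.ndarray):
    """Dihedral over four positions (rad, in (-pi, pi]) and its gradient.

    Uses the standard n1 = b1 x b2, n2 = b2 x b3 construction; raises
    DegenerateGeometryError if any bonded triple is collinear.
    """
    b1 = r2 - r1
    b2 = r3 - r2
    b3 = r4 - r3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(n1 @ n1)
    n2sq = float(n2 @ n2)
    nb2 = float(np.linalg.norm(b2))
    if n1sq < 1e-18 or n2sq < 1e-18 or nb2 < 1e-12:
        raise DegenerateGeometryError("collinear triple within dihedral quadruple")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / nb2))
    phi = float(np.arctan2(y, x))
    # Analytic gradient in the n1/n2 basis (pinned against finite differences).
    f1 = -(nb2 / n1sq) * n1
    f4 = (nb2 / n2sq) * n2
    p = float(b1 @ b2) / (nb2 * nb2)
    q = float(b3 @ b2) / (nb2 * nb2)
    f2 = -(1.0 + p) * f1 + q * f4
    f3 = p * f1 - (1.0 + q) * f4
    return phi, (f1, f2, f3, f4)


def angles_batch(coords: np.ndarray, triples: np.ndarray):
    """Vectorised angles over (n, 3) index triples: values (n,), grads (n, 3, 3)."""
    triples = np.asarray(triples, dtype=int).reshape(-1, 3)
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise DegenerateGeometryError("coincident atoms in angle")
    eu = u / nu[:, None]
    ev = v / nv[:, None]
    c = np.clip(np.sum(eu * ev, axis=1), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 0.0))
    if np.any(s < 1e-10):
        raise DegenerateGeometryError("collinear atoms in angle")
    theta = np.arccos(c)
    gi = -(ev - c[:, None] * eu) / (nu * s)[:, None]
    gk = -(eu - c[:, None] * ev) / (nv * s)[:, None]
    grads = np.stack([gi, -(gi + gk), gk], axis=1)
    return theta, grads


def cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product for (n, 3) arrays without np.cross overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def dihedrals_batch(coords: np.ndarray, quads: np.ndarray):
    """Dihedrals over (n, 4) index quadruples: values (n,), grads (n, 4, 3)."""
    from ._kernels import dihedral_phis_grads
    quads = np.ascontiguousarray(np.asarray(quads, dtype=int).reshape(-1, 4))
    phis, grads, ok = dihedral_phis_grads(np.ascontiguousarray(coords, dtype=float), quads)
    if not ok:
        raise DegenerateGeometryError("collinear triple within dihedral quadruple")
    return phis, grads


def dihedrals_batch_reference(coords: np.ndarray, quads: np.ndarray):
    """Pure-numpy dihedral batch; the numba kernel is pinned against this."""
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    r1, r2, r3, r4 = (coords[quads[:, k]] for k in range(4))
    b1 = r2 - r1
    b2 = r3 - r2
    b3 = r4 - r3
    n1 = cross3(b1, b2)
    n2 = cross3(b2, b3)
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    nb2 = np.linalg.norm(b2, axis=1)
    if np.any(n1sq < 1e-18) or np.any(n2sq < 1e-18) or np.any(nb2 < 1e-12):
        raise DegenerateGeometryError("collinear triple within dihedral quadruple")
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(cross3(n1, n2) * (b2 / nb2[:, None]), axis=1)
    phi = np.arctan2(y, x)
    f1 = -(nb2 / n1sq)[:, None] * n1
    f4 = (nb2 / n2sq)[:, None] * n2
    p = (np.sum(b1 * b2, axis=1) / (nb2 * nb2))[:, None]
    q = (np.sum(b3 * b2, axis=1) / (nb2 * nb2))[:, None]
    f2 = -(1.0 + p) * f1 + q * f4
    f3 = p * f1 - (1.0 + q) * f4
    grads = np.stack([f1, f2, f3, f4], axis=1)
    return phi, grads
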