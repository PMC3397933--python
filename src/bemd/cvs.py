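"""Differentiable collective variables (CVs) with Gaussian widths and walls.

The CV kinds mirror those routinely used to bias disordered-peptide
simulations: smooth coordination numbers over atom groups, similarity of
backbone dihedrals to the alpha region, correlation of successive dihedrals,
smooth hydrogen-bond counts, and a soft minimum distance from a ligand probe
atom to the peptide.  Functional forms follow the conventions of the common
metadynamics plugins: a rational switching function

    s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m),   n < m,

for contact counting (the removable singularity at r = r0 is evaluated by its
limit n/m), and a log-sum-exp soft minimum for distances.  Every evaluation
returns both the scalar value and its gradient with respect to coordinates so
biasing forces follow by the chain rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import DegenerateGeometryError, dihedrals_batch

__all__ = [
    "CVValue",
    "Wall",
    "CVDefinition",
    "coordination_number",
    "dihedral_similarity_alpha",
    "dihedral_correlation",
    "hbond_count",
    "softmin_distance",
    "DEFAULT_PSI_REF",
]

#: Default reference psi for the alpha-helical region (rad); config-exposed.
DEFAULT_PSI_REF = -0.82


@dataclass
class CVValue:
    """Scalar CV value plus its per-coordinate gradient (CV units / nm)."""

    value: float
    gradient: np.ndarray


@dataclass
class Wall:
    """Half-harmonic confinement of a CV to [lower, upper].

    Energy k*(s-upper)^2 beyond the upper bound, k*(lower-s)^2 below the
    lower bound, zero inside; k in kJ/mol per CV-unit^2.
    """

    lower: float
    upper: float
    k: float = 100.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"wall requires lower < upper, got [{self.lower}, {self.upper}]")
        if self.k <= 0:
            raise ValueError("wall spring constant must be positive")

    def energy_dvds(self, s: float) -> tuple[float, float]:
        """Wall energy and dE/ds at CV value s."""
        if s > self.upper:
            d = s - self.upper
            return self.k * d * d, 2.0 * self.k * d
        if s < self.lower:
            d = s - self.lower
            return self.k * d * d, 2.0 * self.k * d
        return 0.0, 0.0


def _switching(r: np.ndarray, r0: float, n: int, m: int):
    """Rational switching value and ds/dr, elementwise; handles x ~ 1 by series."""
    x = r / r0
    xn = x**n
    xm = x**m
    den = 1.0 - xm
    near = np.abs(x - 1.0) < 1e-6
    safe_den = np.where(near, 1.0, den)
    s = np.where(near, n / m + (n * (n - m) / (2.0 * m)) * (x - 1.0), (1.0 - xn) / safe_den)
    # ds/dx = [-n x^{n-1} (1-x^m) + m x^{m-1} (1-x^n)] / (1-x^m)^2
    dsdx_reg = (-n * x ** (n - 1) * den + m * x ** (m - 1) * (1.0 - xn)) / (safe_den * safe_den)
    dsdx = np.where(near, n * (n - m) / (2.0 * m), dsdx_reg)
    return s, dsdx / r0


def _pair_indices(group_a: np.ndarray, group_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("atom groups must be non-empty")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        sa = np.sort(a)
        ii, jj = np.triu_indices(sa.size, k=1)
        return sa[ii], sa[jj]
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint or identical")
    ii, jj = np.meshgrid(a, b, indexing="ij")
    return ii.ravel(), jj.ravel()


def _contact_sum(coords: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray,
                 r0: float, n: int, m: int) -> CVValue:
    from ._kernels import contact_sum as _kernel
    value, grad = _kernel(np.ascontiguousarray(coords, dtype=float),
                          np.ascontiguousarray(idx_i), np.ascontiguousarray(idx_j),
                          float(r0), int(n), int(m))
    if np.isnan(value):
        raise ValueError("coincident atoms in contact pair")
    return CVValue(value=float(value), gradient=grad)


def _contact_sum_reference(coords: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray,
                           r0: float, n: int, m: int) -> CVValue:
    dx = coords[idx_i] - coords[idx_j]
    r = np.linalg.norm(dx, axis=1)
    if np.any(r < 1e-10):
        raise ValueError("coincident atoms in contact pair")
    s, dsdr = _switching(r, r0, n, m)
    grad = np.zeros_like(coords)
    per_pair = (dsdr / r)[:, None] * dx
    np.add.at(grad, idx_i, per_pair)
    np.add.at(grad, idx_j, -per_pair)
    return CVValue(value=float(np.sum(s)), gradient=grad)


def coordination_number(coords: np.ndarray, group_a: Sequence[int], group_b: Sequence[int],
                        r0: float, n: int = 6, m: int = 12) -> CVValue:
    """Smooth coordination number between two atom groups.

    Identical groups are paired i<j; distinct groups must be disjoint and are
    paired all-against-all.  Requires n < m so the switching function decays.
    """
    if n >= m:
        raise ValueError(f"switching exponents require n < m, got n={n}, m={m}")
    idx_i, idx_j = _pair_indices(np.asarray(group_a), np.asarray(group_b))
    return _contact_sum(np.asarray(coords, dtype=float), idx_i, idx_j, r0, n, m)


def hbond_count(coords: np.ndarray, donor_group: Sequence[int], acceptor_group: Sequence[int],
                r0: float = 0.25, n: int = 6, m: int = 12) -> CVValue:
    """Smooth hydrogen-bond count: coordination between donor and acceptor groups."""
    return coordination_number(coords, donor_group, acceptor_group, r0, n=n, m=m)


def dihedral_similarity_alpha(coords: np.ndarray, psi_quads: Sequence[Sequence[int]],
                              psi_ref: float = DEFAULT_PSI_REF) -> CVValue:
    """Similarity of backbone psi dihedrals to a reference (alpha) angle.

    Sum over dihedrals of (1 + cos(psi_i - psi_ref))/2, ranging from 0 (all
    anti-aligned) to N (all at the reference).
    """
    quads = np.asarray(psi_quads, dtype=int).reshape(-1, 4)
    if quads.shape[0] < 1:
        raise ValueError("at least one dihedral quadruple required")
    coords = np.asarray(coords, dtype=float)
    phis, grads = dihedrals_batch(coords, quads)
    value = float(np.sum(0.5 * (1.0 + np.cos(phis - psi_ref))))
    grad = np.zeros_like(coords)
    coef = (-0.5 * np.sin(phis - psi_ref))[:, None, None]
    np.add.at(grad, quads.ravel(), (coef * grads).reshape(-1, 3))
    return CVValue(value=value, gradient=grad)


def dihedral_correlation(coords: np.ndarray, quads: Sequence[Sequence[int]]) -> CVValue:
    """Correlation of successive dihedrals: sum of (1 + cos(phi_{i+1} - phi_i))/2."""
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    if quads.shape[0] < 2:
        raise ValueError("at least two dihedrals required for a correlation")
    coords = np.asarray(coords, dtype=float)
    phis, grads = dihedrals_batch(coords, quads)
    d = np.diff(phis)
    value = float(np.sum(0.5 * (1.0 + np.cos(d))))
    grad = np.zeros_like(coords)
    coef = -0.5 * np.sin(d)
    up = coef[:, None, None] * grads[1:]
    down = -coef[:, None, None] * grads[:-1]
    np.add.at(grad, quads[1:].ravel(), up.reshape(-1, 3))
    np.add.at(grad, quads[:-1].ravel(), down.reshape(-1, 3))
    return CVValue(value=float(value), gradient=grad)


def softmin_distance(coords: np.ndarray, probe_atom: int, target_group: Sequence[int],
                     beta_s: float = 1.0) -> CVValue:
    """Differentiable soft minimum distance from a probe atom to a group.

    s = beta_s / ln sum_j exp(beta_s / d_j); converges to min_j d_j as
    beta_s (nm) grows large relative to the spacing of the d_j.
    """
    targets = np.asarray(target_group, dtype=int)
    if targets.size == 0:
        raise ValueError("target group must be non-empty")
    coords = np.asarray(coords, dtype=float)
    dx = coords[probe_atom] - coords[targets]
    d = np.linalg.norm(dx, axis=1)
    if np.any(d < 1e-10):
        raise ValueError("probe coincides with a target atom (singular input)")
    a = beta_s / d
    amax = a.max()
    logsum = amax + np.log(np.sum(np.exp(a - amax)))
    value = beta_s / logsum
    # With L = ln S, S = sum_j exp(beta/d_j) and w_j the softmax weights:
    # dL/dd_j = -w_j beta / d_j^2, hence ds/dd_j = beta^2 w_j / (L^2 d_j^2).
    w = np.exp(a - amax) / np.sum(np.exp(a - amax))
    dsdd = beta_s * beta_s * w / (logsum * logsum * d * d)
    grad = np.zeros_like(coords)
    per_target = (dsdd / d)[:, None] * dx
    grad[probe_atom] = np.sum(per_target, axis=0)
    np.add.at(grad, targets, -per_target)
    return CVValue(value=float(value), gradient=grad)


@dataclass
class CVDefinition:
    """A named CV with selectors, parameters, Gaussian width and optional wall.

    ``kind`` is one of 'coordination', 'dihedral_similarity',
    'dihedral_correlation', 'hbond_count', 'softmin_distance' or 'coordinate'
    (the identity CV on one coordinate of a low-dimensional toy system).
    Group selectors are bead-label strings resolved against the model at
    evaluation time; for toy systems 'coordinate' takes an index parameter.
    """

    name: str
    kind: str
    sigma: float
    params: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)
    wall: Optional[Wall] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    KINDS = (
        "coordination",
        "dihedral_similarity",
        "dihedral_correlation",
        "hbond_count",
        "softmin_distance",
        "coordinate",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("gaussian width sigma must be positive")

    def _resolve(self, model, label: str) -> np.ndarray:
        key = ("group", id(model), label)
        idx = self._cache.get(key)
        if idx is None:
            idx = model.group(label)
            if len(idx) == 0:
                raise ValueError(f"selector {label!r} resolves to an empty set")
            self._cache[key] = idx
        return idx

    def _pairs(self, model, label_a: str, label_b: str) -> tuple[np.ndarray, np.ndarray]:
        key = ("pairs", id(model), label_a, label_b)
        pair = self._cache.get(key)
        if pair is None:
            pair = _pair_indices(self._resolve(model, label_a), self._resolve(model, label_b))
            self._cache[key] = pair
        return pair

    def _quads(self, model) -> np.ndarray:
        key = ("quads", id(model))
        quads = self._cache.get(key)
        if quads is None:
            quads = self._cache[key] = np.asarray(model.backbone_dihedral_quads(), dtype=int)
        return quads

    def evaluate(self, coords: np.ndarray, model=None) -> CVValue:
        k = self.kind
        if k == "coordinate":
            i = int(self.params.get("index", 0))
            flat = np.asarray(coords, dtype=float).reshape(-1)
            grad = np.zeros_like(flat)
            grad[i] = 1.0
            return CVValue(value=float(flat[i]), gradient=grad.reshape(np.shape(coords)))
        if model is None:
            raise ValueError(f"CV kind {k!r} requires a model with group labels")
        if k in ("coordination", "hbond_count"):
            if k == "coordination":
                idx_i, idx_j = self._pairs(model, self.groups["a"], self.groups["b"])
                r0 = self.params.get("r0", 0.65)
            else:
                idx_i, idx_j = self._pairs(model, self.groups["donor"], self.groups["acceptor"])
                r0 = self.params.get("r0", 0.25)
            n = int(self.params.get("n", 6))
            m = int(self.params.get("m", 12))
            if n >= m:
                raise ValueError(f"switching exponents require n < m, got n={n}, m={m}")
            return _contact_sum(np.asarray(coords, dtype=float), idx_i, idx_j, r0, n, m)
        if k == "dihedral_similarity":
            return dihedral_similarity_alpha(
                coords, self._quads(model),
                psi_ref=self.params.get("psi_ref", DEFAULT_PSI_REF),
            )
        if k == "dihedral_correlation":
            return dihedral_correlation(coords, self._quads(model))
        if k == "softmin_distance":
            probe = self._resolve(model, self.groups["probe"])
            return softmin_distance(
                coords, int(probe[0]),
                self._resolve(model, self.groups["target"]),
                beta_s=self.params.get("beta_s", 1.0),
            )
        raise AssertionError("unreachable")
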