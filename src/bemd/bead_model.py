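"""Coarse bead-chain peptide (optionally with a rigid ligand group).

A deliberately simple stand-in for a solvated peptide: each residue carries a
backbone bead (pseudo-C-alpha), a sidechain bead (pseudo-C-gamma) and an
explicit pseudo-proton bead, so that coordination numbers, backbone-dihedral
CVs, hydrogen-bond counts and proton-proton contact analysis are all well
defined without geometry inference.  The holo variant appends a quasi-rigid
three-bead ligand whose first bead plays the role of the ligand probe atom
for the minimum-distance CV.

Force field: harmonic bonds, a cosine-based angle term, a cosine dihedral
along the backbone, and bounded pairwise nonbonded terms — a harmonic
soft-sphere repulsion between most bead pairs plus a Gaussian contact
attraction between sidechain beads and between the ligand and the peptide —
so the chain interconverts between collapsed and extended states at 300 K.
All nonbonded curvatures are bounded, which keeps the overdamped Euler
integrator stable at the study timestep.  All parameters are free choices of
this package, not fitted to any molecular system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import cross3

__all__ = ["BeadChainModel", "make_bead_peptide"]

_BOND_K = 300.0       # kJ/mol/nm^2
_BB_BOND = 0.38       # nm, backbone-backbone
_BG_BOND = 0.25       # nm, backbone-sidechain
_BH_BOND = 0.15       # nm, backbone-proton
_LIG_BOND = 0.25      # nm, intra-ligand (stiff springs -> quasi-rigid triangle)
_LIG_K = 600.0
_ANGLE_K = 15.0       # kJ/mol, on (cos th - cos th0)^2
_ANGLE_0 = 2.0        # rad
_DIHEDRAL_K = 1.0     # kJ/mol
_K_REP = 10.0         # kJ/mol, soft-sphere repulsion strength
_EPS_ATTR = 3.0       # kJ/mol, Gaussian contact well depth
_ATTR_WIDTH = 0.12    # nm, Gaussian contact well width
_CUTOFF = 1.2         # nm


@dataclass
class BeadChainModel:
    """Bead-chain peptide with labelled groups and an analytic force field."""

    n_residues: int
    holo: bool
    seed: int
    coordinates: np.ndarray
    labels: list
    bonds: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray
    dihedrals: np.ndarray
    nb_pairs: np.ndarray
    nb_sigma: np.ndarray
    nb_attractive: np.ndarray
    residue_of: np.ndarray = field(default=None)

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    def group(self, label: str) -> np.ndarray:
        return np.array([i for i, ls in enumerate(self.labels) if label in ls], dtype=int)

    def initial_coordinates(self) -> np.ndarray:
        return self.coordinates.copy()

    def backbone_dihedral_quads(self) -> np.ndarray:
        """Quadruples of successive backbone beads defining the pseudo-psi dihedrals."""
        bb = self.group("calpha")
        return np.stack([bb[i : i + 4] for i in range(len(bb) - 3)])

    # -- force field ---------------------------------------------------------

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_forces(np.asarray(coords, dtype=float))[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return -self.energy_forces(np.asarray(coords, dtype=float))[1]

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        from ._kernels import bead_energy_forces
        c = np.ascontiguousarray(coords, dtype=float)
        e, f = bead_energy_forces(
            c, self.bonds, self.bond_r0, self.bond_k, self.angles,
            np.cos(_ANGLE_0), _ANGLE_K, self.dihedrals, _DIHEDRAL_K,
            self.nb_pairs, self.nb_sigma, self.nb_attractive,
            _K_REP, _EPS_ATTR, _ATTR_WIDTH, _CUTOFF,
        )
        return float(e), f

    def energy_forces_reference(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Pure-numpy force routine; the numba kernel is pinned against this."""
        c = np.asarray(coords, dtype=float)
        f = np.zeros_like(c)
        # bonds
        dx = c[self.bonds[:, 0]] - c[self.bonds[:, 1]]
        r = np.linalg.norm(dx, axis=1)
        dr = r - self.bond_r0
        e = float(np.sum(self.bond_k * dr * dr))
        fpair = (-2.0 * self.bond_k * dr / r)[:, None] * dx
        np.add.at(f, self.bonds[:, 0], fpair)
        np.add.at(f, self.bonds[:, 1], -fpair)
        # angles: U = k (cos th - cos th0)^2, singularity-free at collinear
        if len(self.angles):
            u = c[self.angles[:, 0]] - c[self.angles[:, 1]]
            v = c[self.angles[:, 2]] - c[self.angles[:, 1]]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            eu = u / nu[:, None]
            ev = v / nv[:, None]
            cth = np.sum(eu * ev, axis=1)
            d = cth - np.cos(_ANGLE_0)
            e += float(np.sum(_ANGLE_K * d * d))
            coef = -2.0 * _ANGLE_K * d
            gi = (ev - cth[:, None] * eu) / nu[:, None]
            gk = (eu - cth[:, None] * ev) / nv[:, None]
            np.add.at(f, self.angles[:, 0], coef[:, None] * gi)
            np.add.at(f, self.angles[:, 2], coef[:, None] * gk)
            np.add.at(f, self.angles[:, 1], -coef[:, None] * (gi + gk))
        # backbone dihedrals, U = k (1 + cos phi); gradient regularised at the
        # collinear degeneracy, where the torque prefactor sin(phi) vanishes
        if len(self.dihedrals):
            q = self.dihedrals
            b1 = c[q[:, 1]] - c[q[:, 0]]
            b2 = c[q[:, 2]] - c[q[:, 1]]
            b3 = c[q[:, 3]] - c[q[:, 2]]
            n1 = cross3(b1, b2)
            n2 = cross3(b2, b3)
            n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-12)
            n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-12)
            nb2 = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
            x = np.sum(n1 * n2, axis=1)
            y = np.sum(cross3(n1, n2) * (b2 / nb2[:, None]), axis=1)
            phi = np.arctan2(y, x)
            e += float(np.sum(_DIHEDRAL_K * (1.0 + np.cos(phi))))
            f1 = -(nb2 / n1sq)[:, None] * n1
            f4 = (nb2 / n2sq)[:, None] * n2
            p = (np.sum(b1 * b2, axis=1) / (nb2 * nb2))[:, None]
            qq = (np.sum(b3 * b2, axis=1) / (nb2 * nb2))[:, None]
            coef = (_DIHEDRAL_K * np.sin(phi))[:, None]
            np.add.at(f, q[:, 0], coef * f1)
            np.add.at(f, q[:, 1], coef * (-(1.0 + p) * f1 + qq * f4))
            np.add.at(f, q[:, 2], coef * (p * f1 - (1.0 + qq) * f4))
            np.add.at(f, q[:, 3], coef * f4)
        # nonbonded: soft-sphere repulsion inside sigma, Gaussian contact
        # attraction around sigma for flagged pairs; both have bounded curvature
        dx = c[self.nb_pairs[:, 0]] - c[self.nb_pairs[:, 1]]
        r = np.linalg.norm(dx, axis=1)
        within = r < _CUTOFF
        if np.any(within):
            rw = np.maximum(r[within], 1e-8)
            sig = self.nb_sigma[within]
            attr = self.nb_attractive[within]
            dudr = np.zeros_like(rw)
            overlap = rw < sig
            t = 1.0 - rw / sig
            e += float(np.sum(np.where(overlap, _K_REP * t * t, 0.0)))
            dudr += np.where(overlap, -2.0 * _K_REP * t / sig, 0.0)
            if attr.any():
                dr = rw - sig
                g = np.exp(-dr * dr / (2.0 * _ATTR_WIDTH**2))
                e += float(np.sum(np.where(attr, -_EPS_ATTR * g, 0.0)))
                dudr += np.where(attr, _EPS_ATTR * g * dr / _ATTR_WIDTH**2, 0.0)
            fpair = (-dudr / rw)[:, None] * dx[within]
            np.add.at(f, self.nb_pairs[within, 0], fpair)
            np.add.at(f, self.nb_pairs[within, 1], -fpair)
        return e, f

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": "bead_peptide",
            "n_residues": int(self.n_residues),
            "holo": bool(self.holo),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeadChainModel":
        return make_bead_peptide(d["n_residues"], holo=d["holo"], seed=d["seed"])


def make_bead_peptide(n_residues: int = 11, holo: bool = False, seed: int = 0) -> BeadChainModel:
    """Build a bead-chain peptide; deterministic for a fixed seed.

    The 11-residue default matches the length of the disordered peptide the
    pipeline is designed around.  Requires at least 3 residues so that
    backbone angles exist; backbone dihedral CVs additionally need >= 4.
    """
    if n_residues < 3:
        raise ValueError(f"n_residues must be >= 3, got {n_residues}")
    rng = np.random.Generator(np.random.Philox(key=seed))

    labels: list[frozenset] = []
    coords = []
    for i in range(n_residues):
        base = np.array([i * 0.36, 0.12 * (-1) ** i, 0.0])
        coords.append(base)                                   # backbone bead
        labels.append(frozenset({"backbone", "calpha", "acceptor", "heavy"}))
        coords.append(base + np.array([0.0, 0.22, 0.12]))     # sidechain bead
        labels.append(frozenset({"sidechain", "cgamma", "heavy"}))
        coords.append(base + np.array([0.0, -0.10, -0.11]))   # proton bead
        labels.append(frozenset({"proton", "donor"}))
    if holo:
        center = np.array([(n_residues - 1) * 0.18, 0.0, 0.7])
        lig = [
            center,
            center + np.array([_LIG_BOND, 0.0, 0.0]),
            center + np.array([_LIG_BOND / 2, _LIG_BOND * np.sqrt(3) / 2, 0.0]),
        ]
        coords.extend(lig)
        labels.append(frozenset({"ligand", "ligand_c1", "heavy"}))
        labels.append(frozenset({"ligand", "proton", "heavy"}))
        labels.append(frozenset({"ligand", "proton", "heavy"}))
    coords = np.array(coords, dtype=float)
    coords += 0.01 * rng.standard_normal(coords.shape)

    B = lambda i: 3 * i
    G = lambda i: 3 * i + 1
    H = lambda i: 3 * i + 2
    bonds, r0s, ks = [], [], []
    for i in range(n_residues):
        if i + 1 < n_residues:
            bonds.append((B(i), B(i + 1))); r0s.append(_BB_BOND); ks.append(_BOND_K)
        bonds.append((B(i), G(i))); r0s.append(_BG_BOND); ks.append(_BOND_K)
        bonds.append((B(i), H(i))); r0s.append(_BH_BOND); ks.append(_BOND_K)
    n_pep = 3 * n_residues
    if holo:
        l0, l1, l2 = n_pep, n_pep + 1, n_pep + 2
        for (a, b) in ((l0, l1), (l1, l2), (l0, l2)):
            bonds.append((a, b)); r0s.append(_LIG_BOND); ks.append(_LIG_K)
    bonds = np.array(bonds, dtype=int)

    angles = np.array(
        [(B(i - 1), B(i), B(i + 1)) for i in range(1, n_residues - 1)], dtype=int
    ).reshape(-1, 3)
    dihedrals = (
        np.array([(B(i), B(i + 1), B(i + 2), B(i + 3)) for i in range(n_residues - 3)], dtype=int)
        .reshape(-1, 4)
    )

    # nonbonded pair list: all pairs except those within 2 bonds on the graph
    n = coords.shape[0]
    adj = {i: set() for i in range(n)}
    for a, b in bonds:
        adj[a].add(b); adj[b].add(a)
    excluded = set()
    for a in range(n):
        for b in adj[a]:
            excluded.add(frozenset((a, b)))
            for cth in adj[b]:
                if cth != a:
                    excluded.add(frozenset((a, cth)))
    radius = np.empty(n)
    is_sidechain = np.zeros(n, dtype=bool)
    is_ligand = np.zeros(n, dtype=bool)
    is_heavy = np.zeros(n, dtype=bool)
    for i, ls in enumerate(labels):
        radius[i] = 0.08 if ("proton" in ls and "ligand" not in ls) else 0.17
        is_sidechain[i] = "sidechain" in ls
        is_ligand[i] = "ligand" in ls
        is_heavy[i] = "heavy" in ls
    pairs, sigma, attractive = [], [], []
    for a in range(n):
        for b in range(a + 1, n):
            if frozenset((a, b)) in excluded:
                continue
            pairs.append((a, b))
            sigma.append(radius[a] + radius[b])
            attr = (is_sidechain[a] and is_sidechain[b]) or (
                (is_ligand[a] != is_ligand[b]) and is_heavy[a] and is_heavy[b]
            )
            attractive.append(attr)
    model = BeadChainModel(
        n_residues=n_residues,
        holo=holo,
        seed=seed,
        coordinates=coords,
        labels=labels,
        bonds=bonds,
        bond_r0=np.array(r0s),
        bond_k=np.array(ks),
        angles=angles,
        dihedrals=dihedrals,
        nb_pairs=np.array(pairs, dtype=int),
        nb_sigma=np.array(sigma),
        nb_attractive=np.array(attractive, dtype=bool),
    )
    res_of = np.empty(model.n_beads, dtype=int)
    for i in range(model.n_beads):
        res_of[i] = i // 3 if i < n_pep else -1  # -1 marks ligand beads
    model.residue_of = res_of
    return model
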