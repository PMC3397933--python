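"""Structural analysis of weighted conformational ensembles.

Covers the analyses used to characterise disordered-peptide ensembles:
weighted-RMSD comparison after optimal (Kabsch) superposition, greedy
neighbour-count (Daura) clustering at a fixed RMSD cutoff, selection of
low-free-energy snapshots, proton-proton contact matrices with holo-apo
difference maps, RMSD distributions against a reference conformation, and
sliding-window Kyte-Doolittle hydropathy profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB, DEFAULT_TEMPERATURE

__all__ = [
    "DistanceMetricSpec",
    "ClusterResult",
    "ContactMatrix",
    "RMSDHistogram",
    "HydropathyProfile",
    "rmsd",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "select_low_free_energy",
    "contact_matrix",
    "contact_difference",
    "rmsd_distribution",
    "hydropathy_profile",
    "population_errors",
    "KYTE_DOOLITTLE",
]

#: Kyte-Doolittle hydropathy scale (standard published values).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}


@dataclass
class DistanceMetricSpec:
    """Atom subset and per-atom weights used for superposition + RMSD.

    ``subset`` holds atom indices; ``weights`` default to 1 per atom (a
    ligand-weighting of 3 is the conventional choice when resolving binding
    modes).  Superposition is the weighted optimal rigid-body fit.
    """

    subset: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.subset = np.asarray(self.subset, dtype=int)
        if self.subset.size == 0:
            raise ValueError("metric subset must be non-empty")
        if self.weights is None:
            self.weights = np.ones(self.subset.size)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.subset.size,):
            raise ValueError("weights must match the subset length")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")


def rmsd(conf_a: np.ndarray, conf_b: np.ndarray, metric: DistanceMetricSpec) -> float:
    """Weighted RMSD after weighted optimal superposition (symmetric in a, b)."""
    ca = np.asarray(conf_a, dtype=float)
    cb = np.asarray(conf_b, dtype=float)
    if metric.subset.max() >= ca.shape[0] or metric.subset.max() >= cb.shape[0]:
        raise ValueError("metric subset exceeds the conformations' atom count")
    a = ca[metric.subset]
    b = cb[metric.subset]
    if a.shape != b.shape:
        raise ValueError("conformations disagree on the metric subset")
    w = metric.weights
    wsum = w.sum()
    ac = a - np.average(a, axis=0, weights=w)
    bc = b - np.average(b, axis=0, weights=w)
    _, rssd = Rotation.align_vectors(ac, bc, weights=w)
    return float(rssd / np.sqrt(wsum))


def pairwise_rmsd_matrix(coords: np.ndarray, metric: DistanceMetricSpec) -> np.ndarray:
    """All-pairs RMSD for a stack of conformations (n_frames, n_atoms, 3)."""
    n = coords.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rmsd(coords[i], coords[j], metric)
    return d


@dataclass
class ClusterResult:
    """Daura clustering output: centers, members, weighted populations."""

    centers: list
    members: list               # list of index arrays, parallel to centers
    populations: np.ndarray
    population_errors: Optional[np.ndarray] = None

    def labels(self, n: int) -> np.ndarray:
        lab = np.full(n, -1, dtype=int)
        for k, mem in enumerate(self.members):
            lab[np.asarray(mem, dtype=int)] = k
        return lab


def daura_cluster(coords: np.ndarray, weights: Optional[np.ndarray],
                  metric: DistanceMetricSpec, cutoff: float,
                  rmsd_matrix: Optional[np.ndarray] = None) -> ClusterResult:
    """Greedy neighbour-count clustering.

    The structure with the most neighbours (pairwise RMSD < cutoff) defines a
    cluster centre; it and its neighbours are removed, and the procedure
    iterates until nothing is left.  Neighbour counting uses raw snapshot
    counts; fractional populations sum the (normalised) snapshot weights.
    Ties in neighbour count break to the lowest snapshot index.
    """
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty ensemble")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    d = pairwise_rmsd_matrix(coords, metric) if rmsd_matrix is None else rmsd_matrix
    neighbor = d < cutoff
    np.fill_diagonal(neighbor, False)
    unassigned = np.ones(n, dtype=bool)
    centers, members = [], []
    while unassigned.any():
        counts = (neighbor & unassigned[None, :] & unassigned[:, None]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax returns the lowest index on ties
        group = np.where(unassigned & (neighbor[center] | (np.arange(n) == center)))[0]
        centers.append(center)
        members.append(group)
        unassigned[group] = False
    pops = np.array([w[m].sum() for m in members])
    return ClusterResult(centers=centers, members=members, populations=pops)


def select_low_free_energy(binset, threshold_kt: float = 6.0,
                           temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Snapshot rows of bins within threshold_kt * kT of the lowest-F bin."""
    bins = binset.retained
    fs = np.array([b.free_energy for b in bins])
    fmin = np.nanmin(fs)
    cut = threshold_kt * KB * temperature
    rows = []
    for b, f in zip(bins, fs):
        if f - fmin <= cut:
            rows.extend(b.all_rows)
    return np.asarray(sorted(rows), dtype=int)


@dataclass
class ContactMatrix:
    """Weighted-average inter-group proton contact counts.

    Symmetric on the residue-residue block; entry (i, j) is the ensemble
    average of the number of proton pairs between groups i and j closer than
    the cutoff (intra-group pairs counted once, i < j).
    """

    labels: list
    counts: np.ndarray
    cutoff: float  # Angstrom

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.counts[i, j]


def contact_matrix(coords: np.ndarray, weights: Optional[np.ndarray],
                   group_map: dict, cutoff: float = 3.0,
                   coords_in_nm: bool = True) -> ContactMatrix:
    """Proton-proton contact matrix over a weighted ensemble.

    ``group_map`` maps label -> indices of that group's proton atoms (a label
    with no protons yields a zero row/column and a warning).  ``cutoff`` is in
    Angstrom; coordinates are nm internally unless flagged otherwise.
    """
    labels = list(group_map)
    n_frames = coords.shape[0]
    if weights is None:
        weights = np.full(n_frames, 1.0 / n_frames)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cut = cutoff * 0.1 if coords_in_nm else cutoff
    for lab, idx in group_map.items():
        if len(idx) == 0:
            warnings.warn(f"group {lab!r} has no proton atoms; zero row/column")
    m = len(labels)
    counts = np.zeros((m, m))
    for i in range(m):
        gi = np.asarray(group_map[labels[i]], dtype=int)
        for j in range(i, m):
            gj = np.asarray(group_map[labels[j]], dtype=int)
            if gi.size == 0 or gj.size == 0:
                continue
            if i == j:
                if gi.size < 2:
                    continue
                ii, jj = np.triu_indices(gi.size, k=1)
                pa, pb = gi[ii], gi[jj]
            else:
                pa, pb = np.meshgrid(gi, gj, indexing="ij")
                pa, pb = pa.ravel(), pb.ravel()
            d = np.linalg.norm(coords[:, pa, :] - coords[:, pb, :], axis=2)
            per_frame = (d < cut).sum(axis=1)
            counts[i, j] = counts[j, i] = float(np.sum(w * per_frame))
    return ContactMatrix(labels=labels, counts=counts, cutoff=cutoff)


def contact_difference(matrix_holo: ContactMatrix, matrix_apo: ContactMatrix) -> ContactMatrix:
    """Element-wise holo - apo on the shared labels.

    Labels present only in the holo matrix (the ligand block) are kept and
    reported as holo values; a mismatch on shared labels is rejected.
    """
    shared = [l for l in matrix_holo.labels if l in matrix_apo.labels]
    apo_only = [l for l in matrix_apo.labels if l not in matrix_holo.labels]
    if apo_only:
        raise ValueError(f"apo-only labels not allowed: {apo_only}")
    out = matrix_holo.counts.copy()
    hl = matrix_holo.labels
    for a in shared:
        for b in shared:
            i, j = hl.index(a), hl.index(b)
            out[i, j] -= matrix_apo.counts[matrix_apo.labels.index(a),
                                           matrix_apo.labels.index(b)]
    return ContactMatrix(labels=list(hl), counts=out, cutoff=matrix_holo.cutoff)


@dataclass
class RMSDHistogram:
    """Weighted RMSD-to-reference distribution plus the similar fraction."""

    bin_edges: np.ndarray
    densities: np.ndarray
    threshold: float
    fraction_below: float
    rmsd_values: np.ndarray = field(default=None, repr=False)


def rmsd_distribution(coords: np.ndarray, reference: np.ndarray,
                      weights: Optional[np.ndarray], metric: DistanceMetricSpec,
                      threshold: float = 2.5, bin_width: float = 0.5,
                      coords_in_nm: bool = True) -> RMSDHistogram:
    """Weighted histogram of RMSD (Angstrom) to a reference conformation.

    Reports the weighted fraction of the ensemble below the similarity
    threshold (2.5 Angstrom by default, the conventional backbone-similarity
    criterion).
    """
    n = coords.shape[0]
    if weights is None:
        weights = np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    scale = 10.0 if coords_in_nm else 1.0  # report Angstrom
    vals = np.array([rmsd(c, reference, metric) * scale for c in coords])
    hi = vals.max() + bin_width
    if np.isfinite(threshold):
        hi = max(hi, threshold + bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    dens, _ = np.histogram(vals, bins=edges, weights=w, density=True)
    return RMSDHistogram(
        bin_edges=edges,
        densities=dens,
        threshold=threshold,
        fraction_below=float(w[vals < threshold].sum()),
        rmsd_values=vals,
    )


@dataclass
class HydropathyProfile:
    sequence: str
    window: int
    scores: np.ndarray  # length = len(sequence) - window + 1, indexed by window center


def hydropathy_profile(sequence: str, window: int = 3,
                       tyrosine_as_phenylalanine: bool = True) -> HydropathyProfile:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    With ``tyrosine_as_phenylalanine`` (the default) tyrosine scores as
    phenylalanine (2.8), which highlights short aromatic/hydrophobic patches
    that favour small-molecule binding.  Positive windows are hydrophobic.
    """
    seq = sequence.strip().upper()
    if len(seq) < window:
        raise ValueError("sequence shorter than the window")
    scale = dict(KYTE_DOOLITTLE)
    if tyrosine_as_phenylalanine:
        scale["Y"] = scale["F"]
    vals = []
    for pos, aa in enumerate(seq):
        if aa not in scale:
            raise ValueError(f"invalid residue {aa!r} at position {pos + 1}")
        vals.append(scale[aa])
    v = np.asarray(vals)
    kernel = np.ones(window) / window
    scores = np.convolve(v, kernel, mode="valid")
    return HydropathyProfile(sequence=seq, window=window, scores=scores)


def populations_at_centers(coords: np.ndarray, weights: Optional[np.ndarray],
                           center_coords: np.ndarray, metric: DistanceMetricSpec,
                           cutoff: float) -> np.ndarray:
    """Weighted populations of one run against fixed (combined-run) centers.

    Each snapshot joins the first center, in center order, within the RMSD
    cutoff — the same precedence the greedy peeling established; snapshots
    near no center are left unassigned and contribute to no population.
    """
    n = coords.shape[0]
    if weights is None:
        weights = np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pops = np.zeros(center_coords.shape[0])
    for i in range(n):
        for k in range(center_coords.shape[0]):
            if rmsd(coords[i], center_coords[k], metric) < cutoff:
                pops[k] += w[i]
                break
    return pops


def population_errors(populations_a: np.ndarray, populations_b: np.ndarray):
    """Mean and standard error of cluster populations from two independent runs.

    Both runs must be clustered against the same (combined-ensemble) centers,
    so populations align index-by-index.  With two samples the standard error
    of the mean is |p_a - p_b| / 2.
    """
    pa = np.asarray(populations_a, dtype=float)
    pb = np.asarray(populations_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("population vectors must align (same cluster centers)")
    mean = 0.5 * (pa + pb)
    se = np.abs(pa - pb) / 2.0
    return mean, se
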