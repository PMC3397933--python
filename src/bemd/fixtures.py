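"""Conformational-ensemble fixtures with planted cluster structure.

Used to validate the greedy RMSD clustering: members of a planted cluster sit
within the intended cutoff of each other (under superposition-RMSD), while
distinct cluster centers sit more than twice the cutoff apart, which makes
the planted labels the unique greedy-clustering solution at that cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import DistanceMetricSpec, pairwise_rmsd_matrix, rmsd

__all__ = ["FixtureEnsemble", "make_cluster_fixture"]


@dataclass
class FixtureEnsemble:
    """Stack of conformations with planted cluster labels and the metric spec."""

    conformations: np.ndarray       # (n_frames, n_atoms, 3), nm
    planted_labels: np.ndarray      # cluster id per conformation
    metric: DistanceMetricSpec
    cutoff: float                   # nm; planting guaranteed at this cutoff


def make_cluster_fixture(n_clusters: int, n_per_cluster: int, spread: float,
                         separation: float, seed: int = 0,
                         n_atoms: int = 8) -> FixtureEnsemble:
    """Generate an ensemble whose clustering at cutoff = separation/2.5 is planted.

    ``spread`` bounds within-cluster pairwise RMSD and ``separation`` is the
    minimum between-center RMSD.  With the intended cutoff separation/2.5 the
    planting requires separation > 2*cutoff > 2*spread, i.e.
    separation > 5*spread; the generated geometry is additionally verified
    numerically against the planted-cluster inequalities and rejected if they
    fail.
    """
    if n_clusters < 1 or n_per_cluster < 1:
        raise ValueError("need at least one cluster and one member")
    if not separation > 5.0 * spread:
        raise ValueError(
            f"separation ({separation}) must exceed 5x the spread ({spread}) so that "
            "separation > 2*cutoff > 2*spread holds at the intended cutoff"
        )
    rng = np.random.Generator(np.random.Philox(key=seed))
    metric = DistanceMetricSpec(subset=np.arange(n_atoms))

    # random centers, rescaled so the minimum pairwise center RMSD matches
    # the requested separation (RMSD scales linearly with coordinates)
    centers = rng.standard_normal((n_clusters, n_atoms, 3))
    centers -= centers.mean(axis=1, keepdims=True)
    if n_clusters > 1:
        dmin = np.inf
        for i in range(n_clusters):
            for j in range(i + 1, n_clusters):
                dmin = min(dmin, rmsd(centers[i], centers[j], metric))
        centers *= 1.05 * separation / dmin
    confs = []
    labels = []
    for k in range(n_clusters):
        for _ in range(n_per_cluster):
            if spread > 0:
                # perturbation RMSD before fitting is spread/2 on average;
                # superposition only shrinks it
                noise = rng.standard_normal((n_atoms, 3))
                noise *= (spread / 2.5) / np.sqrt(np.mean(np.sum(noise**2, axis=1)))
                confs.append(centers[k] + noise)
            else:
                confs.append(centers[k].copy())
            labels.append(k)
    confs = np.asarray(confs)
    labels = np.asarray(labels, dtype=int)

    cutoff = separation / 2.5
    d = pairwise_rmsd_matrix(confs, metric)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    if same[off].any() and not np.all(d[same & off] < cutoff):
        raise ValueError("fixture generation failed: within-cluster distance >= cutoff")
    if (~same).any() and not np.all(d[~same] > 2.0 * cutoff - 1e-9):
        raise ValueError("fixture generation failed: between-cluster distance too small")
    return FixtureEnsemble(conformations=confs, planted_labels=labels,
                           metric=metric, cutoff=cutoff)
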