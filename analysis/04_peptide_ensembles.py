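"""Apo and holo bead-peptide ensembles: clustering, contacts, RMSD shifts.

Runs the scaled-down bias-exchange study on the 11-residue bead peptide with
and without the ligand (two independent seeds each), reweights the biased
snapshots by binning + WHAM, keeps the bins within 6 kT of the minimum, and
characterises the resulting ensembles: greedy RMSD clusters with
populations averaged over the two runs (ligand beads weighted 3x in the holo
metric), residue-residue proton contact maps with the holo-apo difference,
and the distribution of RMSD to the dominant apo conformation.
"""

import sys
from pathlib import Path

import numpy as np

from bemd import (
    CVGridSpec, bin_snapshots, converged_bias_profile, daura_cluster,
    population_errors, populations_at_centers, rmsd_distribution, run_bemd,
    select_low_free_energy, wham_bin_free_energies,
)
from bemd.analysis import contact_difference, contact_matrix
from bemd.io import write_conformations
from bemd.pipeline import _cluster_metric, _proton_groups, _snapshot_coordinates
from bemd.studies import bead_peptide_config, bead_peptide_system

OUT = Path("results/peptide_ensembles")
SEEDS = (21, 22)
TOTAL_TIME = 120.0           # ps per replica
GRID_CVS = ["coord_ca", "alpha_sim"]   # scaled-down binning subset
MIN_OCCUPANCY = 3
CLUSTER_CUTOFF_A = 3.5
CONTACT_CUTOFF_A = 3.0
RMSD_THRESHOLD_A = 2.5
LIGAND_WEIGHT = 3.0


class _MetricConfig:
    """Minimal stand-in carrying the analysis knobs for _cluster_metric."""

    class analysis:
        ligand_weight = LIGAND_WEIGHT
        excluded_labels: list = []


def run_condition(holo: bool, seed: int):
    model = bead_peptide_system(holo=holo)
    config = bead_peptide_config(seed, holo=holo, total_time=TOTAL_TIME)
    result = run_bemd(model, config, model=model)
    biased = result.biased_colvar().reset_index(drop=True)
    by_name = {cv.name: cv for cv in config.cvs}
    spec = CVGridSpec(
        cv_names=GRID_CVS,
        widths=[2 * by_name[n].sigma for n in GRID_CVS],
        origin=[by_name[n].wall.lower for n in GRID_CVS],
    )
    binset = bin_snapshots(biased, spec, min_occupancy=MIN_OCCUPANCY)
    conv, cv_of = {}, {}
    for i, cv in enumerate(config.cvs):
        lo, hi = cv.wall.lower - 6 * cv.sigma, cv.wall.upper + 6 * cv.sigma
        _, fn = converged_bias_profile(result.hills[cv.name], np.linspace(lo, hi, 401),
                                       (config.discard_time, config.total_time))
        conv[i], cv_of[i] = fn, cv.name
    binset = wham_bin_free_energies(binset, conv, colvar=biased, cv_of_ensemble=cv_of)
    rows = select_low_free_energy(binset, threshold_kt=6.0)
    coords, weights = _snapshot_coordinates(result, biased, binset, rows)
    return model, coords, weights


def analyse_condition(label: str, holo: bool):
    runs = [run_condition(holo, s) for s in SEEDS]
    model = runs[0][0]
    coords = np.concatenate([r[1] for r in runs])
    weights = np.concatenate([0.5 * r[2] for r in runs])
    metric = _cluster_metric(model, _MetricConfig)
    clusters = daura_cluster(coords, weights, metric, cutoff=CLUSTER_CUTOFF_A / 10.0)
    centers = coords[clusters.centers]
    per_run = [
        populations_at_centers(r[1], r[2], centers, metric, CLUSTER_CUTOFF_A / 10.0)
        for r in runs
    ]
    mean_pop, se_pop = population_errors(per_run[0], per_run[1])
    order = np.argsort(mean_pop)[::-1]
    with open(OUT / f"clusters_{label}.dat", "w") as fh:
        fh.write("# cluster population stderr n_members\n")
        for rank, k in enumerate(order):
            fh.write(f"{rank} {float(mean_pop[k])!r} {float(se_pop[k])!r} {len(clusters.members[k])}\n")
    print(f"{label}: {len(clusters.centers)} clusters from "
          f"{coords.shape[0]} snapshots; top populations " +
          ", ".join(f"{mean_pop[k]:.3f}+-{se_pop[k]:.3f}" for k in order[:3]))
    cmat = contact_matrix(coords, weights, _proton_groups(model),
                          cutoff=CONTACT_CUTOFF_A)
    with open(OUT / f"contacts_{label}.dat", "w") as fh:
        fh.write("# " + " ".join(cmat.labels) + "\n")
        for i, lab in enumerate(cmat.labels):
            fh.write(lab + " " + " ".join(repr(float(v)) for v in cmat.counts[i]) + "\n")
    write_conformations(OUT / f"ensemble_{label}.xyz", coords, labels=model.labels)
    return model, coords, weights, metric, clusters, cmat


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    apo = analyse_condition("apo", holo=False)
    holo = analyse_condition("holo", holo=True)

    diff = contact_difference(holo[5], apo[5])
    with open(OUT / "contacts_holo_minus_apo.dat", "w") as fh:
        fh.write("# " + " ".join(diff.labels) + "\n")
        for i, lab in enumerate(diff.labels):
            fh.write(lab + " " + " ".join(repr(float(v)) for v in diff.counts[i]) + "\n")
    shared = [l for l in diff.labels if l != "LIG"]
    block = diff.counts[np.ix_(
        [diff.labels.index(l) for l in shared],
        [diff.labels.index(l) for l in shared])]
    print(f"holo - apo residue contacts: mean change {block.mean():+.3f}, "
          f"largest |change| {np.max(np.abs(block)):.3f}")

    # RMSD of both ensembles to the dominant apo conformation (backbone metric)
    apo_model, apo_coords, apo_w, _, apo_clusters, _ = apo
    ref = apo_coords[apo_clusters.centers[int(np.argmax(apo_clusters.populations))]]
    from bemd import DistanceMetricSpec

    bb = apo_model.group("calpha")
    metric_bb = DistanceMetricSpec(subset=bb)
    for label, (model, coords, weights, *_rest) in (("apo", apo), ("holo", holo)):
        hist = rmsd_distribution(coords, ref, weights, metric_bb,
                                 threshold=RMSD_THRESHOLD_A)
        with open(OUT / f"rmsd_hist_{label}.dat", "w") as fh:
            fh.write(f"# bin_lo_A bin_hi_A density  "
                     f"fraction_below_{RMSD_THRESHOLD_A}A={float(hist.fraction_below)!r}\n")
            for lo, hi, d in zip(hist.bin_edges[:-1], hist.bin_edges[1:],
                                 hist.densities):
                fh.write(f"{float(lo)!r} {float(hi)!r} {float(d)!r}\n")
        print(f"{label}: fraction within {RMSD_THRESHOLD_A} A backbone RMSD of the "
              f"dominant apo conformation: {hist.fraction_below:.3f}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
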