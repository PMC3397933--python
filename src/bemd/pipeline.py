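"""End-to-end pipeline: simulate -> discard -> FES -> bin+WHAM -> select -> analyse.

Stage order mirrors the standard bias-exchange workflow; every stage writes
plain-text outputs into the run directory and the manifest records a sha256
per file, so re-running with the same config and seed reproduces every
numeric output bit-identically (the manifest differs only in timings).
"""

from __future__ import annotations

import logging
import time
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .analysis import (
    DistanceMetricSpec, contact_matrix, daura_cluster, rmsd_distribution,
    select_low_free_energy,
)
from .bead_model import BeadChainModel
from .constants import KB
from .metad import NEUTRAL, BEMDConfig, run_bemd
from .reweight import (
    CVGridSpec, bin_snapshots, bins_to_weighted_ensemble, converged_bias_profile,
    fes_from_hills, neutral_replica_average, wham_bin_free_energies, weighted_average,
)

__all__ = ["run_pipeline"]


def _pkg_version() -> str:
    try:
        return version("bemd")
    except PackageNotFoundError:
        return "unknown"


log = logging.getLogger("bemd.pipeline")


def run_pipeline(config: bio.RunConfig) -> bio.RunManifest:
    """Run all stages described by the config; returns the written manifest."""
    sched0 = config.schedule
    log.info(
        "run parameters: hill_height=%s kJ/mol, tau_deposit=%s ps, tau_exchange=%s ps, "
        "save_stride=%s ps, discard=%s, T=%s K, dt=%s ps, friction=%s /ps, "
        "min_occupancy=%s, fes_threshold=%s kT, cluster_cutoff=%s A, contact_cutoff=%s A, "
        "rmsd_threshold=%s A, ligand_weight=%s, seed=%s",
        sched0.hill_height, sched0.tau_deposit, sched0.tau_exchange, sched0.save_stride,
        sched0.discard_time, sched0.temperature, sched0.timestep, sched0.friction,
        config.analysis.min_occupancy, config.analysis.fes_threshold_kt,
        config.analysis.cluster_cutoff, config.analysis.contact_cutoff,
        config.analysis.rmsd_threshold, config.analysis.ligand_weight, config.seed,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = bio.RunManifest(
        config_hash=bio.config_hash(config), seed=config.seed,
        package_version=_pkg_version(),
    )
    system = config.system.build()
    cvs = [c.build() for c in config.cvs]
    sched = config.schedule
    bemd_config = BEMDConfig(
        cvs=cvs, total_time=sched.total_time, hill_height=sched.hill_height,
        tau_deposit=sched.tau_deposit, tau_exchange=sched.tau_exchange,
        save_stride=sched.save_stride, discard_time=sched.discard_time,
        temperature=sched.temperature, timestep=sched.timestep,
        friction=sched.friction, seed=config.seed,
    )
    kT = KB * sched.temperature

    # -- stage 1: simulate --------------------------------------------------
    t0 = time.perf_counter()
    model = system if isinstance(system, BeadChainModel) else None
    result = run_bemd(system, bemd_config, model=model)
    files = {}
    for rid, df in result.colvar.items():
        p = out / f"colvar_replica{rid}.dat"
        bio.write_colvar(p, df)
        files[p.name] = bio.RunManifest.file_sha256(p)
    for name, ledger in result.hills.items():
        p = out / f"hills_{name}.dat"
        bio.write_hills(p, ledger)
        files[p.name] = bio.RunManifest.file_sha256(p)
    p = out / "exchange_log.dat"
    with open(p, "w") as fh:
        fh.write("# time replica_a replica_b delta accepted\n")
        for _, r in result.exchange_log.iterrows():
            fh.write(f"{float(r['time'])!r} {int(r['replica_a'])} {int(r['replica_b'])} "
                     f"{float(r['delta'])!r} {int(r['accepted'])}\n")
    files[p.name] = bio.RunManifest.file_sha256(p)
    manifest.add_stage("simulate", files, time.perf_counter() - t0)
    manifest.write(out / "manifest.json")

    # -- stage 2: FES per CV ------------------------------------------------
    t0 = time.perf_counter()
    window = (bemd_config.discard_time, bemd_config.total_time)
    files = {}
    fes_profiles = {}
    for cv in cvs:
        if cv.wall is not None:
            lo, hi = cv.wall.lower, cv.wall.upper
        else:
            lo, hi = system.quadrature_domain[0]
        grid = np.linspace(lo, hi, 201)
        prof = fes_from_hills(result.hills[cv.name], grid, window)
        fes_profiles[cv.name] = prof
        p = out / f"fes_{cv.name}.dat"
        with open(p, "w") as fh:
            fh.write(f"# {cv.name} free_energy_kJ_mol\n")
            for x, f in zip(prof.grid, prof.free_energy):
                fh.write(f"{float(x)!r} {float(f)!r}\n")
        files[p.name] = bio.RunManifest.file_sha256(p)
    manifest.add_stage("fes", files, time.perf_counter() - t0)
    manifest.write(out / "manifest.json")

    # -- stage 3: bin + WHAM ------------------------------------------------
    t0 = time.perf_counter()
    biased = result.biased_colvar(discard=True).reset_index(drop=True)
    grid_names = config.analysis.grid_cvs or [cv.name for cv in cvs]
    by_name = {cv.name: cv for cv in cvs}
    widths = [2.0 * by_name[n].sigma for n in grid_names]
    origins = []
    for n in grid_names:
        cv = by_name[n]
        origins.append(cv.wall.lower if cv.wall is not None else
                       system.quadrature_domain[0][0])
    spec = CVGridSpec(cv_names=grid_names, widths=widths, origin=origins)
    binset = bin_snapshots(biased, spec, min_occupancy=config.analysis.min_occupancy)
    conv_bias = {}
    cv_of_ens = {}
    for i, cv in enumerate(cvs):
        if cv.wall is not None:
            lo, hi = cv.wall.lower - 6 * cv.sigma, cv.wall.upper + 6 * cv.sigma
        else:
            lo, hi = system.quadrature_domain[0]
        _, fn = converged_bias_profile(result.hills[cv.name], np.linspace(lo, hi, 401), window)
        conv_bias[i] = fn
        cv_of_ens[i] = cv.name
    binset = wham_bin_free_energies(binset, conv_bias, temperature=sched.temperature,
                                    colvar=biased, cv_of_ensemble=cv_of_ens)
    files = {}
    p = out / "bin_report.dat"
    with open(p, "w") as fh:
        fh.write("# index occupancy excluded free_energy_kJ_mol weight\n")
        for b in binset.bins:
            idx = ",".join(str(i) for i in b.index)
            fh.write(f"{idx} {b.occupancy} {int(b.excluded)} "
                     f"{float(b.free_energy)!r} {float(b.weight)!r}\n")
    files[p.name] = bio.RunManifest.file_sha256(p)
    ensemble = bins_to_weighted_ensemble(binset)
    p = out / "weights.dat"
    with open(p, "w") as fh:
        fh.write("# snapshot_row weight\n")
        for r, wt in zip(ensemble.rows, ensemble.weights):
            fh.write(f"{int(r)} {float(wt)!r}\n")
    files[p.name] = bio.RunManifest.file_sha256(p)
    manifest.add_stage("wham", files, time.perf_counter() - t0)
    manifest.write(out / "manifest.json")

    # -- stage 4: observables (both reweighting routes) ---------------------
    t0 = time.perf_counter()
    neutral = result.neutral_colvar(discard=True)
    files = {}
    p = out / "observables.dat"
    with open(p, "w") as fh:
        fh.write("# observable wham_reweighted neutral_replica\n")
        for cv in cvs:
            col = biased[cv.name].to_numpy()
            wham_mean = weighted_average(binset, col)
            wham_sq = weighted_average(binset, col**2)
            neu_mean = neutral_replica_average(neutral[cv.name].to_numpy())
            neu_sq = neutral_replica_average(neutral[cv.name].to_numpy() ** 2)
            fh.write(f"mean_{cv.name} {float(wham_mean)!r} {float(neu_mean)!r}\n")
            fh.write(f"meansq_{cv.name} {float(wham_sq)!r} {float(neu_sq)!r}\n")
    files[p.name] = bio.RunManifest.file_sha256(p)
    manifest.add_stage("observables", files, time.perf_counter() - t0)
    manifest.write(out / "manifest.json")

    # -- stage 5: structural analysis (bead systems) ------------------------
    if isinstance(system, BeadChainModel):
        t0 = time.perf_counter()
        files = {}
        rows = select_low_free_energy(binset, config.analysis.fes_threshold_kt,
                                      temperature=sched.temperature)
        coords, weights = _snapshot_coordinates(result, biased, binset, rows)
        metric = _cluster_metric(system, config)
        clusters = daura_cluster(coords, weights, metric,
                                 cutoff=config.analysis.cluster_cutoff / 10.0)
        p = out / "clusters.dat"
        with open(p, "w") as fh:
            fh.write("# cluster center_row n_members population\n")
            for k, (c, mem, pop) in enumerate(
                zip(clusters.centers, clusters.members, clusters.populations)
            ):
                fh.write(f"{k} {int(rows[c])} {len(mem)} {float(pop)!r}\n")
        files[p.name] = bio.RunManifest.file_sha256(p)
        cmat = contact_matrix(coords, weights, _proton_groups(system),
                              cutoff=config.analysis.contact_cutoff)
        p = out / "contacts.dat"
        with open(p, "w") as fh:
            fh.write("# " + " ".join(cmat.labels) + "\n")
            for i, lab in enumerate(cmat.labels):
                fh.write(lab + " " + " ".join(repr(float(v)) for v in cmat.counts[i]) + "\n")
        files[p.name] = bio.RunManifest.file_sha256(p)
        ref = coords[clusters.centers[0]]
        hist = rmsd_distribution(coords, ref, weights, metric,
                                 threshold=config.analysis.rmsd_threshold)
        p = out / "rmsd_hist.dat"
        with open(p, "w") as fh:
            fh.write(f"# bin_lo_A bin_hi_A density  fraction_below_{hist.threshold}A="
                     f"{float(hist.fraction_below)!r}\n")
            for lo, hi2, d in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.densities):
                fh.write(f"{float(lo)!r} {float(hi2)!r} {float(d)!r}\n")
        files[p.name] = bio.RunManifest.file_sha256(p)
        p = out / "ensemble.xyz"
        bio.write_conformations(p, coords, labels=system.labels)
        files[p.name] = bio.RunManifest.file_sha256(p)
        manifest.add_stage("structures", files, time.perf_counter() - t0)
        manifest.write(out / "manifest.json")

    return manifest


def _snapshot_coordinates(result, biased: pd.DataFrame, binset, rows):
    """Coordinates and WHAM weights for the selected pooled-biased rows."""
    weights_all = np.zeros(len(biased))
    for b in binset.retained:
        rws = b.all_rows
        for r in rws:
            weights_all[r] = b.weight / len(rws)
    coords = []
    for r in rows:
        rid = int(biased.loc[r, "replica"])
        t = float(biased.loc[r, "time"])
        times, traj = result.trajectories[rid]
        k = int(np.argmin(np.abs(times - t)))
        coords.append(traj[k])
    w = weights_all[rows]
    return np.asarray(coords), w / w.sum()


def _cluster_metric(system: BeadChainModel, config: bio.RunConfig) -> DistanceMetricSpec:
    """Heavy-bead metric; holo adds ligand beads at the configured weight."""
    excluded = set(config.analysis.excluded_labels)
    idx = []
    wts = []
    for i, ls in enumerate(system.labels):
        if ls & excluded:
            continue
        if "ligand" in ls:
            if system.holo:
                idx.append(i)
                wts.append(config.analysis.ligand_weight)
        elif "heavy" in ls:
            idx.append(i)
            wts.append(1.0)
    return DistanceMetricSpec(subset=np.asarray(idx), weights=np.asarray(wts))


def _proton_groups(system: BeadChainModel) -> dict:
    groups: dict = {}
    for i, ls in enumerate(system.labels):
        if "proton" not in ls:
            continue
        if "ligand" in ls:
            groups.setdefault("LIG", []).append(i)
        else:
            groups.setdefault(f"R{int(system.residue_of[i]) + 1}", []).append(i)
    return groups
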