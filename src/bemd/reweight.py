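"""Free-energy reconstruction and WHAM reweighting of biased trajectories.

Two complementary routes to equilibrium properties are implemented, mirroring
standard bias-exchange practice:

1. Hypercube binning + WHAM.  Snapshots from all biased ensembles are
   assigned to half-open hypercube bins on a regular grid in a chosen CV
   subset (bin width defaulting to twice the Gaussian width of each CV).
   Bin free energies follow from the self-consistent WHAM equations

       P_a ∝ sum_r n_a^r / sum_r N_r exp(beta (f_r - V_r(a)))
       exp(-beta f_r) = sum_a P_a exp(-beta V_r(a))

   where V_r(a) is the *converged* bias of ensemble r at bin a: the
   time-average of the deposited bias over the final window, evaluated at the
   snapshots assigned to the bin.  Ensemble properties are then weighted bin
   averages with weights exp(-beta F_a).

2. Neutral-replica averaging: plain means over snapshots recorded under the
   neutral assignment, whose distribution approximates the canonical one.

The free-energy profile along each biased CV is the negative of the bias
averaged over the final window, shifted so its minimum is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import KB, DEFAULT_TEMPERATURE
from .metad import HillsLedger

__all__ = [
    "FESProfile1D",
    "CVGridSpec",
    "BinRecord",
    "BinSet",
    "WeightedEnsemble",
    "fes_from_hills",
    "converged_bias_profile",
    "bin_snapshots",
    "wham_bin_free_energies",
    "weighted_average",
    "neutral_replica_average",
    "fes_from_neutral_histogram",
    "compare_profiles",
]


@dataclass
class FESProfile1D:
    """Free energy along one CV, shifted so the (defined) minimum is zero.

    Cells where the estimate is undefined (e.g. empty histogram bins) are NaN.
    """

    cv_name: str
    grid: np.ndarray
    free_energy: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("profile grid must be strictly increasing")
        f = np.asarray(self.free_energy, dtype=float)
        fin = np.isfinite(f)
        if not fin.any():
            raise ValueError("profile has no defined values")
        f = f - np.nanmin(f[fin])
        self.grid = g
        self.free_energy = f

    def interp(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.grid, self.free_energy)


def fes_from_hills(ledger: HillsLedger, grid: np.ndarray,
                   window: tuple[float, float]) -> FESProfile1D:
    """FES as the negative of the bias averaged over the window.

    The average runs over the bias snapshots at the ledger's deposition times
    inside [window[0], window[1]]; the result is shifted to minimum zero.
    """
    grid = np.asarray(grid, dtype=float)
    c, w, h, t = ledger.arrays()
    t0, t1 = window
    if len(t) == 0 or t0 >= t1:
        raise ValueError("empty averaging window")
    in_window = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    if not in_window.any():
        raise ValueError(f"no depositions inside window [{t0}, {t1}]")
    running = np.zeros_like(grid)
    acc = np.zeros_like(grid)
    n_avg = 0
    for k in range(len(t)):
        if t[k] > t1 + 1e-12:
            break
        d = grid - c[k]
        running += h[k] * np.exp(-d * d / (2.0 * w[k] ** 2))
        if t[k] >= t0 - 1e-12:
            acc += running
            n_avg += 1
    return FESProfile1D(cv_name=ledger.cv_name, grid=grid, free_energy=-(acc / n_avg))


def converged_bias_profile(ledger: HillsLedger, grid: np.ndarray,
                           window: tuple[float, float]):
    """Window-averaged bias on a grid plus a callable interpolant.

    This is the 'converged bias' entering WHAM — the same time average whose
    negative defines the FES profile.
    """
    grid = np.asarray(grid, dtype=float)
    c, w, h, t = ledger.arrays()
    t0, t1 = window
    if len(t) == 0 or t0 >= t1:
        raise ValueError("empty averaging window")
    running = np.zeros_like(grid)
    acc = np.zeros_like(grid)
    n_avg = 0
    for k in range(len(t)):
        if t[k] > t1 + 1e-12:
            break
        d = grid - c[k]
        running += h[k] * np.exp(-d * d / (2.0 * w[k] ** 2))
        if t[k] >= t0 - 1e-12:
            acc += running
            n_avg += 1
    vbar = acc / n_avg
    return vbar, (lambda s, g=grid, v=vbar: np.interp(np.asarray(s, dtype=float), g, v))


@dataclass
class CVGridSpec:
    """Regular hypercube grid over a CV subset.

    ``widths`` default to 2*sigma of each CV; ``origin`` anchors bin edges
    (per-CV wall minimum by default).  Binning is half-open [low, high): a
    value exactly on an edge belongs to the upper bin.
    """

    cv_names: Sequence[str]
    widths: Sequence[float]
    origin: Sequence[float]
    bounds: Optional[Sequence[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if len(self.cv_names) != len(self.widths) or len(self.cv_names) != len(self.origin):
            raise ValueError("cv_names, widths and origin must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ValueError("bin widths must be positive")

    def index_of(self, values: np.ndarray) -> tuple:
        idx = []
        for v, w, o in zip(values, self.widths, self.origin):
            # lower-closed / upper-open with a deterministic edge rule
            u = (v - o) / w
            i = int(np.floor(u + 1e-12))
            idx.append(i)
        return tuple(idx)

    def center_of(self, index: tuple) -> np.ndarray:
        return np.array(
            [o + (i + 0.5) * w for i, w, o in zip(index, self.widths, self.origin)]
        )


@dataclass
class BinRecord:
    """One hypercube bin: snapshots per source ensemble, occupancy, WHAM outputs."""

    index: tuple
    snapshots: dict                 # ensemble id -> list of row ids
    occupancy: int = 0
    excluded: bool = False
    mean_bias: dict = field(default_factory=dict)   # ensemble id -> kJ/mol
    free_energy: float = np.nan
    weight: float = 0.0

    @property
    def all_rows(self) -> list:
        out = []
        for rows in self.snapshots.values():
            out.extend(rows)
        return out


@dataclass
class BinSet:
    """Binned snapshot collection plus the sentinel overflow bin."""

    grid_spec: CVGridSpec
    bins: list
    overflow: BinRecord
    ensembles: list
    converged: bool = True

    @property
    def retained(self) -> list:
        return [b for b in self.bins if not b.excluded]


def bin_snapshots(colvar: pd.DataFrame, grid_spec: CVGridSpec,
                  min_occupancy: int = 5, ensemble_column: str = "assignment") -> BinSet:
    """Assign snapshots to hypercube bins in the selected CV subset.

    ``colvar`` must contain the grid's CV columns and an ensemble id column
    (the bias assignment under which the snapshot was recorded).  Bins with
    fewer than ``min_occupancy`` snapshots are flagged excluded; snapshots
    outside the grid bounds land in the sentinel overflow bin.
    """
    for name in grid_spec.cv_names:
        if name not in colvar.columns:
            raise ValueError(f"colvar table lacks CV column {name!r}")
    values = colvar[list(grid_spec.cv_names)].to_numpy()
    ensembles = colvar[ensemble_column].to_numpy()
    table: dict[tuple, BinRecord] = {}
    overflow = BinRecord(index=("overflow",), snapshots={})
    bounds = grid_spec.bounds
    for row, (v, ens) in enumerate(zip(values, ensembles)):
        if bounds is not None and any(
            not (lo <= x < hi) for x, (lo, hi) in zip(v, bounds)
        ):
            overflow.snapshots.setdefault(ens, []).append(row)
            overflow.occupancy += 1
            continue
        idx = grid_spec.index_of(v)
        rec = table.get(idx)
        if rec is None:
            rec = table[idx] = BinRecord(index=idx, snapshots={})
        rec.snapshots.setdefault(ens, []).append(row)
        rec.occupancy += 1
    bins = [table[k] for k in sorted(table)]
    for b in bins:
        b.excluded = b.occupancy < min_occupancy
    if overflow.occupancy:
        warnings.warn(f"{overflow.occupancy} snapshots fell outside the CV grid bounds")
    return BinSet(grid_spec=grid_spec, bins=bins, overflow=overflow,
                  ensembles=sorted(set(ensembles.tolist())))


def wham_bin_free_energies(binset: BinSet, converged_bias: dict,
                           temperature: float = DEFAULT_TEMPERATURE,
                           tol: float = 1e-6, max_iter: int = 100_000,
                           colvar: Optional[pd.DataFrame] = None,
                           cv_of_ensemble: Optional[dict] = None) -> BinSet:
    """Solve the WHAM self-consistency for the retained bins.

    ``converged_bias`` maps ensemble id -> callable (CV value -> kJ/mol), the
    window-averaged bias of that ensemble along its own CV.  The per-bin bias
    V_r(a) is the mean over the bin's snapshots of the ensemble's bias at the
    snapshot's CV value when ``colvar``/``cv_of_ensemble`` are given (so CVs
    outside the binning subset are handled); otherwise it is evaluated at the
    bin center, which requires the ensemble's CV to be part of the grid.

    Adding a constant to every bias leaves all bin free energies unchanged
    (gauge invariance); non-convergence is flagged on the returned BinSet and
    warned, never silent.
    """
    bins = binset.retained
    if not bins:
        raise ValueError("no retained bins: nothing to reweight")
    reps = binset.ensembles
    kT = KB * temperature
    beta = 1.0 / kT
    n_bins = len(bins)
    n_rep = len(reps)
    counts = np.zeros((n_bins, n_rep))
    vmat = np.zeros((n_bins, n_rep))
    for a, b in enumerate(bins):
        for r_i, r in enumerate(reps):
            counts[a, r_i] = len(b.snapshots.get(r, []))
        for r_i, r in enumerate(reps):
            fn = converged_bias[r]
            if colvar is not None and cv_of_ensemble is not None:
                rows = b.all_rows
                svals = colvar[cv_of_ensemble[r]].to_numpy()[rows]
                vmat[a, r_i] = float(np.mean(fn(svals)))
            else:
                center = binset.grid_spec.center_of(b.index)
                name_to_pos = {n: i for i, n in enumerate(binset.grid_spec.cv_names)}
                cvname = cv_of_ensemble[r] if cv_of_ensemble else binset.grid_spec.cv_names[r_i]
                if cvname not in name_to_pos:
                    raise ValueError(
                        f"ensemble {r} CV {cvname!r} not in grid; pass colvar for "
                        "per-snapshot bias evaluation"
                    )
                vmat[a, r_i] = float(fn(center[name_to_pos[cvname]]))
        b.mean_bias = {r: vmat[a, r_i] for r_i, r in enumerate(reps)}
    n_tot = counts.sum(axis=0)
    # numerically stable iteration in log space on shifted biases
    vshift = vmat - vmat.min()
    f = np.zeros(n_rep)
    prev_F = None
    converged = False
    resid = np.inf
    p = None
    for _ in range(int(max_iter)):
        denom = np.sum(n_tot[None, :] * np.exp(beta * (f[None, :] - vshift)), axis=1)
        p = counts.sum(axis=1) / denom
        p = p / p.sum()
        with np.errstate(divide="ignore"):
            F = -kT * np.log(p)
        F = F - F.min()
        # update ensemble free energies
        f = -kT * np.log(np.sum(p[:, None] * np.exp(-beta * vshift), axis=0))
        if prev_F is not None:
            resid = float(np.max(np.abs(F - prev_F)))
        prev_F = F
        if resid < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"WHAM did not converge in {max_iter} iterations (residual {resid:.2e})")
    binset.converged = converged
    for a, b in enumerate(bins):
        b.free_energy = float(prev_F[a])
        b.weight = float(p[a])
    return binset


@dataclass
class WeightedEnsemble:
    """Snapshot references with normalised equilibrium weights."""

    rows: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if abs(s - 1.0) > 1e-10:
            w = w / s
        self.weights = w
        self.rows = np.asarray(self.rows, dtype=int)


def bins_to_weighted_ensemble(binset: BinSet) -> WeightedEnsemble:
    """Per-snapshot weights: each bin's WHAM weight split evenly over its snapshots."""
    rows, wts = [], []
    for b in binset.retained:
        rws = b.all_rows
        for r in rws:
            rows.append(r)
            wts.append(b.weight / len(rws))
    w = np.asarray(wts)
    return WeightedEnsemble(rows=np.asarray(rows), weights=w / w.sum())


def weighted_average(binset: BinSet, observable) -> float:
    """WHAM-weighted ensemble average of a per-snapshot observable.

    ``observable`` is an array indexed by snapshot row id (NaN = missing; such
    snapshots are dropped from their bin mean with a warning) or a callable
    row id -> float.  Excluded bins contribute nothing.
    """
    bins = binset.retained
    if callable(observable):
        getval = observable
    else:
        arr = np.asarray(observable, dtype=float)
        getval = lambda r: arr[r]
    num = 0.0
    den = 0.0
    n_missing = 0
    for b in bins:
        vals = np.array([getval(r) for r in b.all_rows], dtype=float)
        ok = np.isfinite(vals)
        n_missing += int((~ok).sum())
        if not ok.any():
            continue
        obar = float(vals[ok].mean())
        num += b.weight * obar
        den += b.weight
    if n_missing:
        warnings.warn(f"{n_missing} snapshots lacked the observable and were dropped")
    if den == 0.0:
        raise ValueError("no bin had any observable value")
    return num / den


def neutral_replica_average(values: Sequence[float]) -> float:
    """Unweighted mean over neutral-replica snapshots (equilibration already discarded)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no neutral-replica snapshots to average")
    return float(v.mean())


def fes_from_neutral_histogram(values: Sequence[float], cv_name: str,
                               grid_edges: np.ndarray,
                               temperature: float = DEFAULT_TEMPERATURE) -> FESProfile1D:
    """-kT log of the neutral-replica histogram density, shifted to min zero.

    Empty cells are NaN (undefined), never zero.
    """
    v = np.asarray(values, dtype=float)
    edges = np.asarray(grid_edges, dtype=float)
    counts, _ = np.histogram(v, bins=edges)
    if counts.sum() == 0:
        raise ValueError("all histogram cells are empty")
    hist = counts / counts.sum() / np.diff(edges)
    kT = KB * temperature
    with np.errstate(divide="ignore"):
        f = np.where(hist > 0, -kT * np.log(np.where(hist > 0, hist, 1.0)), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FESProfile1D(cv_name=cv_name, grid=centers, free_energy=f)


def compare_profiles(p1: FESProfile1D, p2: FESProfile1D, max_f: float):
    """RMS and max |F1 - F2| on p1's grid where both are defined and F1 <= max_f."""
    f2 = np.interp(p1.grid, p2.grid, p2.free_energy)
    mask = np.isfinite(p1.free_energy) & np.isfinite(f2) & (p1.free_energy <= max_f)
    if not mask.any():
        raise ValueError("no overlapping region below the free-energy cut")
    d = p1.free_energy[mask] - f2[mask]
    return float(np.sqrt(np.mean(d * d))), float(np.max(np.abs(d)))
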