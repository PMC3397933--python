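"""Canonical study conditions used by the analysis drivers and validation runs.

These fix, once, the toy-system parameters that play the role of the
production simulation setup: the double-well landscape with its CV, wall
positions and schedule, and the bead-peptide apo/holo configurations.  The
same conditions are shared by the numbered analysis scripts, the test suite
and the acceptance script so all of them probe one set of physics.

Parameter rationale (see docs/methods.md for the full account):

* hill height 0.2 kJ/mol, deposition every 2.0 ps, saves every 2.0 ps,
  exchanges every 20.0 ps, 300 K — the standard bias-exchange schedule for
  peptide sampling, kept verbatim.
* double well: barrier 10 kJ/mol (~4 kT, comparable to a backbone
  rearrangement), minima at +/-1 nm; walls at +/-1.6 nm, where the potential
  reaches ~10 kT above the minimum, following the convention that walls
  confine the profile to the ~10 kT region.
* Gaussian width sigma = 0.07 nm from the usual width rule (about one third
  of the basin fluctuation sqrt(kT/U''(min)) ~ 0.18 nm).
* friction 5.0/ps with dt 0.005 ps: satisfies the overdamped-Euler stability
  bound dt*max|U''|/friction < 0.5 on this landscape (the package-wide
  default friction of 1.0/ps does not).
* total time 10 ns (2e6 steps), first 1/6 discarded as equilibration; the
  free-energy average runs over the remaining 5/6 of the run.
"""

from __future__ import annotations

import numpy as np

from .bead_model import make_bead_peptide
from .cvs import CVDefinition, Wall
from .metad import BEMDConfig
from .potentials import DoubleWell1D, make_double_well

__all__ = [
    "DOUBLE_WELL_BARRIER", "DOUBLE_WELL_HALF_SEP", "DOUBLE_WELL_SIGMA",
    "DOUBLE_WELL_WALL", "double_well_system", "double_well_cv",
    "double_well_config", "bead_peptide_cvs", "bead_peptide_config",
]

DOUBLE_WELL_BARRIER = 10.0     # kJ/mol
DOUBLE_WELL_HALF_SEP = 1.0     # nm
DOUBLE_WELL_SIGMA = 0.07       # nm
DOUBLE_WELL_WALL = 1.6         # nm, |x| wall position (~10 kT contour)
_FRICTION = 5.0                # 1/ps
_TIMESTEP = 0.005              # ps


def double_well_system() -> DoubleWell1D:
    return make_double_well(DOUBLE_WELL_BARRIER, DOUBLE_WELL_HALF_SEP)


def double_well_cv(sigma: float = DOUBLE_WELL_SIGMA) -> CVDefinition:
    return CVDefinition(
        name="x", kind="coordinate", sigma=sigma, params={"index": 0},
        wall=Wall(-DOUBLE_WELL_WALL, DOUBLE_WELL_WALL, 100.0),
    )


def double_well_config(seed: int, total_time: float = 10_000.0,
                       hill_height: float = 0.2) -> BEMDConfig:
    """Standard double-well BEMD schedule: 1 biased + 1 neutral replica."""
    return BEMDConfig(
        cvs=[double_well_cv()], total_time=total_time, hill_height=hill_height,
        tau_deposit=2.0, tau_exchange=20.0, save_stride=2.0,
        timestep=_TIMESTEP, friction=_FRICTION, seed=seed,
    )


def bead_peptide_cvs(holo: bool) -> list[CVDefinition]:
    """The CV set biased on the bead peptide, one replica per CV plus neutral.

    Mirrors the roles of the standard peptide CV battery: coordination numbers
    over backbone and sidechain beads, backbone-dihedral similarity to the
    alpha region and successive-dihedral correlation, smooth hydrogen-bond
    counts, and (holo only) the soft minimum distance from the ligand probe
    bead to the backbone.  Widths follow the usual per-kind conventions
    (0.7 for the backbone coordination, 0.5 for the sidechain one, 0.25 for
    dihedral/H-bond counts); wall positions were set from short unrestrained
    pilot runs so that the profiles stay within roughly 10 kT.
    """
    cvs = [
        CVDefinition(name="coord_ca", kind="coordination", sigma=0.7,
                     params={"r0": 0.65}, groups={"a": "calpha", "b": "calpha"},
                     wall=Wall(10.0, 44.0, 100.0)),
        CVDefinition(name="coord_cg", kind="coordination", sigma=0.5,
                     params={"r0": 0.65}, groups={"a": "cgamma", "b": "cgamma"},
                     wall=Wall(10.0, 54.0, 100.0)),
        CVDefinition(name="alpha_sim", kind="dihedral_similarity", sigma=0.25,
                     wall=Wall(0.5, 7.5, 100.0)),
        CVDefinition(name="dih_corr", kind="dihedral_correlation", sigma=0.25,
                     wall=Wall(0.1, 6.9, 100.0)),
        CVDefinition(name="hbonds", kind="hbond_count", sigma=0.25,
                     params={"r0": 0.25}, groups={"donor": "donor", "acceptor": "acceptor"},
                     wall=Wall(6.0, 24.0, 100.0)),
    ]
    if holo:
        cvs.append(
            CVDefinition(name="lig_dist", kind="softmin_distance", sigma=0.05,
                         params={"beta_s": 2.0},
                         groups={"probe": "ligand_c1", "target": "calpha"},
                         wall=Wall(0.3, 1.2, 200.0))
        )
    return cvs


def bead_peptide_config(seed: int, holo: bool, total_time: float = 240.0) -> BEMDConfig:
    """Bead-peptide BEMD schedule (scaled-down apo/holo production analogue).

    dt 0.001 ps with friction 2.0/ps keeps the stability bound satisfied for
    the bead force field's bonded terms; hill height, paces and save stride
    are the standard schedule.
    """
    return BEMDConfig(
        cvs=bead_peptide_cvs(holo), total_time=total_time, hill_height=0.2,
        tau_deposit=2.0, tau_exchange=20.0, save_stride=2.0,
        timestep=0.001, friction=2.0, seed=seed,
    )


def bead_peptide_system(holo: bool, seed: int = 7):
    return make_bead_peptide(11, holo=holo, seed=seed)
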