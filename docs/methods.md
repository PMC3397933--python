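# Methods

This package reimplements, at desk scale, the sampling-and-analysis workflow
used to characterise the conformational ensembles of a short intrinsically
disordered peptide with and without a bound small molecule: bias-exchange
metadynamics (BEMD) sampling, free-energy reconstruction from the deposited
bias, WHAM reweighting of the biased trajectories to an equilibrium
ensemble, and structural analysis of that ensemble (greedy RMSD clustering,
proton-contact maps, RMSD distributions, hydropathy profiles).  The
explicit-solvent atomistic system of the original study is replaced by toy
systems with exact references, so every stage can be validated: a 1-D/2-D
analytic landscape whose Boltzmann statistics are computable by quadrature,
and a bead-chain peptide on which all collective-variable (CV) kinds are
well defined.

## Model systems

**Analytic landscapes.** The workhorse is the quartic double well
U(x) = h((x/a)² − 1)², default h = 10 kJ/mol (≈ 4 kT at 300 K) and a = 1 nm.
Its free-energy profile along x *is* U(x) up to a constant, and any
Boltzmann expectation is computable by deterministic grid quadrature
(`boltzmann_reference`), reported with a grid-refinement error estimate.
A two-basin 2-D landscape (inverted Gaussians plus a confining quartic)
covers the 2-D case.  Quadrature domains are chosen so the neglected
Boltzmann mass is below 1e-10 at 300 K.

**Bead-chain peptide.** Eleven residues (matching the length of the studied
peptide), three beads per residue — backbone (pseudo-C-alpha), sidechain
(pseudo-C-gamma) and an explicit pseudo-proton — plus an optional
quasi-rigid three-bead ligand whose first bead is the probe atom of the
minimum-distance CV.  The force field is deliberately simple and entirely a
construction of this package: harmonic bonds (k = 300 kJ/mol/nm², ligand
600), a cosine-based angle term k(cos θ − cos θ₀)² that has no collinear
singularity, a weak backbone dihedral k(1 + cos φ), a harmonic soft-sphere
repulsion inside the contact radius, and a Gaussian contact attraction
(3.0 kJ/mol deep, 0.12 nm wide) between sidechain beads and between ligand
and peptide.  All nonbonded terms have bounded curvature, so the overdamped
Euler integrator is stable at the study timestep.  The attraction strength
was chosen so the chain interconverts between collapsed (Rg ≈ 0.45 nm) and
extended (Rg > 0.75 nm) states within ~10⁵ steps at 300 K, which a smoke
test pins.  These parameters emulate the *heterogeneity* of a disordered
peptide — multiple interconverting compact and extended states — not any
specific molecular system; passing tests demonstrate the machinery, not
fidelity to protein energetics.

## Dynamics

Position-only (overdamped) Langevin dynamics:
x' = x − (Δt/γ)∇(U + V_bias + V_wall) + √(2kT Δt/γ) η.  The observables of
the workflow are configurational, so no velocities are propagated.  Units
package-wide: nm, kJ/mol, ps, K, k_B = 0.0083144621 kJ/mol/K, default 300 K.
Defaults γ = 1/ps and Δt = 0.005 ps, with a stability check warning when
Δt·max|U''|/γ ≥ 0.5.  The double-well study uses γ = 5/ps (the default
violates the stability bound on that landscape); the bead-peptide study uses
Δt = 0.001 ps, γ = 2/ps for the same reason.

Each replica draws its noise from a private Philox stream keyed on
(seed, replica id) and consumed sequentially; exchange decisions use a
separate stream.  The exchange schedule therefore never perturbs the
dynamical noise sequences, and identical seeds give bit-identical
trajectories.

## Collective variables

Five differentiable CV kinds cover the functional roles of the usual
disordered-peptide battery: coordination numbers over bead groups (rational
switching function s(r) = (1 − (r/r0)ⁿ)/(1 − (r/r0)ᵐ), defaults n = 6,
m = 12, r0 = 0.65 nm for backbone coordination; the removable singularity at
r = r0 is evaluated by its limit n/m), similarity of backbone dihedrals to a
reference alpha angle Σ(1 + cos(ψᵢ − ψ_ref))/2 with ψ_ref = −0.82 rad
(config-exposed), correlation of successive dihedrals, smooth hydrogen-bond
counts (switching function with r0 = 0.25 nm over donor/acceptor groups),
and a log-sum-exp soft minimum distance s = β_s / ln Σ exp(β_s/d_j), which
approaches the hard minimum as β_s grows relative to the distances (β_s =
2 nm in the study).  Every CV returns value plus analytic gradient; gradients
are pinned against central finite differences at 1e-5 relative tolerance,
and all CVs are exactly invariant under rigid rotation and translation.

Half-harmonic walls k(s − bound)² (default k = 100 kJ/mol per CV-unit²)
confine each CV to the range where its free-energy profile stays within
roughly 10 kT of the minimum; wall positions for the bead-peptide CVs were
read off short unrestrained pilot runs.  Wall stiffness is a package choice:
only the positions follow the 10 kT convention.

## Bias-exchange metadynamics

Each biased replica deposits Gaussians of fixed height 0.2 kJ/mol every
2.0 ps on its assigned CV, at the instantaneous CV value of the saved step
(save stride 2.0 ps, coincident with the deposition pace).  One neutral
replica carries no bias.  Every 20 ps a uniformly random replica pair
attempts to swap *bias assignments* with Metropolis probability
min(1, exp(−βΔ)), Δ = V_a(x_b) + V_b(x_a) − V_a(x_a) − V_b(x_b);
configurations keep their coordinates, so the hills ledger of a CV collects
depositions from whichever replica currently carries that bias, and the
"neutral ensemble" is the pool of snapshots recorded under the neutral
assignment.  Walls of all CVs act on all replicas, including the neutral
one, so all ensembles share the same CV support.  Random-pair selection is a
declared choice (logged per attempt, so any other scheme is replayable).

During dynamics the bias is evaluated from a regular grid updated
incrementally at each deposition (spacing σ/20, linear interpolation).  With
many overlapping hills the interpolation error scales with the accumulated
curvature; σ/20 keeps it below 1% of one hill height, which a test pins
against the exact ledger sum.  Hill heights are constant (no well-tempered
damping).

**Double-well study conditions** (frozen in `bemd.studies`): barrier
10 kJ/mol, minima ±1 nm, walls ±1.6 nm (the ~10 kT contour), Gaussian width
σ = 0.07 nm from the standard width rule (about one third of the basin
fluctuation √(kT/U'') ≈ 0.18 nm), 10 ns = 2e6 steps per replica, one biased
plus one neutral replica, first 1/6 of the run discarded as equilibration
(generalising the production convention of discarding the first sixth).

## Free energies and reweighting

The FES along a biased CV is the negative of the deposited bias averaged
over the post-equilibration window, shifted to minimum zero.  On the double
well this recovers the analytic potential to ~0.13 kT RMS over the 10 kT
region, and two independent seeds agree within ~0.4 kT — comfortably inside
the ~1 kT run-to-run reproducibility expected of converged profiles.

Equilibrium properties are computed two ways:

1. **Binning + WHAM.**  Snapshots from all biased ensembles (pooled by bias
   assignment, not by trajectory) are assigned to half-open hypercube bins
   on a regular CV grid, bin width 2σ per CV, origin anchored at the per-CV
   wall minimum, values on an edge belonging to the upper bin.  Bins with
   fewer than 5 snapshots are excluded.  Bin free energies solve the
   standard multi-ensemble WHAM equations with the *converged bias* of each
   ensemble — the final-window time-average of its deposited bias, evaluated
   at the snapshots assigned to the bin (so CVs outside the binning subset
   are handled).  Iteration stops at max|ΔF| < 1e-6 kJ/mol or 1e5 iterations
   (non-convergence is flagged and warned, never silent).  Gauge invariance
   under constant bias shifts and two closed-form cases (zero bias = raw
   histogram; 2-bin/2-ensemble vs an independently solved fixed point) are
   pinned by tests.  Ensemble averages weight within-bin means by
   exp(−βF_a).  Variants that split each trajectory into time-window
   sub-ensembles were evaluated and change nothing here (with a single
   biased ensemble the time-dependent offset cancels), so the per-ensemble
   form is retained.

2. **Neutral-replica averaging.**  Plain means over the neutral-assignment
   snapshots.

On the double well both routes agree with the quadrature oracle: ⟨x²⟩ from
WHAM deviates by about −0.4% (within 2 standard errors over five seeds),
the neutral route by a similar amount, and the two routes agree within
combined errors.  The residual WHAM deviation is the hysteresis error of
fixed-height metadynamics concentrated in the wall-adjacent bins, where the
sweeping bias lags quasi-equilibrium; it shrinks with smaller hills or
slower deposition but does not average out with longer runs.  The
neutral-histogram FES matches the hills FES within ~0.5 kT near the minima
but sits systematically *below* it in high-free-energy regions: rare states
reach the neutral ensemble through exchanges faster than they decay, so the
neutral replica overrepresents them — the reason ensemble properties here
are taken from the reweighted biased trajectories.

## Structural analysis

Snapshots from bins within 6 kT of the lowest-F bin form the analysis
subset.  Pairwise RMSD uses weighted optimal superposition
(scipy's Kabsch-type `align_vectors`); the holo metric uses heavy beads plus
ligand beads weighted 3x (to resolve binding modes), the apo metric heavy
beads minus a configurable exclusion list (no automatic symmetry
detection).  Clustering is the greedy neighbour-count algorithm at a 3.5 Å
cutoff: the snapshot with the most neighbours under the cutoff becomes a
centre, it and its neighbours are removed, and the procedure iterates;
neighbour counting uses raw snapshot counts while populations sum snapshot
weights; ties break to the lowest snapshot index.  The implementation is
pinned, member-for-member, against an independent brute-force
reimplementation and recovers planted cluster fixtures exactly.  Population
uncertainties come from two independent runs clustered against the combined
ensemble's centres (each run's snapshots join the first centre, in centre
order, within the cutoff); with two runs the standard error is |p₁ − p₂|/2.

Contact maps count proton-bead pairs within 3.0 Å (weighted ensemble
average per residue pair; ±0.5 Å only affects pairs whose distances fall in
the perturbed band, which a sensitivity test pins).  The holo − apo
difference map is element-wise on shared labels, with ligand rows retained
from the holo block.  RMSD distributions against a reference conformation
report the weighted fraction below 2.5 Å, the conventional
backbone-similarity criterion.  Hydropathy profiles are window-3 sliding
means of the Kyte-Doolittle scale with tyrosine rescored as phenylalanine
(2.8), highlighting short aromatic/hydrophobic patches.

## Numerical and design notes

* Binning edge rule, bin origin, and the pooling of biased snapshots by
  assignment are deterministic conventions, stated above, so pipeline
  reruns are bit-identical (the manifest differs only in wall-clock
  timings; its config hash excludes the output path).
* The dihedral-gradient formulas, the force kernels (numba) and their numpy
  reference implementations are pinned against each other and against
  finite differences.
* Degenerate inputs: collinear dihedral quadruples raise a
  degenerate-geometry error in the CV layer; the bead force field instead
  uses a cosine-based angle term and a regularised dihedral gradient
  (the torque prefactor sin φ vanishes at the degeneracy), so free dynamics
  cannot blow up there.  Coincident atoms in contact or soft-min CVs raise
  singular-input errors.
* Non-converged WHAM returns its best iterate flagged on the result.
* Problem sizes: the validation studies use 2e6 steps per replica on the
  double well and 1.2e5 steps per replica on the bead peptide (two seeds
  per condition), with 2-D binning (backbone coordination x alpha
  similarity) and min occupancy 3 for the bead ensembles, where the 4-D
  grid of the full-scale protocol would leave too few occupied bins at this
  snapshot count.

## Known limitations

* The bead model has no solvent, electrostatics, or realistic amino-acid
  chemistry; apo/holo differences it produces are qualitative demonstrations
  of the machinery only.
* Fixed-height metadynamics carries an O(h) hysteresis error near walls
  that reweighting inherits (see above); well-tempered damping is out of
  scope.
* The exchange scheme attempts one uniformly random pair per attempt time;
  neighbour-only or all-pairs schedules are not implemented.
* Kinetics (rates, Markov-state models on the bin network) are deliberately
  not reconstructed from the biased trajectories.
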