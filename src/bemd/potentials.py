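"""Analytic toy energy landscapes with quadrature Boltzmann oracles.

These low-dimensional potentials stand in for a molecular Hamiltonian: their
free-energy profiles are known in closed form (1-D) or by deterministic grid
quadrature (2-D), so every sampling and reweighting stage of the pipeline can
be validated against an exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE

__all__ = [
    "AnalyticPotential",
    "DoubleWell1D",
    "TwoBasin2D",
    "QuadratureResult",
    "make_double_well",
    "make_two_basin_2d",
    "boltzmann_reference",
    "boltzmann_density_1d",
]


class AnalyticPotential:
    """Base class for analytic potentials.

    Subclasses provide ``energy`` and ``gradient`` for a single configuration
    (shape ``(dimensionality,)``) plus a vectorised ``energy_array`` over
    points stacked along the first axis.  ``quadrature_domain`` is a closed
    per-dimension interval that contains all but a negligible (<1e-10)
    fraction of the Boltzmann mass at 300 K.
    """

    dimensionality: int
    parameters: dict
    quadrature_domain: list[tuple[float, float]]

    def energy(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def energy_array(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.array([self.energy(p) for p in pts])


@dataclass
class DoubleWell1D(AnalyticPotential):
    """Symmetric quartic double well U(x) = h*((x/a)^2 - 1)^2.

    Minima at x = ±a with U = 0; barrier of height ``h`` at x = 0.
    """

    barrier_height: float
    half_separation: float
    dimensionality: int = field(default=1, init=False)

    def __post_init__(self) -> None:
        if self.barrier_height <= 0 or self.half_separation <= 0:
            raise ValueError(
                "barrier_height and half_separation must be positive, got "
                f"{self.barrier_height}, {self.half_separation}"
            )
        self.parameters = {
            "barrier_height": self.barrier_height,
            "half_separation": self.half_separation,
        }
        # Domain where U <= ~60 kT at 300 K; Boltzmann mass outside is far
        # below 1e-10 of the total.
        u_max = 60.0 * KB * DEFAULT_TEMPERATURE
        a = self.half_separation
        xmax = a * np.sqrt(1.0 + np.sqrt(u_max / self.barrier_height))
        self.quadrature_domain = [(-float(xmax), float(xmax))]

    def energy(self, x: np.ndarray) -> float:
        x0 = float(np.asarray(x).reshape(-1)[0])
        t = (x0 / self.half_separation) ** 2 - 1.0
        return self.barrier_height * t * t

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x0 = float(np.asarray(x).reshape(-1)[0])
        a2 = self.half_separation**2
        t = x0 * x0 / a2 - 1.0
        return np.array([4.0 * self.barrier_height * x0 * t / a2])

    def energy_array(self, pts: np.ndarray) -> np.ndarray:
        x = np.asarray(pts, dtype=float).reshape(-1)
        t = (x / self.half_separation) ** 2 - 1.0
        return self.barrier_height * t * t

    def initial_coordinates(self) -> np.ndarray:
        return np.array([-self.half_separation])


@dataclass
class TwoBasin2D(AnalyticPotential):
    """Two inverted Gaussian basins plus a confining quartic in 2-D.

    U(r) = -d1*exp(-|r-c1|^2/2w^2) - d2*exp(-|r-c2|^2/2w^2) + kq*|r-c0|^4
    with c0 the midpoint of the two centers.
    """

    basin_depths: tuple[float, float]
    basin_centers: tuple[tuple[float, float], tuple[float, float]]
    width: float
    confinement: float = 5.0
    dimensionality: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        c1 = np.asarray(self.basin_centers[0], dtype=float)
        c2 = np.asarray(self.basin_centers[1], dtype=float)
        if np.allclose(c1, c2):
            raise ValueError("basin centers must be distinct")
        if self.width <= 0:
            raise ValueError("width must be positive")
        self._c1, self._c2 = c1, c2
        self._c0 = 0.5 * (c1 + c2)
        self.parameters = {
            "basin_depths": tuple(self.basin_depths),
            "basin_centers": (tuple(c1), tuple(c2)),
            "width": self.width,
            "confinement": self.confinement,
        }
        # Quartic dominates far out: kq*R^4 = 60 kT sets the box half-width.
        u_max = 60.0 * KB * DEFAULT_TEMPERATURE + max(self.basin_depths)
        rmax = (u_max / self.confinement) ** 0.25 + float(
            np.max(np.abs(np.stack([c1, c2]) - self._c0))
        )
        dom = [
            (float(self._c0[d] - rmax), float(self._c0[d] + rmax)) for d in range(2)
        ]
        self.quadrature_domain = dom

    def _basin_terms(self, r: np.ndarray):
        w2 = self.width**2
        d1, d2 = self.basin_depths
        dr1 = r - self._c1
        dr2 = r - self._c2
        g1 = np.exp(-np.sum(dr1 * dr1, axis=-1) / (2 * w2))
        g2 = np.exp(-np.sum(dr2 * dr2, axis=-1) / (2 * w2))
        return d1, d2, dr1, dr2, g1, g2, w2

    def energy(self, x: np.ndarray) -> float:
        r = np.asarray(x, dtype=float).reshape(2)
        d1, d2, dr1, dr2, g1, g2, _ = self._basin_terms(r)
        dr0 = r - self._c0
        return float(-d1 * g1 - d2 * g2 + self.confinement * np.sum(dr0 * dr0) ** 2)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        r = np.asarray(x, dtype=float).reshape(2)
        d1, d2, dr1, dr2, g1, g2, w2 = self._basin_terms(r)
        dr0 = r - self._c0
        grad = (d1 * g1 / w2) * dr1 + (d2 * g2 / w2) * dr2
        grad = grad + 4.0 * self.confinement * np.sum(dr0 * dr0) * dr0
        return grad

    def energy_array(self, pts: np.ndarray) -> np.ndarray:
        r = np.atleast_2d(np.asarray(pts, dtype=float))
        d1, d2, dr1, dr2, g1, g2, _ = self._basin_terms(r)
        dr0 = r - self._c0
        return -d1 * g1 - d2 * g2 + self.confinement * np.sum(dr0 * dr0, axis=-1) ** 2

    def initial_coordinates(self) -> np.ndarray:
        return self._c1.copy()


def make_double_well(barrier_height: float, half_separation: float) -> DoubleWell1D:
    """Quartic double well with the given barrier (kJ/mol) and minima at ±half_separation (nm)."""
    return DoubleWell1D(barrier_height=barrier_height, half_separation=half_separation)


def make_two_basin_2d(
    basin_depths: Sequence[float],
    basin_centers: Sequence[Sequence[float]],
    width: float,
    confinement: float = 5.0,
) -> TwoBasin2D:
    """Two-basin 2-D landscape; depths kJ/mol, centers nm."""
    return TwoBasin2D(
        basin_depths=(float(basin_depths[0]), float(basin_depths[1])),
        basin_centers=(tuple(basin_centers[0]), tuple(basin_centers[1])),
        width=float(width),
        confinement=float(confinement),
    )


@dataclass
class QuadratureResult:
    """Boltzmann expectation with a grid-refinement error estimate."""

    value: float
    error: float
    n_grid: int

    def __float__(self) -> float:  # convenience in arithmetic contexts
        return self.value


def _grid_expectation(
    potential: AnalyticPotential,
    beta: float,
    observable: Callable[[np.ndarray], np.ndarray],
    n: int,
) -> float:
    dom = potential.quadrature_domain
    axes = [np.linspace(lo, hi, n) for lo, hi in dom]
    if potential.dimensionality == 1:
        pts = axes[0][:, None]
    else:
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
    u = potential.energy_array(pts)
    u = u - u.min()  # stabilise exponentials; cancels in the ratio
    w = np.exp(-beta * u)
    obs = np.asarray(observable(pts), dtype=float).reshape(w.shape)
    return float(np.sum(w * obs) / np.sum(w))


def boltzmann_reference(
    potential: AnalyticPotential,
    temperature: float = DEFAULT_TEMPERATURE,
    observable: Callable[[np.ndarray], np.ndarray] | None = None,
    n_grid: int = 2001,
) -> QuadratureResult:
    """Deterministic grid quadrature of a Boltzmann expectation.

    Computes ``<O> = ∫ O e^{-βU} / ∫ e^{-βU}`` over the potential's
    quadrature domain at resolution ``n_grid`` and again at half resolution;
    the difference between the two is reported as the discretisation-error
    estimate.  Only 1-D and 2-D potentials are supported — this is the
    independent oracle for all reweighting tests, and quadrature is not
    feasible in higher dimension.
    """
    if potential.dimensionality > 2:
        raise ValueError(
            "boltzmann_reference requires dimensionality <= 2 "
            f"(got {potential.dimensionality}): quadrature oracle not available"
        )
    if observable is None:
        observable = lambda pts: np.ones(pts.shape[0])
    beta = 1.0 / (KB * temperature)
    n_coarse = max(3, n_grid // 2)
    fine = _grid_expectation(potential, beta, observable, n_grid)
    coarse = _grid_expectation(potential, beta, observable, n_coarse)
    return QuadratureResult(value=fine, error=abs(fine - coarse), n_grid=n_grid)


def boltzmann_density_1d(
    potential: AnalyticPotential,
    grid: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Normalised Boltzmann density of a 1-D potential on the given grid."""
    if potential.dimensionality != 1:
        raise ValueError("boltzmann_density_1d requires a 1-D potential")
    beta = 1.0 / (KB * temperature)
    u = potential.energy_array(np.asarray(grid, dtype=float))
    w = np.exp(-beta * (u - u.min()))
    return w / np.trapezoid(w, grid)
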