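"""Overdamped Langevin sampling of a model system under bias and wall forces.

Position-only (Brownian) dynamics: one step advances coordinates by

    x' = x - (dt/gamma) * grad(U + V_bias + V_wall) + sqrt(2 kB T dt/gamma) * eta

with independent standard-normal noise per coordinate.  The scheme targets
configurational observables only; no velocities are propagated.

Reproducibility: each replica draws its noise from a private Philox stream
keyed on (seed, replica id) and consumed sequentially, while exchange
decisions draw from a separate stream, so the bias-exchange schedule never
perturbs the alignment of the dynamical noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE

__all__ = ["ThermostatState", "TrajectoryFrame", "IntegratorBlowUp", "step", "run_segment",
           "noise_generator"]


class IntegratorBlowUp(RuntimeError):
    """Raised when a non-finite force appears; carries the offending coordinate index."""

    def __init__(self, message: str, coordinate_index: int):
        super().__init__(message)
        self.coordinate_index = coordinate_index


def noise_generator(seed: int, stream: int) -> np.random.Generator:
    """Philox generator for a (seed, stream) pair; streams are independent."""
    return np.random.Generator(np.random.Philox(key=[int(seed), int(stream)]))


@dataclass
class ThermostatState:
    """Integration parameters plus the replica's private RNG stream.

    ``rng_stream`` counts the normal variates consumed so far; two
    ThermostatStates with the same seed/stream/position generate identical
    noise and hence identical trajectories.
    """

    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0     # 1/ps
    timestep: float = 0.005   # ps
    rng_seed: int = 0
    stream_id: int = 0
    rng_stream: int = 0       # number of variates consumed
    _gen: Optional[np.random.Generator] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be positive")

    def normals(self, n: int) -> np.ndarray:
        """Draw n standard normals from the private stream (sequential consumption)."""
        if self._gen is None:
            self._gen = noise_generator(self.rng_seed, self.stream_id)
            if self.rng_stream:
                self._gen.standard_normal(self.rng_stream)
        self.rng_stream += n
        return self._gen.standard_normal(n)

    def check_stability(self, max_curvature: float) -> None:
        """Warn if dt * max|U''| / gamma >= 0.5 (overdamped Euler stability)."""
        if self.timestep * max_curvature / self.friction >= 0.5:
            warnings.warn(
                "timestep*max|U''|/friction = "
                f"{self.timestep * max_curvature / self.friction:.2f} >= 0.5; "
                "the overdamped Euler step may be unstable",
                stacklevel=2,
            )


@dataclass
class TrajectoryFrame:
    """One saved snapshot: time, coordinates and cached energies/CV values."""

    time: float
    coordinates: np.ndarray
    potential_energy: float
    bias_energy: float
    cv_values: dict = field(default_factory=dict)


def _total_force(system, bias, x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Force = -grad(U + V_bias); returns (force, U, V_bias)."""
    g = np.asarray(system.gradient(x), dtype=float)
    u = float(system.energy(x))
    if bias is not None:
        vb, gb = bias.energy_gradient(x)
    else:
        vb, gb = 0.0, 0.0
    force = -(g + gb)
    if not np.all(np.isfinite(force)):
        idx = int(np.argmax(~np.isfinite(np.asarray(force).reshape(-1))))
        raise IntegratorBlowUp(f"non-finite force at coordinate index {idx}", idx)
    return force, u, float(vb)


def step(frame: TrajectoryFrame, system, bias, thermostat: ThermostatState) -> TrajectoryFrame:
    """Advance one overdamped Langevin step from the given frame."""
    x = np.asarray(frame.coordinates, dtype=float)
    force, _, _ = _total_force(system, bias, x)
    dt = thermostat.timestep
    gamma = thermostat.friction
    amp = np.sqrt(2.0 * KB * thermostat.temperature * dt / gamma)
    eta = thermostat.normals(x.size).reshape(x.shape)
    x_new = x + (dt / gamma) * force + amp * eta
    _, u_new, vb_new = _total_force(system, bias, x_new)
    return TrajectoryFrame(
        time=frame.time + dt,
        coordinates=x_new,
        potential_energy=u_new,
        bias_energy=vb_new,
    )


def run_segment(system, bias, thermostat: ThermostatState, n_steps: int,
                save_stride: int = 1, x0: Optional[np.ndarray] = None,
                t0: float = 0.0,
                cv_functions: Optional[dict] = None) -> list[TrajectoryFrame]:
    """Integrate ``n_steps`` steps, saving every ``save_stride`` steps.

    The initial and final frames are always included.  CV values from
    ``cv_functions`` (name -> coords -> scalar) are cached on saved frames.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if x0 is None:
        x0 = np.asarray(system.initial_coordinates(), dtype=float)
    x = np.asarray(x0, dtype=float).copy()
    dt = thermostat.timestep
    gamma = thermostat.friction
    amp = np.sqrt(2.0 * KB * thermostat.temperature * dt / gamma)

    def make_frame(t: float, x: np.ndarray) -> TrajectoryFrame:
        _, u, vb = _total_force(system, bias, x)
        fr = TrajectoryFrame(time=t, coordinates=x.copy(), potential_energy=u, bias_energy=vb)
        if cv_functions:
            fr.cv_values = {name: float(fn(x)) for name, fn in cv_functions.items()}
        return fr

    frames = [make_frame(t0, x)]
    noise = thermostat.normals(n_steps * x.size).reshape((n_steps,) + x.shape)
    for k in range(1, n_steps + 1):
        try:
            force, _, _ = _total_force(system, bias, x)
        except IntegratorBlowUp as exc:
            raise IntegratorBlowUp(f"step {k}: {exc}", exc.coordinate_index) from exc
        x = x + (dt / gamma) * force + amp * noise[k - 1]
        if k % save_stride == 0 or k == n_steps:
            frames.append(make_frame(t0 + k * dt, x))
    return frames
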