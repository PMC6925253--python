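"""Minimal validation systems for the dynamics and work-accounting layer.

The dragged harmonic trap is the standard exactly-solvable testbed for
steered-dynamics bookkeeping: a free particle pulled through a moving
harmonic restraint on a translational coordinate has a center-independent
equilibrium free energy, so the Jarzynski estimate of the free-energy
difference between the endpoints must be zero, and the instantaneous-jump
work is exactly ``1/2 k d^2``.
"""

from __future__ import annotations

import numpy as np

from .colvars import AtomGroup, CVSpec
from .dynamics import SteeringProtocol

__all__ = ["FreeParticleModel", "dragged_trap_protocol"]


class FreeParticleModel:
    """N non-interacting particles (zero internal energy).

    Implements the small surface the integrator needs (`energy`, `forces`,
    `start_coords`, `ion_present`, `content_hash`).
    """

    ion_present = False

    def __init__(self, n_particles: int = 1, start=None):
        self.n_particles = int(n_particles)
        self._start = (
            np.zeros((self.n_particles, 3))
            if start is None
            else np.asarray(start, dtype=float).reshape(self.n_particles, 3)
        )

    def energy(self, coords) -> float:
        return 0.0

    def forces(self, coords) -> np.ndarray:
        return np.zeros_like(np.asarray(coords, dtype=float))

    def start_coords(self, state: str = "of") -> np.ndarray:
        return self._start.copy()

    def content_hash(self) -> str:
        return f"free-{self.n_particles}"


def dragged_trap_protocol(
    k: float,
    distance: float,
    duration: int,
    hold: int = 0,
    axis=(1.0, 0.0, 0.0),
) -> SteeringProtocol:
    """Harmonic trap on the x-projection of particle 0, dragged from 0 to
    ``distance`` over ``duration`` steps."""
    spec = CVSpec(
        kind="com_projection", group=AtomGroup((0,)), axis=tuple(axis), name="x"
    )
    return SteeringProtocol(
        terms=((spec, 0.0, float(distance), float(k)),),
        duration=int(duration),
        hold=int(hold),
        name="dragged_trap",
    )
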