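"""In-memory container for one Lagrangian platelet trajectory."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stress_kernel import ScalarStressSeries, stress_accumulation


@dataclass
class Trajectory:
    """Time-ordered samples of one tracked particle.

    Positions in metres, velocities in m/s, scalar stress in Pa, sampled
    at the export cadence of the simulation that produced them.  ``status``
    records how tracking ended: still ``in_domain``, or exited through the
    aortic outlet / ventricular inlet.
    """

    particle_id: int
    t: np.ndarray          # (n,) s
    pos: np.ndarray        # (n, 3) m
    vel: np.ndarray        # (n, 3) m/s
    sigma: np.ndarray      # (n,) Pa
    seed_xy: tuple[float, float] | None = None  # seeding-plane coordinates, m
    status: str = "in_domain"  # in_domain | exited_aorta | exited_inlet

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float).reshape(len(self.t), 3)
        self.vel = np.asarray(self.vel, dtype=float).reshape(len(self.t), 3)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.t) == 0:
            raise ValueError("trajectory needs at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(
                f"particle {self.particle_id}: time not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def stress_series(self) -> ScalarStressSeries:
        return ScalarStressSeries(self.t, self.sigma)

    def stress_accumulation(self, *, rule: str = "left") -> float:
        """Total SA (Pa·s) over the particle's whole tracked life."""
        return stress_accumulation(self.stress_series(), rule=rule)
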