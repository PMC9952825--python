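"""Scalar platelet stress and stress accumulation along trajectories.

The instantaneous stress state seen by a platelet — six independent
components of a symmetric tensor — is reduced to a von-Mises-type scalar

    sigma = sqrt[(sxx² + syy² + szz² − sxx·syy − syy·szz − szz·sxx
                  + 3(txy² + tyz² + tzx²)) / 3]

which is invariant under hydrostatic offsets and under rotation of the
tensor (it is built from the second deviatoric invariant).  Integrating
sigma along a platelet's path gives its stress accumulation

    SA = ∫ sigma(t) dt ≈ Σ sigma_i · Δt_i   [Pa·s]

using the left-rectangle rule on the export grid, matching the discrete
sum used in Lagrangian blood-damage post-processing.  SA is compared with
the Hellums activation threshold of 3.5 Pa·s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class StressTensorSample:
    """Six independent components of a symmetric stress tensor, Pa."""

    sxx: float = 0.0
    syy: float = 0.0
    szz: float = 0.0
    txy: float = 0.0
    tyz: float = 0.0
    tzx: float = 0.0

    def as_matrix(self) -> np.ndarray:
        return np.array([
            [self.sxx, self.txy, self.tzx],
            [self.txy, self.syy, self.tyz],
            [self.tzx, self.tyz, self.szz],
        ])


@dataclass
class ScalarStressSeries:
    """Time series of scalar stress along one trajectory."""

    t: np.ndarray  # s, strictly increasing
    sigma: np.ndarray  # Pa, ≥ 0

    def __post_init__(self) -> None:
        self.t = np.atleast_1d(np.asarray(self.t, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.t.shape != self.sigma.shape or len(self.t) < 1:
            raise ValueError("t and sigma must be equal-length, non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("scalar stress must be non-negative")


def scalar_stress(s: StressTensorSample | None = None, *,
                  sxx=0.0, syy=0.0, szz=0.0,
                  txy=0.0, tyz=0.0, tzx=0.0) -> float | np.ndarray:
    """Reduce a symmetric stress tensor to the scalar platelet stress, Pa.

    Accepts either a :class:`StressTensorSample` or (vectorized) component
    arrays.  The result is non-negative and unaffected by adding any
    hydrostatic tensor.
    """
    if s is not None:
        sxx, syy, szz = s.sxx, s.syy, s.szz
        txy, tyz, tzx = s.txy, s.tyz, s.tzx
    comps = [np.asarray(c, dtype=float) for c in (sxx, syy, szz, txy, tyz, tzx)]
    if any(not np.all(np.isfinite(c)) for c in comps):
        raise ValueError("non-finite stress components")
    sxx, syy, szz, txy, tyz, tzx = comps
    # algebraically identical to
    #   (sxx²+syy²+szz² − sxx·syy − syy·szz − szz·sxx + 3(txy²+tyz²+tzx²))/3
    # but written in normal-stress differences, so hydrostatic states give
    # exactly zero instead of a cancellation residue
    q = ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2) / 6.0 \
        + txy ** 2 + tyz ** 2 + tzx ** 2
    out = np.sqrt(q)
    return float(out) if out.ndim == 0 else out


def scalar_stress_from_tensors(tensors: np.ndarray) -> np.ndarray:
    """Vectorized scalar stress from an (..., 3, 3) array of symmetric tensors."""
    t = np.asarray(tensors, dtype=float)
    return scalar_stress(
        sxx=t[..., 0, 0], syy=t[..., 1, 1], szz=t[..., 2, 2],
        txy=t[..., 0, 1], tyz=t[..., 1, 2], tzx=t[..., 2, 0])


def stress_accumulation(series: ScalarStressSeries, *,
                        rule: str = "left") -> float:
    """Stress accumulation SA (Pa·s) of a scalar-stress series.

    ``rule='left'`` (default) uses the left-rectangle sum Σ sigma_i·Δt_i on
    the per-interval Δt from the time stamps, matching the discrete SA
    definition; ``rule='trapezoid'`` is available for comparison.  A
    single-sample series has zero exposure and returns 0.
    """
    t, sig = series.t, series.sigma
    if len(t) < 2:
        return 0.0
    dt = np.diff(t)
    if rule == "left":
        return float(np.sum(sig[:-1] * dt))
    if rule == "trapezoid":
        return float(np.trapezoid(sig, t))
    raise ValueError(f"unknown quadrature rule: {rule!r}")


def viscous_stress_from_gradient(grad_u: np.ndarray,
                                 mu: float) -> StressTensorSample:
    """Deviatoric viscous stress tau = mu * (∇u + ∇uᵀ) from a velocity gradient.

    ``grad_u[i, j]`` is du_i/dx_j (1/s).  The pressure part is omitted:
    the scalar-stress reduction annihilates hydrostatic contributions, so
    nothing is lost for SA purposes.
    """
    g = np.asarray(grad_u, dtype=float)
    if g.shape != (3, 3) or not np.all(np.isfinite(g)):
        raise ValueError("grad_u must be a finite 3x3 array")
    tau = mu * (g + g.T)
    return StressTensorSample(
        sxx=tau[0, 0], syy=tau[1, 1], szz=tau[2, 2],
        txy=tau[0, 1], tyz=tau[1, 2], tzx=tau[2, 0])


def viscous_stress_tensors(grad_u: np.ndarray, mu: float) -> np.ndarray:
    """Vectorized tau = mu*(G + Gᵀ) for an (..., 3, 3) gradient array."""
    g = np.asarray(grad_u, dtype=float)
    return mu * (g + np.swapaxes(g, -1, -2))
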