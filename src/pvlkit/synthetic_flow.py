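"""Idealized pulsatile valve + leak-channel flow with Lagrangian advection.

This is the package's synthetic-data generator.  It emulates the flow
environment around a transcatheter aortic valve with mild paravalvular
leak (PVL) as a piecewise-analytic velocity field rather than a numerical
flow solve: the analysis stages downstream (stress accumulation, entry
statistics, thrombogenic footprint) are the object of study, so the
generator's job is to produce controllable, oracle-friendly platelet
trajectories with the right statistical structure, not CFD fidelity.

Model summary
-------------
* A periodic ventricular-minus-aortic pressure gradient drives a lumped
  two-branch circuit: a valve branch whose resistance switches between an
  open systolic value and an effectively infinite diastolic value (the
  lumped re-expression of a time-switched Darcy inverse-permeability
  leaflet model), and a constant-resistance leak branch representing the
  paravalvular channels.  Conductance switches over a short smoothing
  ramp; the overlap of the closing ramp with the falling gradient
  produces the closing-volume transient.
* Geometry: a cylindrical outflow tract (LVOT) below the valve plane, a
  central orifice jet, an annular sinus region alongside 1–4 narrow
  rectangular leak channels at the lumen periphery, and an aortic outflow
  above.  Within each subregion velocities are Poiseuille-type profiles
  scaled to the instantaneous branch flux, with analytic gradients.  The
  sinus region carries a slow phase-dependent secondary drift (systolic
  washout toward the aorta, diastolic entrainment toward the channel
  mouths); its gradients are treated as zero, consistent with its
  quasi-stagnant role.
* Platelet-like particles (3 µm, neutrally buoyant) are seeded on a
  square grid across the LVOT cross-section throughout the systolic
  window and advected with fixed-step RK4 (tracer mode) or an
  exponential-integrator Stokes-drag update (inertial mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hemodynamics import (FlowWaveform, FluidProperties, PressureWaveform,
                           segment_phases)
from .stress_kernel import scalar_stress_from_tensors, viscous_stress_tensors
from .trajectory import Trajectory

ML_S_TO_M3_S = 1e-6


# ---------------------------------------------------------------------------
# pressure-gradient generator

def synthetic_pressure_waveform(*, bpm: float = 70.0,
                                systole_s: float = 0.210,
                                dp_sys_avg_mmhg: float = 30.0,
                                dp_dia_avg_mmhg: float = -85.0,
                                transition_s: float = 0.030,
                                n: int = 4096) -> PressureWaveform:
    """Periodic ventricular–aortic gradient waveform.

    Systole is a half-sine of the requested time-average (physiologic
    range roughly +25 to +48 mmHg); diastole is a plateau with half-cosine
    shoulders whose time-average matches ``dp_dia_avg_mmhg`` (roughly −82
    to −88 mmHg).  The waveform is zero at both cycle ends, so its
    periodic extension is continuous and has exactly two zero crossings
    per cycle.
    """
    period = 60.0 / bpm
    t_dia = period - systole_s
    if t_dia <= 2 * transition_s:
        raise ValueError("diastole too short for the requested transitions")
    t = np.linspace(0.0, period, n, endpoint=False)
    dp = np.zeros_like(t)

    sys_mask = t < systole_s
    dp[sys_mask] = (math.pi * dp_sys_avg_mmhg / 2.0) * np.sin(
        math.pi * t[sys_mask] / systole_s)

    plateau = dp_dia_avg_mmhg * t_dia / (t_dia - transition_s)
    u = t[~sys_mask] - systole_s
    shape = np.ones_like(u)
    lead = u < transition_s
    shape[lead] = 0.5 * (1.0 - np.cos(math.pi * u[lead] / transition_s))
    tail = u > t_dia - transition_s
    shape[tail] = 0.5 * (1.0 - np.cos(math.pi * (t_dia - u[tail]) / transition_s))
    dp[~sys_mask] = plateau * shape
    # close the cycle: dp(period) = dp(0) = 0
    t = np.append(t, period)
    dp = np.append(dp, 0.0)
    return PressureWaveform(t=t, dp=dp, period=period)


# ---------------------------------------------------------------------------
# geometry

@dataclass
class LeakChannel:
    """One narrow paravalvular leak channel at the lumen periphery.

    The channel is a thin curved slab: azimuthal extent ``width`` (arc
    length, m), radial gap ``height`` (m), axial extent ``length`` (m)
    from the valve plane upward along the sinus.  ``offset`` is the radial
    distance of the channel centerline inward from the lumen wall.
    """

    azimuth: float  # rad, channel center
    width: float    # m, arc extent
    height: float   # m, radial gap
    length: float   # m, axial extent
    offset: float | None = None  # m, centerline offset from lumen wall

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def hydraulic_diameter(self) -> float:
        return 2.0 * self.width * self.height / (self.width + self.height)


@dataclass
class SyntheticGeometry:
    """Idealized axial geometry around a deployed transcatheter valve."""

    lvot_radius: float = 0.010        # m
    orifice_radius: float = 0.007     # m, open-valve jet radius
    annulus_z: float = 0.0            # m, valve plane
    sinus_length: float = 0.020       # m, axial extent of sinus/channels
    seeding_plane_z: float = -0.020   # m (2 cm proximal to the valve)
    inlet_z: float = -0.040           # m, ventricular inlet
    outlet_margin: float = 0.030      # m above the sinus top
    leak_channels: list[LeakChannel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.orifice_radius < self.lvot_radius:
            raise ValueError("need 0 < orifice_radius < lvot_radius")
        if not self.inlet_z < self.seeding_plane_z < self.annulus_z:
            raise ValueError("seeding plane must lie in the inlet region")
        for ch in self.leak_channels:
            if ch.area <= 0:
                raise ValueError("channel cross-section area must be > 0")
            if ch.offset is None:
                ch.offset = ch.height / 2.0
            if ch.offset + ch.height / 2.0 > self.lvot_radius:
                raise ValueError("leak channels must lie at the lumen periphery")

    @property
    def outlet_z(self) -> float:
        return self.annulus_z + self.sinus_length + self.outlet_margin

    @property
    def total_channel_area(self) -> float:
        return sum(ch.area for ch in self.leak_channels)


# ---------------------------------------------------------------------------
# valve schedule

@dataclass
class ValveSchedule:
    """Time-switched valve state and its lumped-resistance equivalents.

    ``d_open``/``d_closed`` are the nominal inverse permeabilities of the
    porous-leaflet picture (0 during systole, ≥ 1e10 1/m² during
    diastole); the lumped model works with the equivalent resistances
    ``r_valve_open``/``r_valve_closed`` and the constant leak resistance
    ``r_leak`` in mmHg/(mL/s).  Conductance switches over ``ramp_s``; an
    explicit exponential closing pulse of volume ``closing_extra_ml`` and
    time constant ``closing_tau_s`` supplements the ramp-overlap
    transient so presets can hit a target closing volume.
    """

    r_valve_open: float          # mmHg/(mL/s)
    r_leak: float                # mmHg/(mL/s)
    r_valve_closed: float = 1.0e4
    ramp_s: float = 0.010
    closing_extra_ml: float = 0.0
    closing_tau_s: float = 0.015
    d_open: float = 0.0          # 1/m²
    d_closed: float = 1.0e12     # 1/m²

    def __post_init__(self) -> None:
        if self.r_valve_open <= 0 or self.r_leak <= 0:
            raise ValueError("resistances must be positive and finite")
        if self.d_closed < 1e10:
            raise ValueError("closed-valve inverse permeability must be ≥ 1e10")
        if self.d_open != 0.0:
            raise ValueError("open-valve inverse permeability must be 0")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


# ---------------------------------------------------------------------------
# the flow field

class SyntheticFlowField:
    """Piecewise-analytic velocity field driven by the lumped valve model.

    Precomputes branch fluxes on a fine single-cycle grid and evaluates
    velocities/gradients vectorized over particle positions.  All the
    tunables that shape the secondary sinus flow are exposed:

    ``wash_frac``
        systolic sinus washout speed as a fraction of the mean jet speed;
    ``feed_frac``
        diastolic channel-mouth entrainment speed as a fraction of the
        mean channel speed;
    ``capture_len``
        e-folding distance of the entrainment field (default: one channel
        width), which localizes capture to the channel mouths.
    """

    def __init__(self, dp: PressureWaveform, geometry: SyntheticGeometry,
                 schedule: ValveSchedule,
                 fluid: FluidProperties | None = None, *,
                 wash_frac: float = 0.08, feed_frac: float = 0.10,
                 capture_len: float | None = None, n_grid: int = 8192):
        self.dp = dp
        self.geometry = geometry
        self.schedule = schedule
        self.fluid = fluid or FluidProperties()
        self.wash_frac = wash_frac
        self.feed_frac = feed_frac
        self.capture_len = capture_len
        self.period = dp.period
        self._t0 = float(dp.t[0])

        seg = segment_phases(dp)
        self.segmentation = seg
        tg = np.linspace(self._t0, self._t0 + self.period, n_grid,
                         endpoint=False)
        self._tg = tg
        self._s = self._systole_indicator(tg, seg)
        dpg = dp(tg)
        g_open = 1.0 / schedule.r_valve_open
        g_closed = 1.0 / schedule.r_valve_closed
        g_valve = g_closed + (g_open - g_closed) * self._s
        self._qv = dpg * g_valve                       # mL/s, valve branch
        self._ql = dpg / schedule.r_leak               # mL/s, leak branch
        self._qc = self._closing_pulse(tg, seg)        # mL/s, closure pulse

        ch = geometry.leak_channels
        self._ch_az = np.array([c.azimuth for c in ch])
        self._ch_w = np.array([c.width for c in ch])
        self._ch_h = np.array([c.height for c in ch])
        self._ch_rc = np.array([geometry.lvot_radius - c.offset for c in ch])
        self._ch_A = np.array([c.area for c in ch])
        self._ch_L = np.array([c.length for c in ch])
        self._ch_frac = (self._ch_A / self._ch_A.sum()
                         if len(ch) else np.zeros(0))

    # -- scheduling helpers -------------------------------------------------

    def _systole_indicator(self, t: np.ndarray,
                           seg) -> np.ndarray:
        """Smooth 0/1 systole indicator; the fall ramp follows valve closure."""
        ramp = max(self.schedule.ramp_s, 1e-9)
        tm = self._t0 + np.mod(t - self._t0, self.period)
        s = np.zeros_like(tm)
        for a, b in seg.systole:
            s = s + _smoothstep((tm - a) / ramp) - _smoothstep((tm - b) / ramp)
        return np.clip(s, 0.0, 1.0)

    def _closing_pulse(self, t: np.ndarray, seg) -> np.ndarray:
        v = self.schedule.closing_extra_ml
        tau = self.schedule.closing_tau_s
        if v <= 0.0:
            return np.zeros_like(t)
        tm = self._t0 + np.mod(t - self._t0, self.period)
        out = np.zeros_like(tm)
        for _, b in seg.systole:
            u = tm - b
            mask = (u >= 0) & (u < 8.0 * tau)
            # normalized so the truncated pulse integrates to exactly -v
            norm = 1.0 - math.exp(-8.0)
            out[mask] -= (v / tau / norm) * np.exp(-u[mask] / tau)
        return out

    def _pint(self, t, arr):
        tm = self._t0 + np.mod(np.asarray(t, dtype=float) - self._t0,
                               self.period)
        return np.interp(tm, self._tg, arr, period=self.period)

    # -- branch fluxes (mL/s) ----------------------------------------------

    def systole_weight(self, t):
        return self._pint(t, self._s)

    def q_valve(self, t):
        """Transvalvular branch flow incl. the closing pulse, mL/s."""
        return self._pint(t, self._qv + self._qc)

    def q_leak(self, t):
        """Paravalvular branch flow, mL/s (negative = sinus → LVOT)."""
        return self._pint(t, self._ql)

    def q_total(self, t):
        return self._pint(t, self._qv + self._qc + self._ql)

    def lumped_flow_waveform(self) -> FlowWaveform:
        """The net flow waveform Q(t) = dp/R_valve(t) + dp/R_leak (+closure)."""
        qq = self._qv + self._qc + self._ql
        return FlowWaveform(t=np.append(self._tg, self._t0 + self.period),
                            q=np.append(qq, qq[0]),
                            period=self.period)

    def transvalvular_closed_volume(self) -> float:
        """|volume| through the valve branch while fully closed, mL/beat.

        The porous-leaflet picture requires this to be negligible
        (< 0.1 mL/beat); here it is dp/R_closed integrated over the part
        of the cycle where the switching ramp has fully decayed.
        """
        closed = self._s < 1e-6
        dt = self.period / len(self._tg)
        return float(np.sum(np.abs(self._qv[closed])) * dt)

    def branch_volumes(self) -> dict[str, float]:
        """Per-beat signed volumes (mL) of each branch and their total."""
        dt = self.period / len(self._tg)
        return {
            "valve": float(np.sum(self._qv) * dt),
            "closing_pulse": float(np.sum(self._qc) * dt),
            "leak": float(np.sum(self._ql) * dt),
            "total": float(np.sum(self._qv + self._qc + self._ql) * dt),
        }

    # -- velocity field -----------------------------------------------------

    def velocity(self, x: np.ndarray, t: float
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Velocity (N,3) m/s and gradient (N,3,3) 1/s at positions ``x``.

        ``grad[n, i, j]`` is du_i/dx_j.  Points outside the axial domain
        get zero velocity (they are flagged as exited by the integrator).
        """
        g = self.geometry
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = len(x)
        u = np.zeros((n, 3))
        grad = np.zeros((n, 3, 3))

        px, py, pz = x[:, 0], x[:, 1], x[:, 2]
        r = np.hypot(px, py)
        phi = np.arctan2(py, px)

        qv = float(self.q_valve(t)) * ML_S_TO_M3_S
        ql = float(self.q_leak(t)) * ML_S_TO_M3_S
        qt = qv + ql
        s_w = float(self.systole_weight(t))

        z_lo, z_hi = g.annulus_z, g.annulus_z + g.sinus_length
        in_dom = (pz >= g.inlet_z - 1e-9) & (pz <= g.outlet_z + 1e-9)
        lvot = in_dom & (pz < z_lo)
        aorta = in_dom & (pz > z_hi)
        band = in_dom & ~lvot & ~aorta

        # -- lumen Poiseuille (LVOT below the valve, aorta above the sinus)
        for mask in (lvot, aorta):
            if not mask.any():
                continue
            R = g.lvot_radius
            rr = np.minimum(r[mask], R)
            c = 2.0 * qt / (math.pi * R ** 2)
            u[mask, 2] = c * (1.0 - (rr / R) ** 2)
            dcdr = -2.0 * c / R ** 2  # du_z/dr / r
            grad[mask, 2, 0] = dcdr * px[mask]
            grad[mask, 2, 1] = dcdr * py[mask]

        if band.any():
            in_channel = np.zeros(n, dtype=bool)
            # -- leak channels: plane-Poiseuille across the radial gap
            for k in range(len(self._ch_az)):
                dphi = np.angle(np.exp(1j * (phi - self._ch_az[k])))
                arc = r * dphi
                xi = (r - self._ch_rc[k]) / (self._ch_h[k] / 2.0)
                m = band & (np.abs(arc) <= self._ch_w[k] / 2.0) \
                    & (np.abs(xi) <= 1.0) \
                    & (pz <= z_lo + self._ch_L[k])
                if not m.any():
                    continue
                in_channel |= m
                qk = ql * self._ch_frac[k]
                umean = qk / self._ch_A[k]
                u[m, 2] = 1.5 * umean * (1.0 - xi[m] ** 2)
                duz_dr = -6.0 * qk * xi[m] / (self._ch_A[k] * self._ch_h[k])
                rr = np.maximum(r[m], 1e-12)
                grad[m, 2, 0] = duz_dr * px[m] / rr
                grad[m, 2, 1] = duz_dr * py[m] / rr

            # -- central orifice jet
            jet = band & ~in_channel & (r < g.orifice_radius)
            if jet.any():
                Ro = g.orifice_radius
                c = 2.0 * qv / (math.pi * Ro ** 2)
                u[jet, 2] = c * (1.0 - (r[jet] / Ro) ** 2)
                dcdr = -2.0 * c / Ro ** 2
                grad[jet, 2, 0] = dcdr * px[jet]
                grad[jet, 2, 1] = dcdr * py[jet]

            # -- sinus annulus: slow phase-dependent secondary drift.
            sinus = band & ~in_channel & (r >= g.orifice_radius)
            if sinus.any():
                self._sinus_drift(u, sinus, px, py, pz, r, phi, qv, ql, s_w)

        u[~in_dom] = 0.0
        return u, grad

    def _sinus_drift(self, u, m, px, py, pz, r, phi, qv, ql, s_w) -> None:
        """Secondary flow in the sinus: systolic washout, diastolic capture."""
        g = self.geometry
        # systolic washout toward the aorta, scaled to the mean jet speed
        jet_speed = abs(qv) / (math.pi * g.orifice_radius ** 2)
        u[m, 2] += s_w * self.wash_frac * jet_speed

        if len(self._ch_az) == 0 or ql >= 0.0:
            return
        # diastolic entrainment toward the nearest channel centerline
        idx = np.argmin(np.abs(np.angle(
            np.exp(1j * (phi[m, None] - self._ch_az[None, :])))), axis=1)
        rc = self._ch_rc[idx]
        az = self._ch_az[idx]
        tx, ty = rc * np.cos(az), rc * np.sin(az)
        dx, dy = tx - px[m], ty - py[m]
        d = np.hypot(dx, dy)
        d = np.maximum(d, 1e-9)
        cap = self.capture_len if self.capture_len is not None \
            else float(np.mean(self._ch_w))
        qk = np.abs(ql) * self._ch_frac[idx]
        v_feed = self.feed_frac * qk / self._ch_A[idx]
        speed = (1.0 - s_w) * v_feed * np.exp(-d / cap)
        u[m, 0] += speed * dx / d
        u[m, 1] += speed * dy / d


def lumped_flow_waveform(dp: PressureWaveform, schedule: ValveSchedule,
                         geometry: SyntheticGeometry | None = None,
                         fluid: FluidProperties | None = None) -> FlowWaveform:
    """Net flow waveform of the two-branch lumped valve model."""
    geometry = geometry or SyntheticGeometry(
        leak_channels=[LeakChannel(0.0, 5e-3, 5e-4, 0.020)])
    return SyntheticFlowField(dp, geometry, schedule,
                              fluid).lumped_flow_waveform()


# ---------------------------------------------------------------------------
# schedule calibration

def calibrate_schedule(dp: PressureWaveform, *, eoa_cm2: float,
                       leak_ml: float, closing_ml: float,
                       fluid: FluidProperties | None = None,
                       r_valve_closed: float = 1.0e4,
                       ramp_s: float = 0.010,
                       closing_tau_s: float = 0.015) -> ValveSchedule:
    """Choose lumped resistances so the generated case hits target metrics.

    * ``r_leak`` makes the diastolic leak-branch volume equal ``leak_ml``
      (exact: leak volume is linear in conductance);
    * ``r_valve_open`` solves the quadratic that makes the systolic RMS of
      the summed branch flows match the RMS implied by the target EOA;
    * the explicit closing pulse tops up whatever closing volume the
      ramp-overlap transient already provides, up to ``closing_ml``.
    """
    fluid = fluid or FluidProperties()
    seg = segment_phases(dp)
    tg = np.linspace(dp.t[0], dp.t[0] + dp.period, 16384, endpoint=False)
    dpg = dp(tg)
    dt = dp.period / len(tg)

    dia = np.zeros(len(tg), dtype=bool)
    for a, b in seg.diastole:
        dia |= (tg >= a) & (tg < b)
    v_dia = float(np.sum(dpg[dia]) * dt)  # mmHg·s, negative
    if v_dia >= 0:
        raise ValueError("no diastolic reverse gradient to calibrate against")
    r_leak = abs(v_dia) / leak_ml

    # target systolic RMS flow from the EOA definition
    sys = np.zeros(len(tg), dtype=bool)
    for a, b in seg.systole:
        sys |= (tg >= a) & (tg < b)
    dp_sys = float(np.mean(dpg[sys]))
    q_rms_target = eoa_cm2 * 51.6 * math.sqrt(dp_sys / fluid.rho_g_cm3)

    # systole indicator with the ramp, for the valve branch
    ramp = max(ramp_s, 1e-9)
    s = np.zeros(len(tg))
    for a, b in seg.systole:
        s += _smoothstep((tg - a) / ramp) - _smoothstep((tg - b) / ramp)
    s = np.clip(s, 0.0, 1.0)

    # solve a·g² + b·g + c = q_rms_target² for the open conductance g
    w = sys
    a_c = float(np.mean((dpg[w] * s[w]) ** 2))
    b_c = 2.0 * float(np.mean(dpg[w] ** 2 * s[w])) / r_leak
    c_c = float(np.mean(dpg[w] ** 2)) / r_leak ** 2 - q_rms_target ** 2
    disc = b_c ** 2 - 4 * a_c * c_c
    if disc < 0 or a_c <= 0:
        raise ValueError("EOA target unreachable with this waveform")
    g_open = (-b_c + math.sqrt(disc)) / (2 * a_c)
    if g_open <= 0:
        raise ValueError("EOA target implies non-positive valve conductance")

    # closing volume already delivered by the ramp overlap
    g_closed = 1.0 / r_valve_closed
    g_valve = g_closed + (g_open - g_closed) * s
    qv = dpg * g_valve
    v_ramp = float(np.sum(np.minimum(qv[dia], 0.0)) * dt)  # mL, ≤ 0
    extra = max(0.0, closing_ml - abs(v_ramp))

    return ValveSchedule(r_valve_open=1.0 / g_open, r_leak=r_leak,
                         r_valve_closed=r_valve_closed, ramp_s=ramp_s,
                         closing_extra_ml=extra, closing_tau_s=closing_tau_s)


# ---------------------------------------------------------------------------
# seeding

@dataclass
class ParticleState:
    id: int
    position: np.ndarray           # (3,) m
    velocity: np.ndarray | None    # (3,) m/s, None until released
    t_inject: float                # s
    grid_index: int
    diameter: float = 3e-6         # m
    density: float = 1120.0        # kg/m³ (neutrally buoyant)


@dataclass
class SeedingPlan:
    """Grid seeding of the LVOT cross-section over the systolic window."""

    spacing: float = 200e-6        # m
    window_start: float = 0.0      # s
    window_duration: float = 0.210  # s
    cadence: float = 5e-4          # s between injections
    radius: float | None = None    # m; default: the lumen radius
    jitter: float = 0.0            # m, optional uniform seeding jitter

    @property
    def n_steps(self) -> int:
        return int(round(self.window_duration / self.cadence))


def seeding_grid(radius: float, spacing: float) -> np.ndarray:
    """Center-anchored square grid of (x, y) points with x² + y² ≤ r²."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > 2 * radius:
        raise ValueError("spacing larger than lumen")
    k = int(math.floor(radius / spacing))
    i = np.arange(-k, k + 1)
    X, Y = np.meshgrid(i * spacing, i * spacing)
    keep = X ** 2 + Y ** 2 <= radius ** 2 * (1 + 1e-12)
    return np.column_stack([X[keep], Y[keep]])


def seed_particles(plan: SeedingPlan, geom: SyntheticGeometry, *,
                   seed: int = 0) -> list[ParticleState]:
    """Seed the grid at every injection step across the systolic window.

    Particle ids encode (injection step, grid index) as
    ``step * n_grid + grid_index``.  Initial velocity is assigned at
    release time by the integrator (the local fluid velocity).
    """
    radius = plan.radius if plan.radius is not None else geom.lvot_radius
    grid = seeding_grid(radius, plan.spacing)
    rng = np.random.default_rng(seed)
    particles: list[ParticleState] = []
    n_grid = len(grid)
    for step in range(plan.n_steps):
        t_inj = plan.window_start + step * plan.cadence
        pts = grid
        if plan.jitter > 0:
            pts = grid + rng.uniform(-plan.jitter, plan.jitter, grid.shape)
        for gi, (gx, gy) in enumerate(pts):
            particles.append(ParticleState(
                id=step * n_grid + gi,
                position=np.array([gx, gy, geom.seeding_plane_z]),
                velocity=None, t_inject=t_inj, grid_index=gi))
    return particles


# ---------------------------------------------------------------------------
# advection

_STATUS = {1: "in_domain", 2: "exited_aorta", 3: "exited_inlet"}


def advect(particles: Sequence[ParticleState], field: SyntheticFlowField, *,
           n_cycles: int = 3, dt: float = 5e-4, mode: str = "tracer",
           seed: int = 0, export_every: int = 2,
           t_start: float | None = None) -> list[Trajectory]:
    """Advect seeded particles through the synthetic field for ``n_cycles``.

    Tracer mode integrates dx/dt = u(x, t) with fixed-step RK4; inertial
    mode applies Stokes drag dv/dt = (u − v)/τp with τp = ρp·d²/(18 µ)
    via an exponential update that remains stable for the sub-microsecond
    platelet response times.  Samples (position, velocity, scalar stress)
    are stored every ``export_every`` steps; particles leaving through the
    aortic outlet or the ventricular inlet stop being tracked.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 5e-4 + 1e-12:
        raise ValueError("dt must be ≤ 0.5 ms")
    if n_cycles < 1:
        raise ValueError("n_cycles must be ≥ 1")
    if mode not in ("tracer", "inertial"):
        raise ValueError(f"unknown mode: {mode!r}")

    geom = field.geometry
    mu = field.fluid.mu
    n = len(particles)
    pos = np.stack([p.position for p in particles]).astype(float)
    vel = np.zeros((n, 3))
    t_inj = np.array([p.t_inject for p in particles])
    ids = np.array([p.id for p in particles])
    tau_p = np.array([p.density * p.diameter ** 2 / (18.0 * mu)
                      for p in particles])
    status = np.zeros(n, dtype=np.int8)  # 0 pending, else _STATUS codes
    released = np.zeros(n, dtype=bool)

    if t_start is None:
        t_start = float(np.min(t_inj))
    t_end = t_start + n_cycles * field.period
    n_steps = int(round((t_end - t_start) / dt))

    snaps: list[tuple[np.ndarray, ...]] = []

    def record(t: float) -> None:
        act = status == 1
        if not act.any():
            return
        u, grad = field.velocity(pos[act], t)
        sig = scalar_stress_from_tensors(viscous_stress_tensors(grad, mu))
        v_out = u if mode == "tracer" else vel[act]
        snaps.append((np.full(act.sum(), t), ids[act].copy(),
                      pos[act].copy(), v_out.copy(), sig))

    t = t_start
    for step in range(n_steps + 1):
        # release newly injected particles with the local fluid velocity
        new = (~released) & (t_inj <= t + 1e-12)
        if new.any():
            u0, _ = field.velocity(pos[new], t)
            vel[new] = u0
            status[new] = 1
            released[new] = True

        if step % export_every == 0:
            record(t)
        if step == n_steps:
            break

        act = status == 1
        if act.any():
            xa = pos[act]
            k1, _ = field.velocity(xa, t)
            k2, _ = field.velocity(xa + 0.5 * dt * k1, t + 0.5 * dt)
            k3, _ = field.velocity(xa + 0.5 * dt * k2, t + 0.5 * dt)
            k4, _ = field.velocity(xa + dt * k3, t + dt)
            x_rk4 = xa + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if mode == "tracer":
                pos[act] = x_rk4
                vel[act] = k4
            else:
                # exponential Stokes-drag update on top of the RK4 fluid
                # path: exact for constant slip, reduces to the tracer
                # scheme as τp → 0 (platelet τp ≈ 0.2 µs ≪ dt)
                va = vel[act]
                tp = tau_p[act][:, None]
                decay = np.exp(-dt / tp)
                pos[act] = x_rk4 + (va - k1) * tp * (1.0 - decay)
                vel[act] = k4 + (va - k1) * decay

            # exit handling
            za = pos[act][:, 2]
            out_a = za > geom.outlet_z
            out_i = za < geom.inlet_z
            sub = status[act]
            sub[out_a] = 2
            sub[out_i] = 3
            status[act] = sub
        t = t_start + (step + 1) * dt

    # assemble per-particle trajectories from the export snapshots
    if not snaps:
        return []
    all_t = np.concatenate([s[0] for s in snaps])
    all_id = np.concatenate([s[1] for s in snaps])
    all_pos = np.concatenate([s[2] for s in snaps])
    all_vel = np.concatenate([s[3] for s in snaps])
    all_sig = np.concatenate([s[4] for s in snaps])
    order = np.argsort(all_id, kind="stable")

    by_id = {p.id: p for p in particles}
    final = {int(i): _STATUS.get(int(st), "in_domain")
             for i, st in zip(ids, status)}
    out: list[Trajectory] = []
    uniq, starts = np.unique(all_id[order], return_index=True)
    bounds = np.append(starts, len(order))
    for j, pid in enumerate(uniq):
        sl = order[bounds[j]:bounds[j + 1]]
        p = by_id[int(pid)]
        out.append(Trajectory(
            particle_id=int(pid), t=all_t[sl], pos=all_pos[sl],
            vel=all_vel[sl], sigma=all_sig[sl],
            seed_xy=(float(p.position[0]), float(p.position[1])),
            status=final[int(pid)]))
    return out


# ---------------------------------------------------------------------------
# laminar-regime check

def reynolds_check(source, geometry: SyntheticGeometry | None = None,
                   fluid: FluidProperties | None = None
                   ) -> tuple[float, float]:
    """(mean_Re, max_Re) of the diastolic leak-channel flow.

    ``Re = rho·|u|·D_h/mu`` with the hydraulic diameter of the containing
    channel.  ``source`` may be a :class:`SyntheticFlowField` (Re is then
    evaluated from channel center-plane velocities across diastole) or an
    iterable of trajectories together with an explicit geometry/fluid
    (Re from in-channel diastolic samples).  Used to assert that a
    generated configuration respects the laminar-flow assumption.
    """
    if isinstance(source, SyntheticFlowField):
        field_, geometry, fluid = source, source.geometry, source.fluid
        res: list[float] = []
        for a, b in field_.segmentation.diastole:
            tt = np.linspace(a, b, 256)
            ql = np.abs(np.asarray(field_.q_leak(tt))) * ML_S_TO_M3_S
            for ch in geometry.leak_channels:
                frac = ch.area / geometry.total_channel_area
                upk = 1.5 * ql * frac / ch.area
                res.extend(fluid.rho * upk * ch.hydraulic_diameter / fluid.mu)
        if not res:
            return 0.0, 0.0
        arr = np.asarray(res)
        return float(arr.mean()), float(arr.max())

    if geometry is None:
        raise ValueError("geometry required for trajectory-based Re check")
    fluid = fluid or FluidProperties()
    vals: list[float] = []
    for traj in source:
        r = np.hypot(traj.pos[:, 0], traj.pos[:, 1])
        phi = np.arctan2(traj.pos[:, 1], traj.pos[:, 0])
        speed = np.linalg.norm(traj.vel, axis=1)
        for ch in geometry.leak_channels:
            rc = geometry.lvot_radius - (ch.offset or ch.height / 2)
            dphi = np.angle(np.exp(1j * (phi - ch.azimuth)))
            inside = ((np.abs(r * dphi) <= ch.width / 2)
                      & (np.abs(r - rc) <= ch.height / 2)
                      & (traj.pos[:, 2] >= geometry.annulus_z)
                      & (traj.pos[:, 2] <= geometry.annulus_z + ch.length)
                      & (traj.vel[:, 2] < 0))  # reverse (diastolic) flow
            if inside.any():
                re = fluid.rho * speed[inside] * ch.hydraulic_diameter / fluid.mu
                vals.extend(re)
    if not vals:
        return 0.0, 0.0
    arr = np.asarray(vals)
    return float(arr.mean()), float(arr.max())
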