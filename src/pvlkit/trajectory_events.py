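"""PVL-region residence detection and cohort entry/re-entry statistics.

A platelet "enters" the PVL domain when it resides inside the leak-channel
volumes (plus a collar at each channel mouth that captures entrainment at
the channel exits).  Re-entry requires an intervening exit: a platelet is
only counted as re-entering once it has left the domain and come back —
the phenomenon by which pulsatile leak flows expose the same platelet to
the high-stress channels over successive cardiac cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .hemodynamics import PhaseSegmentation
from .stress_kernel import ScalarStressSeries, stress_accumulation
from .synthetic_flow import SyntheticGeometry
from .trajectory import Trajectory


# ---------------------------------------------------------------------------
# region primitives

@dataclass
class Box:
    """Axis-aligned box, bounds in metres."""

    lo: np.ndarray
    hi: np.ndarray

    def inside(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        return np.all((pos >= self.lo) & (pos <= self.hi), axis=1)


@dataclass
class Cylinder:
    """Finite cylinder along z."""

    center_xy: tuple[float, float]
    radius: float
    z_lo: float
    z_hi: float

    def inside(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        r = np.hypot(pos[:, 0] - self.center_xy[0],
                     pos[:, 1] - self.center_xy[1])
        return (r <= self.radius) & (pos[:, 2] >= self.z_lo) \
            & (pos[:, 2] <= self.z_hi)


@dataclass
class ChannelSector:
    """Curved-slab volume of one leak channel in cylinder coordinates.

    Matches the channel parameterization of the synthetic geometry:
    azimuthal arc ``width`` about ``azimuth``, radial gap ``height``
    centred at radius ``r_center``, axial span [z_lo, z_hi].
    """

    azimuth: float
    width: float
    height: float
    r_center: float
    z_lo: float
    z_hi: float

    def inside(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        r = np.hypot(pos[:, 0], pos[:, 1])
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        arc = r * np.angle(np.exp(1j * (phi - self.azimuth)))
        return (np.abs(arc) <= self.width / 2.0) \
            & (np.abs(r - self.r_center) <= self.height / 2.0) \
            & (pos[:, 2] >= self.z_lo) & (pos[:, 2] <= self.z_hi)


@dataclass
class RegionGeometry:
    """Named region as a union of inside-predicates."""

    name: str
    primitives: list = field(default_factory=list)
    boundary_tolerance: float = 0.0

    def inside(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        out = np.zeros(len(pos), dtype=bool)
        for p in self.primitives:
            out |= p.inside(pos)
        return out


def pvl_region(geom: SyntheticGeometry, *,
               collar_widths: float = 1.0) -> RegionGeometry:
    """The PVL domain: leak-channel volumes plus a mouth collar.

    The collar extends each channel axially by ``collar_widths`` channel
    widths at both mouths, capturing platelets being entrained at the
    channel exits without counting general sinus residence.
    """
    prims = []
    for ch in geom.leak_channels:
        collar = collar_widths * ch.width
        prims.append(ChannelSector(
            azimuth=ch.azimuth, width=ch.width, height=ch.height,
            r_center=geom.lvot_radius - (ch.offset or ch.height / 2.0),
            z_lo=geom.annulus_z - collar,
            z_hi=geom.annulus_z + ch.length + collar))
    return RegionGeometry(name="PVL domain", primitives=prims)


# ---------------------------------------------------------------------------
# entry detection

@dataclass
class EntryRecord:
    particle_id: int
    t_enter: float
    t_exit: float | None          # None = still inside at trajectory end
    phase_at_entry: str           # "systole" | "diastole" | "unknown"
    interval_sa: float            # Pa·s accumulated while inside

    @property
    def closed(self) -> bool:
        return self.t_exit is not None


def detect_entries(traj: Trajectory, region: RegionGeometry, *,
                   debounce: int = 2,
                   segmentation: PhaseSegmentation | None = None,
                   period: float | None = None) -> list[EntryRecord]:
    """Residence intervals of one trajectory in the region.

    An entry opens once ``debounce`` consecutive samples lie inside and
    closes once ``debounce`` consecutive samples lie outside (debounce 0
    or 1 reacts to single samples).  A trajectory that ends inside yields
    an open record.  ``interval_sa`` integrates the scalar stress over
    the samples of the residence interval (left-rectangle rule).  Phase
    at entry is looked up in ``segmentation`` (reduced modulo ``period``)
    when provided.
    """
    need = max(1, int(debounce))
    inside = region.inside(traj.pos)
    n = len(inside)
    records: list[EntryRecord] = []

    state = False     # currently inside an open entry?
    run = 0
    start_idx = 0
    i_enter = 0

    for i in range(n):
        if not state:
            run = run + 1 if inside[i] else 0
            if run >= need:
                state = True
                i_enter = i - need + 1
                run = 0
        else:
            run = run + 1 if not inside[i] else 0
            if run >= need:
                i_exit = i - need + 1  # first sample of the outside run
                records.append(_make_record(
                    traj, i_enter, i_exit, segmentation, period))
                state = False
                run = 0
    if state:
        records.append(_make_record(traj, i_enter, None, segmentation, period))
    return records


def _make_record(traj: Trajectory, i_enter: int, i_exit: int | None,
                 segmentation, period) -> EntryRecord:
    t_enter = float(traj.t[i_enter])
    t_exit = None if i_exit is None else float(traj.t[i_exit])
    end = len(traj.t) if i_exit is None else i_exit
    sl = slice(i_enter, end)
    if end - i_enter >= 2:
        sa = stress_accumulation(
            ScalarStressSeries(traj.t[sl], traj.sigma[sl]))
    else:
        sa = 0.0
    phase = "unknown"
    if segmentation is not None:
        t_mod = t_enter if period is None else t_enter % period
        phase = segmentation.phase_at(t_mod)
    return EntryRecord(particle_id=traj.particle_id, t_enter=t_enter,
                       t_exit=t_exit, phase_at_entry=phase, interval_sa=sa)


# ---------------------------------------------------------------------------
# cohort statistics

@dataclass
class EntryStats:
    n_particles: int
    n_entering: int
    n_reentering: int
    pct_entering: float
    pct_reentering: float
    max_entries_per_particle: int
    entries_by_phase: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_particles": self.n_particles,
            "n_entering": self.n_entering,
            "n_reentering": self.n_reentering,
            "pct_entering": self.pct_entering,
            "pct_reentering": self.pct_reentering,
            "max_entries_per_particle": self.max_entries_per_particle,
            "entries_by_phase": dict(self.entries_by_phase),
        }


def cohort_entry_stats(records_per_particle: dict[int, list[EntryRecord]],
                       n_particles: int) -> EntryStats:
    """Entry/re-entry percentages over all seeded particles.

    Re-entry requires ≥ 2 entry records for a particle, which by
    construction of :func:`detect_entries` implies an intervening exit.
    A particle whose single entry never closes counts as entering only.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be ≥ 1")
    n_entering = sum(1 for recs in records_per_particle.values() if recs)
    n_re = sum(1 for recs in records_per_particle.values() if len(recs) >= 2)
    max_entries = max((len(r) for r in records_per_particle.values()),
                      default=0)
    by_phase: dict[str, int] = {}
    for recs in records_per_particle.values():
        for r in recs:
            by_phase[r.phase_at_entry] = by_phase.get(r.phase_at_entry, 0) + 1
    return EntryStats(
        n_particles=n_particles, n_entering=n_entering, n_reentering=n_re,
        pct_entering=100.0 * n_entering / n_particles,
        pct_reentering=100.0 * n_re / n_particles,
        max_entries_per_particle=max_entries, entries_by_phase=by_phase)


def split_sa_by_entry(trajectories: Sequence[Trajectory],
                      records_per_particle: dict[int, list[EntryRecord]]
                      ) -> tuple[list[float], list[float]]:
    """Partition total per-particle SA into (entered-PVL, never-entered)."""
    sa_pvl: list[float] = []
    sa_non: list[float] = []
    for traj in trajectories:
        sa = traj.stress_accumulation()
        if records_per_particle.get(traj.particle_id):
            sa_pvl.append(sa)
        else:
            sa_non.append(sa)
    return sa_pvl, sa_non


def seeding_origin_map(trajectories: Sequence[Trajectory],
                       records_per_particle: dict[int, list[EntryRecord]],
                       *, radius: float, n_bins: int = 20
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entry fraction by seeding-plane cell: (x_edges, y_edges, fraction).

    For each cell of an ``n_bins`` × ``n_bins`` grid over the seeding
    disc, the fraction of particles seeded in that cell (over all
    injection steps) that ever entered the PVL region.  Cells with no
    seeded particles are NaN.
    """
    edges = np.linspace(-radius, radius, n_bins + 1)
    seeded = np.zeros((n_bins, n_bins))
    entered = np.zeros((n_bins, n_bins))
    for traj in trajectories:
        if traj.seed_xy is None:
            continue
        ix = min(np.searchsorted(edges, traj.seed_xy[0], side="right") - 1,
                 n_bins - 1)
        iy = min(np.searchsorted(edges, traj.seed_xy[1], side="right") - 1,
                 n_bins - 1)
        if ix < 0 or iy < 0:
            continue
        seeded[ix, iy] += 1
        if records_per_particle.get(traj.particle_id):
            entered[ix, iy] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(seeded > 0, entered / np.maximum(seeded, 1), np.nan)
    return edges, edges, frac


def radial_entry_profile(trajectories: Sequence[Trajectory],
                         records_per_particle: dict[int, list[EntryRecord]],
                         *, radius: float, n_bins: int = 5
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Entry fraction by radial seeding bin: (bin_edges, fraction).

    Companion to the origin map for the qualitative claim that platelets
    seeded near the lumen periphery are entrained into the leak channels
    at a higher rate than centrally seeded platelets.
    """
    edges = np.linspace(0.0, radius, n_bins + 1)
    seeded = np.zeros(n_bins)
    entered = np.zeros(n_bins)
    for traj in trajectories:
        if traj.seed_xy is None:
            continue
        r = float(np.hypot(*traj.seed_xy))
        b = min(np.searchsorted(edges, r, side="right") - 1, n_bins - 1)
        if b < 0:
            continue
        seeded[b] += 1
        if records_per_particle.get(traj.particle_id):
            entered[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(seeded > 0, entered / np.maximum(seeded, 1), np.nan)
    return edges, frac


def detect_cohort_entries(trajectories: Sequence[Trajectory],
                          region: RegionGeometry, *, debounce: int = 2,
                          segmentation: PhaseSegmentation | None = None,
                          period: float | None = None
                          ) -> dict[int, list[EntryRecord]]:
    """Per-particle entry records for a whole cohort."""
    return {traj.particle_id: detect_entries(
        traj, region, debounce=debounce,
        segmentation=segmentation, period=period)
        for traj in trajectories}
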