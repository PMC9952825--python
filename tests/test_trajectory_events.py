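"""Entry detection, re-entry statistics, SA partition and origin maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvlkit.trajectory import Trajectory
from pvlkit.trajectory_events import (Box, ChannelSector, EntryRecord,
                                      RegionGeometry, cohort_entry_stats,
                                      detect_cohort_entries, detect_entries,
                                      pvl_region, radial_entry_profile,
                                      seeding_origin_map, split_sa_by_entry)

UNIT_BOX = RegionGeometry("box", [Box(np.array([0.0, 0.0, 0.0]),
                                      np.array([1.0, 1.0, 1.0]))])


def _traj_from_x(x, pid=0, dt=1e-3, sigma=None, seed_xy=None):
    """Trajectory moving along x with y = z = 0.5 (inside box iff 0≤x≤1)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    t = np.arange(n) * dt
    pos = np.column_stack([x, np.full(n, 0.5), np.full(n, 0.5)])
    sig = np.ones(n) if sigma is None else np.asarray(sigma, dtype=float)
    return Trajectory(particle_id=pid, t=t, pos=pos,
                      vel=np.zeros((n, 3)), sigma=sig, seed_xy=seed_xy)


def brute_force_entries(inside: np.ndarray, debounce: int) -> list[tuple]:
    """Independent interval scan: (i_enter, i_exit_or_None) per entry.

    Builds run-length segments of the inside flag and walks them,
    opening on an inside-run of length ≥ debounce and closing on an
    outside-run of length ≥ debounce.
    """
    need = max(1, debounce)
    runs = []  # (value, start, length)
    start = 0
    for i in range(1, len(inside) + 1):
        if i == len(inside) or inside[i] != inside[start]:
            runs.append((bool(inside[start]), start, i - start))
            start = i
    out = []
    open_at = None
    for val, s, ln in runs:
        if open_at is None and val and ln >= need:
            open_at = s
        elif open_at is not None and not val and ln >= need:
            out.append((open_at, s))
            open_at = None
    if open_at is not None:
        out.append((open_at, None))
    return out


class TestDetectEntries:
    def test_never_inside_gives_no_records(self):
        traj = _traj_from_x(np.linspace(-2, -1, 50))
        assert detect_entries(traj, UNIT_BOX) == []

    def test_two_residences_with_gap(self):
        # inside during samples [300,500] and [1200,1400] (1 ms sampling)
        x = np.full(1600, -1.0)
        x[300:501] = 0.5
        x[1200:1401] = 0.5
        recs = detect_entries(_traj_from_x(x), UNIT_BOX, debounce=2)
        assert len(recs) == 2
        assert recs[0].t_enter == pytest.approx(0.300, abs=2e-3)
        assert recs[0].t_exit == pytest.approx(0.501, abs=2e-3)
        assert recs[1].t_enter == pytest.approx(1.200, abs=2e-3)
        assert recs[1].closed

    def test_boundary_grazing_sample_debounced(self):
        x = np.full(20, -1.0)
        x[10] = 0.5  # single inside sample
        assert detect_entries(_traj_from_x(x), UNIT_BOX, debounce=2) == []

    def test_trajectory_ending_inside_yields_open_record(self):
        x = np.concatenate([np.full(10, -1.0), np.full(10, 0.5)])
        recs = detect_entries(_traj_from_x(x), UNIT_BOX, debounce=2)
        assert len(recs) == 1
        assert recs[0].t_exit is None

    def test_interval_sa_sums_below_total(self):
        rng = np.random.default_rng(4)
        x = rng.choice([-1.0, 0.5], size=500, p=[0.5, 0.5])
        sig = rng.uniform(0, 5, size=500)
        traj = _traj_from_x(x, sigma=sig)
        recs = detect_entries(traj, UNIT_BOX, debounce=2)
        assert sum(r.interval_sa for r in recs) <= \
            traj.stress_accumulation() + 1e-12

    def test_six_entries_representable(self):
        blocks = []
        for _ in range(6):
            blocks += [np.full(5, -1.0), np.full(5, 0.5)]
        blocks.append(np.full(5, -1.0))
        recs = detect_entries(_traj_from_x(np.concatenate(blocks)),
                              UNIT_BOX, debounce=2)
        assert len(recs) == 6

    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_brute_force_scan(self, seed, debounce):
        rng = np.random.default_rng(seed)
        inside = rng.random(rng.integers(2, 120)) < 0.45
        x = np.where(inside, 0.5, -1.0)
        recs = detect_entries(_traj_from_x(x), UNIT_BOX, debounce=debounce)
        expected = brute_force_entries(inside, debounce)
        assert len(recs) == len(expected)
        for rec, (i_en, i_ex) in zip(recs, expected):
            assert rec.t_enter == pytest.approx(i_en * 1e-3)
            if i_ex is None:
                assert rec.t_exit is None
            else:
                assert rec.t_exit == pytest.approx(i_ex * 1e-3)

    def test_entries_bounded_by_sample_budget(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(10, 300))
            deb = int(rng.integers(1, 4))
            x = np.where(rng.random(n) < 0.5, 0.5, -1.0)
            recs = detect_entries(_traj_from_x(x), UNIT_BOX, debounce=deb)
            assert len(recs) <= n // (2 * deb) + 1


class TestCohortStats:
    def test_percentages_of_constructed_cohort(self):
        records = {}
        for pid in range(1000):
            if pid < 15:
                records[pid] = [_rec(pid), _rec(pid)]
            elif pid < 65:
                records[pid] = [_rec(pid)]
            else:
                records[pid] = []
        stats = cohort_entry_stats(records, 1000)
        assert stats.pct_entering == pytest.approx(6.5)
        assert stats.pct_reentering == pytest.approx(1.5)
        assert stats.max_entries_per_particle == 2

    def test_no_entries(self):
        stats = cohort_entry_stats({0: [], 1: []}, 2)
        assert stats.pct_entering == 0.0
        assert stats.pct_reentering == 0.0

    def test_open_single_entry_counts_entering_only(self):
        rec = EntryRecord(0, 0.1, None, "systole", 1.0)
        stats = cohort_entry_stats({0: [rec]}, 1)
        assert stats.n_entering == 1
        assert stats.n_reentering == 0

    def test_reentering_never_exceeds_entering(self, reduced_entries):
        _, stats = reduced_entries
        assert 0 <= stats.pct_reentering <= stats.pct_entering <= 100


def _rec(pid, t0=0.1, t1=0.2):
    return EntryRecord(pid, t0, t1, "diastole", 0.5)


class TestSaSplit:
    def test_exact_partition(self):
        trajs = [_traj_from_x(np.full(10, 0.5), pid=0),
                 _traj_from_x(np.full(10, -1.0), pid=1),
                 _traj_from_x(np.full(10, -1.0), pid=2)]
        records = {0: [_rec(0)], 1: [], 2: []}
        sa_pvl, sa_non = split_sa_by_entry(trajs, records)
        assert len(sa_pvl) == 1 and len(sa_non) == 2

    def test_all_entered(self):
        trajs = [_traj_from_x(np.full(10, 0.5), pid=i) for i in range(3)]
        records = {i: [_rec(i)] for i in range(3)}
        sa_pvl, sa_non = split_sa_by_entry(trajs, records)
        assert sa_non == []

    def test_empty_cohort(self):
        assert split_sa_by_entry([], {}) == ([], [])


class TestSeedingMaps:
    def test_no_entries_gives_zero_grid(self):
        trajs = [_traj_from_x(np.full(5, -1.0), pid=i,
                              seed_xy=(0.001 * i, 0.0)) for i in range(4)]
        _, _, frac = seeding_origin_map(trajs, {i: [] for i in range(4)},
                                        radius=0.01, n_bins=4)
        assert np.nansum(frac) == 0.0

    def test_single_cell_seeding(self):
        trajs = [_traj_from_x(np.full(5, 0.5), pid=i, seed_xy=(0.0, 0.0))
                 for i in range(4)]
        records = {0: [_rec(0)], 1: [_rec(1)], 2: [], 3: []}
        _, _, frac = seeding_origin_map(trajs, records, radius=0.01,
                                        n_bins=4)
        vals = frac[~np.isnan(frac)]
        assert len(vals) == 1
        assert vals[0] == pytest.approx(0.5)

    def test_periphery_exceeds_center_on_synthetic_run(
            self, reduced_case, reduced_cohort, reduced_entries):
        _, cohort = reduced_cohort
        records, _ = reduced_entries
        radius = reduced_case.config.geometry.lvot_radius
        _, frac = radial_entry_profile(cohort, records, radius=radius,
                                       n_bins=5)
        frac = np.nan_to_num(frac)
        # monotone non-decreasing entry fraction from center to periphery
        assert np.all(np.diff(frac) >= -1e-12)
        assert frac[-1] > frac[0]


class TestPvlRegion:
    def test_channel_sector_contains_centerline(self, reduced_case):
        geom = reduced_case.config.geometry
        region = pvl_region(geom)
        ch = geom.leak_channels[0]
        rc = geom.lvot_radius - ch.offset
        inside = region.inside(np.array(
            [[rc * np.cos(ch.azimuth), rc * np.sin(ch.azimuth), 0.01]]))
        assert inside[0]

    def test_collar_extends_past_mouths(self, reduced_case):
        geom = reduced_case.config.geometry
        region = pvl_region(geom, collar_widths=1.0)
        ch = geom.leak_channels[0]
        rc = geom.lvot_radius - ch.offset
        below = np.array([[rc * np.cos(ch.azimuth),
                           rc * np.sin(ch.azimuth),
                           geom.annulus_z - 0.5 * ch.width]])
        assert region.inside(below)[0]
        far_below = below.copy()
        far_below[0, 2] = geom.annulus_z - 2.0 * ch.width
        assert not region.inside(far_below)[0]

    def test_jet_core_not_in_region(self, reduced_case):
        region = pvl_region(reduced_case.config.geometry)
        assert not region.inside(np.array([[0.0, 0.0, 0.01]]))[0]
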