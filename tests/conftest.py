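"""Shared fixtures: waveforms and one reduced-scale synthetic cohort run.

The cohort run (anatomy A at coarse seeding, three cycles) is expensive,
so it is built once per session and shared by the event-statistics,
footprint and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pvlkit import cli_io
from pvlkit.hemodynamics import (FlowWaveform, PressureWaveform,
                                 segment_phases)
from pvlkit.synthetic_flow import advect, seed_particles
from pvlkit import trajectory_events as ev


@pytest.fixture(scope="session")
def square_dp() -> PressureWaveform:
    """Square gradient: +40 mmHg for 0.21 s, −85 mmHg for the rest."""
    t = np.linspace(0, 60 / 70, 6001)
    dp = np.where(t % (60 / 70) < 0.21, 40.0, -85.0)
    dp[-1] = 40.0  # periodic wrap sample
    return PressureWaveform(t=t, dp=dp, period=60 / 70)


@pytest.fixture(scope="session")
def reduced_case():
    """Anatomy-A case at desk scale (coarse grid, slow cadence)."""
    cfg = cli_io.load_preset("anatomy_a", reduced=True)
    return cli_io.build_case(cfg)


@pytest.fixture(scope="session")
def reduced_cohort(reduced_case):
    """(particles, trajectories) of a 3-cycle reduced anatomy-A run."""
    cfg = reduced_case.config
    particles = seed_particles(cfg.seeding, cfg.geometry, seed=1)
    cohort = advect(particles, reduced_case.field, n_cycles=3, dt=5e-4,
                    export_every=cfg.integrator.get("export_every", 4))
    return particles, cohort


@pytest.fixture(scope="session")
def reduced_entries(reduced_case, reduced_cohort):
    """(records_per_particle, stats) for the reduced cohort."""
    particles, cohort = reduced_cohort
    region = ev.pvl_region(reduced_case.config.geometry)
    seg = segment_phases(reduced_case.dp)
    records = ev.detect_cohort_entries(cohort, region, debounce=2,
                                       segmentation=seg,
                                       period=reduced_case.dp.period)
    stats = ev.cohort_entry_stats(records, len(particles))
    return records, stats
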