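#!/usr/bin/env python
"""PVL entry/re-entry statistics for each simulated cohort.

Reads the trajectory files of 01_simulate_cohorts.py, detects leak-
channel residence intervals per platelet, and tabulates the percentage
of platelets entering and re-entering the PVL domain per case, plus the
radial profile of entry fraction over the seeding plane.  Writes
results/entry_stats.csv and results/radial_entry_profile.csv, and a
per-platelet SA table per case for the footprint stage.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pvlkit import cli_io
from pvlkit.hemodynamics import segment_phases
from pvlkit import trajectory_events as ev

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "trajectories"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    stat_rows, radial_rows = [], []
    for name in cli_io.available_presets():
        traj_file = SCRATCH / f"{name}.csv"
        if not traj_file.exists():
            raise SystemExit(f"{traj_file} missing - run "
                             "analysis/01_simulate_cohorts.py first")
        cfg = cli_io.load_preset(name, reduced=True)
        case = cli_io.build_case(cfg)
        cohort = cli_io.read_trajectories(traj_file)
        region = ev.pvl_region(cfg.geometry)
        seg = segment_phases(case.dp)
        records = ev.detect_cohort_entries(cohort, region, debounce=2,
                                           segmentation=seg,
                                           period=case.dp.period)
        stats = ev.cohort_entry_stats(records, len(cohort))
        stat_rows.append({"case": cfg.case_id, **{
            k: v for k, v in stats.as_dict().items()
            if k != "entries_by_phase"},
            "entries_systole": stats.entries_by_phase.get("systole", 0),
            "entries_diastole": stats.entries_by_phase.get("diastole", 0)})

        edges, frac = ev.radial_entry_profile(
            cohort, records, radius=cfg.geometry.lvot_radius, n_bins=5)
        for lo, hi, f in zip(edges[:-1], edges[1:], frac):
            radial_rows.append({"case": cfg.case_id, "r_lo_m": lo,
                                "r_hi_m": hi, "entry_fraction": f})

        cli_io.write_sa_table(
            RESULTS / f"sa_table_{cfg.case_id.lower()}.csv",
            [t.particle_id for t in cohort],
            [t.stress_accumulation() for t in cohort],
            [bool(records.get(t.particle_id)) for t in cohort])
        print(f"{cfg.case_id}: {stats.pct_entering:.1f}% entered the PVL "
              f"domain, {stats.pct_reentering:.1f}% re-entered "
              f"(max {stats.max_entries_per_particle} entries/platelet)")

    pd.DataFrame(stat_rows).to_csv(RESULTS / "entry_stats.csv", index=False)
    pd.DataFrame(radial_rows).to_csv(RESULTS / "radial_entry_profile.csv",
                                     index=False)
    prof = pd.DataFrame(radial_rows)
    inner = prof[prof.r_lo_m == 0].entry_fraction.mean()
    outer = prof.groupby("case").entry_fraction.last().mean()
    print(f"\nMean entry fraction rises from {inner:.2f} in the central "
          f"bin to {outer:.2f} at the lumen periphery: entrainment is a "
          "near-wall phenomenon.")


if __name__ == "__main__":
    main()
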