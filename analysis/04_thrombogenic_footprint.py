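#!/usr/bin/env python
"""Bootstrapped thrombogenic-footprint PDFs per case.

Collapses each case's per-platelet stress accumulations into PVL vs
non-PVL probability densities with the size-matching bootstrap, and
summarizes mean/median SA and the fraction of platelets at or above the
3.5 Pa·s activation threshold.  Writes results/footprint_summary.csv and
a plot-ready density table per case.
"""

from pathlib import Path

import pandas as pd

from pvlkit import cli_io
from pvlkit.footprint import bootstrap_compare

SEED = 17
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    rows = []
    for name in cli_io.available_presets():
        case_id = name.split("_")[1].upper()
        sa_file = RESULTS / f"sa_table_{case_id.lower()}.csv"
        if not sa_file.exists():
            raise SystemExit(f"{sa_file} missing - run "
                             "analysis/03_entrainment_events.py first")
        _, sa, flags = cli_io.read_sa_table(sa_file)
        res = bootstrap_compare(sa[flags], sa[~flags], n_boot=500,
                                seed=SEED)
        dens_rows = []
        for label, g in res.groups.items():
            rows.append({"case": case_id, "group": label, "n": g.n,
                         "mean_sa_pa_s": g.mean_sa,
                         "median_sa_pa_s": g.median_sa,
                         "frac_above_3.5_pa_s": g.frac_above_threshold})
            for lo, hi, d in zip(res.bin_edges[:-1], res.bin_edges[1:],
                                 g.density):
                dens_rows.append({"group": label, "sa_lo": lo, "sa_hi": hi,
                                  "density": d})
        pd.DataFrame(dens_rows).to_csv(
            RESULTS / f"footprint_density_{case_id.lower()}.csv",
            index=False)
        pvl, non = res.groups["pvl"], res.groups["non_pvl"]
        print(f"{case_id}: PVL platelets mean SA {pvl.mean_sa:.2f} Pa·s "
              f"({pvl.frac_above_threshold:.0%} above threshold) vs "
              f"{non.mean_sa:.2f} Pa·s ({non.frac_above_threshold:.0%}) "
              "outside - the footprint is right-shifted for PVL flow.")
    pd.DataFrame(rows).to_csv(RESULTS / "footprint_summary.csv",
                              index=False)


if __name__ == "__main__":
    main()
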