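#!/usr/bin/env python
"""Cross-case correlations of valve performance vs platelet entrainment.

Recomputes, from the packaged per-case metrics table, the linear
relationships between bulk hydrodynamic performance (the EOA/EROA ratio
and the regurgitant fraction) and the percentage of platelets entering /
re-entering the leak channels, plus the secondary EROA and leak-flow
fits.  Writes results/correlations.csv.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from pvlkit.cohort_analysis import (headline_correlations,
                                    secondary_correlations)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, res in {**headline_correlations(),
                      **secondary_correlations()}.items():
        rows.append({"fit": name, **asdict(res)})
        print(f"{name}: r = {res.r:+.2f}, r² = {res.r2:.2f} (n={res.n})")
    pd.DataFrame(rows).to_csv(RESULTS / "correlations.csv", index=False)
    print("\nThe EOA/EROA performance ratio tracks platelet entrainment "
          "(r² ≈ 0.75 entering, 0.83 re-entering) far better than the "
          "regurgitant fraction (r² ≈ 0.31 / 0.56): how strongly a valve "
          "fills the sinuses relative to its leak matters more than the "
          "leak volume itself.")


if __name__ == "__main__":
    main()
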