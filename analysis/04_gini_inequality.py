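#!/usr/bin/env python
"""Concentration-inequality profiles: per-analyte Gini with bootstrap CIs,
overlaid across the healthy-donor and disease groups."""

from pathlib import Path

from aabnet import read_cohort_table
from aabnet.gini import gini_profile, profile_plot

SEED = 20240915
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort_table(OUT / "cohort.csv")
    frame = gini_profile(table, table.groups, B=1000, level=0.95, seed=SEED)
    frame.to_csv(OUT / "gini.csv", index=False)
    profile_plot(frame, str(OUT / "gini_profile.png"))
    flagged = frame[frame["ci_nonoverlap"]]["analyte"].unique()
    print(f"{len(frame)} (analyte, group) Gini estimates; "
          f"{len(flagged)} analytes with non-overlapping CIs: {list(flagged)}")
    wide = frame.pivot_table(index="analyte", columns="group", values="g")
    print((wide.round(3)).to_string())


if __name__ == "__main__":
    main()
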