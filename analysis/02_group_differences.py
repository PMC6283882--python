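#!/usr/bin/env python
"""Per-analyte concentration differences between healthy donors and each
disease group (Mann-Whitney with BH adjustment, median/IQR summaries)."""

from pathlib import Path

import pandas as pd

from aabnet import read_cohort_table
from aabnet.groups import compare_panel, panel_summary, results_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort_table(OUT / "cohort.csv")
    frames = []
    for disease in ("SSc", "OC", "AD"):
        res = compare_panel(table, "HD", disease)
        frame = results_frame(res)
        frame.insert(0, "comparison", f"HD_vs_{disease}")
        frames.append(frame)
        print(f"HD vs {disease}: {panel_summary(res)}")
    pd.concat(frames).to_csv(OUT / "group_tests.csv", index=False)
    print(f"wrote {OUT / 'group_tests.csv'}")


if __name__ == "__main__":
    main()
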