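#!/usr/bin/env python
"""Fisher LDA of the global antibody signature: how well does the panel
separate healthy donors from each disease group?  Reports cross-validated
nearest-centroid accuracy per pairwise contrast."""

from pathlib import Path

import pandas as pd

from aabnet import fit_lda, read_cohort_table
from aabnet.lda import discrimination_score, scores_frame

SEED = 20240915
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort_table(OUT / "cohort.csv")
    model = fit_lda(table)
    scores_frame(model, table).to_csv(OUT / "lda_scores.csv")
    rows = []
    for disease in ("SSc", "OC", "AD"):
        pair = table.select_groups(["HD", disease])
        acc = discrimination_score(pair, folds=5, seed=SEED)
        rows.append({"comparison": f"HD_vs_{disease}", "cv_accuracy": acc})
        print(f"HD vs {disease}: cross-validated accuracy {acc:.3f}")
    pd.DataFrame(rows).to_csv(OUT / "lda_accuracy.csv", index=False)
    print("eigenvalues (between/within ratios):",
          [round(e, 3) for e in model.eigenvalues])


if __name__ == "__main__":
    main()
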