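#!/usr/bin/env python
"""Parameter recovery: can cross-tabulation re-estimate known dynamics?

Generates a 300x300 banded landscape, advances it one year cell-wise under
the published annual transition matrix (no spatial contagion, so the truth
is the exact cell-independent chain), re-estimates the matrix from the map
pair, and reports each entry's deviation in binomial standard errors.
Writes results/matrix_recovery.csv.

Finding: all nine entries are recovered well within 3 SE at this grid size
(>= 10^4 source cells per class).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from marshca import estimate_transitions
from marshca import reference as R
from marshca.synthetic import SyntheticConfig, evolve, make_banded_grid

OUT = Path(__file__).resolve().parent.parent / "results"
DYN = [R.SUAEDA, R.PHRAGMITES, R.MUDFLAT]
SEED = 2024


def main():
    cfg = SyntheticConfig(rows=300, cols=300, contagion_weight=0.0, seed=SEED)
    g0 = make_banded_grid(cfg, date=1985)
    g1 = evolve(g0, cfg, 1)[0]
    est = estimate_transitions(g0, g1, dynamic_codes=DYN)
    truth = R.TRANSITION_1985_1990_ANNUAL

    rows = []
    for i, ci in enumerate(DYN):
        n = int((g0.values == ci).sum())
        for j, cj in enumerate(DYN):
            p = truth.probs[truth.class_codes.index(ci),
                            truth.class_codes.index(cj)]
            se = max(np.sqrt(p * (1 - p) / n), 1e-12)
            rows.append({
                "from": R.YANCHENG_SCHEME.name_of(ci),
                "to": R.YANCHENG_SCHEME.name_of(cj),
                "true_p": p, "estimated_p": round(float(est.probs[i, j]), 4),
                "n_source_cells": n, "z_score": round(float(abs(est.probs[i, j] - p) / se), 2),
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "matrix_recovery.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nmax |z| = {df.z_score.max():.2f} (all within 3 SE: "
          f"{bool((df.z_score <= 3).all())})")


if __name__ == "__main__":
    main()
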