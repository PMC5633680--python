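#!/usr/bin/env python
"""Statistical comparison of correction strategies from the quality table.

Reads results/quality_table.csv (written by 04_run_study.py), computes per
metric and network the two-factor within-subject ANOVA (Method x TR) and the
follow-up paired t-tests, and the per-strategy ICC of each metric; writes the
tables under results/evaluation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from physioeval.evaluation import classify_icc, followup_paired_t, two_factor_rm_anova
from physioeval.pipeline import icc_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    qt = pd.read_csv(OUT / "quality_table.csv")
    evaldir = OUT / "evaluation"
    evaldir.mkdir(parents=True, exist_ok=True)

    anova_rows = []
    for (metric, net), sub in qt.groupby(["metric", "network"]):
        if metric == "dice" or sub["condition"].nunique() < 2:
            continue
        try:
            res = two_factor_rm_anova(sub)
        except ValueError:
            continue
        for factor, d in res.items():
            anova_rows.append({"metric": metric, "network": net,
                               "factor": factor, **d})
        tt = followup_paired_t(sub, holm=True)
        tt.to_csv(evaldir / f"ttests_{metric}_net{net}.csv", index=False)
    anova = pd.DataFrame(anova_rows)
    anova.to_csv(evaldir / "anova.csv", index=False)

    icc_rows = []
    for (metric, net, strat, cond), _ in qt[qt.run.isin(["run-1", "run-2"])] \
            .groupby(["metric", "network", "strategy", "condition"]):
        try:
            val = icc_table(qt, metric, net, strat, cond)
        except ValueError:
            continue
        icc_rows.append({"metric": metric, "network": net, "strategy": strat,
                         "condition": cond, "icc": val,
                         "category": classify_icc(min(val, 1.0))})
    iccs = pd.DataFrame(icc_rows)
    iccs.to_csv(evaldir / "icc_summary.csv", index=False)

    print("ANOVA results (Method and TR factors):")
    print(anova[anova.factor.isin(["Method", "TR"])]
          .pivot_table(index=["metric", "network"], columns="factor",
                       values="p").round(3).head(12))
    print("\nmedian ICC by metric and strategy:")
    print(iccs.pivot_table(index="metric", columns="strategy", values="icc",
                           aggfunc="median").round(3))


if __name__ == "__main__":
    main()
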