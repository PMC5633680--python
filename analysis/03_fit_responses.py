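#!/usr/bin/env python
"""Voxel-wise Gaussian response recovery at 15% per-signal contamination.

Builds 200 synthetic voxels with known (amplitude, latency, width) responses
to all three physiological signals, fits the joint response model, and
tabulates how often the latency/width land within one 1-s grid step and the
response magnitude within 10% of truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from physioeval.correction import convolve_regressor, fit_physio_responses, gaussian_kernel
from physioeval.datatypes import SIGNALS
from physioeval.synthgen import make_network_atlas, make_response_fixture

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    atlas = make_network_atlas((14, 14, 7), n_networks=7, seed=SEED)
    run, regs, truth = make_response_fixture(atlas, n_vox=200, seed=SEED + 11)
    fit = fit_physio_responses(run, regs)
    t_k = np.arange(0, 40.0 + 0.5 * run.tr, run.tr)

    rows = []
    for s in SIGNALS:
        mu_ok = np.abs(fit.latency[s] - truth[s]["latency"]) <= 1.0
        sg_ok = np.abs(fit.width[s] - truth[s]["width"]) <= 1.0
        amp_ok = np.zeros(200, bool)
        for v in range(200):
            kern = gaussian_kernel(fit.amplitude[s][v], float(fit.latency[s][v]),
                                   float(fit.width[s][v]), t_k)
            fitted = convolve_regressor(regs[s], kern)
            true_rms = truth[s]["component"][:, v].std()
            amp_ok[v] = abs(fitted.std() - true_rms) <= 0.10 * true_rms
        rows.append({"signal": s, "latency_within_1s": mu_ok.mean(),
                     "width_within_1s": sg_ok.mean(),
                     "magnitude_within_10pct": amp_ok.mean(),
                     "all_criteria": (mu_ok & sg_ok & amp_ok).mean()})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "response_recovery.csv", index=False)
    print(df.to_string(index=False))
    print(f"\npooled recovery rate: {df.all_criteria.mean():.3f}")


if __name__ == "__main__":
    main()
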