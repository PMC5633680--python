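#!/usr/bin/env python
"""Directional findings: does end-tidal CO2 correction help, and does the
sampling rate matter?

Replicates the study ten times with CO2-dominant contamination and compares
connectivity reproducibility (voxel-wise ICC of seed-network Fisher z) and
network separability between no correction and CO2 correction; then compares
fast-TR runs with their decimated versions to isolate the sampling-rate
effect. Writes both tables under results/.
"""

from pathlib import Path

import pandas as pd

from physioeval.pipeline import directional_comparison, sampling_rate_comparison

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = directional_comparison(n_studies=10, seed=SEED)
    df.to_csv(OUT / "directional_comparison.csv", index=False)
    med = df.groupby("strategy")[["icc", "si"]].median().round(4)
    print("median over 10 replicated studies:")
    print(med)
    print("\nCO2 correction changes the median connectivity ICC by "
          f"{med.loc['PETCO2', 'icc'] - med.loc['Base', 'icc']:+.3f} and the "
          f"median separability by {med.loc['PETCO2', 'si'] - med.loc['Base', 'si']:+.4f}")

    sr = sampling_rate_comparison(n_studies=3, seed=SEED + 100)
    sr.to_csv(OUT / "sampling_rate_comparison.csv", index=False)
    wide = sr.pivot_table(index=["study", "strategy"], columns="condition", values="si")
    tr_delta = (wide["shortTR"] - wide["shortTR_downsampled"]).abs().mean()
    bystrat = sr.pivot_table(index=["study", "condition"], columns="strategy", values="si")
    strat_delta = (bystrat["PETCO2"] - bystrat["Base"]).abs().mean()
    print(f"\nmean |SI| change from decimation: {tr_delta:.4f}; "
          f"from switching strategy: {strat_delta:.4f} "
          f"(sampling rate matters {tr_delta/strat_delta:.2f}x as much)")


if __name__ == "__main__":
    main()
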