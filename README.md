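# physioeval

Resting-state fMRI (rs-fMRI) inferences ride on slow spontaneous BOLD
fluctuations below 0.1 Hz — the same band occupied by low-frequency
physiology: end-tidal CO2 (PETCO2), respiration volume per time (RVT), and
cardiac-rate variation (CRV). Whether regressing these signals out *improves*
rs-fMRI measurements is surprisingly hard to settle, because the answer
depends on the quality measure: removing a reproducible artifact can lower
test–retest reliability while raising validity.

`physioeval` is an end-to-end evaluation pipeline for this question, built
around a synthetic study with known ground truth. It provides:

* **a synthetic-study generator** — a test–retest design (8 subjects × 2
  runs; 8-minute runs at TR = 2 s and TR = 0.323 s plus a decimated variant)
  with a 7-network atlas, raw physiological waveforms (pulse, belt, CO2), and
  BOLD runs contaminated by voxel-wise Gaussian responses
  `h(t) = A·exp(−(t−μ)²/2σ²)` to the three physiological regressors;
* **regressor extraction** — beat/breath detection, CRV (inter-beat interval
  in a centered 4-s window), RVT (breath depth over period), PETCO2
  (breath-by-breath CO2 maxima), and RETROICOR phase regressors;
* **voxel-wise correction** — simultaneous grid-search estimation of the
  Gaussian responses and regression of any of the eight strategy combinations
  (Base, PETCO2, CRV, RVT, the three pairs, All), without orthogonalization;
* **rs-fMRI measures** — normalized ALFF, ReHo (Kendall's W over 27-voxel
  neighborhoods), and seed connectivity z-maps with Gaussian+Gamma
  mixture-model correction;
* **a quality battery** — test–retest ICC `(MS_b − MS_w)/(MS_b + (k−1)MS_w)`,
  Dice overlap of thresholded maps, the separability index
  `(WNC − BNC)/(WNC + BNC)`, atlas-based sensitivity/specificity, and a
  two-factor within-subject ANOVA (Method × TR) with follow-up paired t-tests.

## Worked example

```python
import warnings
from physioeval.pipeline import StudyConfig, run_study, icc_table

cfg = StudyConfig(grid_dims=(14, 14, 7), conditions=("longTR",),
                  strategies=("Base", "PETCO2"), metrics=("fc",),
                  mu_step=2.0, sigma_step=2.0, seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    qt, manifest = run_study(cfg)

for strat in ("Base", "PETCO2"):
    si = qt[(qt.metric == "SI") & (qt.strategy == strat)]["value"].mean()
    print(strat, round(si, 3))
```

prints

```
Base 0.919
PETCO2 0.927
```

— the mean separability index of the two seed networks rises slightly after
CO2 correction, because the globally shared CO2-driven signal inflates
between-network correlation under "Base". Replicating the whole study ten
times (`analysis/06_directional_findings.py`) gives the headline comparison:

```
median over 10 replicated studies:
             icc      si
strategy
Base      0.4256  0.9157
PETCO2    0.5490  0.9222
```

so with CO2-dominant contamination, CO2 correction raises the median
test–retest ICC of seed-network connectivity by +0.12 and the median
separability by +0.007, while decimating the fast-TR data to the slow-TR
grid moves the separability by less than switching strategy does — the
sampling rate is not what drives the correction effect.

The numbered drivers under `analysis/` walk the full study:
`01_simulate.py` (generate and decompose variance), `02_extract_regressors.py`
(waveform → regressor recovery), `03_fit_responses.py` (voxel-wise response
recovery), `04_run_study.py` (all eight strategies, full quality table),
`05_evaluate.py` (ANOVA, t-tests, ICC summaries), and
`06_directional_findings.py`. Each writes its tables under `results/`.

A CLI mirrors the stages for file-based use:

```bash
physioeval simulate --out study/ --seed 1
physioeval physio --cardiac c.tsv --resp r.tsv --co2 g.tsv --frames f.json --out reg.tsv
physioeval correct --run run.nii.gz --regressors reg.tsv --strategy PETCO2+RVT --out corrected.nii.gz
physioeval metrics --run corrected.nii.gz --measure alff --out maps/
physioeval run-all --out study/ --seed 1
```

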