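"""End-to-end study orchestration.

``run_study`` executes the whole evaluation for a configured synthetic study:
simulate -> RETROICOR regression -> voxel-wise response fit (on unfiltered
data) -> strategy regression -> spatial smoothing -> metrics (ALFF from the
unfiltered branch; band-pass then ReHo and seed connectivity) -> mixture
correction and thresholding -> a tidy quality table. Stage order follows the
processing conventions for resting-state physiological correction; ALFF is
structurally guaranteed to never see band-passed data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .datatypes import STRATEGIES, BoldRun, NetworkAtlas
from .synthgen import SimulatedRun, make_bold_study, make_network_atlas
from .physio import detect_beats, extract_regressors, retroicor_design
from .correction import (
    apply_strategy,
    bandpass_filter,
    decimate_to_tr,
    fit_physio_responses,
    regress_nuisance,
    spatial_smooth,
)
from .rsmetrics import (
    binarize,
    compute_alff,
    compute_reho,
    fit_null_mixture,
    make_seed_roi,
    mixture_correct,
    normalize_map,
    seed_z_map,
)
from .evaluation import dice, icc, sens_spec, separability

logger = logging.getLogger("physioeval")

__all__ = ["StudyConfig", "run_study", "icc_table", "voxelwise_connectivity_icc"]


@dataclass
class StudyConfig:
    """Configuration of a synthetic evaluation study.

    Defaults mirror the emulated acquisition: 8 subjects x 2 runs, 8-minute
    runs at TR = 2 s (240 frames) and TR = 0.323 s (1,486 frames, the first
    2 minutes already discarded), with a decimated variant of the short-TR
    runs; all eight correction strategies; 0.01-0.1 Hz band; 10 mm FWHM
    smoothing; corrected-z threshold 0.5.
    """

    grid_dims: Tuple[int, int, int] = (20, 20, 10)
    n_networks: int = 7
    voxel_size: Tuple[float, float, float] = (3.44, 3.44, 4.6)
    n_subjects: int = 8
    n_runs: int = 2
    conditions: Tuple[str, ...] = ("longTR", "shortTR", "shortTR_downsampled")
    tr_long: float = 2.0
    n_frames_long: int = 240
    tr_short: float = 0.323
    n_frames_short: int = 1486
    contamination_scale: float = 0.15
    noise_sd: float = 1.0
    strategies: Tuple[str, ...] = tuple(STRATEGIES)
    metrics: Tuple[str, ...] = ("alff", "reho", "fc")
    band: Tuple[float, float] = (0.01, 0.1)
    smoothing_fwhm: float = 10.0
    seed_networks: Tuple[int, ...] = (1, 4)     # motor / DMN analogues
    seed_radius_mm: float = 4.0
    z_threshold: float = 0.5
    retroicor_order: int = 2
    crv_window: float = 4.0
    mu_step: float = 1.0
    sigma_step: float = 1.0
    fit_max_cycles: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d))

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("at least one TR condition is required")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        for k in self.seed_networks:
            if not (1 <= k <= self.n_networks):
                raise ValueError(f"seed network {k} outside 1..{self.n_networks}")


def _seed_rois(atlas: NetworkAtlas, config: StudyConfig) -> Dict[int, np.ndarray]:
    rois = {}
    for net in config.seed_networks:
        center = np.round(ndimage.center_of_mass(atlas.labels == net)).astype(int)
        roi = make_seed_roi(center, atlas.voxel_size, atlas.labels.shape,
                            config.seed_radius_mm)
        roi &= atlas.labels == net
        if not roi.any():
            roi[tuple(center)] = True
        rois[net] = roi
    return rois


def _network_means(values: np.ndarray, atlas: NetworkAtlas) -> Dict[int, float]:
    return {k: float(np.nanmean(values[atlas.labels == k]))
            for k in range(1, atlas.n_networks + 1)}


def run_study(config: StudyConfig, out_dir: Optional[Path] = None
              ) -> Tuple[pd.DataFrame, Dict]:
    """Run the full evaluation; returns (quality table, manifest).

    The quality table is tidy: one record per {subject, run, condition,
    strategy, metric, network} cell, plus between-run Dice records (run =
    "1-2"). Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    t_start = time.time()
    atlas = make_network_atlas(config.grid_dims, config.n_networks,
                               config.voxel_size, seed=config.seed)
    rois = _seed_rois(atlas, config)
    records: List[dict] = []
    binmaps: Dict[tuple, np.ndarray] = {}
    network_z: Dict[tuple, np.ndarray] = {}
    manifest: Dict = {"master_seed": config.seed, "version": __version__,
                      "stages": [], "files": []}

    base_conditions = [c for c in config.conditions if c != "shortTR_downsampled"]
    need_short = ("shortTR_downsampled" in config.conditions
                  and "shortTR" not in base_conditions)
    sim_conditions = base_conditions + (["shortTR"] if need_short else [])

    for condition in sim_conditions:
        tr, n_frames = ((config.tr_long, config.n_frames_long)
                        if condition == "longTR"
                        else (config.tr_short, config.n_frames_short))
        logger.info("simulating condition %s (TR=%.3f, %d frames)", condition, tr, n_frames)
        sims = make_bold_study(atlas, config.n_subjects, config.n_runs, tr,
                               n_frames, config.contamination_scale,
                               config.noise_sd, seed=config.seed,
                               condition=condition)
        manifest["stages"].append({"stage": f"simulate:{condition}",
                                   "runs": len(sims), "t": time.time() - t_start})
        emit = condition in config.conditions
        for sim in sims:
            if emit:
                _process_run(sim, atlas, rois, config, records, binmaps, network_z)
            if condition == "shortTR" and "shortTR_downsampled" in config.conditions:
                down = SimulatedRun(
                    bold=decimate_to_tr(sim.bold, config.tr_long),
                    recordings=sim.recordings, truth=sim.truth,
                    resp_phase_frames=sim.resp_phase_frames)
                _process_run(down, atlas, rois, config, records, binmaps, network_z)

    _append_dice_records(records, binmaps, config)
    qt = pd.DataFrame.from_records(records)
    manifest["network_z"] = network_z
    manifest["stages"].append({"stage": "evaluate", "t": time.time() - t_start})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        qt_path = out_dir / "quality_table.csv"
        qt.to_csv(qt_path, index=False)
        from .io import save_json, sha256_of
        manifest["files"].append({"path": str(qt_path), "sha256": sha256_of(qt_path)})
        serializable = {k: v for k, v in manifest.items() if k != "network_z"}
        save_json(serializable, out_dir / "manifest.json")
    return qt, manifest


def _process_run(sim: SimulatedRun, atlas: NetworkAtlas, rois, config: StudyConfig,
                 records: List[dict], binmaps: Dict[tuple, np.ndarray],
                 network_z: Dict[tuple, np.ndarray]) -> None:
    run = sim.bold
    subject, run_id, condition = run.subject_id, run.run_id, run.condition
    ft = run.frame_times

    # time-locked cardiac/respiratory regression (RETROICOR stage)
    beats = detect_beats(sim.recordings["cardiac"])
    design = retroicor_design(beats, sim.recordings["respiratory"], ft,
                              order=config.retroicor_order)
    cleaned = regress_nuisance(run, design)

    pet, rvt, crv = extract_regressors(sim.recordings["cardiac"],
                                       sim.recordings["respiratory"],
                                       sim.recordings["co2"], ft,
                                       crv_window=config.crv_window)
    regressors = {"PETCO2": pet, "RVT": rvt, "CRV": crv}

    # responses are fitted (and corrections applied) in gray matter only:
    # the physiological effects live there, and it halves the fit cost
    gm_view = BoldRun(data=cleaned.data, tr=cleaned.tr, mask=atlas.gm_mask,
                      subject_id=subject, run_id=run_id, condition=condition,
                      frame_times=ft, voxel_size=cleaned.voxel_size)
    needs_fit = any(STRATEGIES[s].included_signals for s in config.strategies)
    responses = None
    if needs_fit:
        responses = fit_physio_responses(
            gm_view, regressors, mu_step=config.mu_step,
            sigma_step=config.sigma_step, max_cycles=config.fit_max_cycles)

    for sname in config.strategies:
        corrected_gm = apply_strategy(gm_view, regressors, responses, sname)
        corrected = cleaned.with_data(corrected_gm.data)
        smoothed = (spatial_smooth(corrected, config.smoothing_fwhm)
                    if config.smoothing_fwhm > 0 else corrected)
        common = {"subject": subject, "run": run_id, "condition": condition,
                  "strategy": sname}

        if "alff" in config.metrics:
            alff = normalize_map(compute_alff(smoothed, config.band),
                                 mask=atlas.gm_mask)
            for net, v in _network_means(alff.values, atlas).items():
                records.append({**common, "metric": "nALFF", "network": net, "value": v})

        needs_bp = ("reho" in config.metrics) or ("fc" in config.metrics)
        if needs_bp:
            bp = bandpass_filter(smoothed, *config.band)
        if "reho" in config.metrics:
            reho = compute_reho(bp, mask=atlas.gm_mask)
            for net, v in _network_means(reho.values, atlas).items():
                records.append({**common, "metric": "ReHo", "network": net, "value": v})
        if "fc" in config.metrics:
            for net, roi in rois.items():
                zmap = seed_z_map(bp, roi, mask=run.mask)
                # the null is anchored on the whole in-brain map (the non-gray
                # rim carries no physiology), as when correcting whole-brain
                # connectivity maps against a reference null
                fit = fit_null_mixture(zmap.values[run.mask])
                cz = mixture_correct(zmap, fit)
                bmap = binarize(cz, config.z_threshold, mask=atlas.gm_mask)
                summ = separability(cz, atlas, net)
                sens, spec = sens_spec(bmap, atlas, net)
                records.append({**common, "metric": "connectivity", "network": net,
                                "value": float(np.nanmean(cz.values[atlas.labels == net]))})
                records.append({**common, "metric": "SI", "network": net, "value": summ.si})
                records.append({**common, "metric": "sensitivity", "network": net,
                                "value": sens})
                records.append({**common, "metric": "specificity", "network": net,
                                "value": spec})
                binmaps[(subject, run_id, condition, sname, net)] = bmap.members
                network_z[(subject, run_id, condition, sname, net)] = (
                    cz.values[atlas.labels == net].copy())
                network_z[("raw", subject, run_id, condition, sname, net)] = (
                    zmap.values[atlas.labels == net].copy())


def _append_dice_records(records, binmaps, config) -> None:
    keys = {(s, c, strat, net) for (s, r, c, strat, net) in binmaps}
    for (subject, condition, sname, net) in sorted(keys):
        runs = sorted(r for (s, r, c, st, n) in binmaps
                      if (s, c, st, n) == (subject, condition, sname, net))
        for i in range(len(runs) - 1):
            a = binmaps[(subject, runs[i], condition, sname, net)]
            b = binmaps[(subject, runs[i + 1], condition, sname, net)]
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                d = dice(a, b)
            records.append({"subject": subject, "run": f"{runs[i]}-{runs[i+1]}",
                            "condition": condition, "strategy": sname,
                            "metric": "dice", "network": net, "value": d})


def icc_table(qt: pd.DataFrame, metric: str, network: int, strategy: str,
              condition: str) -> float:
    """ICC of one metric cell: subjects x runs table pulled from the tidy
    quality table."""
    sel = qt[(qt["metric"] == metric) & (qt["network"] == network)
             & (qt["strategy"] == strategy) & (qt["condition"] == condition)]
    wide = sel.pivot_table(index="subject", columns="run", values="value")
    return icc(wide.to_numpy())


def directional_comparison(n_studies: int = 10, seed: int = 0,
                           grid_dims: Tuple[int, int, int] = (14, 14, 7),
                           strategies: Tuple[str, str] = ("Base", "PETCO2"),
                           seed_networks: Tuple[int, ...] = (1, 4)) -> pd.DataFrame:
    """Replicate the study ``n_studies`` times and summarize, per study and
    strategy, the connectivity-value reproducibility (mean voxel-wise ICC of
    the raw Fisher z over the seed networks) and the separability index.

    Long-TR condition only; used to test whether end-tidal CO2 correction
    improves reproducibility and network separability under CO2-dominant
    contamination.
    """
    import warnings as _w

    rows = []
    for k in range(n_studies):
        cfg = StudyConfig(grid_dims=grid_dims, conditions=("longTR",),
                          strategies=strategies, metrics=("fc",),
                          seed_networks=seed_networks,
                          mu_step=2.0, sigma_step=2.0, fit_max_cycles=3,
                          seed=seed + k)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            qt, man = run_study(cfg)
        nz = man["network_z"]
        for strat in strategies:
            iccs = [voxelwise_connectivity_icc(nz, net, strat, "longTR",
                                               corrected=False)
                    for net in seed_networks]
            sis = [qt[(qt.metric == "SI") & (qt.strategy == strat)
                      & (qt.network == net)]["value"].mean()
                   for net in seed_networks]
            rows.append({"study": k, "strategy": strat,
                         "icc": float(np.mean(iccs)), "si": float(np.mean(sis))})
    return pd.DataFrame(rows)


def sampling_rate_comparison(n_studies: int = 3, seed: int = 100,
                             grid_dims: Tuple[int, int, int] = (14, 14, 7),
                             strategies: Tuple[str, str] = ("Base", "PETCO2"),
                             seed_networks: Tuple[int, ...] = (1, 4)) -> pd.DataFrame:
    """Short-TR vs decimated short-TR: per study/strategy/condition mean SI.

    Used to test that the sampling rate barely moves the metrics compared to
    the choice of correction strategy.
    """
    import warnings as _w

    rows = []
    for k in range(n_studies):
        cfg = StudyConfig(grid_dims=grid_dims,
                          conditions=("shortTR", "shortTR_downsampled"),
                          strategies=strategies, metrics=("fc",), n_runs=1,
                          seed_networks=seed_networks,
                          mu_step=2.0, sigma_step=2.0, fit_max_cycles=3,
                          seed=seed + k)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            qt, _ = run_study(cfg)
        for strat in strategies:
            for cond in cfg.conditions:
                si = qt[(qt.metric == "SI") & (qt.strategy == strat)
                        & (qt.condition == cond)]["value"].mean()
                rows.append({"study": k, "strategy": strat, "condition": cond,
                             "si": float(si)})
    return pd.DataFrame(rows)


def voxelwise_connectivity_icc(network_z: Dict[tuple, np.ndarray], network: int,
                               strategy: str, condition: str,
                               corrected: bool = True) -> float:
    """Mean voxel-wise ICC of corrected connectivity z inside a network.

    The per-run network z-vectors recorded by ``run_study`` (one value per
    network voxel) are assembled into a subjects x runs table per voxel; the
    ICC map is averaged over the network, the common way ICC maps are
    summarized regionally."""
    if corrected:
        keys = [k for k in network_z if len(k) == 5
                and k[2] == condition and k[3] == strategy and k[4] == network]
        subjects = sorted({k[0] for k in keys})
        runs = sorted({k[1] for k in keys})
        table = np.stack([[network_z[(s, r, condition, strategy, network)]
                           for r in runs] for s in subjects])
    else:
        keys = [k for k in network_z if len(k) == 6 and k[0] == "raw"
                and k[3] == condition and k[4] == strategy and k[5] == network]
        subjects = sorted({k[1] for k in keys})
        runs = sorted({k[2] for k in keys})
        table = np.stack([[network_z[("raw", s, r, condition, strategy, network)]
                           for r in runs] for s in subjects])
    vals = [icc(table[:, :, v]) for v in range(table.shape[2])]
    return float(np.mean(vals))
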