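"""Synthetic study generator: atlas, physiological waveforms, and BOLD runs.

The generator emulates a test-retest resting-state fMRI study (by default
8 subjects x 2 runs, 8-minute runs at TR = 2 s or TR = 0.323 s) in which the
BOLD signal of every gray-matter voxel is a sum of

* a network component (one shared low-frequency signal per network, scaled by
  a subject-specific coupling, so seed-based connectivity has ground truth),
* a low-frequency physiological component: the three regressors (PETCO2, RVT,
  CRV) convolved with voxel-wise Gaussian responses,
* a time-locked quasi-periodic cardiac/respiratory component (the part
  RETROICOR targets), and
* white measurement noise.

Raw waveforms (pulse, belt, CO2 trace) are generated alongside so the
extraction stage can be validated against the hidden truth. All randomness
flows from one master seed through per-subject/run/stream sub-seeds, so equal
seeds give bit-identical studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (
    SIGNALS,
    BoldRun,
    GroundTruth,
    NetworkAtlas,
    PhysioRecording,
)

__all__ = [
    "make_network_atlas",
    "make_cardiac_waveform",
    "make_respiratory_waveform",
    "make_co2_waveform",
    "make_bold_study",
    "make_response_fixture",
    "SimulatedRun",
    "random_band_series",
    "aligned_variance",
    "windowed_interval_mean",
]


# --------------------------------------------------------------------------
# seeding helpers
# --------------------------------------------------------------------------

_STREAMS = {
    "subject": 1,
    "cardiac": 2,
    "resp": 3,
    "co2": 4,
    "network": 5,
    "noise": 6,
    "locked": 7,
}


def _rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child generator for a (subject, run, stream) tuple."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, keys)]))


def random_band_series(rng: np.random.Generator, f_lo: float, f_hi: float,
                       n_components: int = 24) -> Callable[[np.ndarray], np.ndarray]:
    """A smooth random function of time with power confined to [f_lo, f_hi] Hz.

    Sum of sinusoids at random frequencies/phases, normalized to unit
    time-average variance. Used for slow physiological modulations and for
    the per-network neural signals.
    """
    freqs = rng.uniform(f_lo, f_hi, n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_components)
    amps = rng.uniform(0.5, 1.5, n_components)
    norm = np.sqrt(np.sum(amps ** 2) / 2.0)

    def series(t):
        t = np.asarray(t, dtype=float)
        return (amps * np.sin(2.0 * np.pi * freqs * t[..., None] + phases)).sum(axis=-1) / norm

    return series


# --------------------------------------------------------------------------
# atlas
# --------------------------------------------------------------------------

def _partition_box(lo: np.ndarray, hi: np.ndarray, k: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Recursively bisect an axis-aligned box into k contiguous blocks."""
    if k == 1:
        return [(lo.copy(), hi.copy())]
    k1 = k // 2
    extents = hi - lo
    ax = int(np.argmax(extents))
    cut = lo[ax] + int(round(extents[ax] * k1 / k))
    cut = min(max(cut, lo[ax] + 1), hi[ax] - 1)
    lo_a, hi_a = lo.copy(), hi.copy()
    hi_a[ax] = cut
    lo_b, hi_b = lo.copy(), hi.copy()
    lo_b[ax] = cut
    return _partition_box(lo_a, hi_a, k1) + _partition_box(lo_b, hi_b, k - k1)


def make_network_atlas(grid_dims: Sequence[int] = (20, 20, 10), n_networks: int = 7,
                       voxel_size: Sequence[float] = (3.44, 3.44, 4.6),
                       seed: int = 0, rim: int = 1) -> NetworkAtlas:
    """Build a block-shaped network parcellation on a regular grid.

    Gray matter is the interior box obtained by stripping ``rim`` voxels from
    every face (the rim supplies non-gray-matter voxels so specificity has
    true negatives); the gray-matter box is partitioned into ``n_networks``
    contiguous axis-aligned blocks by recursive bisection.
    """
    del seed  # the partition is deterministic; the argument fixes the contract
    grid_dims = tuple(int(d) for d in grid_dims)
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    lo = np.array([rim] * 3)
    hi = np.array(grid_dims) - rim
    if np.any(hi - lo < 1):
        raise ValueError("grid too small for the requested rim")
    labels = np.zeros(grid_dims, dtype=np.int32)
    for i, (blo, bhi) in enumerate(_partition_box(lo, hi, n_networks), start=1):
        labels[blo[0]:bhi[0], blo[1]:bhi[1], blo[2]:bhi[2]] = i
    counts = np.bincount(labels.ravel(), minlength=n_networks + 1)[1:]
    if np.any(counts < 8):
        raise ValueError(
            f"grid {grid_dims} too small: smallest network has {counts.min()} voxels (< 8)")
    return NetworkAtlas(labels=labels, gm_mask=labels > 0,
                        voxel_size=tuple(float(v) for v in voxel_size),
                        n_networks=n_networks)


# --------------------------------------------------------------------------
# physiological waveforms
# --------------------------------------------------------------------------

def make_cardiac_waveform(duration: float, fs: float,
                          beat_interval_series: Callable[[float], float],
                          seed: int = 0,
                          noise_sd: float = 0.01,
                          t0: float = 0.0) -> Tuple[PhysioRecording, np.ndarray]:
    """Raised-cosine pulse train with beat times driven by an interval series.

    Returns the recording and the ground-truth beat times. One dominant local
    maximum per beat, so peak detection can recover the beats. ``t0`` starts
    the recording before the scan, as physiological monitoring usually does.
    """
    rng = np.random.default_rng(seed)
    beats = [t0]
    while True:
        iv = float(beat_interval_series(beats[-1]))
        if iv <= 0:
            raise ValueError("beat interval must be positive")
        nxt = beats[-1] + iv
        if nxt >= t0 + duration - 1e-12:
            break
        beats.append(nxt)
    beats = np.asarray(beats)
    intervals = np.diff(beats)
    if intervals.size:
        mean_iv = float(intervals.mean())
        if not (0.5 <= mean_iv <= 1.5):
            raise ValueError(f"mean beat interval {mean_iv:.3f} s outside [0.5, 1.5] s")
        if fs < 2.0 / intervals.min():
            raise ValueError("sampling rate below twice the beat rate")
    if fs < 25.0:
        raise ValueError("cardiac sampling rate must be >= 25 Hz")

    n = int(round(duration * fs)) + 1
    t = t0 + np.arange(n) / fs
    wave = np.zeros(n)
    for k, b in enumerate(beats):
        local = intervals[min(k, len(intervals) - 1)] if intervals.size else 1.0
        half = 0.5 * 0.4 * local  # pulse occupies 40% of the beat interval
        i0 = max(0, int(np.ceil((b - half - t0) * fs)))
        i1 = min(n, int(np.floor((b + half - t0) * fs)) + 1)
        if i1 > i0:
            wave[i0:i1] += 0.5 * (1.0 + np.cos(np.pi * (t[i0:i1] - b) / half))
    wave += noise_sd * rng.standard_normal(n)
    return PhysioRecording(samples=wave, fs=fs, kind="cardiac", t0=t0), beats


def _phase_track(duration: float, fs: float,
                 period_series: Callable[[np.ndarray], np.ndarray],
                 phi0: float = 0.0, t0: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate dphi/dt = 2*pi/period(t); period modulation causes no jumps."""
    n = int(round(duration * fs)) + 1
    t = t0 + np.arange(n) / fs
    periods = np.asarray(period_series(t), dtype=float)
    if np.any(periods <= 0):
        raise ValueError("breathing period must be positive")
    if np.any((periods < 2.0) | (periods > 8.0)):
        raise ValueError("breathing period outside [2, 8] s")
    dphi = 2.0 * np.pi / periods / fs
    phi = phi0 + np.concatenate([[0.0], np.cumsum(dphi[:-1])])
    return t, phi


def _phase_crossings(t: np.ndarray, phi: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Times at which the monotone phase track crosses each target phase."""
    return np.interp(targets, phi, t)


def _breath_extrema(t: np.ndarray, phi: np.ndarray, clean: np.ndarray,
                    center_phase: float) -> Tuple[np.ndarray, np.ndarray]:
    """Exact per-breath extremum of a noise-free waveform.

    One extremum is located per cycle, searching the half-cycle phase window
    around ``center_phase`` (pi/2 for peaks, 3*pi/2 for troughs); slow
    amplitude modulation shifts the true extremum slightly away from the
    phase crossing, which this search captures.
    """
    centers = np.arange(center_phase, phi[-1], 2.0 * np.pi)
    times = np.empty(centers.size)
    values = np.empty(centers.size)
    maximize = np.sin(center_phase) > 0
    lo_idx = np.searchsorted(phi, centers - np.pi / 2)
    hi_idx = np.searchsorted(phi, centers + np.pi / 2)
    keep = np.zeros(centers.size, dtype=bool)
    for i, (lo, hi) in enumerate(zip(lo_idx, hi_idx)):
        if hi - lo < 3:
            continue
        seg = clean[lo:hi]
        j = int(np.argmax(seg) if maximize else np.argmin(seg))
        times[i] = t[lo + j]
        values[i] = seg[j]
        keep[i] = True
    return times[keep], values[keep]


def make_respiratory_waveform(duration: float, fs: float,
                              depth_series: Callable[[np.ndarray], np.ndarray],
                              period_series: Callable[[np.ndarray], np.ndarray],
                              seed: int = 0, noise_sd: float = 0.01,
                              t0: float = 0.0,
                              ) -> Tuple[PhysioRecording, np.ndarray, np.ndarray]:
    """Respiratory-belt waveform from a phase-integrated oscillator.

    The belt signal is ``depth(t)/2 * sin(phase)``, so consecutive local
    maxima/minima differ by the depth at that time. Returns
    ``(recording, breath_peak_times, true_rvt_per_breath)`` with
    ``true_rvt = depth/period`` evaluated at each breath peak.
    """
    rng = np.random.default_rng(seed)
    t, phi = _phase_track(duration, fs, period_series, t0=t0)
    depths = np.asarray(depth_series(t), dtype=float)
    if np.any(depths <= 0):
        raise ValueError("breathing depth must be positive")
    wave = 0.5 * depths * np.sin(phi) + noise_sd * rng.standard_normal(t.size)

    # RVT is defined from the waveform geometry (peak minus adjacent troughs
    # over the breath period), so the ground truth is computed from the exact
    # per-breath extrema of the noise-free waveform (on an oversampled grid).
    tf, phif = _phase_track(duration, 4.0 * fs, period_series, t0=t0)
    clean = 0.5 * np.asarray(depth_series(tf), dtype=float) * np.sin(phif)
    peak_times, pk_val = _breath_extrema(tf, phif, clean, np.pi / 2)
    trough_times, tr_val = _breath_extrema(tf, phif, clean, 3 * np.pi / 2)
    depth_breath = np.full(peak_times.size, np.nan)
    for i, p in enumerate(peak_times):
        before = np.where(trough_times < p)[0]
        after = np.where(trough_times > p)[0]
        if before.size and after.size:
            depth_breath[i] = pk_val[i] - 0.5 * (tr_val[before[-1]] + tr_val[after[0]])
        elif after.size:
            depth_breath[i] = pk_val[i] - tr_val[after[0]]
        elif before.size:
            depth_breath[i] = pk_val[i] - tr_val[before[-1]]
    periods = np.empty(peak_times.size)
    if peak_times.size > 2:
        periods[1:-1] = 0.5 * (peak_times[2:] - peak_times[:-2])
    periods[0] = peak_times[1] - peak_times[0]
    periods[-1] = peak_times[-1] - peak_times[-2]
    true_rvt = depth_breath / periods
    ok = np.isfinite(true_rvt)
    return (PhysioRecording(samples=wave, fs=fs, kind="respiratory", t0=t0),
            peak_times[ok], true_rvt[ok])


def make_co2_waveform(duration: float, fs: float,
                      petco2_series: Callable[[np.ndarray], np.ndarray],
                      period_series: Callable[[np.ndarray], np.ndarray],
                      seed: int = 0, noise_sd: float = 0.05,
                      t0: float = 0.0,
                      ) -> Tuple[PhysioRecording, np.ndarray, np.ndarray]:
    """CO2 tracing whose breath-by-breath maxima equal the end-tidal series.

    The trace follows ``petco2(t) * max(sin(phase), 0)**0.6``: near-zero during
    inhalation, rising to the end-tidal value at each expiratory peak. Returns
    ``(recording, breath_peak_times, true_petco2_per_breath)``.
    """
    rng = np.random.default_rng(seed)
    t, phi = _phase_track(duration, fs, period_series, t0=t0)
    pet = np.asarray(petco2_series(t), dtype=float)
    if np.any((pet < 25.0) | (pet > 55.0)):
        raise ValueError("end-tidal CO2 outside the physiological range [25, 55] mmHg")
    shape = np.clip(np.sin(phi), 0.0, None) ** 0.6
    wave = pet * shape + noise_sd * rng.standard_normal(t.size)

    # the end-tidal value is defined as the per-breath maximum of the tracing,
    # so the truth is the exact per-breath maximum of the noise-free waveform
    tf, phif = _phase_track(duration, 4.0 * fs, period_series, t0=t0)
    cleanf = (np.asarray(petco2_series(tf), dtype=float)
              * np.clip(np.sin(phif), 0.0, None) ** 0.6)
    peak_times, true_pet = _breath_extrema(tf, phif, cleanf, np.pi / 2)
    return PhysioRecording(samples=wave, fs=fs, kind="co2", t0=t0), peak_times, true_pet


# --------------------------------------------------------------------------
# ground-truth regressor definitions
# --------------------------------------------------------------------------

def windowed_interval_mean(event_times: np.ndarray, frame_times: np.ndarray,
                           window: float = 4.0) -> np.ndarray:
    """Mean inter-event interval among intervals whose midpoint falls in a
    centered window around each frame; empty windows take the nearest defined
    value. This direct loop is the generator-side definition of CRV."""
    event_times = np.asarray(event_times, dtype=float)
    intervals = np.diff(event_times)
    mids = 0.5 * (event_times[:-1] + event_times[1:])
    out = np.full(len(frame_times), np.nan)
    for i, ft in enumerate(np.asarray(frame_times, dtype=float)):
        sel = (mids >= ft - window / 2.0) & (mids <= ft + window / 2.0)
        if sel.any():
            out[i] = intervals[sel].mean()
    if np.isnan(out).any():
        if np.isnan(out).all():
            raise ValueError("no interval midpoint falls in any frame window")
        idx = np.arange(out.size)
        good = ~np.isnan(out)
        nearest = idx[good][np.abs(idx[good][None, :] - idx[~good][:, None]).argmin(axis=1)]
        out[~good] = out[nearest]
    return out


# --------------------------------------------------------------------------
# BOLD study
# --------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    """One synthetic run: the BOLD data, its raw recordings, and the truth."""

    bold: BoldRun
    recordings: Dict[str, PhysioRecording]
    truth: GroundTruth
    resp_phase_frames: np.ndarray = field(default=None)  # for locked-component checks


def _gaussian_kernel_samples(latency: float, width: float, tr: float,
                             t_max: float = 40.0) -> np.ndarray:
    t = np.arange(0.0, t_max + 0.5 * tr, tr)
    return np.exp(-((t - latency) ** 2) / (2.0 * width ** 2))


def _causal_conv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    return np.convolve(x, kernel)[: x.size]


#: recordings start this many seconds before the first frame
REC_T0 = -6.0

# population-level response defaults (between-subject distributions)
POP_LATENCY_MEAN = 10.0   # s
POP_LATENCY_SD = 3.0
POP_WIDTH_MEAN = 5.0      # s
POP_WIDTH_SD = 1.0
# relative contamination weights; PETCO2-dominant by default
SIGNAL_WEIGHTS = {"PETCO2": 1.0, "RVT": 0.55, "CRV": 0.55}
#: per-network physiological gain, emulating regional (vascular) heterogeneity
#: of low-frequency physiological effects: the motor analogue (network 1) is
#: weakly affected, the default-mode analogue (network 4) most strongly
NETWORK_PHYSIO_GAIN = (0.6, 1.4, 0.8, 1.6, 1.0, 1.2, 0.9)


def _subject_params(master_seed: int, subject: int, n_gm: int) -> Dict[str, Dict[str, np.ndarray]]:
    rng = _rng(master_seed, _STREAMS["subject"], subject)
    params: Dict[str, Dict[str, np.ndarray]] = {}
    for s in SIGNALS:
        mu = float(np.clip(rng.normal(POP_LATENCY_MEAN, POP_LATENCY_SD), 2.0, 25.0))
        sigma = float(np.clip(rng.normal(POP_WIDTH_MEAN, POP_WIDTH_SD), 2.0, 12.0))
        amp_factor = SIGNAL_WEIGHTS[s] * float(rng.lognormal(0.0, 0.1))
        voxel_jitter = 1.0 + 0.2 * rng.standard_normal(n_gm)
        voxel_jitter = np.clip(voxel_jitter, 0.2, None)
        params[s] = {"mu": mu, "sigma": sigma,
                     "amp": amp_factor * voxel_jitter}
    # subject-level network coupling and within-network voxel weights
    params["_coupling_rng_state"] = rng.integers(0, 2 ** 31)
    return params


def make_bold_study(atlas: NetworkAtlas,
                    n_subjects: int = 8,
                    n_runs: int = 2,
                    tr: float = 2.0,
                    n_frames: int = 240,
                    contamination_scale: float = 0.15,
                    noise_sd: float = 1.0,
                    seed: int = 0,
                    condition: str = "longTR",
                    locked_scale: float = 0.5,
                    network_amp: float = 1.0,
                    coupling_sd: float = 0.15,
                    network_physio_gain: Optional[Sequence[float]] = None,
                    kernel_t_max: float = 40.0) -> List[SimulatedRun]:
    """Generate the full test-retest study for one TR condition.

    ``contamination_scale`` sets the fraction of gray-matter signal variance
    contributed by the low-frequency physiological terms (the generator
    rescales the physiological component per run to hit it); subject-level
    response parameters persist across runs while noise and physiological
    realizations are redrawn, which is exactly what test-retest ICC measures.
    Time-locked cardiac/respiratory components scale with ``locked_scale *
    noise_sd`` so noise-free limits stay exact.
    """
    if not (0.0 <= contamination_scale < 1.0):
        raise ValueError("contamination_scale must lie in [0, 1)")
    cond_key = {"longTR": 0, "shortTR": 1, "shortTR_downsampled": 2}[condition]
    gm = atlas.gm_mask
    n_gm = int(gm.sum())
    gm_labels = atlas.labels[gm]
    if network_physio_gain is None:
        base = NETWORK_PHYSIO_GAIN
        network_physio_gain = tuple(base[k % len(base)] for k in range(atlas.n_networks))
    physio_gain_vox = np.asarray(network_physio_gain, dtype=float)[gm_labels - 1]
    frame_times = np.arange(n_frames) * tr
    duration = n_frames * tr + 6.0 - REC_T0

    runs: List[SimulatedRun] = []
    for subj in range(n_subjects):
        sp = _subject_params(seed, subj, n_gm)
        crng = np.random.default_rng(sp.pop("_coupling_rng_state"))
        coupling = np.clip(crng.normal(1.0, coupling_sd, atlas.n_networks), 0.2, None)
        voxel_weight = np.clip(1.0 + 0.15 * crng.standard_normal(n_gm), 0.2, None)

        alpha_holder = {}   # contamination scale fixed at the subject's first
                            # run, so run-to-run physiological power varies
        for run in range(n_runs):
            bundle = _simulate_run(
                atlas, sp, coupling, voxel_weight, subj, run, cond_key, condition,
                tr, n_frames, frame_times, duration, contamination_scale, noise_sd,
                seed, locked_scale, network_amp, kernel_t_max, gm, n_gm, gm_labels,
                physio_gain_vox, alpha_holder)
            runs.append(bundle)
    return runs


def _simulate_run(atlas, sp, coupling, voxel_weight, subj, run, cond_key, condition,
                  tr, n_frames, frame_times, duration, contamination_scale, noise_sd,
                  seed, locked_scale, network_amp, kernel_t_max, gm, n_gm, gm_labels,
                  physio_gain_vox, alpha_holder) -> SimulatedRun:
    rec_t0 = REC_T0
    # --- physiological recordings (fresh realization per run) -------------
    rng_c = _rng(seed, _STREAMS["cardiac"], subj, run, cond_key)
    rng_r = _rng(seed, _STREAMS["resp"], subj, run, cond_key)
    rng_g = _rng(seed, _STREAMS["co2"], subj, run, cond_key)

    # sessions differ in physiological state: each run draws its own scale
    # for the slow modulation depths (arousal, breathing pattern, CO2 state)
    # lognormal(-sigma^2, sigma) has unit mean square, so the study-average
    # contamination share stays at its calibrated value
    state_r = float(rng_r.lognormal(-0.09, 0.3))
    state_c = float(rng_c.lognormal(-0.09, 0.3))
    state_g = float(rng_g.lognormal(-0.09, 0.3))

    resp_period_mod = random_band_series(rng_r, 0.003, 0.03, 12)
    resp_depth_slow = random_band_series(rng_r, 0.005, 0.04, 16)
    resp_depth_fast = random_band_series(rng_r, 0.04, 0.12, 16)  # breath-to-breath variability
    period_fn = lambda t: np.clip(4.0 * (1.0 + 0.12 * resp_period_mod(t)), 2.5, 7.0)
    depth_fn = lambda t: np.clip(
        2.0 * (1.0 + state_r * (0.25 * resp_depth_slow(t) + 0.32 * resp_depth_fast(t))),
        0.3, None)

    hr_slow = random_band_series(rng_c, 0.005, 0.05, 16)
    hr_fast = random_band_series(rng_c, 0.05, 0.12, 16)
    rsa_phase = rng_c.uniform(0, 2 * np.pi)
    interval_fn = lambda t: 1.0 * (1.0 + state_c * (0.05 * hr_slow(t) + 0.035 * hr_fast(t))
                                   + 0.04 * np.sin(2 * np.pi * t / 4.0 + rsa_phase))

    pet_slow = random_band_series(rng_g, 0.004, 0.05, 12)
    pet_fast = random_band_series(rng_g, 0.04, 0.12, 16)  # breath-to-breath variability
    pet_fn = lambda t: np.clip(
        40.0 + state_g * (2.0 * pet_slow(t) + 2.2 * pet_fast(t)), 28.0, 52.0)

    cardiac, beat_times = make_cardiac_waveform(
        duration, 50.0, interval_fn, seed=int(rng_c.integers(2 ** 31)), t0=rec_t0)
    resp, resp_peaks, rvt_breaths = make_respiratory_waveform(
        duration, 25.0, depth_fn, period_fn, seed=int(rng_r.integers(2 ** 31)), t0=rec_t0)
    co2, co2_peaks, pet_breaths = make_co2_waveform(
        duration, 25.0, pet_fn, period_fn, seed=int(rng_g.integers(2 ** 31)), t0=rec_t0)

    # --- ground-truth regressors on the frame grid -------------------------
    # RVT and PETCO2 are breath-by-breath quantities: the frame-grid truth is
    # the per-breath value linearly interpolated onto the frame times.
    true_crv = windowed_interval_mean(beat_times, frame_times, window=4.0)
    true_rvt = np.interp(frame_times, resp_peaks, rvt_breaths)
    true_pet = np.interp(frame_times, co2_peaks, pet_breaths)
    regressors = {"PETCO2": true_pet, "RVT": true_rvt, "CRV": true_crv}

    # --- components --------------------------------------------------------
    rng_n = _rng(seed, _STREAMS["network"], subj, run, cond_key)
    net_sigs = np.empty((atlas.n_networks, n_frames))
    for k in range(atlas.n_networks):
        sig = random_band_series(rng_n, 0.01, 0.08, 30)(frame_times)
        # realized amplitude is held at the subject's coupling level exactly,
        # so run-to-run variability comes from noise and physiology alone
        net_sigs[k] = network_amp * sig / sig.std()
    neural = (coupling[gm_labels - 1] * voxel_weight)[:, None] * net_sigs[gm_labels - 1]

    # per-signal convolved series, unit variance, scaled by voxel amplitudes
    physio = np.zeros((n_gm, n_frames))
    amp_truth: Dict[str, Dict[str, np.ndarray]] = {}
    conv_units = alpha_holder.setdefault("conv_units", {})
    for s in SIGNALS:
        kern = _gaussian_kernel_samples(sp[s]["mu"], sp[s]["sigma"], tr, kernel_t_max)
        conv = _causal_conv(regressors[s], kern)
        if s not in conv_units:
            # unit scale fixed at the subject's first run: later runs keep
            # their own physiological power
            conv_units[s] = conv.std() or 1.0
        physio += (physio_gain_vox * sp[s]["amp"])[:, None] * (conv / conv_units[s])[None, :]

    rng_l = _rng(seed, _STREAMS["locked"], subj, run, cond_key)
    # frame-grid phases of the quasi-periodic components
    card_phase = _frame_cardiac_phase(beat_times, frame_times)
    t_resp, phi_resp = _phase_track(duration, 25.0, period_fn, t0=rec_t0)
    resp_phase_frames = np.interp(frame_times, t_resp, phi_resp)
    locked_amp = locked_scale * noise_sd
    locked = np.zeros((n_gm, n_frames))
    for phase in (card_phase, resp_phase_frames):
        u = rng_l.standard_normal(n_gm)
        v = rng_l.standard_normal(n_gm)
        locked += locked_amp / np.sqrt(2.0) * (
            u[:, None] * np.cos(phase)[None, :] + v[:, None] * np.sin(phase)[None, :])

    rng_e = _rng(seed, _STREAMS["noise"], subj, run, cond_key)
    noise = noise_sd * rng_e.standard_normal((n_gm, n_frames))

    # --- scale physiology to the requested variance share ------------------
    if "alpha" in alpha_holder:
        alpha = alpha_holder["alpha"]
    else:
        var_rest = (neural.var(axis=1) + locked.var(axis=1) + noise.var(axis=1)).mean()
        var_phys = physio.var(axis=1).mean()
        if contamination_scale > 0 and var_phys > 0:
            alpha = np.sqrt(contamination_scale / (1.0 - contamination_scale)
                            * var_rest / var_phys)
        else:
            alpha = 0.0
        alpha_holder["alpha"] = alpha
    physio *= alpha

    gm_signal = neural + physio + locked + noise
    total_var = gm_signal.var(axis=1).mean()
    shares = {
        "neural": float(neural.var(axis=1).mean()),
        "physio": float(physio.var(axis=1).mean()),
        "locked": float(locked.var(axis=1).mean()),
        "noise": float(noise.var(axis=1).mean()),
        "total": float(total_var),
    }
    shares["cross"] = shares["total"] - (shares["neural"] + shares["physio"]
                                         + shares["locked"] + shares["noise"])

    # assemble the 4-D volume: baseline 100, rim voxels get noise only
    rng_rim = _rng(seed, _STREAMS["noise"], subj, run, cond_key, 99)
    data = np.full(atlas.labels.shape + (n_frames,), 100.0)
    data += noise_sd * rng_rim.standard_normal(data.shape)
    data[gm] = 100.0 + gm_signal

    amp_truth = {
        s: {
            "amplitude": alpha * physio_gain_vox * sp[s]["amp"] / conv_units[s],
            "latency": np.full(n_gm, sp[s]["mu"]),
            "width": np.full(n_gm, sp[s]["sigma"]),
        }
        for s in SIGNALS
    }

    bold = BoldRun(data=data, tr=tr, mask=np.ones(atlas.labels.shape, dtype=bool),
                   subject_id=f"sub-{subj:02d}", run_id=f"run-{run + 1}",
                   condition=condition, frame_times=frame_times,
                   voxel_size=atlas.voxel_size)
    truth = GroundTruth(
        beat_times=beat_times, true_crv=true_crv, true_rvt=true_rvt,
        true_petco2=true_pet, response_params=amp_truth,
        network_signals=net_sigs, noise_sd=noise_sd,
        physio_component=physio.T.copy(), variance_shares=shares)
    return SimulatedRun(bold=bold,
                        recordings={"cardiac": cardiac, "respiratory": resp, "co2": co2},
                        truth=truth, resp_phase_frames=resp_phase_frames)


def _frame_cardiac_phase(beat_times: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Cardiac phase 2*pi*(t - previous beat)/interval at each frame time."""
    beat_times = np.asarray(beat_times, dtype=float)
    idx = np.clip(np.searchsorted(beat_times, frame_times, side="right") - 1,
                  0, len(beat_times) - 2)
    prev = beat_times[idx]
    nxt = beat_times[idx + 1]
    return 2.0 * np.pi * (frame_times - prev) / (nxt - prev)


def make_response_fixture(atlas: NetworkAtlas, n_vox: int = 200,
                          share_per_signal: float = 0.15,
                          tr: float = 0.323, n_frames: int = 1486,
                          condition: str = "shortTR",
                          seed: int = 0) -> Tuple[BoldRun, Dict, Dict]:
    """Synthetic voxels with known Gaussian responses for recovery testing.

    Each voxel responds to all three physiological signals with latency/width
    drawn from the population distributions (snapped to 1-s grid values) and
    an amplitude calibrated so each signal contributes ``share_per_signal`` of
    the voxel's variance — the contamination level reported for end-tidal CO2
    effects on resting-state BOLD. Returns (run, regressors, truth) where
    truth maps each signal to per-voxel latency/width/amplitude and the exact
    contaminating component.
    """
    from .physio import extract_regressors

    sims = make_bold_study(atlas, n_subjects=1, n_runs=1, tr=tr,
                           n_frames=n_frames, seed=seed, condition=condition)
    sim = sims[0]
    ft = sim.bold.frame_times
    pet, rvt, crv = extract_regressors(sim.recordings["cardiac"],
                                       sim.recordings["respiratory"],
                                       sim.recordings["co2"], ft)
    regs = {"PETCO2": pet, "RVT": rvt, "CRV": crv}
    rng = np.random.default_rng(seed + 1)
    t_kernel = np.arange(0.0, 40.0 + 0.5 * tr, tr)
    truth = {s: {"latency": np.clip(np.round(rng.normal(POP_LATENCY_MEAN,
                                                        POP_LATENCY_SD, n_vox)), 2, 25),
                 "width": np.clip(np.round(rng.normal(POP_WIDTH_MEAN,
                                                      POP_WIDTH_SD, n_vox)), 2, 12),
                 "amplitude": np.zeros(n_vox),
                 "component": np.zeros((n_frames, n_vox))}
             for s in SIGNALS}
    Y = rng.standard_normal((n_frames, n_vox))
    denom = 1.0 - 3.0 * share_per_signal
    for s in SIGNALS:
        xc = regs[s].values - regs[s].values.mean()
        for v in range(n_vox):
            kern = np.exp(-((t_kernel - truth[s]["latency"][v]) ** 2)
                          / (2.0 * truth[s]["width"][v] ** 2))
            c = np.convolve(xc, kern)[:n_frames]
            A = np.sqrt(share_per_signal / denom) / c.std()
            if rng.random() >= 0.8:
                A = -A
            truth[s]["amplitude"][v] = A
            truth[s]["component"][:, v] = A * c
            Y[:, v] += A * c
    data = np.zeros((n_vox, 1, 1, n_frames))
    data[:, 0, 0, :] = Y.T
    run = BoldRun(data=data, tr=tr, mask=np.ones((n_vox, 1, 1), dtype=bool),
                  condition=condition)
    return run, regs, truth


def aligned_variance(series: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-voxel variance of ``series`` aligned with a known reference series.

    ``series`` and ``reference`` are (n_frames, n_voxels); the result is
    cov(y, p)^2 / var(p) per voxel — the variance in y explained by p. Used
    to bookkeep how much ground-truth physiological variance survives
    correction.
    """
    y = series - series.mean(axis=0)
    p = reference - reference.mean(axis=0)
    var_p = (p ** 2).mean(axis=0)
    var_p = np.where(var_p > 0, var_p, np.inf)
    cov = (y * p).mean(axis=0)
    return cov ** 2 / var_p
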