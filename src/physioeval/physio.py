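"""Extract low-frequency physiological regressors from raw waveforms.

Three regressors are produced on the BOLD frame grid:

* CRV — cardiac-rate variation: the inter-beat (R-R) interval averaged in a
  centered 4-s window,
* RVT — respiration volume per time: breath depth (peak minus adjacent
  trough) divided by breath period,
* PETCO2 — end-tidal CO2: the breath-by-breath maxima of the CO2 tracing.

Breath-wise series are linearly interpolated onto the frame times; frames
outside the span of defined values take the nearest defined value (the run
edges are not stated anywhere authoritative, so nearest-value extension is
the package's convention). A RETROICOR Fourier design for the time-locked
cardiac/respiratory components is also provided.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy.signal import find_peaks

from .datatypes import EventSeries, PhysioRecording, PhysioRegressor

__all__ = [
    "detect_events",
    "compute_crv",
    "compute_rvt",
    "compute_petco2",
    "retroicor_design",
    "extract_regressors",
]


def detect_events(recording: PhysioRecording, min_separation: float,
                  polarity: str = "maxima",
                  prominence_frac: float = 0.1) -> EventSeries:
    """Locate local extrema separated by at least ``min_separation`` seconds.

    Conflicting candidates are resolved greedily by amplitude (the behaviour
    of :func:`scipy.signal.find_peaks` with a ``distance`` constraint).
    ``prominence_frac`` scales the required prominence by the signal range.
    """
    if min_separation <= 2.0 / recording.fs:
        raise ValueError("min_separation must exceed two sample intervals")
    if polarity not in ("maxima", "minima", "both"):
        raise ValueError(f"unknown polarity {polarity!r}")
    x = recording.samples
    rng_ = float(np.ptp(x))
    if rng_ == 0.0:
        warnings.warn("flat-line recording: no events detected", stacklevel=2)
        return EventSeries(times=np.array([]), kind="breath_peak")
    distance = max(1, int(round(min_separation * recording.fs)))
    prominence = prominence_frac * rng_

    def _peaks(sig):
        idx, _ = find_peaks(sig, distance=distance, prominence=prominence)
        return idx

    if polarity == "maxima":
        idx = _peaks(x)
        kind = "breath_peak"
    elif polarity == "minima":
        idx = _peaks(-x)
        kind = "breath_trough"
    else:
        idx = np.sort(np.concatenate([_peaks(x), _peaks(-x)]))
        kind = "breath_peak"
    times = recording.t0 + idx / recording.fs
    return EventSeries(times=times, kind=kind)


def detect_beats(recording: PhysioRecording,
                 expected_interval: float = 1.0) -> EventSeries:
    """Detect heartbeats with a separation floor of half the expected interval."""
    ev = detect_events(recording, min_separation=0.5 * expected_interval,
                       polarity="maxima", prominence_frac=0.3)
    return EventSeries(times=ev.times, kind="beat")


def compute_crv(beats: EventSeries, frame_times: np.ndarray,
                window: float = 4.0) -> PhysioRegressor:
    """Cardiac-rate variation: windowed mean of inter-beat intervals.

    At frame time t the value is the mean of the R-R intervals whose midpoint
    lies in [t - window/2, t + window/2]; frames whose window contains no
    interval take the nearest defined value.
    """
    if len(beats) < 2:
        raise ValueError("CRV needs at least two beats")
    if window <= 0:
        raise ValueError("window must be positive")
    bt = beats.times
    intervals = np.diff(bt)
    mids = 0.5 * (bt[:-1] + bt[1:])
    frame_times = np.asarray(frame_times, dtype=float)

    # windowed mean via cumulative sums over midpoints sorted in time
    csum = np.concatenate([[0.0], np.cumsum(intervals)])
    lo = np.searchsorted(mids, frame_times - window / 2.0, side="left")
    hi = np.searchsorted(mids, frame_times + window / 2.0, side="right")
    counts = hi - lo
    values = np.full(frame_times.size, np.nan)
    nonempty = counts > 0
    values[nonempty] = (csum[hi[nonempty]] - csum[lo[nonempty]]) / counts[nonempty]
    values = _fill_nearest(values)
    return PhysioRegressor(values=values, kind="CRV", frame_times=frame_times, units="s")


def compute_rvt(resp: PhysioRecording, frame_times: np.ndarray,
                expected_period: float = 4.0) -> PhysioRegressor:
    """Respiration volume per time: breath depth over breath period.

    Per breath peak, depth is the peak height minus the preceding trough
    (the following trough for the first breath) and the period is the spacing
    to the next peak (previous spacing for the last breath); the breath-wise
    ratio is linearly interpolated onto the frame times.
    """
    # breathing depth varies several-fold, so shallow breaths need a low
    # prominence floor relative to the overall signal range
    peaks = detect_events(resp, min_separation=0.5 * expected_period,
                          polarity="maxima", prominence_frac=0.04)
    troughs = detect_events(resp, min_separation=0.5 * expected_period,
                            polarity="minima", prominence_frac=0.04)
    if len(peaks) < 2:
        raise ValueError("RVT needs at least two breath peaks")
    pt, pv = _refine_extrema(resp, peaks.times)
    tt, tv = _refine_extrema(resp, troughs.times)

    # centered estimates: the mean of the adjacent troughs and the half-
    # spacing of the flanking peaks cancel first-order drift in depth/period;
    # breaths missing a flanking trough (run edges) are dropped and their
    # frames take the nearest interior breath value
    depth = np.full(pt.size, np.nan)
    for i, p in enumerate(pt):
        before = np.where(tt < p)[0]
        after = np.where(tt > p)[0]
        if before.size and after.size:
            depth[i] = pv[i] - 0.5 * (tv[before[-1]] + tv[after[0]])
    periods = np.empty(pt.size)
    if pt.size > 2:
        periods[1:-1] = 0.5 * (pt[2:] - pt[:-2])
    periods[0] = pt[1] - pt[0]
    periods[-1] = pt[-1] - pt[-2]
    rvt = depth / periods
    ok = np.isfinite(rvt)
    if ok.sum() < 2:
        raise ValueError("too few complete breaths for RVT")
    pt, rvt = pt[ok], rvt[ok]
    values = np.interp(np.asarray(frame_times, dtype=float), pt, rvt)
    return PhysioRegressor(values=values, kind="RVT",
                           frame_times=np.asarray(frame_times, dtype=float),
                           units="a.u./s")


def compute_petco2(co2: PhysioRecording, frame_times: np.ndarray,
                   expected_period: float = 4.0) -> PhysioRegressor:
    """End-tidal CO2: breath-by-breath maxima of the CO2 tracing,
    linearly interpolated onto the frame grid."""
    peaks = detect_events(co2, min_separation=0.5 * expected_period, polarity="maxima")
    if len(peaks) < 2:
        raise ValueError("PETCO2 needs at least two breaths")
    pt, pv = _refine_extrema(co2, peaks.times)
    values = np.interp(np.asarray(frame_times, dtype=float), pt, pv)
    return PhysioRegressor(values=values, kind="PETCO2",
                           frame_times=np.asarray(frame_times, dtype=float),
                           units="mmHg")


def retroicor_design(beats: EventSeries, resp: PhysioRecording,
                     frame_times: np.ndarray, order: int = 2) -> np.ndarray:
    """Fourier design for time-locked cardiac/respiratory regression.

    Cardiac phase at frame time t is 2*pi*(t - previous beat)/interbeat
    interval; respiratory phase follows the amplitude-histogram convention
    (phase in [-pi, pi], magnitude from the equalized amplitude, sign from the
    slope of the belt signal). Columns are [sin, cos] of harmonics 1..order
    for each of the two signals: 2*2*order columns in total.
    """
    if len(beats) < 2:
        raise ValueError("RETROICOR needs at least two beats")
    frame_times = np.asarray(frame_times, dtype=float)
    bt = beats.times
    if frame_times.min() < bt[0] or frame_times.max() > bt[-1]:
        warnings.warn("frames outside the beat span: cardiac phase extrapolated",
                      stacklevel=2)
    idx = np.clip(np.searchsorted(bt, frame_times, side="right") - 1, 0, len(bt) - 2)
    card_phase = 2.0 * np.pi * (frame_times - bt[idx]) / (bt[idx + 1] - bt[idx])

    resp_phase = _respiratory_phase(resp, frame_times)

    cols = []
    for phase in (card_phase, resp_phase):
        for m in range(1, order + 1):
            cols.append(np.sin(m * phase))
            cols.append(np.cos(m * phase))
    return np.column_stack(cols)


def _respiratory_phase(resp: PhysioRecording, frame_times: np.ndarray) -> np.ndarray:
    """Histogram-equalized respiratory phase (Glover-style convention)."""
    x = resp.samples
    # amplitude normalized to [0, 1]; cumulative histogram gives the equalized value
    order_stat = np.argsort(np.argsort(x))
    equalized = (order_stat + 0.5) / x.size
    slope = np.gradient(x)
    phase = np.pi * equalized * np.sign(slope)
    return np.interp(frame_times, resp.times, phase)


def extract_regressors(cardiac: PhysioRecording, resp: PhysioRecording,
                       co2: PhysioRecording, frame_times: np.ndarray,
                       crv_window: float = 4.0,
                       ) -> Tuple[PhysioRegressor, PhysioRegressor, PhysioRegressor]:
    """Convenience wrapper: (PETCO2, RVT, CRV) regressors from raw recordings."""
    beats = detect_beats(cardiac)
    crv = compute_crv(beats, frame_times, window=crv_window)
    rvt = compute_rvt(resp, frame_times)
    pet = compute_petco2(co2, frame_times)
    return pet, rvt, crv


def _refine_extrema(rec: PhysioRecording, times: np.ndarray,
                    half_window: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    """Sub-sample refinement of extremum times/values.

    A quadratic is least-squares fitted to the samples in a small window
    around each detected extremum; its vertex gives the refined time and
    value. The window averages sensor noise, so the refined value is much
    less biased than the raw extreme sample.
    """
    x = rec.samples
    t = rec.times
    fs = rec.fs
    out_t = np.empty(times.size)
    out_v = np.empty(times.size)
    for j, tt in enumerate(np.asarray(times, dtype=float)):
        i = int(round((tt - rec.t0) * fs))
        lo = max(0, i - half_window)
        hi = min(x.size, i + half_window + 1)
        ts = t[lo:hi] - tt
        coeffs = np.polyfit(ts, x[lo:hi], 2)
        a, b, c = coeffs
        if a == 0:
            out_t[j], out_v[j] = tt, x[i]
            continue
        dt = -b / (2.0 * a)
        dt = float(np.clip(dt, -1.5 / fs, 1.5 / fs))
        out_t[j] = tt + dt
        out_v[j] = a * dt ** 2 + b * dt + c
    # refinement must preserve strict ordering
    keep = np.concatenate([[True], np.diff(out_t) > 0])
    return out_t[keep], out_v[keep]


def _fill_nearest(values: np.ndarray) -> np.ndarray:
    """Replace NaNs by the nearest defined value (edge convention)."""
    out = values.copy()
    bad = np.isnan(out)
    if not bad.any():
        return out
    if bad.all():
        raise ValueError("no defined values to extend from")
    idx = np.arange(out.size)
    good_idx = idx[~bad]
    nearest = good_idx[np.abs(good_idx[None, :] - idx[bad][:, None]).argmin(axis=1)]
    out[bad] = out[nearest]
    return out
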