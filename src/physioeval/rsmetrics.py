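"""Resting-state fMRI measures: ALFF, ReHo, and seed-based connectivity.

* ALFF — mean amplitude of the voxel's Fourier spectrum in 0.01-0.1 Hz,
  computed on temporally unfiltered data; normalized ALFF (nALFF) subtracts
  the global in-mask mean and divides by the global SD so values compare
  across acquisition protocols.
* ReHo — Kendall's coefficient of concordance (W) between each voxel and its
  3x3x3 neighborhood, on band-passed data, with the standard tie correction.
* Seed connectivity — Pearson correlation with the mean signal of a small
  spherical seed ROI, Fisher-transformed to z = atanh(r) * sqrt(n - 3), then
  re-standardized against a fitted Gaussian(null) + Gamma(alternative)
  mixture ("mixture-model correction") before thresholding. The mixture
  absorbs autocorrelation-inflated z scales, which differ strongly between
  fast- and slow-TR protocols.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .datatypes import BinaryMap, BoldRun, MetricMap, MixtureFit

__all__ = [
    "compute_alff",
    "normalize_map",
    "kendalls_w",
    "compute_reho",
    "make_seed_roi",
    "seed_z_map",
    "fit_null_mixture",
    "mixture_correct",
    "binarize",
]


# --------------------------------------------------------------------------
# ALFF
# --------------------------------------------------------------------------

def compute_alff(run: BoldRun, band: Tuple[float, float] = (0.01, 0.1),
                 reduce: str = "mean") -> MetricMap:
    """Amplitude of low-frequency fluctuation per voxel.

    The voxel mean is removed, the one-sided amplitude spectrum is computed,
    and the amplitudes of the frequency bins inside ``band`` are averaged
    (``reduce="sum"`` totals them instead; the mean keeps values comparable
    between protocols with different bin counts). The input run must not be
    band-pass filtered.
    """
    n = run.n_frames
    freqs = np.fft.rfftfreq(n, run.tr)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"no frequency bin falls in {band} Hz at TR={run.tr} s")
    Y = run.masked_series()
    Y = Y - Y.mean(axis=0)
    amp = np.abs(np.fft.rfft(Y, axis=0)) * 2.0 / n
    vals = amp[in_band].sum(axis=0) if reduce == "sum" else amp[in_band].mean(axis=0)
    out = np.zeros(run.mask.shape)
    out[run.mask] = vals
    return MetricMap(values=out, metric="ALFF", mask=run.mask,
                     provenance={"subject": run.subject_id, "run": run.run_id,
                                 "condition": run.condition})


def normalize_map(metric_map: MetricMap, mask: Optional[np.ndarray] = None) -> MetricMap:
    """Global normalization: subtract the in-mask mean, divide by the in-mask SD."""
    mask = metric_map.mask if mask is None else np.asarray(mask, dtype=bool)
    vals = metric_map.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or vals.std() == 0:
        raise ValueError("degenerate map: zero in-mask variance")
    out = metric_map.values.copy()
    out[mask] = (metric_map.values[mask] - vals.mean()) / vals.std()
    metric = "nALFF" if metric_map.metric in ("ALFF", "nALFF") else metric_map.metric
    return MetricMap(values=out, metric=metric, mask=mask,
                     provenance=dict(metric_map.provenance))


# --------------------------------------------------------------------------
# ReHo
# --------------------------------------------------------------------------

def kendalls_w(series_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance for K series over n time points.

    W = 12 S / (K^2 (n^3 - n) - K T), where S is the sum of squared deviations
    of the per-timepoint rank sums and T the usual tie correction
    (sum over tied groups of t^3 - t, totalled over series).
    """
    M = np.asarray(series_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a K x n matrix with K >= 2, n >= 2")
    K, n = M.shape
    ranks = stats.rankdata(M, axis=1, method="average")
    T = sum(_tie_term(row) for row in M)
    denom = K ** 2 * (n ** 3 - n) - K * T
    if denom <= 0:
        raise ValueError("all series constant: W undefined")
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    return float(np.clip(12.0 * S / denom, 0.0, 1.0))


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    ties = counts[counts > 1]
    return float((ties.astype(float) ** 3 - ties).sum())


_NEIGHBOR_OFFSETS = [(dx, dy, dz)
                     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]


def compute_reho(run: BoldRun, mask: Optional[np.ndarray] = None,
                 min_neighbors: int = 7) -> MetricMap:
    """Regional homogeneity: Kendall's W over each voxel's 3x3x3 neighborhood.

    The run should be band-pass filtered to 0.01-0.1 Hz beforehand. The
    neighborhood is restricted to in-mask voxels (K <= 27); voxels with fewer
    than ``min_neighbors`` contributing series are set to NaN.
    """
    mask = run.mask if mask is None else np.asarray(mask, dtype=bool)
    n = run.n_frames
    shape = mask.shape
    ranks = np.zeros(shape + (n,))
    tie = np.zeros(shape)
    ranks[mask] = stats.rankdata(run.data[mask], axis=1, method="average")
    # tie corrections are only nonzero where a voxel's series has repeats
    srt = np.sort(run.data[mask], axis=1)
    has_tie = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
    if has_tie.any():
        vox = np.argwhere(mask)[has_tie]
        for (i, j, k) in vox:
            tie[i, j, k] = _tie_term(run.data[i, j, k])

    rank_sum = np.zeros(shape + (n,))
    tie_sum = np.zeros(shape)
    k_count = np.zeros(shape)
    maskf = mask.astype(float)
    for off in _NEIGHBOR_OFFSETS:
        src, dst = _shift_slices(shape, off)
        rank_sum[dst] += ranks[src] * maskf[src][..., None]
        tie_sum[dst[:3]] += tie[src[:3]] * maskf[src[:3]]
        k_count[dst[:3]] += maskf[src[:3]]

    out = np.full(shape, np.nan)
    valid = mask & (k_count >= min_neighbors)
    K = k_count[valid]
    R = rank_sum[valid]
    S = ((R - R.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    denom = K ** 2 * (n ** 3 - n) - K * tie_sum[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * S / denom, np.nan)
    out[valid] = np.clip(w, 0.0, 1.0)
    return MetricMap(values=out, metric="ReHo", mask=valid,
                     provenance={"subject": run.subject_id, "run": run.run_id,
                                 "condition": run.condition})


def _shift_slices(shape, offset):
    src, dst = [], []
    for dim, off in zip(shape, offset):
        if off >= 0:
            src.append(slice(0, dim - off))
            dst.append(slice(off, dim))
        else:
            src.append(slice(-off, dim))
            dst.append(slice(0, dim + off))
    return tuple(src), tuple(dst)


# --------------------------------------------------------------------------
# seed-based connectivity
# --------------------------------------------------------------------------

def make_seed_roi(center: Sequence[int], voxel_size: Sequence[float],
                  shape: Sequence[int], radius_mm: float = 4.0) -> np.ndarray:
    """Boolean mask of the voxels within ``radius_mm`` of a center voxel
    (at least the center voxel itself)."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, voxel_size))
    roi = d2 <= radius_mm ** 2
    roi[tuple(center)] = True
    return roi


def seed_z_map(run: BoldRun, seed_roi: np.ndarray,
               mask: Optional[np.ndarray] = None) -> MetricMap:
    """Fisher-z map of correlation with the seed ROI's mean time series.

    z = atanh(r) * sqrt(n - 3); |r| is capped just below 1 so identical
    series map to a finite cap. Zero-variance voxels are set to NaN.
    """
    if run.n_frames < 10:
        raise ValueError("need at least 10 frames for a seed correlation map")
    mask = run.mask if mask is None else np.asarray(mask, dtype=bool)
    seed_roi = np.asarray(seed_roi, dtype=bool)
    if not seed_roi.any():
        raise ValueError("empty seed ROI")
    seed = run.data[seed_roi].mean(axis=0)
    seed = seed - seed.mean()
    seed_sd = seed.std()
    if seed_sd == 0:
        raise ValueError("seed signal has zero variance")

    Y = run.data[mask].T
    Y = Y - Y.mean(axis=0)
    sd = Y.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Y * seed[:, None]).mean(axis=0) / (sd * seed_sd)
    r = np.where(sd > 0, r, np.nan)
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    z = np.arctanh(r) * np.sqrt(run.n_frames - 3.0)
    out = np.full(mask.shape, np.nan)
    out[mask] = z
    return MetricMap(values=out, metric="z", mask=mask,
                     provenance={"subject": run.subject_id, "run": run.run_id,
                                 "condition": run.condition})


# --------------------------------------------------------------------------
# mixture-model correction
# --------------------------------------------------------------------------

def fit_null_mixture(z_values: np.ndarray, max_iter: int = 500,
                     tol: float = 1e-6) -> MixtureFit:
    """EM fit of a Gaussian null + positive Gamma alternative to a z sample.

    Initialization is robust (median and 1.4826 * MAD); the Gamma component
    is supported on z > 0 and updated by weighted moment matching. If the
    alternative collapses or EM fails to converge, the robust null is
    returned with a warning.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 500:
        raise ValueError("need at least 500 z values for a stable mixture fit")
    m0 = float(np.median(z))
    s0 = float(1.4826 * np.median(np.abs(z - m0)))
    if s0 <= 0:
        s0 = max(float(z.std()), 1e-6)

    robust = MixtureFit(null_mean=m0, null_sd=s0, null_weight=1.0,
                        alt_shape=np.nan, alt_scale=np.nan,
                        converged=False, n_iter=0, log_likelihood=np.nan)

    tail = z[z > m0 + 2.0 * s0]
    if tail.size < 10:
        return MixtureFit(null_mean=m0, null_sd=s0, null_weight=1.0,
                          alt_shape=np.nan, alt_scale=np.nan,
                          converged=True, n_iter=0,
                          log_likelihood=float(stats.norm.logpdf(z, m0, s0).sum()))
    w1 = tail.size / z.size
    mg, vg = float(tail.mean()), float(max(tail.var(), 1e-6))
    a = float(np.clip(mg ** 2 / vg, 0.5, 200.0))
    th = mg / a
    w0 = 1.0 - w1

    pos = z > 0
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pn = w0 * stats.norm.pdf(z, m0, s0)
        pa = np.zeros_like(z)
        pa[pos] = w1 * stats.gamma.pdf(z[pos], a, scale=th)
        denom = pn + pa
        denom = np.where(denom > 0, denom, np.finfo(float).tiny)
        ll = float(np.log(denom).sum())
        r = pn / denom

        sw = r.sum()
        m0 = float((r * z).sum() / sw)
        s0 = float(np.sqrt(max((r * (z - m0) ** 2).sum() / sw, 1e-12)))
        wa = 1.0 - r
        swa = wa[pos].sum()
        if swa < 1e-8 or wa.sum() / z.size < 1e-4:
            w0, w1 = 1.0, 0.0
            converged = True
            break
        mg = float((wa[pos] * z[pos]).sum() / swa)
        vg = float(max((wa[pos] * (z[pos] - mg) ** 2).sum() / swa, 1e-8))
        a = float(np.clip(mg ** 2 / vg, 0.5, 200.0))
        th = mg / a
        w0 = float(sw / z.size)
        w1 = 1.0 - w0

        if abs(ll - prev_ll) < tol * max(abs(prev_ll), 1.0):
            converged = True
            break
        prev_ll = ll

    if not converged:
        warnings.warn("mixture EM did not converge; falling back to the robust null",
                      stacklevel=2)
        return robust
    return MixtureFit(null_mean=m0, null_sd=s0, null_weight=w0,
                      alt_shape=a if w1 > 0 else np.nan,
                      alt_scale=th if w1 > 0 else np.nan,
                      converged=True, n_iter=it,
                      log_likelihood=ll)


def mixture_correct(z_map: MetricMap, fit: MixtureFit) -> MetricMap:
    """Re-standardize a z-map against its fitted null: (z - m0) / s0."""
    out = z_map.values.copy()
    out[z_map.mask] = (z_map.values[z_map.mask] - fit.null_mean) / fit.null_sd
    return MetricMap(values=out, metric="corrected_z", mask=z_map.mask,
                     provenance=dict(z_map.provenance))


def binarize(metric_map: MetricMap, threshold: float = 0.5,
             mask: Optional[np.ndarray] = None) -> BinaryMap:
    """Threshold a corrected z-map: members are in-mask voxels with value
    strictly above ``threshold`` (ties excluded)."""
    mask = metric_map.mask if mask is None else np.asarray(mask, dtype=bool)
    with np.errstate(invalid="ignore"):
        members = mask & (metric_map.values > threshold)
    return BinaryMap(members=members, threshold_used=threshold)
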