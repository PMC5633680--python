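"""Core in-memory containers for the synthetic physiological-correction study.

Everything downstream (regressor extraction, voxel-wise response fitting, the
rs-fMRI metrics and the quality battery) operates on these light dataclasses.
Arrays are plain numpy; persistence to NIfTI-1 / TSV / JSON lives in
:mod:`physioeval.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "NetworkAtlas",
    "PhysioRecording",
    "EventSeries",
    "PhysioRegressor",
    "BoldRun",
    "GroundTruth",
    "ResponseModel",
    "CorrectionStrategy",
    "STRATEGIES",
    "STRATEGY_NAMES",
    "SIGNALS",
    "MetricMap",
    "BinaryMap",
    "MixtureFit",
]

#: The three low-frequency physiological signals, in canonical order.
SIGNALS: Tuple[str, str, str] = ("PETCO2", "RVT", "CRV")


@dataclass
class NetworkAtlas:
    """Integer-labelled network parcellation on a regular voxel grid.

    ``labels`` is 0 outside gray matter and 1..n_networks inside; the networks
    partition the gray-matter mask.
    """

    labels: np.ndarray            # (x, y, z) int
    gm_mask: np.ndarray           # (x, y, z) bool
    voxel_size: Tuple[float, float, float]  # mm
    n_networks: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.gm_mask = np.asarray(self.gm_mask, dtype=bool)
        if self.labels.shape != self.gm_mask.shape:
            raise ValueError("labels and gm_mask shapes differ")
        if np.any((self.labels > 0) & ~self.gm_mask):
            raise ValueError("positive labels outside the gray-matter mask")

    def network_mask(self, network_id: int) -> np.ndarray:
        return self.labels == network_id


@dataclass
class PhysioRecording:
    """A raw, uniformly sampled physiological waveform."""

    samples: np.ndarray
    fs: float                     # Hz
    kind: str                     # cardiac | respiratory | co2
    t0: float = 0.0               # s, time of first sample

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 2:
            raise ValueError("recording needs at least two samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.fs


@dataclass
class EventSeries:
    """Strictly increasing event times (R peaks, breath peaks/troughs)."""

    times: np.ndarray
    kind: str                     # beat | breath_peak | breath_trough

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class PhysioRegressor:
    """A low-frequency physiological series resampled onto the BOLD frame grid."""

    values: np.ndarray
    kind: str                     # CRV | RVT | PETCO2
    frame_times: np.ndarray       # s
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("regressor length must equal number of frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor contains non-finite values")


@dataclass
class BoldRun:
    """A 4-D BOLD run with its frame grid and in-brain mask."""

    data: np.ndarray              # (x, y, z, t)
    tr: float                     # s
    mask: np.ndarray              # (x, y, z) bool
    subject_id: str = "sub-00"
    run_id: str = "run-1"
    condition: str = "longTR"     # longTR | shortTR | shortTR_downsampled
    frame_times: Optional[np.ndarray] = None
    voxel_size: Tuple[float, float, float] = (3.44, 3.44, 4.6)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        if self.frame_times is None:
            self.frame_times = np.arange(self.data.shape[3]) * self.tr
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.size != self.data.shape[3]:
            raise ValueError("frame_times length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])

    def masked_series(self) -> np.ndarray:
        """Return an (n_frames, n_in-mask-voxels) view of the data."""
        return self.data[self.mask].T.copy()

    def with_data(self, data: np.ndarray, condition: Optional[str] = None,
                  tr: Optional[float] = None,
                  frame_times: Optional[np.ndarray] = None) -> "BoldRun":
        return BoldRun(
            data=data,
            tr=self.tr if tr is None else tr,
            mask=self.mask,
            subject_id=self.subject_id,
            run_id=self.run_id,
            condition=self.condition if condition is None else condition,
            frame_times=self.frame_times if frame_times is None and tr is None else frame_times,
            voxel_size=self.voxel_size,
        )


@dataclass
class GroundTruth:
    """The generator's hidden truth for one run, used only in recovery tests.

    ``physio_component`` holds the actual contaminating time series per in-mask
    voxel so that variance attributable to physiology can be bookkept exactly.
    """

    beat_times: np.ndarray
    true_crv: np.ndarray          # per frame, s
    true_rvt: np.ndarray          # per frame, a.u./s
    true_petco2: np.ndarray       # per frame, mmHg
    response_params: Dict[str, Dict[str, np.ndarray]]  # signal -> {amplitude, latency, width}
    network_signals: np.ndarray   # (n_networks, n_frames)
    noise_sd: float
    physio_component: Optional[np.ndarray] = None   # (n_frames, n_gm_voxels)
    variance_shares: Dict[str, float] = field(default_factory=dict)


@dataclass
class ResponseModel:
    """Per-voxel Gaussian response parameters for the three signals.

    Parameter arrays are indexed over the in-mask voxels of the run the model
    was fitted on (same order as ``BoldRun.masked_series`` columns).
    """

    amplitude: Dict[str, np.ndarray]   # %BOLD per regressor unit
    latency: Dict[str, np.ndarray]     # s
    width: Dict[str, np.ndarray]       # s
    residual_variance: np.ndarray
    r_squared: np.ndarray
    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        for s, w in self.width.items():
            if np.any(np.asarray(w) <= 0):
                raise ValueError(f"non-positive response width for {s}")


@dataclass(frozen=True)
class CorrectionStrategy:
    """One of the eight correction combinations."""

    name: str
    included_signals: Tuple[str, ...]


STRATEGIES: Dict[str, CorrectionStrategy] = {
    "Base": CorrectionStrategy("Base", ()),
    "PETCO2": CorrectionStrategy("PETCO2", ("PETCO2",)),
    "CRV": CorrectionStrategy("CRV", ("CRV",)),
    "RVT": CorrectionStrategy("RVT", ("RVT",)),
    "PETCO2+CRV": CorrectionStrategy("PETCO2+CRV", ("PETCO2", "CRV")),
    "PETCO2+RVT": CorrectionStrategy("PETCO2+RVT", ("PETCO2", "RVT")),
    "CRV+RVT": CorrectionStrategy("CRV+RVT", ("CRV", "RVT")),
    "All": CorrectionStrategy("All", ("PETCO2", "RVT", "CRV")),
}

STRATEGY_NAMES = tuple(STRATEGIES)


@dataclass
class MetricMap:
    """A 3-D metric field (ALFF, nALFF, ReHo, z, corrected_z) with provenance."""

    values: np.ndarray
    metric: str
    mask: np.ndarray
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("metric map and mask shapes differ")

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class BinaryMap:
    """A thresholded (0/1) map, e.g. a suprathreshold connectivity map."""

    members: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.members.sum())


@dataclass
class MixtureFit:
    """Fitted null (Gaussian) + alternative (Gamma) mixture for a z-map."""

    null_mean: float
    null_sd: float
    null_weight: float
    alt_shape: float
    alt_scale: float
    converged: bool
    n_iter: int
    log_likelihood: float

    def __post_init__(self) -> None:
        if self.null_sd <= 0:
            raise ValueError("null sd must be positive")
        if not (0.0 <= self.null_weight <= 1.0):
            raise ValueError("null weight must lie in [0, 1]")
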