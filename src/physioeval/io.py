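"""Standard-format persistence: NIfTI-1 runs and maps, TSV waveforms and
regressors, JSON for fits, truth, and manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import BoldRun, MetricMap, PhysioRecording, PhysioRegressor, ResponseModel

__all__ = [
    "save_bold",
    "load_bold",
    "io_roundtrip",
    "save_waveform",
    "load_waveform",
    "save_regressors",
    "load_regressors",
    "save_map",
    "save_response_model",
    "save_json",
    "sha256_of",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_bold(run: BoldRun, path: Union[str, Path]) -> Path:
    """Write a run as NIfTI-1 (float32, TR in the header) plus a mask image
    and a JSON sidecar with provenance."""
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(run.voxel_size))
    img.header.set_zooms(tuple(run.voxel_size) + (run.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    base = path.name.split(".")[0]
    mask_img = nib.Nifti1Image(run.mask.astype(np.uint8), _affine(run.voxel_size))
    nib.save(mask_img, str(path.parent / f"{base}_mask.nii.gz"))
    sidecar = {
        "subject_id": run.subject_id,
        "run_id": run.run_id,
        "condition": run.condition,
        "tr": run.tr,
        "t0": float(run.frame_times[0]),
    }
    (path.parent / f"{base}.json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_bold(path: Union[str, Path]) -> BoldRun:
    path = Path(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    base = path.name.split(".")[0]
    mask_path = path.parent / f"{base}_mask.nii.gz"
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    else:
        mask = np.ones(img.shape[:3], dtype=bool)
    meta = {}
    sidecar = path.parent / f"{base}.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    t0 = float(meta.get("t0", 0.0))
    data = np.asarray(img.dataobj, dtype=np.float64)
    return BoldRun(
        data=data, tr=tr, mask=mask,
        subject_id=meta.get("subject_id", "sub-00"),
        run_id=meta.get("run_id", "run-1"),
        condition=meta.get("condition", "longTR"),
        frame_times=t0 + np.arange(data.shape[3]) * tr,
        voxel_size=tuple(float(z) for z in zooms[:3]))


def io_roundtrip(run: BoldRun, workdir: Union[str, Path]) -> BoldRun:
    """Write a run to NIfTI and read it back (float32 precision, TR and mask
    preserved); raises on header/data inconsistency."""
    path = Path(workdir) / f"{run.subject_id}_{run.run_id}_{run.condition}.nii.gz"
    save_bold(run, path)
    back = load_bold(path)
    if back.data.shape != run.data.shape:
        raise ValueError("round-trip changed the data shape")
    return back


def save_waveform(rec: PhysioRecording, path: Union[str, Path]) -> Path:
    """Two-column TSV (time_s, value) with '# fs=<Hz>' and '# kind=' headers."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n# kind={rec.kind}\n# t0={rec.t0}\n")
        fh.write("time_s\tvalue\n")
        for t, v in zip(rec.times, rec.samples):
            fh.write(f"{t:.6f}\t{v:.8g}\n")
    return path


def load_waveform(path: Union[str, Path]) -> PhysioRecording:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return PhysioRecording(samples=df["value"].to_numpy(),
                           fs=float(meta["fs"]), kind=meta.get("kind", "unknown"),
                           t0=float(meta.get("t0", 0.0)))


def save_regressors(regs: Dict[str, PhysioRegressor], path: Union[str, Path]) -> Path:
    """Per-run TSV: frame index, time_s, then one column per regressor."""
    path = Path(path)
    first = next(iter(regs.values()))
    df = pd.DataFrame({"frame": np.arange(first.values.size),
                       "time_s": first.frame_times})
    for name, reg in regs.items():
        df[name] = reg.values
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def load_regressors(path: Union[str, Path]) -> Dict[str, PhysioRegressor]:
    df = pd.read_csv(path, sep="\t")
    ft = df["time_s"].to_numpy()
    out = {}
    for col in df.columns:
        if col in ("frame", "time_s"):
            continue
        out[col] = PhysioRegressor(values=df[col].to_numpy(), kind=col, frame_times=ft)
    return out


def save_map(metric_map: MetricMap, path: Union[str, Path],
             voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(metric_map.values.astype(np.float32), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def save_response_model(model: ResponseModel, mask: np.ndarray,
                        outdir: Union[str, Path],
                        voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    """Three parameter maps (amplitude/latency/width) per signal as NIfTI plus
    a JSON fit summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in model.amplitude:
        for pname, arr in (("amplitude", model.amplitude[s]),
                           ("latency", model.latency[s]),
                           ("width", model.width[s])):
            vol = np.zeros(mask.shape, dtype=np.float32)
            vol[mask] = arr
            nib.save(nib.Nifti1Image(vol, _affine(voxel_size)),
                     str(outdir / f"response_{s}_{pname}.nii.gz"))
    summary = {
        "median_r_squared": float(np.median(model.r_squared)),
        "mu_grid": model.mu_grid.tolist(),
        "sigma_grid": model.sigma_grid.tolist(),
        "tr": model.tr,
    }
    (outdir / "response_summary.json").write_text(json.dumps(summary, indent=2))
    return outdir


def save_json(obj, path: Union[str, Path]) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path


def sha256_of(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
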