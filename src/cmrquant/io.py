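"""Readers and writers for the pipeline's standard formats.

Image series travel as NIfTI-1 volumes (float32) with a JSON sidecar
carrying per-frame timing (``inversion_times_ms`` for MOLLI stacks,
``frame_times_s`` for dynamic perfusion series) and the pixel spacing, or
as a DICOM directory (read-only) whose per-frame InversionTime /
TriggerTime tags supply the same metadata.  Cohorts are plain CSV with a
header.  Arrays are row-major with pixel (0, 0) at top-left; stacks are
``(n_frames, rows, cols)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import yaml

from .cohort import COHORT_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class ImageSeries:
    """An image stack plus per-frame timing metadata."""

    stack: np.ndarray  # (n_frames, rows, cols)
    frame_times: np.ndarray  # ms (inversion times) or s (dynamic)
    kind: str  # "molli" or "dynamic"
    pixel_spacing: float = 1.0  # mm


def _sidecar_path(nifti_path: Path) -> Path:
    name = nifti_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return nifti_path.with_name(name[: -len(suffix)] + ".json")
    raise ValueError(f"{nifti_path} is not a NIfTI file")


def write_image_series(path, series: ImageSeries) -> Path:
    """Write a stack as NIfTI + JSON sidecar; returns the NIfTI path.

    The stack is stored with frames along the last NIfTI axis (rows, cols,
    n_frames) per convention, float32, with the pixel spacing in the
    affine/zooms and the units (ms T1 / s frame time) noted in the header
    description.
    """
    path = Path(path)
    data = np.moveaxis(np.asarray(series.stack, dtype=np.float32), 0, -1)
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = (
        b"MOLLI stack, TI in sidecar (ms)" if series.kind == "molli" else b"dynamic stack, t in sidecar (s)"
    )
    nib.save(img, str(path))
    key = "inversion_times_ms" if series.kind == "molli" else "frame_times_s"
    sidecar = {
        key: [float(t) for t in series.frame_times],
        "kind": series.kind,
        "pixel_spacing_mm": series.pixel_spacing,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def write_map(path, values: np.ndarray, pixel_spacing: float = 1.0, descrip: str = "") -> Path:
    """Write a single 2-D parameter map (T1/ECV/perfusion) as NIfTI float32."""
    path = Path(path)
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))
    return path


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _read_nifti_series(path: Path) -> ImageSeries:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D stack, got shape {data.shape}")
    stack = np.moveaxis(data, -1, 0)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"timing sidecar {sidecar_file} is missing")
    meta = json.loads(sidecar_file.read_text())
    if "inversion_times_ms" in meta:
        times, kind = meta["inversion_times_ms"], "molli"
    elif "frame_times_s" in meta:
        times, kind = meta["frame_times_s"], "dynamic"
    else:
        raise ValueError(f"{sidecar_file}: no inversion_times_ms or frame_times_s entry")
    times = np.asarray(times, dtype=float)
    if len(times) != stack.shape[0]:
        raise ValueError(
            f"sidecar lists {len(times)} frames but the stack has {stack.shape[0]}"
        )
    if kind == "dynamic":
        d = np.diff(times)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("dynamic frame times must be a uniform increasing grid")
    spacing = float(meta.get("pixel_spacing_mm", img.header.get_zooms()[0]))
    return ImageSeries(stack=stack, frame_times=times, kind=kind, pixel_spacing=spacing)


def _read_dicom_series(path: Path) -> ImageSeries:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ".ima", ""})
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM stray file
            continue
    if not datasets:
        raise ValueError(f"{path}: no readable DICOM files")
    orientations = {tuple(np.round(np.asarray(d.get("ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float), 4)) for d in datasets}
    if len(orientations) > 1:
        raise ValueError(f"{path}: mixed image orientations in series")
    if all(d.get("InversionTime") is not None for d in datasets):
        kind = "molli"
        times = np.asarray([float(d.InversionTime) for d in datasets])
    elif all(d.get("TriggerTime") is not None for d in datasets):
        kind = "dynamic"
        times = np.asarray([float(d.TriggerTime) / 1000.0 for d in datasets])  # ms -> s
    else:
        raise ValueError(f"{path}: frames lack InversionTime/TriggerTime metadata")
    order = np.argsort(times, kind="stable")
    stack = np.stack([datasets[i].pixel_array.astype(float) for i in order])
    spacing = float(datasets[0].get("PixelSpacing", [1.0, 1.0])[0])
    return ImageSeries(stack=stack, frame_times=times[order], kind=kind, pixel_spacing=spacing)


def read_image_series(path) -> ImageSeries:
    """Read a NIfTI(+sidecar) stack or a DICOM directory; frames time-ordered."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti_series(path)


def write_cohort_csv(path, cohort: pd.DataFrame) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table; hematocrit given in percent is converted.

    Any ``hct`` value above 1 is interpreted as percent and divided by 100
    (logged), so both the fraction and the percent conventions load to the
    same in-memory fraction.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {missing}")
    if "hct" in df.columns and (df["hct"] > 1).any():
        n = int((df["hct"] > 1).sum())
        logger.info("interpreting %d hct values > 1 as percent", n)
        df.loc[df["hct"] > 1, "hct"] = df.loc[df["hct"] > 1, "hct"] / 100.0
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        logger.info("cohort CSV has extra columns: %s", extra)
    return df


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_report_json(path, report: dict) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserialisable {type(o)}")

    path.write_text(json.dumps(report, indent=1, default=default))
    return path
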