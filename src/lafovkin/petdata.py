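"""Core data containers and I/O for dynamic PET data.

Conventions used throughout the package:

* activity concentration is stored in kBq/mL,
* time is seconds at every I/O boundary (frame schedules, sidecars, TSV
  curves) and minutes inside the kinetic code,
* rate constants are per minute; ``K1`` is carried as mL·min⁻¹·mL⁻¹ and
  converted to mL/(min·dL) only when printing,
* a TAC sample refers to the frame *midpoint*,
* images are assumed decay-corrected to injection time by the scanner
  reconstruction; no decay handling happens here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TAC",
    "InputFunction",
    "DynamicImage",
    "LabelImage",
    "SubjectMeta",
    "frame_midpoints",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_label_image",
    "write_label_image",
    "roi_tac",
    "read_tac",
    "write_tac",
    "read_input_function",
    "write_input_function",
    "write_results_table",
    "read_results_table",
    "k1_to_ml_min_dl",
    "RESULT_COLUMNS",
]

_SCHEDULE_TOL = 1e-6


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing grid: per-frame start and duration in seconds."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise ValueError("start_s and duration_s must be 1-D and of equal length")
        if start.size < 1:
            raise ValueError("schedule needs at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise ValueError("frame times must be finite")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[:-1] + dur[:-1] > start[1:] + _SCHEDULE_TOL):
            raise ValueError("frames overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @classmethod
    def from_durations(cls, durations_s, t0_s: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(durations_s, dtype=float)
        start = t0_s + np.concatenate([[0.0], np.cumsum(dur[:-1])])
        return cls(start, dur)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoints in seconds: ``start + duration / 2``."""
    return schedule.mid_s


@dataclass(frozen=True)
class TAC:
    """Time-activity curve sampled on a frame schedule (kBq/mL)."""

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ValueError(
                f"TAC has {values.size} values but schedule has "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")

    @property
    def mid_s(self) -> np.ndarray:
        return self.schedule.mid_s


@dataclass(frozen=True)
class InputFunction:
    """Arterial (blood or plasma) input curve with its applied delay state.

    ``delay_s`` records the shift already applied to the curve; models treat
    the stored samples as the delay-corrected input.
    """

    tac: TAC
    matrix: str = "whole_blood"
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.matrix not in ("whole_blood", "plasma"):
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if not np.isfinite(self.delay_s):
            raise ValueError("delay_s must be finite")

    @property
    def values(self) -> np.ndarray:
        return self.tac.values

    @property
    def schedule(self) -> FrameSchedule:
        return self.tac.schedule

    def with_values(self, values, **kw) -> "InputFunction":
        return replace(self, tac=replace(self.tac, values=np.asarray(values, float)), **kw)


@dataclass(frozen=True)
class DynamicImage:
    """4-D dynamic PET volume (x, y, z, frame) in kBq/mL."""

    voxels: np.ndarray
    voxel_size_mm: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        vs = np.asarray(self.voxel_size_mm, dtype=float)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size_mm", vs)
        if vox.ndim != 4:
            raise ValueError("voxels must be 4-D (x, y, z, frame)")
        if vox.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"image has {vox.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValueError("voxel_size_mm must be three positive values")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass(frozen=True)
class LabelImage:
    """3-D integer organ segmentation; 0 is background."""

    labels: np.ndarray
    names: Mapping[int, str]
    voxel_size_mm: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        vs = np.asarray(self.voxel_size_mm, dtype=float)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "names", dict(self.names))
        if lab.ndim != 3:
            raise ValueError("labels must be 3-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def mask(self, label: int | str) -> np.ndarray:
        return self.labels == self.index_of(label)

    def index_of(self, label: int | str) -> int:
        if isinstance(label, str):
            for idx, name in self.names.items():
                if name == label:
                    return idx
            raise KeyError(f"no region named {label!r}")
        return int(label)


@dataclass(frozen=True)
class SubjectMeta:
    """Subject-level quantities needed for SUV and glucose-uptake scaling."""

    injected_dose_MBq: float
    weight_kg: float
    tracer: str
    hematocrit: float | None = None
    plasma_glucose_mmol_L: float | None = None

    def __post_init__(self) -> None:
        if self.injected_dose_MBq <= 0 or self.weight_kg <= 0:
            raise ValueError("injected dose and weight must be positive")
        if self.tracer not in ("H2O", "FDG"):
            raise ValueError(f"unknown tracer {self.tracer!r}")
        if self.hematocrit is not None and not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must lie in (0, 1)")


def k1_to_ml_min_dl(k1_ml_min_ml: float) -> float:
    """Convert K1 from mL·min⁻¹·mL⁻¹ to the printed unit mL/(min·dL)."""
    return 100.0 * k1_ml_min_ml


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O (BIDS-PET style key names)
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_dynamic_image(img: DynamicImage, path_nifti, path_sidecar=None,
                        meta: SubjectMeta | None = None) -> None:
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32),
                          _affine(img.voxel_size_mm))
    nib.save(nii, str(path_nifti))
    if path_sidecar is not None:
        sidecar = {
            "FrameTimesStart": img.schedule.start_s.tolist(),
            "FrameDuration": img.schedule.duration_s.tolist(),
        }
        if meta is not None:
            sidecar.update(
                InjectedRadioactivity=meta.injected_dose_MBq,
                InjectedRadioactivityUnits="MBq",
                BodyWeight=meta.weight_kg,
                TracerName=meta.tracer,
            )
            if meta.hematocrit is not None:
                sidecar["Hematocrit"] = meta.hematocrit
            if meta.plasma_glucose_mmol_L is not None:
                sidecar["PlasmaGlucose"] = meta.plasma_glucose_mmol_L
        Path(path_sidecar).write_text(json.dumps(sidecar, indent=1))


def read_dynamic_image(path_nifti, path_sidecar) -> DynamicImage:
    """Load a 4-D PET NIfTI with its JSON sidecar (frame timing)."""
    nii = nib.load(str(path_nifti))
    data = np.asarray(nii.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {data.shape}")
    sidecar = json.loads(Path(path_sidecar).read_text())
    schedule = FrameSchedule(np.asarray(sidecar["FrameTimesStart"], float),
                             np.asarray(sidecar["FrameDuration"], float))
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"image has {data.shape[3]} frames but sidecar lists "
            f"{schedule.n_frames}"
        )
    voxel_size = np.asarray(nii.header.get_zooms()[:3], float)
    return DynamicImage(data, voxel_size, schedule)


def read_subject_meta(path_sidecar) -> SubjectMeta:
    sidecar = json.loads(Path(path_sidecar).read_text())
    return SubjectMeta(
        injected_dose_MBq=float(sidecar["InjectedRadioactivity"]),
        weight_kg=float(sidecar["BodyWeight"]),
        tracer=str(sidecar["TracerName"]),
        hematocrit=sidecar.get("Hematocrit"),
        plasma_glucose_mmol_L=sidecar.get("PlasmaGlucose"),
    )


def write_label_image(seg: LabelImage, path_nifti, path_names=None) -> None:
    nii = nib.Nifti1Image(np.asarray(seg.labels, dtype=np.int16),
                          _affine(seg.voxel_size_mm))
    nib.save(nii, str(path_nifti))
    if path_names is not None:
        Path(path_names).write_text(
            json.dumps({str(k): v for k, v in seg.names.items()}, indent=1))


def read_label_image(path_nifti, path_names=None) -> LabelImage:
    nii = nib.load(str(path_nifti))
    labels = np.asarray(nii.dataobj).astype(np.int32)
    voxel_size = np.asarray(nii.header.get_zooms()[:3], float)
    if path_names is not None:
        names = {int(k): v for k, v in
                 json.loads(Path(path_names).read_text()).items()}
    else:
        names = {int(v): f"label{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelImage(labels, names, voxel_size)


# ---------------------------------------------------------------------------
# Regional TAC extraction
# ---------------------------------------------------------------------------

def roi_tac(img: DynamicImage, roi: LabelImage, label: int | str) -> TAC:
    """Per-frame mean activity over the voxels carrying ``label``."""
    if img.shape3 != roi.labels.shape:
        raise ValueError(
            f"image grid {img.shape3} does not match label grid "
            f"{roi.labels.shape}"
        )
    if not np.allclose(img.voxel_size_mm, roi.voxel_size_mm):
        raise ValueError("image and label voxel sizes differ")
    mask = roi.mask(label)
    if not mask.any():
        raise ValueError(f"ROI {label!r} is empty")
    values = np.asarray(img.voxels[mask], dtype=float).mean(axis=0)
    name = roi.names.get(roi.index_of(label), str(label))
    return TAC(img.schedule, values, label=name)


# ---------------------------------------------------------------------------
# TSV curves and results tables
# ---------------------------------------------------------------------------

def write_tac(tac: TAC, path) -> None:
    pd.DataFrame({
        "frame_start_s": tac.schedule.start_s,
        "frame_duration_s": tac.schedule.duration_s,
        "value_kBq_mL": tac.values,
        "region": tac.label,
    }).to_csv(path, sep="\t", index=False)


def read_tac(path) -> TAC:
    df = pd.read_csv(path, sep="\t")
    schedule = FrameSchedule(df["frame_start_s"].to_numpy(),
                             df["frame_duration_s"].to_numpy())
    label = str(df["region"].iloc[0]) if "region" in df and len(df) else ""
    return TAC(schedule, df["value_kBq_mL"].to_numpy(), label=label)


def write_input_function(inp: InputFunction, path) -> None:
    df = pd.DataFrame({
        "frame_start_s": inp.schedule.start_s,
        "frame_duration_s": inp.schedule.duration_s,
        "value_kBq_mL": inp.values,
        "matrix": inp.matrix,
        "delay_s": inp.delay_s,
    })
    df.to_csv(path, sep="\t", index=False)


def read_input_function(path) -> InputFunction:
    df = pd.read_csv(path, sep="\t")
    schedule = FrameSchedule(df["frame_start_s"].to_numpy(),
                             df["frame_duration_s"].to_numpy())
    return InputFunction(
        TAC(schedule, df["value_kBq_mL"].to_numpy(), label="input"),
        matrix=str(df["matrix"].iloc[0]),
        delay_s=float(df["delay_s"].iloc[0]),
    )


RESULT_COLUMNS = ["subject", "region", "parameter", "value", "units",
                  "R2", "volume_mL"]


def write_results_table(rows, path) -> pd.DataFrame:
    """Write regional results as a TSV with fixed columns and ordering.

    Rows (mappings or a DataFrame) must provide every column in
    ``RESULT_COLUMNS``; output is sorted by (subject, region, parameter) so
    repeated runs produce byte-identical tables.
    """
    df = pd.DataFrame(list(rows), columns=RESULT_COLUMNS if not len(list(rows)) else None) \
        if not isinstance(rows, pd.DataFrame) else rows.copy()
    if df.empty:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results rows are missing columns: {missing}")
    df = df[RESULT_COLUMNS].sort_values(
        ["subject", "region", "parameter"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
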