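"""Motion handling and ROI utilities.

Covers the preprocessing rules defined around the kinetic core: start- and
reference-frame selection, normalized cross-correlation, the synthetic
dynamic reference used for rigid IDIF motion correction, rigid registration
itself, ROI trimming by morphological erosion, and the per-ROI motion QC
metric. Whole-body diffeomorphic motion correction is out of scope — it is
an external tool in the workflow this package supports.

Rigid transforms rotate about the image centre; rotations follow the
x-y-z Euler convention with angles in degrees and translations in mm.
The motion metric tracks, per ROI, the voxel at the mean x-, maximum y- and
maximum z-coordinate (in voxel-index space converted to mm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .petdata import TAC, DynamicImage, LabelImage

__all__ = [
    "Transform6DOF",
    "MotionTrace",
    "RegistrationResult",
    "ncc",
    "select_start_frame",
    "select_reference_frame",
    "synthetic_reference",
    "apply_transform",
    "rigid_register",
    "trim_roi",
    "motion_metric",
]


@dataclass(frozen=True)
class Transform6DOF:
    """Rigid transform: translation (mm) and rotation (deg, about centre)."""

    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        t = np.asarray(self.translation_mm, float)
        r = np.asarray(self.rotation_deg, float)
        object.__setattr__(self, "translation_mm", t)
        object.__setattr__(self, "rotation_deg", r)
        if t.shape != (3,) or r.shape != (3,):
            raise ValueError("translation and rotation must each have 3 values")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("transform parameters must be finite")

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.translation_mm == 0)
                    and np.all(self.rotation_deg == 0))

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg,
                                   degrees=True).as_matrix()

    def apply_point(self, p_mm: np.ndarray, centre_mm: np.ndarray) -> np.ndarray:
        return self.matrix() @ (np.asarray(p_mm, float) - centre_mm) \
            + centre_mm + self.translation_mm

    def to_dict(self) -> dict:
        return {"translation_mm": self.translation_mm.tolist(),
                "rotation_deg": self.rotation_deg.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Transform6DOF":
        return cls(np.asarray(d["translation_mm"], float),
                   np.asarray(d["rotation_deg"], float))


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame Euclidean displacement (mm) of a tracked ROI voxel."""

    roi: str
    displacement_mm: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_mm, float)
        object.__setattr__(self, "displacement_mm", d)
        if np.any(d < 0):
            raise ValueError("displacements must be non-negative")


def save_transforms(transforms, centre_mm, path) -> None:
    Path(path).write_text(json.dumps({
        "centre_mm": np.asarray(centre_mm, float).tolist(),
        "frames": [t.to_dict() for t in transforms],
    }, indent=1))


def load_transforms(path):
    data = json.loads(Path(path).read_text())
    return [Transform6DOF.from_dict(d) for d in data["frames"]], \
        np.asarray(data["centre_mm"], float)


# ---------------------------------------------------------------------------
# Similarity and frame selection
# ---------------------------------------------------------------------------

def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of intensities over the mask; in [−1, 1]."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("NCC undefined: fewer than 2 voxels or zero variance")
    am, bm = a - a.mean(), b - b.mean()
    return float(np.dot(am, bm) / (np.linalg.norm(am) * np.linalg.norm(bm)))


def select_start_frame(heart_tac: TAC, tracer: str,
                       img: DynamicImage | None = None,
                       reference_index: int | None = None,
                       ncc_threshold: float = 0.8) -> int:
    """Motion-correction start frame.

    Radiowater: first frame after the heart-curve peak whose value falls
    below half of the peak. FDG: first frame whose NCC against the
    reference frame exceeds ``ncc_threshold``. If the criterion is never
    met, the last frame is returned with a warning.
    """
    v = heart_tac.values
    if not np.any(v != 0):
        raise ValueError("heart TAC is identically zero")
    n = v.size
    if tracer == "H2O":
        peak = int(np.argmax(v))
        for i in range(peak + 1, n):
            if v[i] < 0.5 * v[peak]:
                return i
    elif tracer == "FDG":
        if img is None or reference_index is None:
            raise ValueError("FDG start-frame rule needs the image and a "
                             "reference frame index")
        ref = np.asarray(img.voxels[..., reference_index], float)
        for i in range(n):
            if ncc(np.asarray(img.voxels[..., i], float), ref) > ncc_threshold:
                return i
    else:
        raise ValueError(f"unknown tracer {tracer!r}")
    warnings.warn("start-frame criterion never met; using the last frame",
                  stacklevel=2)
    return n - 1


def select_reference_frame(img: DynamicImage, ct_like: np.ndarray) -> int:
    """Frame with the highest NCC against the CT-like image (ties → later)."""
    best, best_ncc = 0, -np.inf
    for i in range(img.schedule.n_frames):
        try:
            c = ncc(np.asarray(img.voxels[..., i], float), ct_like)
        except ValueError:
            continue
        if c >= best_ncc:
            best, best_ncc = i, c
    return best


def synthetic_reference(seg: LabelImage, roi_tacs, frame: int) -> np.ndarray:
    """Noise-free reference frame painted from the segmentation and TACs.

    Each voxel takes its organ's TAC value at ``frame``; background is 0.
    ``roi_tacs`` maps label index or organ name to a :class:`TAC`.
    """
    resolved = {seg.index_of(k): tac for k, tac in roi_tacs.items()}
    out = np.zeros(seg.labels.shape, float)
    for lab in np.unique(seg.labels):
        if lab == 0:
            continue
        if int(lab) not in resolved:
            raise ValueError(
                f"no TAC for label {int(lab)} ({seg.names.get(int(lab))})")
        out[seg.labels == lab] = resolved[int(lab)].values[frame]
    return out


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def _centre_mm(shape, voxel_size_mm) -> np.ndarray:
    return (np.asarray(shape, float) - 1.0) / 2.0 * np.asarray(voxel_size_mm, float)


def apply_transform(vol: np.ndarray, transform: Transform6DOF,
                    voxel_size_mm, order: int = 1) -> np.ndarray:
    """Resample ``vol`` under a rigid transform (trilinear, border 0)."""
    vs = np.asarray(voxel_size_mm, float)
    S = np.diag(vs)
    Sinv = np.diag(1.0 / vs)
    R = transform.matrix()
    c = _centre_mm(vol.shape, vs)
    t = transform.translation_mm
    # output voxel v maps back to input voxel Rᵀ(S v − c − t) + c, in mm
    M = Sinv @ R.T @ S
    offset = Sinv @ (c - R.T @ (c + t))
    return ndimage.affine_transform(np.asarray(vol, float), M, offset=offset,
                                    order=order, mode="constant", cval=0.0)


@dataclass(frozen=True)
class RegistrationResult:
    transform: Transform6DOF
    ncc: float
    improved: bool


def _downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    sm = ndimage.gaussian_filter(vol, sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def rigid_register(moving: np.ndarray, fixed: np.ndarray, voxel_size_mm,
                   init: Transform6DOF | None = None,
                   mask: np.ndarray | None = None,
                   levels: tuple[int, ...] = (2, 1)) -> RegistrationResult:
    """Find the rigid transform maximizing NCC(apply(T, moving), fixed).

    Deterministic multi-resolution Powell search (coarse-to-fine pyramid);
    if the optimizer fails to improve on the initial transform, the initial
    transform is returned with ``improved=False``.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share a grid")
    vs = np.asarray(voxel_size_mm, float)
    init = init or Transform6DOF()
    x = np.concatenate([init.translation_mm, init.rotation_deg])

    def objective(params, mov, fix, vsz, msk):
        t = Transform6DOF(params[:3], params[3:])
        warped = apply_transform(mov, t, vsz)
        try:
            return -ncc(warped, fix, msk)
        except ValueError:
            return 1.0

    for factor in levels:
        if factor > 1:
            mov = _downsample(moving, factor)
            fix = _downsample(fixed, factor)
            msk = None if mask is None else mask[::factor, ::factor, ::factor]
            vsz = vs * factor
        else:
            mov, fix, msk, vsz = moving, fixed, mask, vs
        res = minimize(objective, x, args=(mov, fix, vsz, msk),
                       method="Powell",
                       options={"xtol": 0.05, "ftol": 1e-7, "maxiter": 60})
        x = res.x

    final = Transform6DOF(x[:3], x[3:])
    ncc_init = -objective(np.concatenate([init.translation_mm,
                                          init.rotation_deg]),
                          moving, fixed, vs, mask)
    ncc_final = -objective(x, moving, fixed, vs, mask)
    if ncc_final < ncc_init:
        return RegistrationResult(init, float(ncc_init), improved=False)
    return RegistrationResult(final, float(ncc_final), improved=True)


# ---------------------------------------------------------------------------
# ROI trimming and motion QC
# ---------------------------------------------------------------------------

def trim_roi(mask: np.ndarray, distance_mm: float, voxel_size_mm,
             name: str = "ROI") -> np.ndarray:
    """Erode a mask by ``distance_mm`` using a spherical structuring element.

    Implemented as a Euclidean distance-transform threshold so anisotropic
    voxels are handled exactly.
    """
    if distance_mm < 0:
        raise ValueError("distance must be non-negative")
    mask = np.asarray(mask, bool)
    if distance_mm == 0:
        return mask.copy()
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size_mm)
    out = edt > distance_mm
    if not out.any():
        raise ValueError(
            f"eroding {name} by {distance_mm} mm removed every voxel")
    return out


def motion_metric(seg: LabelImage, transforms) -> dict[str, MotionTrace]:
    """Per-ROI motion trace from per-frame rigid transforms.

    The tracked point of each ROI sits at the mean x-, maximum y- and
    maximum z-coordinate of its voxels (converted to mm); the trace is the
    per-frame Euclidean distance between the transformed and original point.
    """
    vs = seg.voxel_size_mm
    centre = _centre_mm(seg.labels.shape, vs)
    traces: dict[str, MotionTrace] = {}
    for lab, name in seg.names.items():
        coords = np.argwhere(seg.labels == lab)
        if coords.size == 0:
            warnings.warn(f"ROI {name!r} is empty; skipped", stacklevel=2)
            continue
        point = np.array([coords[:, 0].mean(), coords[:, 1].max(),
                          coords[:, 2].max()]) * vs
        disp = np.array([
            np.linalg.norm(t.apply_point(point, centre) - point)
            for t in transforms
        ])
        traces[name] = MotionTrace(roi=name, displacement_mm=disp)
    return traces
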