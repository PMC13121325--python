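"""Synthetic whole-body dynamic PET phantom with full ground truth.

The phantom rasterizes geometric organs (ellipsoids, ellipsoidal shells and
an aortic cylinder) onto a voxel grid, drives each organ with a known
kinetic model against a bolus-shaped arterial input, and optionally applies
a Gaussian point-spread function, per-frame rigid motion and
frame-duration-dependent Gaussian noise. Every generated quantity — organ
parameters, true input curves, injected transforms — is returned as ground
truth, so recovery of the truth by the estimation code can be tested
end-to-end.

Organ centres are specified as fractions of the field of view (so one
geometry serves grids of any size) while organ radii are in millimetres.
The default geometry provides the six-tissue validation set: an aortic
blood cylinder, a myocardial shell, a dual-input liver, kidney cortex and
medulla with distinct perfusion, spleen and skeletal muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import _numerics as num
from .input_function import PortalModelParams, combined_liver_input, make_portal_input
from .kinetics_water import OneTCMParams, onetcm_forward
from .motion_roi import Transform6DOF, apply_transform
from .petdata import (
    TAC,
    DynamicImage,
    FrameSchedule,
    InputFunction,
    LabelImage,
    SubjectMeta,
)

__all__ = [
    "FengParams",
    "OrganSpec",
    "PhantomSpec",
    "PhantomTruth",
    "feng_curve",
    "feng_input",
    "twotcm_irreversible_forward",
    "build_phantom",
    "default_water_spec",
    "default_fdg_spec",
    "WATER_FRAME_DURATIONS_S",
    "FDG_FRAME_DURATIONS_S",
]

#: 26-frame / 5-min radiowater schedule (seconds).
WATER_FRAME_DURATIONS_S = [5.0] * 12 + [10.0] * 6 + [15.0] * 4 + [30.0] * 4
#: 24-frame / 44-min FDG schedule (seconds).
FDG_FRAME_DURATIONS_S = [10.0] * 6 + [30.0] * 4 + [60.0] * 4 + [150.0] * 4 \
    + [270.0] * 6


@dataclass(frozen=True)
class FengParams:
    """Tri-exponential bolus arterial input model.

    ``C_A(t) = [(A1·u − A2 − A3)·e^{λ1 u} + A2·e^{λ2 u} + A3·e^{λ3 u}]``
    with ``u = t − τ`` for ``t > τ`` and 0 before onset. Amplitudes are
    kBq/mL (A1 per minute), eigenrates λ are negative per-minute values.
    The curve is non-negative whenever λ1 ≤ λ2, λ3 and amplitudes ≥ 0.
    """

    a1: float = 800.0      # kBq/mL/min
    a2: float = 12.0       # kBq/mL
    a3: float = 10.0       # kBq/mL
    l1: float = -4.0       # min⁻¹
    l2: float = -0.12      # min⁻¹
    l3: float = -0.01      # min⁻¹
    tau_min: float = 0.25  # bolus arrival

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.a3) < 0:
            raise ValueError("amplitudes must be non-negative")
        if max(self.l1, self.l2, self.l3) >= 0:
            raise ValueError("eigenrates must be negative")
        if self.tau_min < 0:
            raise ValueError("onset must be non-negative")


def feng_curve(params: FengParams, t_s: np.ndarray) -> np.ndarray:
    """Evaluate the bolus model at times given in seconds."""
    u = np.asarray(t_s, float) / 60.0 - params.tau_min
    pos = u > 0
    up = np.where(pos, u, 0.0)
    c = ((params.a1 * up - params.a2 - params.a3) * np.exp(params.l1 * up)
         + params.a2 * np.exp(params.l2 * up)
         + params.a3 * np.exp(params.l3 * up))
    c = np.where(pos, c, 0.0)
    if np.any(c < -1e-9):
        raise ValueError("input model parameters produce a negative curve")
    return np.clip(c, 0.0, None)


def feng_input(params: FengParams, schedule: FrameSchedule,
               dt_s: float = 0.5) -> InputFunction:
    """Frame-averaged bolus input on the given schedule (whole blood)."""
    t_dense = num.dense_grid(schedule, dt_s)
    dense = feng_curve(params, t_dense)
    vals = num.frame_average(dense, t_dense, schedule)
    return InputFunction(TAC(schedule, vals, label="arterial"),
                         matrix="whole_blood")


def twotcm_irreversible_forward(K1: float, k2: float, k3: float,
                                inp: InputFunction,
                                schedule: FrameSchedule | None = None,
                                delay_s: float = 0.0,
                                dt_s: float = 1.0) -> TAC:
    """Irreversible two-tissue model (k4 = 0), frame-averaged.

    Free compartment: C1' = K1·C_p − (k2+k3)·C1; trapped: C2' = k3·C1.
    Solved analytically on the dense grid (the exponential-convolution
    recursion is the exact matrix-exponential solution for piecewise-linear
    input). At late times the Patlak slope of the output approaches
    ``K1·k3/(k2+k3)``.
    """
    if min(K1, k2, k3) < 0:
        raise ValueError("rate constants must be non-negative")
    schedule = schedule or inp.schedule
    t_dense = num.dense_grid(schedule, dt_s)
    cp = num.resample_dense(inp, t_dense, delay_s=delay_s)
    c1 = K1 * num.exp_conv(cp, k2 + k3, dt_s)
    c2 = k3 * num.running_integral(c1, dt_s)
    vals = num.frame_average(c1 + c2, t_dense, schedule)
    return TAC(schedule, vals, label="2tcm_model")


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganSpec:
    """One phantom organ: a geometric primitive plus its kinetic model.

    ``shape`` is ``ellipsoid``, ``shell`` or ``cylinder`` (z-aligned).
    ``center_frac`` positions the organ as fractions of the field of view;
    radii are millimetres. ``kinetics`` is one of::

        {"model": "blood"}
        {"model": "1tcm", "K1": .., "p": .., "VA": .., "delay_s": ..}
        {"model": "2tcm", "K1": .., "k2": .., "k3": .., "delay_s": ..}
        {"model": "liver", "K1": .., "p": .., "VA": .., "r_a": ..,
         "beta_per_min": .., "delay_s": ..}
    """

    name: str
    label: int
    shape: str
    center_frac: tuple[float, float, float]
    radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    inner_radii_mm: tuple[float, float, float] | None = None
    z_range_frac: tuple[float, float] | None = None  # cylinders only
    kinetics: dict = field(default_factory=lambda: {"model": "blood"})


@dataclass(frozen=True)
class PhantomSpec:
    seed: int
    shape: tuple[int, int, int] = (96, 96, 192)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    organs: Sequence[OrganSpec] = ()
    input_params: FengParams = field(default_factory=FengParams)
    schedule: FrameSchedule = field(
        default_factory=lambda: FrameSchedule.from_durations(
            WATER_FRAME_DURATIONS_S))
    tracer: str = "H2O"
    noise_alpha: float = 0.0        # σ² = α·value/duration_min
    psf_fwhm_mm: float = 3.5        # scanner-like resolution; 0 disables
    motion: Sequence[Transform6DOF] | None = None
    meta: SubjectMeta | None = None


@dataclass(frozen=True)
class PhantomTruth:
    """Everything needed to check estimates against the generator."""

    organs: dict                     # name -> {"kinetics":…, "tac": TAC}
    input: InputFunction             # frame-averaged arterial curve
    input_dense: tuple               # (t_s, values) fine-grid arterial curve
    portal: InputFunction | None
    liver_input: InputFunction | None
    transforms: Sequence[Transform6DOF] | None
    seed: int


def _rasterize(organ: OrganSpec, shape, voxel_size_mm) -> np.ndarray:
    vs = np.asarray(voxel_size_mm, float)
    fov = np.asarray(shape, float) * vs
    centre = np.asarray(organ.center_frac, float) * fov
    grids = np.meshgrid(*(np.arange(n) * v + v / 2 for n, v in zip(shape, vs)),
                        indexing="ij")
    dx, dy, dz = (g - c for g, c in zip(grids, centre))
    if organ.shape == "ellipsoid":
        rx, ry, rz = organ.radii_mm
        return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0
    if organ.shape == "shell":
        rx, ry, rz = organ.radii_mm
        outer = (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0
        ix, iy, iz = organ.inner_radii_mm
        inner = (dx / ix) ** 2 + (dy / iy) ** 2 + (dz / iz) ** 2 < 1.0
        return outer & ~inner
    if organ.shape == "cylinder":
        r = organ.radii_mm[0]
        z0, z1 = organ.z_range_frac
        return (dx ** 2 + dy ** 2 <= r ** 2) \
            & (grids[2] >= z0 * fov[2]) & (grids[2] <= z1 * fov[2])
    raise ValueError(f"unknown organ shape {organ.shape!r}")


def _organ_tac(organ: OrganSpec, inp: InputFunction, schedule, dt_s,
               portal_beta_cache: dict) -> tuple[TAC, dict]:
    kin = dict(organ.kinetics)
    model = kin.pop("model")
    extra: dict = {}
    if model == "blood":
        tac = TAC(schedule, inp.values, label=organ.name)
    elif model == "1tcm":
        p = OneTCMParams(K1=kin["K1"], k2=kin["K1"] / kin["p"],
                         VA=kin.get("VA", 0.0),
                         delay_s=kin.get("delay_s", 0.0))
        tac = replace(onetcm_forward(p, inp, schedule, dt_s), label=organ.name)
    elif model == "2tcm":
        tac = replace(
            twotcm_irreversible_forward(kin["K1"], kin["k2"], kin["k3"], inp,
                                        schedule, kin.get("delay_s", 0.0),
                                        dt_s),
            label=organ.name)
    elif model == "liver":
        beta = kin["beta_per_min"]
        if beta not in portal_beta_cache:
            portal_beta_cache[beta] = make_portal_input(
                inp, PortalModelParams(beta), dt_s=dt_s)
        c_pv = portal_beta_cache[beta]
        combined = combined_liver_input(inp, c_pv, kin["r_a"],
                                        1.0 - kin["r_a"])
        p = OneTCMParams(K1=kin["K1"], k2=kin["K1"] / kin["p"],
                         VA=kin.get("VA", 0.0),
                         delay_s=kin.get("delay_s", 0.0))
        tac = replace(onetcm_forward(p, combined, schedule, dt_s),
                      label=organ.name)
        extra = {"portal": c_pv, "liver_input": combined}
    else:
        raise ValueError(f"unknown kinetic model {model!r}")
    return tac, extra


def build_phantom(spec: PhantomSpec, dt_s: float = 1.0
                  ) -> tuple[DynamicImage, LabelImage, PhantomTruth]:
    """Generate the dynamic image, segmentation and ground truth."""
    vs = np.asarray(spec.voxel_size_mm, float)
    labels = np.zeros(spec.shape, dtype=np.int16)
    names: dict[int, str] = {}
    for organ in spec.organs:
        mask = _rasterize(organ, spec.shape, vs)
        if not mask.any():
            raise ValueError(f"organ {organ.name!r} rasterizes to no voxels")
        clash = labels[mask]
        if np.any(clash != 0):
            other = names[int(clash[clash != 0][0])]
            raise ValueError(f"organs overlap: {organ.name!r} and {other!r}")
        labels[mask] = organ.label
        names[organ.label] = organ.name
    seg = LabelImage(labels, names, vs)

    schedule = spec.schedule
    t_fine = num.dense_grid(schedule, 0.5)
    dense_vals = feng_curve(spec.input_params, t_fine)
    inp = feng_input(spec.input_params, schedule, dt_s=0.5)

    portal_cache: dict = {}
    organs_truth: dict = {}
    portal = liver_input = None
    img4d = np.zeros(spec.shape + (schedule.n_frames,), float)
    for organ in spec.organs:
        tac, extra = _organ_tac(organ, inp, schedule, dt_s, portal_cache)
        organs_truth[organ.name] = {"kinetics": dict(organ.kinetics),
                                    "tac": tac, "label": organ.label}
        portal = extra.get("portal", portal)
        liver_input = extra.get("liver_input", liver_input)
        img4d[seg.labels == organ.label, :] = tac.values

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
        for f in range(schedule.n_frames):
            img4d[..., f] = ndimage.gaussian_filter(img4d[..., f],
                                                    sigma=sigma_vox)

    if spec.motion is not None:
        if len(spec.motion) != schedule.n_frames:
            raise ValueError("one transform per frame required")
        for f, t in enumerate(spec.motion):
            if not t.is_identity:
                img4d[..., f] = apply_transform(img4d[..., f], t, vs)

    if spec.noise_alpha > 0:
        rng = np.random.default_rng(spec.seed)
        dur_min = schedule.duration_s / 60.0
        sigma = np.sqrt(spec.noise_alpha * np.clip(img4d, 0.0, None)
                        / dur_min[None, None, None, :])
        img4d = img4d + rng.standard_normal(img4d.shape) * sigma

    img = DynamicImage(img4d, vs, schedule)
    truth = PhantomTruth(
        organs=organs_truth, input=inp,
        input_dense=(t_fine, dense_vals),
        portal=portal, liver_input=liver_input,
        transforms=spec.motion, seed=spec.seed,
    )
    return img, seg, truth


# ---------------------------------------------------------------------------
# Default geometries and kinetic parameters
# ---------------------------------------------------------------------------

def _water_organs() -> list[OrganSpec]:
    return [
        OrganSpec("aorta", 1, "cylinder", (0.50, 0.35, 0.5),
                  radii_mm=(9.0, 9.0, 0.0), z_range_frac=(0.12, 0.88),
                  kinetics={"model": "blood"}),
        OrganSpec("myocardium", 2, "shell", (0.50, 0.66, 0.88),
                  radii_mm=(16.0, 16.0, 12.0),
                  inner_radii_mm=(10.0, 10.0, 8.0),
                  kinetics={"model": "1tcm", "K1": 0.9, "p": 0.91,
                            "VA": 0.30, "delay_s": 2.0}),
        OrganSpec("liver", 3, "ellipsoid", (0.26, 0.62, 0.55),
                  radii_mm=(20.0, 14.0, 20.0),
                  kinetics={"model": "liver", "K1": 1.0, "p": 0.75,
                            "VA": 0.05, "r_a": 0.25, "beta_per_min": 1.0,
                            "delay_s": 4.0}),
        OrganSpec("kidney_cortex", 4, "shell", (0.74, 0.62, 0.38),
                  radii_mm=(13.0, 13.0, 15.0),
                  inner_radii_mm=(7.0, 7.0, 9.0),
                  kinetics={"model": "1tcm", "K1": 2.5, "p": 0.85,
                            "VA": 0.10, "delay_s": 2.0}),
        OrganSpec("kidney_medulla", 5, "ellipsoid", (0.74, 0.62, 0.38),
                  radii_mm=(5.5, 5.5, 7.5),
                  kinetics={"model": "1tcm", "K1": 0.8, "p": 0.90,
                            "VA": 0.05, "delay_s": 3.0}),
        OrganSpec("spleen", 6, "ellipsoid", (0.26, 0.62, 0.22),
                  radii_mm=(10.0, 10.0, 12.0),
                  kinetics={"model": "1tcm", "K1": 1.1, "p": 0.85,
                            "VA": 0.10, "delay_s": 3.0}),
        OrganSpec("muscle", 7, "ellipsoid", (0.74, 0.62, 0.14),
                  radii_mm=(8.0, 8.0, 13.0),
                  kinetics={"model": "1tcm", "K1": 0.05, "p": 0.80,
                            "VA": 0.02, "delay_s": 6.0}),
    ]


def _fdg_kinetics() -> dict[str, dict]:
    return {
        "myocardium": {"model": "2tcm", "K1": 0.6, "k2": 1.2, "k3": 0.10,
                       "delay_s": 2.0},
        "liver": {"model": "2tcm", "K1": 0.7, "k2": 0.9, "k3": 0.01,
                  "delay_s": 4.0},
        "kidney_cortex": {"model": "2tcm", "K1": 0.8, "k2": 1.0, "k3": 0.02,
                          "delay_s": 2.0},
        "kidney_medulla": {"model": "2tcm", "K1": 0.4, "k2": 0.8, "k3": 0.015,
                           "delay_s": 3.0},
        "spleen": {"model": "2tcm", "K1": 0.5, "k2": 0.8, "k3": 0.015,
                   "delay_s": 3.0},
        "muscle": {"model": "2tcm", "K1": 0.03, "k2": 0.25, "k3": 0.012,
                   "delay_s": 6.0},
    }


def default_water_spec(seed: int, shape=(96, 96, 192), voxel_size_mm=3.0,
                       noise_alpha: float = 0.0, psf_fwhm_mm: float = 3.5,
                       motion=None) -> PhantomSpec:
    """Radiowater phantom: 26 frames / 5 min, six validation organs."""
    vs = (voxel_size_mm,) * 3 if np.isscalar(voxel_size_mm) \
        else tuple(voxel_size_mm)
    return PhantomSpec(
        seed=seed, shape=tuple(shape), voxel_size_mm=vs,
        organs=_water_organs(),
        schedule=FrameSchedule.from_durations(WATER_FRAME_DURATIONS_S),
        tracer="H2O", noise_alpha=noise_alpha, psf_fwhm_mm=psf_fwhm_mm,
        motion=motion,
        meta=SubjectMeta(500.0, 75.0, "H2O", hematocrit=0.42),
    )


def default_fdg_spec(seed: int, shape=(96, 96, 192), voxel_size_mm=3.0,
                     noise_alpha: float = 0.0, psf_fwhm_mm: float = 3.5,
                     motion=None) -> PhantomSpec:
    """FDG phantom: 24 frames / 44 min, irreversible two-tissue organs."""
    organs = []
    fdg = _fdg_kinetics()
    for organ in _water_organs():
        if organ.name in fdg:
            organs.append(replace(organ, kinetics=fdg[organ.name]))
        else:
            organs.append(organ)
    vs = (voxel_size_mm,) * 3 if np.isscalar(voxel_size_mm) \
        else tuple(voxel_size_mm)
    return PhantomSpec(
        seed=seed, shape=tuple(shape), voxel_size_mm=vs, organs=organs,
        input_params=FengParams(a1=600.0, a2=22.0, a3=21.0, l1=-4.1,
                                l2=-0.12, l3=-0.01, tau_min=0.5),
        schedule=FrameSchedule.from_durations(FDG_FRAME_DURATIONS_S),
        tracer="FDG", noise_alpha=noise_alpha, psf_fwhm_mm=psf_fwhm_mm,
        motion=motion,
        meta=SubjectMeta(300.0, 80.0, "FDG", hematocrit=0.42,
                         plasma_glucose_mmol_L=5.4),
    )
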