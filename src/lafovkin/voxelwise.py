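"""Voxel-level parametric imaging.

Two linearized estimators for the radiowater 1TCM are provided:

* the **basis-function method** — a bank of exponential-convolution basis
  curves ``B_j(t) = ∫ C_A e^{−k2_j (t−s)} ds`` over a discrete k2 grid
  (default 500 values uniform on [0, 6] min⁻¹); for each voxel and each j a
  two-coefficient non-negative least-squares problem
  ``min ‖θ1·B_j + θ2·C_A − y‖²`` is solved and the j with the smallest
  residual wins (ties to the smaller k2), giving K1 = θ1, V_A = θ2,
  k2 = k2_j;
* the **full three-parameter NNLS** on the integral form of the model,
  ``C(T) = θ1·∫C_A − θ2·∫C + θ3·C_A(T)`` with θ ≥ 0 and
  (K1, k2, V_A) = (θ1 − θ2·θ3, θ2, θ3).

The tracer-arrival delay is estimated per voxel by a lookup over a delay
grid (one basis bank per delay, shared across voxels); liver voxels instead
inherit the ROI-level combined input and delay. FDG voxel maps (Patlak Ki,
intercept, FUR, SUV) reuse the regional estimators in vectorized form.

The two-coefficient NNLS is solved in closed form (project the
unconstrained 2×2 solution onto the active-set candidates), which makes the
whole basis bank a few matrix products per voxel block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.cluster import AgglomerativeClustering

from . import _numerics as num
from .petdata import TAC, DynamicImage, FrameSchedule, InputFunction, LabelImage
from .kinetics_water import OneTCMParams

__all__ = [
    "BasisSet",
    "ParametricMaps",
    "build_basis",
    "voxel_fit_basis",
    "fit_voxels_basis",
    "voxel_fit_nnls3",
    "parametric_water",
    "voxel_delay_map",
    "parametric_fdg",
    "cluster_parametric",
    "assemble_maps",
]


@dataclass(frozen=True)
class BasisSet:
    """Precomputed exponential-convolution basis bank at one delay."""

    k2_grid: np.ndarray           # (n,) min⁻¹, ascending
    basis_frames: np.ndarray      # (n, F) frame-averaged basis curves
    input_frames: np.ndarray      # (F,) frame-averaged delayed input
    schedule: FrameSchedule
    delay_s: float = 0.0


def build_basis(inp: InputFunction, schedule: FrameSchedule | None = None,
                n: int = 500, k2_range: tuple[float, float] = (0.0, 6.0),
                delay_s: float = 0.0, dt_s: float = 1.0) -> BasisSet:
    """Basis curves on a uniform k2 grid, frame-averaged on the schedule."""
    if n < 2:
        raise ValueError("need at least 2 basis functions")
    lo, hi = k2_range
    if hi < lo:
        raise ValueError("k2 range must be non-decreasing")
    schedule = schedule or inp.schedule
    k2_grid = lo + (hi - lo) * np.arange(n) / (n - 1)
    t_dense = num.dense_grid(schedule, dt_s)
    c_dense = num.resample_dense(inp, t_dense, delay_s=delay_s)
    basis = np.empty((n, schedule.n_frames))
    for j, k2 in enumerate(k2_grid):
        basis[j] = num.frame_average(num.exp_conv(c_dense, k2, dt_s),
                                     t_dense, schedule)
    c_frames = num.frame_average(c_dense, t_dense, schedule)
    return BasisSet(k2_grid, basis, c_frames, schedule, float(delay_s))


def _nnls2_closed_form(uu, uv, vv, uy, vy, yy):
    """Vectorized 2-variable NNLS: min ‖θ1 u + θ2 v − y‖², θ ≥ 0.

    Gram quantities are broadcastable: uu, uv (n, 1), vv scalar,
    uy (n, V), vy (1, V), yy (1, V). Returns θ1, θ2, rss of shape (n, V).
    """
    det = uu * vv - uv ** 2
    safe = det > 1e-12 * np.maximum(uu * vv, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        th1 = np.where(safe, (vv * uy - uv * vy) / det, -1.0)
        th2 = np.where(safe, (uu * vy - uv * uy) / det, -1.0)
    interior = (th1 >= 0) & (th2 >= 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.clip(np.where(uu > 0, uy / uu, 0.0), 0.0, None)  # θ2 = 0 edge
        b2 = np.clip(np.where(vv > 0, vy / vv, 0.0), 0.0, None)  # θ1 = 0 edge
    rss_a = yy - 2.0 * a1 * uy + a1 ** 2 * uu
    rss_b = yy - 2.0 * b2 * vy + b2 ** 2 * vv
    use_a = rss_a <= rss_b
    th1_e = np.where(use_a, a1, 0.0)
    th2_e = np.where(use_a, 0.0, b2)
    rss_e = np.where(use_a, rss_a, rss_b)

    rss_i = (yy - 2.0 * th1 * uy - 2.0 * th2 * vy
             + th1 ** 2 * uu + th2 ** 2 * vv + 2.0 * th1 * th2 * uv)
    th1 = np.where(interior, th1, th1_e)
    th2 = np.where(interior, th2, th2_e)
    rss = np.where(interior, rss_i, rss_e)
    return th1, th2, np.clip(rss, 0.0, None)


def fit_voxels_basis(Y: np.ndarray, basis: BasisSet, weights=None,
                     chunk: int = 2048):
    """Basis-function fit of many voxels at once.

    Parameters
    ----------
    Y:
        (V, F) array of voxel TACs.

    Returns
    -------
    dict with (V,) arrays ``K1``, ``k2``, ``VA``, ``rss`` and the (V, F)
    fitted curves.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    F = basis.schedule.n_frames
    if Y.shape[1] != F:
        raise ValueError("voxel TACs and basis are on different schedules")
    w = _weights(basis.schedule, weights)
    U = basis.basis_frames
    c = basis.input_frames
    uu = (U * U * w).sum(axis=1, keepdims=True)          # (n, 1)
    uv = (U * (c * w)).sum(axis=1, keepdims=True)        # (n, 1)
    vv = float((c * c * w).sum())

    V = Y.shape[0]
    out = {k: np.zeros(V) for k in ("K1", "k2", "VA", "rss")}
    fitted = np.zeros((V, F))
    Uw = U * w
    cw = c * w
    for s in range(0, V, chunk):
        Yc = Y[s:s + chunk]
        uy = Uw @ Yc.T                                   # (n, Vc)
        vy = (Yc @ cw)[None, :]
        yy = (Yc * Yc * w).sum(axis=1)[None, :]
        th1, th2, rss = _nnls2_closed_form(uu, uv, vv, uy, vy, yy)
        j = np.argmin(rss, axis=0)                       # ties → smaller k2
        cols = np.arange(Yc.shape[0])
        out["K1"][s:s + chunk] = th1[j, cols]
        out["VA"][s:s + chunk] = th2[j, cols]
        out["k2"][s:s + chunk] = basis.k2_grid[j]
        out["rss"][s:s + chunk] = rss[j, cols]
        fitted[s:s + chunk] = (th1[j, cols, None] * U[j]
                               + th2[j, cols, None] * c[None, :])
    out["fitted"] = fitted
    return out


def voxel_fit_basis(tac: TAC, basis: BasisSet, weights=None
                    ) -> tuple[OneTCMParams, float]:
    """Single-voxel basis-function fit."""
    res = fit_voxels_basis(tac.values[None, :], basis, weights)
    params = OneTCMParams(K1=float(res["K1"][0]), k2=float(res["k2"][0]),
                          VA=float(min(res["VA"][0], 1.0)),
                          delay_s=basis.delay_s)
    return params, float(res["rss"][0])


def _weights(schedule: FrameSchedule, weights) -> np.ndarray:
    if weights is None:
        return schedule.duration_s / schedule.duration_s.sum()
    if isinstance(weights, str) and weights == "uniform":
        return np.full(schedule.n_frames, 1.0 / schedule.n_frames)
    return np.asarray(weights, float)


# ---------------------------------------------------------------------------
# Full three-parameter NNLS
# ---------------------------------------------------------------------------

def _nnls3_design(inp: InputFunction, schedule: FrameSchedule,
                  delay_s: float, dt_s: float):
    t_dense = num.dense_grid(schedule, dt_s)
    c_dense = num.resample_dense(inp, t_dense, delay_s=delay_s)
    mid = schedule.mid_s
    int_ca = np.interp(mid, t_dense, num.running_integral(c_dense, dt_s))
    c_frames = num.frame_average(c_dense, t_dense, schedule)
    if not np.any(int_ca != 0):
        raise ValueError("input function is identically zero")
    return int_ca, c_frames


def _tissue_integral(y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """∫₀ᵗ C_PET (kBq/mL·min) at frame midpoints.

    Exploits that TAC samples are frame averages: the integral over a full
    frame is exactly value × duration, and the half-frame up to the
    midpoint contributes half of that.
    """
    dur_min = schedule.duration_s / 60.0
    full = np.cumsum(y * dur_min)
    return full - 0.5 * y * dur_min


def voxel_fit_nnls3(tac: TAC, inp: InputFunction, delay_s: float = 0.0,
                    weights=None, dt_s: float = 1.0
                    ) -> tuple[OneTCMParams, float]:
    """1TCM parameters from the linearized model solved with NNLS.

    ``C(T) = θ1·∫C_A − θ2·∫C + θ3·C_A(T)`` with all θ ≥ 0 maps back to
    K1 = θ1 − θ2·θ3 (clipped at 0), k2 = θ2, V_A = θ3.
    """
    schedule = tac.schedule
    int_ca, c_frames = _nnls3_design(inp, schedule, delay_s, dt_s)
    y = tac.values
    A = np.column_stack([int_ca, -_tissue_integral(y, schedule),
                         c_frames])
    sw = np.sqrt(_weights(schedule, weights))
    theta, rnorm = nnls(A * sw[:, None], y * sw)
    k2, VA = float(theta[1]), float(min(theta[2], 1.0))
    K1 = max(float(theta[0]) - k2 * VA, 0.0)
    return OneTCMParams(K1=K1, k2=k2, VA=VA, delay_s=delay_s), float(rnorm ** 2)


# ---------------------------------------------------------------------------
# Parametric maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParametricMaps:
    """Named 3-D parameter maps on the PET grid; NaN outside the mask."""

    maps: dict
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError("all maps must share a shape")
        object.__setattr__(self, "voxel_size_mm",
                           np.asarray(self.voxel_size_mm, float))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def roi_mean(self, name: str, mask: np.ndarray) -> float:
        vals = self.maps[name][mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan

    def write(self, out_dir, subject: str, tracer: str) -> list:
        import nibabel as nib
        from pathlib import Path

        out = []
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        for name, vol in self.maps.items():
            path = Path(out_dir) / f"{subject}_{tracer}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), aff),
                     str(path))
            out.append(path)
        return out


def assemble_maps(fits: dict, shape, mask: np.ndarray,
                  voxel_size_mm=(1.0, 1.0, 1.0)) -> ParametricMaps:
    """Scatter per-voxel fit vectors back onto the image grid."""
    n = int(np.asarray(mask, bool).sum())
    maps = {}
    for name, vec in fits.items():
        vec = np.asarray(vec, float)
        if vec.shape != (n,):
            raise ValueError(
                f"map {name!r} has {vec.shape} values for {n} masked voxels")
        vol = np.full(shape, np.nan)
        vol[mask] = vec
        maps[name] = vol
    if "K1" in maps and "VA" in maps and "h2o_flow" not in maps:
        maps["h2o_flow"] = maps["K1"] * (1.0 - maps["VA"])
    return ParametricMaps(maps, voxel_size_mm)


def parametric_water(img: DynamicImage, inp: InputFunction,
                     mask: np.ndarray, method: str = "basis",
                     delay_grid=None, n_basis: int = 500,
                     k2_range=(0.0, 6.0), weights=None,
                     liver_mask: np.ndarray | None = None,
                     liver_input: InputFunction | None = None,
                     liver_delay_s: float = 0.0,
                     dt_s: float = 1.0) -> ParametricMaps:
    """Voxelwise radiowater 1TCM maps with per-voxel delay lookup.

    One basis bank is built per delay-grid value and shared by every voxel;
    each voxel keeps the delay with the smallest residual (ties to the
    smallest delay). Voxels inside ``liver_mask`` are fitted once against
    the ROI-level combined liver input at the ROI-level delay instead.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    Y = np.asarray(img.voxels[mask], float)
    schedule = img.schedule
    delays = [0.0] if delay_grid is None else sorted(float(d) for d in delay_grid)

    V = Y.shape[0]
    best = {k: np.zeros(V) for k in ("K1", "k2", "VA", "delay", "rss", "r2")}
    best["rss"][:] = np.inf
    best_fitted = np.zeros_like(Y)
    for d in delays:
        res = _fit_bank(Y, img, inp, schedule, method, d, n_basis, k2_range,
                        weights, dt_s)
        upd = res["rss"] < best["rss"]
        for k in ("K1", "k2", "VA", "rss"):
            best[k][upd] = res[k][upd]
        best["delay"][upd] = d
        best_fitted[upd] = res["fitted"][upd]

    if liver_mask is not None and liver_input is not None:
        liver_sel = np.asarray(liver_mask, bool)[mask]
        if liver_sel.any():
            res = _fit_bank(Y[liver_sel], img, liver_input, schedule, method,
                            liver_delay_s, n_basis, k2_range, weights, dt_s)
            for k in ("K1", "k2", "VA", "rss"):
                best[k][liver_sel] = res[k]
            best["delay"][liver_sel] = liver_delay_s
            best_fitted[liver_sel] = res["fitted"]

    best["r2"] = _rows_r2(Y, best_fitted)
    del best["rss"]
    best["rss"] = _rows_rss(Y, best_fitted, _weights(schedule, weights))
    return assemble_maps(best, img.shape3, mask, img.voxel_size_mm)


def _fit_bank(Y, img, inp, schedule, method, delay, n_basis, k2_range,
              weights, dt_s):
    if method == "basis":
        basis = build_basis(inp, schedule, n=n_basis, k2_range=k2_range,
                            delay_s=delay, dt_s=dt_s)
        return fit_voxels_basis(Y, basis, weights)
    if method == "nnls3":
        int_ca, c_frames = _nnls3_design(inp, schedule, delay, dt_s)
        sw = np.sqrt(_weights(schedule, weights))
        out = {k: np.zeros(Y.shape[0]) for k in ("K1", "k2", "VA", "rss")}
        fitted = np.zeros_like(Y)
        for i, y in enumerate(Y):
            A = np.column_stack([int_ca,
                                 -_tissue_integral(y, schedule),
                                 c_frames])
            theta, rnorm = nnls(A * sw[:, None], y * sw)
            out["k2"][i], out["VA"][i] = theta[1], min(theta[2], 1.0)
            out["K1"][i] = max(theta[0] - theta[1] * theta[2], 0.0)
            out["rss"][i] = rnorm ** 2
            fitted[i] = A @ theta
        out["fitted"] = fitted
        return out
    raise ValueError(f"unknown voxel method {method!r}")


def _rows_r2(Y, F):
    ym = Y - Y.mean(axis=1, keepdims=True)
    fm = F - F.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(ym, axis=1) * np.linalg.norm(fm, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (ym * fm).sum(axis=1) / denom, 0.0)
    return r ** 2


def _rows_rss(Y, F, w):
    return ((Y - F) ** 2 * w).sum(axis=1)


def voxel_delay_map(img: DynamicImage, inp: InputFunction, mask: np.ndarray,
                    method: str = "basis", delay_grid=None,
                    **kw) -> np.ndarray:
    """Per-voxel tracer-arrival delay (s) chosen by best fit on the grid."""
    maps = parametric_water(img, inp, mask, method=method,
                            delay_grid=delay_grid, **kw)
    return maps["delay"]


# ---------------------------------------------------------------------------
# FDG voxel maps
# ---------------------------------------------------------------------------

def parametric_fdg(img: DynamicImage, plasma: InputFunction,
                   mask: np.ndarray, t_star_min: float = 20.0,
                   meta=None, window_s=None, dt_s: float = 1.0
                   ) -> ParametricMaps:
    """Voxelwise Patlak Ki and intercept, FUR and (if meta given) SUV."""
    from .kinetics_fdg import _plasma_at, _plasma_integral_at

    if plasma.matrix != "plasma":
        raise ValueError("FDG voxel maps require a plasma input")
    mask = np.asarray(mask, bool)
    Y = np.asarray(img.voxels[mask], float)
    schedule = img.schedule
    mid = schedule.mid_s
    sel = mid >= t_star_min * 60.0
    if sel.sum() < 3:
        raise ValueError("need ≥ 3 frames beyond t* for voxel Patlak")
    cp = _plasma_at(plasma, mid[sel])
    x = _plasma_integral_at(plasma, mid[sel], dt_s) / cp
    Yn = Y[:, sel] / cp
    xm = x - x.mean()
    slope = (Yn - Yn.mean(axis=1, keepdims=True)) @ xm / (xm @ xm)
    intercept = Yn.mean(axis=1) - slope * x.mean()

    if window_s is None:
        window_s = (float(schedule.start_s[-1]), float(schedule.end_s[-1]))
    wsel = (mid >= window_s[0]) & (mid <= window_s[1])
    integral = float(_plasma_integral_at(
        plasma, np.array([(window_s[0] + window_s[1]) / 2.0]), dt_s)[0])
    fur_map = Y[:, wsel].mean(axis=1) / integral

    fits = {"Ki": slope, "V": intercept, "FUR": fur_map}
    if meta is not None:
        fits["SUV"] = Y[:, wsel].mean(axis=1) / (meta.injected_dose_MBq
                                                 / meta.weight_kg)
    return assemble_maps(fits, img.shape3, mask, img.voxel_size_mm)


# ---------------------------------------------------------------------------
# Clustering of parametric maps
# ---------------------------------------------------------------------------

def cluster_parametric(map3d: np.ndarray, roi_mask: np.ndarray,
                       voxel_size_mm=(1.0, 1.0, 1.0), k: int = 3,
                       linkage: str = "ward", seed: int = 0,
                       max_voxels: int = 50_000,
                       on_constant: str = "raise") -> LabelImage:
    """Split a parametric map within an ROI into ``k`` subregions.

    Agglomerative (default Ward) clustering on the one-dimensional
    parameter values; output labels are ordered by ascending cluster mean
    (1 = lowest). ROIs larger than ``max_voxels`` are clustered on a seeded
    subsample and remaining voxels are assigned to the nearest cluster
    mean.
    """
    roi_mask = np.asarray(roi_mask, bool)
    vals = np.asarray(map3d, float)[roi_mask]
    finite = np.isfinite(vals)
    idx = np.argwhere(roi_mask)[finite]
    vals = vals[finite]
    if vals.size < k:
        raise ValueError(f"ROI has {vals.size} usable voxels, fewer than k={k}")
    if np.ptp(vals) == 0:
        if on_constant == "raise":
            raise ValueError("parametric map is constant within the ROI")
        warnings.warn("constant map: returning a single cluster", stacklevel=2)
        labels_all = np.ones(vals.size, int)
        k_eff = 1
    else:
        X = vals[:, None]
        if vals.size > max_voxels:
            rng = np.random.default_rng(seed)
            sub = rng.choice(vals.size, max_voxels, replace=False)
            fit_labels = AgglomerativeClustering(
                n_clusters=k, linkage=linkage).fit_predict(X[sub])
            means = np.array([vals[sub][fit_labels == i].mean()
                              for i in range(k)])
            labels_all = np.argmin(np.abs(vals[:, None] - means[None, :]),
                                   axis=1)
        else:
            labels_all = AgglomerativeClustering(
                n_clusters=k, linkage=linkage).fit_predict(X)
        means = np.array([vals[labels_all == i].mean() for i in range(k)])
        order = np.argsort(means)
        remap = np.empty(k, int)
        remap[order] = np.arange(1, k + 1)
        labels_all = remap[labels_all]
        k_eff = k

    out = np.zeros(roi_mask.shape, dtype=np.int16)
    out[tuple(idx.T)] = labels_all
    names = {i: f"cluster_{i}" for i in range(1, k_eff + 1)}
    return LabelImage(out, names, np.asarray(voxel_size_mm, float))
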