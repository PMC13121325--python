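"""FDG glucose-metabolism quantification: Patlak plot, FUR, SUV and
lumped-constant conversion to glucose uptake.

All methods take the plasma input curve (whole blood converted via
hematocrit, see :func:`lafovkin.input_function.blood_to_plasma`). The Patlak
plot regresses ``C_T(t)/C_p(t)`` on the normalized time
``∫₀ᵗ C_p ds / C_p(t)`` over the late linear segment; its slope Ki is the
net irreversible uptake rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr

from . import _numerics as num
from .petdata import TAC, InputFunction, SubjectMeta

__all__ = [
    "PatlakFit",
    "LumpedConstants",
    "patlak",
    "fur",
    "suv",
    "glucose_uptake",
]


@dataclass(frozen=True)
class PatlakFit:
    Ki: float            # min⁻¹, slope of the linear segment
    V: float             # dimensionless intercept
    r2: float            # squared Pearson correlation of the segment
    t_star_min: float    # start of the linear segment
    n_used: int = 0


@dataclass(frozen=True)
class LumpedConstants:
    """Per-organ lumped constants for FDG→glucose conversion.

    Organs without a published value use 1. The defaults carry the
    organ-specific values for brain (0.65), myocardium (1) and skeletal
    muscle (1.16).
    """

    values: dict = field(default_factory=lambda: {
        "brain": 0.65,
        "myocardium": 1.0,
        "muscles": 1.16,
    })
    default: float = 1.0

    def __post_init__(self) -> None:
        if self.default <= 0 or any(v <= 0 for v in self.values.values()):
            raise ValueError("lumped constants must be positive")

    def get(self, organ: str) -> float:
        return float(self.values.get(organ, self.default))

    @classmethod
    def from_json(cls, path) -> "LumpedConstants":
        data = json.loads(Path(path).read_text())
        return cls(values={k: float(v) for k, v in data.get("values", {}).items()},
                   default=float(data.get("default", 1.0)))


def _plasma_at(plasma: InputFunction, t_s: np.ndarray) -> np.ndarray:
    return num.resample_dense(plasma, np.asarray(t_s, float))


def _plasma_integral_at(plasma: InputFunction, t_s: np.ndarray,
                        dt_s: float = 1.0) -> np.ndarray:
    """∫₀ᵗ C_p ds (kBq/mL·min) at the requested times, by trapezoid on the
    densely resampled curve including the linear rise from (0, 0)."""
    t_end = max(float(np.max(t_s)), float(plasma.schedule.end_s[-1]))
    t_dense = np.arange(0.0, t_end + dt_s, dt_s)
    c = num.resample_dense(plasma, t_dense)
    cum = num.running_integral(c, dt_s)
    return np.interp(np.asarray(t_s, float), t_dense, cum)


def patlak(tac: TAC, plasma: InputFunction, t_star_min: float = 20.0,
           dt_s: float = 1.0) -> PatlakFit:
    """Patlak graphical analysis over frames with midpoint ≥ ``t_star``."""
    if plasma.matrix != "plasma":
        raise ValueError("Patlak requires a plasma input curve")
    mid_s = tac.schedule.mid_s
    sel = mid_s >= t_star_min * 60.0
    if sel.sum() < 3:
        raise ValueError(
            f"need ≥ 3 frames beyond t*={t_star_min} min, have {int(sel.sum())}")
    cp = _plasma_at(plasma, mid_s[sel])
    if np.any(cp <= 0):
        raise ValueError("plasma curve must be positive on the Patlak segment")
    x = _plasma_integral_at(plasma, mid_s[sel], dt_s) / cp
    y = tac.values[sel] / cp
    if np.any(np.diff(x) < 0):
        raise ValueError("normalized time is not monotone; check the input")
    slope, intercept = np.polyfit(x, y, 1)
    r = pearsonr(x, y)[0] if np.std(y) > 0 else 1.0
    return PatlakFit(Ki=float(slope), V=float(intercept), r2=float(r ** 2),
                     t_star_min=float(t_star_min), n_used=int(sel.sum()))


def fur(tac: TAC, plasma: InputFunction, window_s=None,
        dt_s: float = 1.0) -> float:
    """Fractional uptake ratio: late tissue activity over the integrated
    plasma activity up to the window midpoint (min⁻¹).

    ``window_s = (t0, t1)`` in seconds; default is the final frame.
    """
    if window_s is None:
        window_s = (float(tac.schedule.start_s[-1]), float(tac.schedule.end_s[-1]))
    t0, t1 = window_s
    if t0 < 0 or t1 > tac.schedule.end_s[-1] + 1e-6:
        raise ValueError("window must lie within the scan")
    sel = (tac.schedule.mid_s >= t0) & (tac.schedule.mid_s <= t1)
    if not sel.any():
        raise ValueError("window contains no frame midpoint")
    mean_ct = float(tac.values[sel].mean())
    integral = float(_plasma_integral_at(plasma, np.array([(t0 + t1) / 2.0]),
                                         dt_s)[0])
    if integral <= 0:
        raise ValueError("plasma integral is non-positive")
    return mean_ct / integral


def suv(tac: TAC, meta: SubjectMeta, window_s=None) -> float:
    """Standardized uptake value with tissue density 1 g/mL.

    Mean activity (kBq/mL) over the window divided by injected dose per
    body weight (kBq/g).
    """
    if window_s is None:
        window_s = (float(tac.schedule.start_s[-1]), float(tac.schedule.end_s[-1]))
    t0, t1 = window_s
    sel = (tac.schedule.mid_s >= t0) & (tac.schedule.mid_s <= t1)
    if not sel.any():
        raise ValueError("window contains no frame midpoint")
    dose_per_g = meta.injected_dose_MBq * 1e3 / (meta.weight_kg * 1e3)
    return float(tac.values[sel].mean()) / dose_per_g


def glucose_uptake(Ki: float, meta: SubjectMeta, lc: LumpedConstants,
                   organ: str) -> float:
    """Glucose uptake ``Ki·C_glucose/LC`` (µmol/(min·mL) when Ki is min⁻¹
    and plasma glucose mmol/L)."""
    if meta.plasma_glucose_mmol_L is None:
        raise ValueError("plasma glucose is required for glucose uptake")
    return Ki * meta.plasma_glucose_mmol_L / lc.get(organ)
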