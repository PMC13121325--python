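"""Validation statistics and quality-control reporting.

Method agreement is summarized the way PET validation studies report it:
squared Pearson correlation, Bland–Altman relative difference with 95%
limits of agreement, and a two-sided paired t-test. The relative
difference uses the pair-mean denominator, ``100·(a−b)/((a+b)/2)``, so it
is antisymmetric under swapping the methods.

The QC report is a single self-contained HTML file (plots embedded as
base64 PNGs, no scripts) with regional TAC + model-fit panels, the motion
trace, a parametric-map montage and the ROI volume table.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, t as t_dist

from .petdata import TAC, read_results_table

__all__ = [
    "AgreementResult",
    "fit_r2",
    "compare_methods",
    "collect_results",
    "qc_report",
]


@dataclass(frozen=True)
class AgreementResult:
    r2: float
    mean_rel_diff_pct: float
    loa95: tuple[float, float]
    t_stat: float
    p_value: float
    n: int
    n_excluded: int = 0


def fit_r2(observed, fitted) -> float:
    """Squared Pearson correlation between observed and model values."""
    obs = observed.values if isinstance(observed, TAC) else np.asarray(observed, float)
    fit = fitted.values if isinstance(fitted, TAC) else np.asarray(fitted, float)
    if obs.size != fit.size or obs.size < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.std(obs) == 0 or np.std(fit) == 0:
        raise ValueError("R² undefined for a zero-variance series")
    return float(pearsonr(obs, fit)[0] ** 2)


def compare_methods(a, b) -> AgreementResult:
    """Pairwise agreement between two methods' estimates.

    Pairs with ``a + b == 0`` (relative difference undefined) are excluded
    and counted in ``n_excluded``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two paired 1-D arrays of length ≥ 2")
    keep = (a + b) != 0
    n_excluded = int((~keep).sum())
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("fewer than 2 valid pairs after exclusion")

    if np.std(a) == 0 or np.std(b) == 0:
        r2 = 1.0 if np.allclose(a, b) else 0.0
    else:
        r2 = float(pearsonr(a, b)[0] ** 2)

    rel = 100.0 * (a - b) / ((a + b) / 2.0)
    mean_rel = float(rel.mean())
    sd_rel = float(rel.std(ddof=1))
    loa = (mean_rel - 1.96 * sd_rel, mean_rel + 1.96 * sd_rel)

    d = a - b
    sd_d = d.std(ddof=1)
    n = d.size
    if sd_d == 0:
        t_stat = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        t_stat = float(d.mean() / (sd_d / np.sqrt(n)))
        p = float(2.0 * t_dist.sf(abs(t_stat), n - 1))
    return AgreementResult(r2=r2, mean_rel_diff_pct=mean_rel, loa95=loa,
                           t_stat=t_stat, p_value=p, n=n,
                           n_excluded=n_excluded)


def collect_results(result_dirs, subjects=None, regions=None, params=None
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Merge per-subject ``results.tsv`` tables into one long table.

    Returns the merged table and a report of requested combinations that
    were not found (missing files or missing subject/region/parameter
    rows) — nothing is dropped silently.
    """
    frames = []
    missing: list[str] = []
    for d in result_dirs:
        path = Path(d) / "results.tsv" if Path(d).is_dir() else Path(d)
        if not path.exists():
            missing.append(f"missing file: {path}")
            continue
        frames.append(read_results_table(path))
    table = pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame()
    for col, wanted in (("subject", subjects), ("region", regions),
                        ("parameter", params)):
        if wanted is not None and not table.empty:
            table = table[table[col].isin(wanted)]
    if not table.empty:
        for subj in subjects or table["subject"].unique():
            for reg in regions or table["region"].unique():
                sub = table[(table["subject"] == subj)
                            & (table["region"] == reg)]
                if sub.empty:
                    missing.append(f"missing result: {subj}/{reg}")
    return table.reset_index(drop=True), missing


# ---------------------------------------------------------------------------
# HTML QC report
# ---------------------------------------------------------------------------

def _png_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, metadata={"Software": ""})
    import matplotlib.pyplot as plt

    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _section(title: str, body: str) -> str:
    return f"<h2>{title}</h2>\n{body}\n"


def _unavailable(what: str) -> str:
    return f"<p><em>{what} unavailable</em></p>"


def qc_report(subject_dir, out_html=None) -> Path:
    """Render the subject's QC report as one self-contained HTML file.

    Expects the layout written by the pipeline: ``results.tsv``,
    ``fits/<region>.tsv`` (observed + fitted TAC), ``motion.tsv`` and
    ``maps/*.nii.gz``; any missing component is rendered as an explicit
    "unavailable" note.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    subject_dir = Path(subject_dir)
    out_html = Path(out_html) if out_html else subject_dir / "qc_report.html"
    parts = ["<html><head><meta charset='utf-8'>"
             "<title>QC report</title></head><body>",
             f"<h1>QC report: {subject_dir.name}</h1>"]

    fits_dir = subject_dir / "fits"
    fit_files = sorted(fits_dir.glob("*.tsv")) if fits_dir.is_dir() else []
    if fit_files:
        body = []
        for path in fit_files:
            df = pd.read_csv(path, sep="\t")
            fig, ax = plt.subplots(figsize=(4, 3))
            t_min = (df["frame_start_s"] + df["frame_duration_s"] / 2) / 60.0
            ax.plot(t_min, df["observed"], "o", ms=3, label="measured")
            ax.plot(t_min, df["fitted"], "-", label="model")
            ax.set_xlabel("time (min)")
            ax.set_ylabel("kBq/mL")
            ax.set_title(path.stem)
            ax.legend(fontsize=7)
            fig.tight_layout()
            body.append(f"<img class='fitplot' "
                        f"src='data:image/png;base64,{_png_b64(fig)}'/>")
        parts.append(_section("Regional fits", "\n".join(body)))
    else:
        parts.append(_section("Regional fits", _unavailable("regional fits")))

    motion_path = subject_dir / "motion.tsv"
    if motion_path.exists():
        df = pd.read_csv(motion_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3))
        for region, grp in df.groupby("region"):
            ax.plot(grp["frame"], grp["displacement_mm"], label=region)
        ax.set_xlabel("frame")
        ax.set_ylabel("displacement (mm)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        parts.append(_section(
            "Motion", f"<img src='data:image/png;base64,{_png_b64(fig)}'/>"))
    else:
        parts.append(_section("Motion", _unavailable("motion trace")))

    maps_dir = subject_dir / "maps"
    map_files = sorted(maps_dir.glob("*.nii*")) if maps_dir.is_dir() else []
    if map_files:
        import nibabel as nib

        body = []
        for path in map_files:
            vol = np.asarray(nib.load(str(path)).dataobj, float)
            fig, ax = plt.subplots(figsize=(3, 3))
            with np.errstate(invalid="ignore"):
                sl = np.nan_to_num(vol[:, :, vol.shape[2] // 2])
            ax.imshow(sl.T, origin="lower", cmap="inferno")
            ax.set_title(path.name.split(".")[0], fontsize=7)
            ax.axis("off")
            fig.tight_layout()
            body.append(f"<img src='data:image/png;base64,{_png_b64(fig)}'/>")
        parts.append(_section("Parametric maps", "\n".join(body)))
    else:
        parts.append(_section("Parametric maps", _unavailable("maps")))

    results_path = subject_dir / "results.tsv"
    if results_path.exists():
        df = read_results_table(results_path)
        vols = df[["region", "volume_mL"]].drop_duplicates().sort_values("region")
        parts.append(_section("ROI volumes",
                              vols.to_html(index=False, border=0)))
    else:
        parts.append(_section("ROI volumes", _unavailable("results table")))

    parts.append("</body></html>")
    out_html.write_text("\n".join(parts))
    return out_html
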