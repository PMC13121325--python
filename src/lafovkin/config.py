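"""Run configuration and pipeline orchestration.

A :class:`RunConfig` captures every tunable of the processing chain —
tracer, phantom geometry, IDIF extraction settings, fit bounds and restart
count, the delay grid, basis-bank settings, Patlak t*, per-organ trim
distances, clustering — and is validated strictly (unknown keys are
rejected) before any computation. :func:`run_pipeline` executes the stages
phantom → idif → fit → voxelwise → cluster → collect → qc, skipping stages
whose outputs already exist unless forced, and writes a machine-readable
run log.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import input_function as idifmod
from . import kinetics_fdg as fdg
from . import kinetics_water as water
from . import motion_roi, petdata, phantom, reporting, voxelwise

__all__ = ["RunConfig", "run_pipeline", "default_config"]


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int, int] = (96, 96, 192)
    voxel_size_mm: float = 3.0
    noise_alpha: float = 0.0
    psf_fwhm_mm: float = 0.0


class IdifConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    length_mm: float = 100.0
    search_radius_mm: float = 20.0
    continuity_mm: float = 10.0
    dilation_mm: float = 0.0


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_starts: int = 100
    k1_max: float = 18.0          # mL·min⁻¹·mL⁻¹ (1800 mL/(min·dL))
    va_max: float = 0.8
    delay_min_s: float = -5.0
    delay_max_s: float = 15.0
    delay_step_s: float = 0.5


class BasisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 500
    k2_min: float = 0.0
    k2_max: float = 6.0


class ClusterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 3
    linkage: str = "ward"
    regions: tuple[str, ...] = ("kidney_cortex",)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tracer: str = "H2O"
    subject: str = "phantom01"
    out_dir: str = "lafovkin_run"
    seed: int = 1
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    idif: IdifConfig = Field(default_factory=IdifConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    basis: BasisConfig = Field(default_factory=BasisConfig)
    t_star_min: float = 20.0
    trim_mm: dict[str, float] = Field(default_factory=dict)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    ncc_start_threshold: float = 0.8
    voxel_method: str = "basis"
    voxel_delay_step_s: float = 2.0   # coarser grid for the voxel lookup

    def delay_grid(self, step=None) -> list[float]:
        step = step or self.fit.delay_step_s
        n = int(round((self.fit.delay_max_s - self.fit.delay_min_s) / step))
        return [self.fit.delay_min_s + i * step for i in range(n + 1)]

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(**overrides) -> RunConfig:
    return RunConfig(**overrides)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(log, name, outputs, force, fn):
    """Run one stage unless all its outputs exist; record in the log."""
    outputs = [Path(p) for p in outputs]
    if outputs and all(p.exists() for p in outputs) and not force:
        log.append({"stage": name, "status": "skipped", "duration_s": 0.0})
        return True
    t0 = time.perf_counter()
    try:
        fn()
    except Exception as exc:  # noqa: BLE001 - report and stop the chain
        log.append({"stage": name, "status": "failed",
                    "duration_s": round(time.perf_counter() - t0, 3),
                    "error": f"{type(exc).__name__}: {exc}"})
        return False
    log.append({"stage": name, "status": "done",
                "duration_s": round(time.perf_counter() - t0, 3)})
    return True


def run_pipeline(config: RunConfig, force: bool = False) -> int:
    """Execute the full chain; returns 0 on success, 1 on stage failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    ctx: dict = {}

    pet_path = out / "pet.nii.gz"
    sidecar = out / "pet.json"
    seg_path = out / "seg.nii.gz"
    names_path = out / "seg_names.json"

    def stage_phantom():
        maker = phantom.default_water_spec if config.tracer == "H2O" \
            else phantom.default_fdg_spec
        spec = maker(seed=config.seed, shape=config.phantom.shape,
                     voxel_size_mm=config.phantom.voxel_size_mm,
                     noise_alpha=config.phantom.noise_alpha,
                     psf_fwhm_mm=config.phantom.psf_fwhm_mm)
        img, seg, truth = phantom.build_phantom(spec)
        petdata.write_dynamic_image(img, pet_path, sidecar, meta=spec.meta)
        petdata.write_label_image(seg, seg_path, names_path)
        ctx["meta"] = spec.meta

    ok = _stage(log, "phantom", [pet_path, sidecar, seg_path, names_path],
                force, stage_phantom)

    input_path = out / "input.tsv"
    idif_mask_path = out / "idif_mask.nii.gz"

    def stage_idif():
        img = petdata.read_dynamic_image(pet_path, sidecar)
        seg = petdata.read_label_image(seg_path, names_path)
        res = idifmod.extract_idif(
            img, seg, length_mm=config.idif.length_mm, tracer=config.tracer,
            search_radius_mm=config.idif.search_radius_mm,
            continuity_mm=config.idif.continuity_mm,
            dilation_mm=config.idif.dilation_mm)
        petdata.write_input_function(res.input, input_path)
        petdata.write_label_image(res.mask, idif_mask_path)

    if ok:
        ok = _stage(log, "idif", [input_path, idif_mask_path], force,
                    stage_idif)

    results_path = out / "results.tsv"
    fits_dir = out / "fits"

    def stage_fit():
        img = petdata.read_dynamic_image(pet_path, sidecar)
        seg = petdata.read_label_image(seg_path, names_path)
        meta = petdata.read_subject_meta(sidecar)
        inp = petdata.read_input_function(input_path)
        fits_dir.mkdir(exist_ok=True)
        rows = []
        liver_state = {}
        for label, region in sorted(seg.names.items()):
            if region in ("aorta", "idif_string"):
                continue
            mask = seg.mask(label)
            if region in config.trim_mm:
                mask = motion_roi.trim_roi(mask, config.trim_mm[region],
                                           seg.voxel_size_mm, name=region)
            vol_mL = float(mask.sum() * np.prod(seg.voxel_size_mm) / 1000.0)
            vals = np.asarray(img.voxels[mask], float).mean(axis=0)
            tac = petdata.TAC(img.schedule, vals, label=region)
            if config.tracer == "H2O":
                rows += _fit_water_region(config, tac, inp, region, vol_mL,
                                          fits_dir, liver_state)
            else:
                rows += _fit_fdg_region(config, tac, inp, meta, region,
                                        vol_mL, fits_dir)
        petdata.write_results_table(pd.DataFrame(rows), results_path)
        if liver_state:
            petdata.write_input_function(liver_state["input"],
                                         out / "liver_input.tsv")
            (out / "liver_fractions.json").write_text(json.dumps(
                {"r_a": liver_state["fractions"].r_a,
                 "r_pv": liver_state["fractions"].r_pv,
                 "beta_per_min": liver_state["fractions"].beta_per_min,
                 "delay_s": liver_state["delay_s"]}))
        # identity motion placeholder trace (no motion stage in this chain)
        transforms = [motion_roi.Transform6DOF()] * img.schedule.n_frames
        traces = motion_roi.motion_metric(seg, transforms)
        pd.DataFrame([
            {"region": name, "frame": f, "displacement_mm": d}
            for name, tr in sorted(traces.items())
            for f, d in enumerate(tr.displacement_mm)
        ]).to_csv(out / "motion.tsv", sep="\t", index=False)

    if ok:
        ok = _stage(log, "fit", [results_path], force, stage_fit)

    maps_dir = out / "maps"

    def stage_voxelwise():
        img = petdata.read_dynamic_image(pet_path, sidecar)
        seg = petdata.read_label_image(seg_path, names_path)
        meta = petdata.read_subject_meta(sidecar)
        inp = petdata.read_input_function(input_path)
        mask = seg.labels > 0
        if config.tracer == "H2O":
            liver_mask = None
            liver_input = None
            liver_delay = 0.0
            liver_json = out / "liver_fractions.json"
            if liver_json.exists():
                liver_mask = np.isin(
                    seg.labels,
                    [lab for lab, nm in seg.names.items() if nm == "liver"])
                liver_input = petdata.read_input_function(
                    out / "liver_input.tsv")
                liver_delay = json.loads(liver_json.read_text())["delay_s"]
            maps = voxelwise.parametric_water(
                img, inp, mask, method=config.voxel_method,
                delay_grid=config.delay_grid(config.voxel_delay_step_s),
                n_basis=config.basis.n,
                k2_range=(config.basis.k2_min, config.basis.k2_max),
                liver_mask=liver_mask, liver_input=liver_input,
                liver_delay_s=liver_delay)
        else:
            plasma = idifmod.blood_to_plasma(inp, meta.hematocrit)
            maps = voxelwise.parametric_fdg(img, plasma, mask,
                                            t_star_min=config.t_star_min,
                                            meta=meta)
        maps_dir.mkdir(exist_ok=True)
        maps.write(maps_dir, config.subject, config.tracer)

    if ok:
        ok = _stage(log, "voxelwise", [maps_dir], force, stage_voxelwise)

    def stage_cluster():
        seg = petdata.read_label_image(seg_path, names_path)
        import nibabel as nib

        param = "h2o_flow" if config.tracer == "H2O" else "Ki"
        map_path = maps_dir / f"{config.subject}_{config.tracer}_{param}.nii.gz"
        vol = np.asarray(nib.load(str(map_path)).dataobj, float)
        for region in config.cluster.regions:
            try:
                mask = seg.mask(region)
            except KeyError:
                continue
            labels = voxelwise.cluster_parametric(
                vol, mask, seg.voxel_size_mm, k=config.cluster.k,
                linkage=config.cluster.linkage, seed=config.seed,
                on_constant="single")
            petdata.write_label_image(labels,
                                      out / f"cluster_{region}.nii.gz")

    if ok:
        ok = _stage(log, "cluster",
                    [out / f"cluster_{r}.nii.gz"
                     for r in config.cluster.regions], force, stage_cluster)

    collected_path = out / "collected.tsv"

    def stage_collect():
        table, missing = reporting.collect_results([out])
        table.to_csv(collected_path, sep="\t", index=False,
                     float_format="%.10g")
        (out / "collect_missing.json").write_text(json.dumps(missing))

    if ok:
        ok = _stage(log, "collect", [collected_path], force, stage_collect)

    qc_path = out / "qc_report.html"

    def stage_qc():
        reporting.qc_report(out, qc_path)

    if ok:
        ok = _stage(log, "qc", [qc_path], force, stage_qc)

    (out / "run_log.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": log,
    }, indent=1))
    return 0 if ok else 1


def _fit_water_region(config, tac, inp, region, vol_mL, fits_dir,
                      liver_state) -> list[dict]:
    bounds = {"K1": (0.0, config.fit.k1_max), "p": (0.0, 1.0),
              "VA": (0.0, config.fit.va_max)}
    grid = config.delay_grid()
    if region == "liver":
        fractions, fit = water.fit_liver_fractions(
            tac, inp, bounds=bounds, n_starts=config.fit.n_starts,
            delay_grid=grid, seed=config.seed)
        liver_state["fractions"] = fractions
        liver_state["delay_s"] = fit.params.delay_s
        liver_state["input"] = idifmod.combined_liver_input(
            inp, idifmod.make_portal_input(
                inp, idifmod.PortalModelParams(fractions.beta_per_min)),
            fractions.r_a, fractions.r_pv)
        extra = [("r_a", fractions.r_a, "fraction"),
                 ("beta", fractions.beta_per_min, "1/min")]
    else:
        fit = water.fit_onetcm(tac, inp, bounds=bounds,
                               n_starts=config.fit.n_starts,
                               delay_grid=grid, seed=config.seed)
        extra = []
    _write_fit_tsv(fits_dir / f"{region}.tsv", tac, fit.fitted)
    p = fit.params
    rows = [
        ("K1", petdata.k1_to_ml_min_dl(p.K1), "mL/(min*dL)"),
        ("k2", p.k2, "1/min"),
        ("VA", p.VA, "fraction"),
        ("delay", p.delay_s, "s"),
        ("h2o_flow", petdata.k1_to_ml_min_dl(fit.h2o_flow), "mL/(min*dL)"),
        ("dv", fit.dv, "mL/mL"),
    ] + extra
    return [{"subject": config.subject, "region": region, "parameter": name,
             "value": value, "units": units, "R2": fit.r2,
             "volume_mL": vol_mL} for name, value, units in rows]


def _fit_fdg_region(config, tac, inp, meta, region, vol_mL, fits_dir
                    ) -> list[dict]:
    plasma = idifmod.blood_to_plasma(inp, meta.hematocrit)
    pat = fdg.patlak(tac, plasma, t_star_min=config.t_star_min)
    fur_v = fdg.fur(tac, plasma)
    suv_v = fdg.suv(tac, meta)
    lc = fdg.LumpedConstants()
    rows = [
        ("Ki", pat.Ki, "1/min"),
        ("V", pat.V, "mL/mL"),
        ("FUR", fur_v, "1/min"),
        ("SUV", suv_v, "g/mL"),
    ]
    if meta.plasma_glucose_mmol_L is not None:
        rows.append(("GU", fdg.glucose_uptake(pat.Ki, meta, lc, region),
                     "umol/(min*mL)"))
    # Patlak line in observed/fitted form for the QC plot
    sel = tac.schedule.mid_s >= config.t_star_min * 60.0
    fitted = np.full(tac.values.shape, np.nan)
    from ._numerics import resample_dense

    cp = resample_dense(plasma, tac.schedule.mid_s)
    from .kinetics_fdg import _plasma_integral_at

    fitted[sel] = (pat.Ki * _plasma_integral_at(plasma, tac.schedule.mid_s[sel])
                   + pat.V * cp[sel])
    _write_fit_tsv(fits_dir / f"{region}.tsv", tac,
                   petdata.TAC(tac.schedule, np.nan_to_num(fitted),
                               label=region))
    return [{"subject": config.subject, "region": region, "parameter": name,
             "value": value, "units": units, "R2": pat.r2,
             "volume_mL": vol_mL} for name, value, units in rows]


def _write_fit_tsv(path, observed, fitted) -> None:
    pd.DataFrame({
        "frame_start_s": observed.schedule.start_s,
        "frame_duration_s": observed.schedule.duration_s,
        "observed": observed.values,
        "fitted": fitted.values,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")
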