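"""End-to-end homogenisation workflow on the synthetic phantom.

Orchestrates the calibration chain: phantom generation, dual-echo B0 mapping,
current-limited spherical-harmonic shimming, the (predicted or re-simulated)
post-shim field, DREAM B1+ mapping, kT-points MLS pulse design, Bloch
validation, and SAR look-ahead — emitting a single JSON-serialisable report
whose every number is recomputed from the stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import b0map, b1map, bloch, ktpulse, phantom, sarmon, shim
from .core import save_json


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phantom: bool = True
    b0map: bool = True
    shim: bool = True
    b1map: bool = True
    design: bool = True
    bloch: bool = True
    inversion: bool = False
    sar: bool = True


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_shape: tuple[int, int, int] = (50, 50, 44)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    ellipsoid_semi_axes_mm: tuple[float, float, float] = (70.0, 85.0, 62.0)
    n_channels: int = 16
    noise_snr: float = 50.0


class B0MapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    te1_s: float = 1.00e-3
    te2_s: float = 3.21e-3
    mask_fraction: float = 0.5
    unwrap: bool = True


class ShimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    include_third_order: bool = True
    #: "predicted" uses the optimiser's predicted post-shim field;
    #: "resimulate" re-acquires a noisy field map under the applied shims.
    post_shim_field: str = "predicted"


class B1MapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_encode_steps: int = 32
    prep_scale_deg_per_ut: float = 55.5 / 0.1253


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_fa_deg: float = 15.0
    k_radius_per_m: float = 6.33
    n_axis_points: int = 6
    lambda_global: float = 1e-3
    lambda_local: float = 0.0
    region_growing: bool = True


class BlochConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    raster_s: float = 5e-6
    sta_check_fa_deg: float = 5.0


class SARConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tr_s: float = 61e-3
    n_fixture_matrices: int = 50
    vop_epsilon: float = 0.05


class WorkflowConfig(BaseModel):
    """Schema-validated workflow configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    stages: StageToggles = StageToggles()
    phantom: PhantomConfig = PhantomConfig()
    b0map: B0MapConfig = B0MapConfig()
    shim: ShimConfig = ShimConfig()
    b1map: B1MapConfig = B1MapConfig()
    design: DesignConfig = DesignConfig()
    bloch: BlochConfig = BlochConfig()
    sar: SARConfig = SARConfig()
    seed: int = 0
    outdir: Optional[str] = None

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "WorkflowConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate(json.loads(text))


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute the homogenisation chain and return the report bundle."""
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    artifacts: dict = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    order = [
        ("phantom", _stage_phantom),
        ("b0map", _stage_b0map),
        ("shim", _stage_shim),
        ("b1map", _stage_b1map),
        ("design", _stage_design),
        ("bloch", _stage_bloch),
        ("inversion", _stage_inversion),
        ("sar", _stage_sar),
    ]
    for name, fn in order:
        if not getattr(config.stages, name):
            continue
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn(config, artifacts, outdir)
        except Exception as err:  # noqa: BLE001 - stage-tagged abort
            raise StageError(name, err) from err
        report["stages"][name]["elapsed_s"] = round(time.perf_counter() - t0, 3)

    if outdir:
        save_json(report, outdir / "report.json")
        if "b0_post" in artifacts:
            from .report import save_panels

            save_panels(artifacts, outdir)
    return report


def _stage_phantom(config: WorkflowConfig, art: dict, outdir) -> dict:
    spec = phantom.PhantomSpec(
        grid_shape=tuple(config.phantom.grid_shape),
        voxel_size_mm=tuple(config.phantom.voxel_size_mm),
        ellipsoid_semi_axes_mm=tuple(config.phantom.ellipsoid_semi_axes_mm),
        n_channels=config.phantom.n_channels,
        noise_snr=config.phantom.noise_snr,
        seed=config.seed,
    )
    art["spec"] = spec
    art["mask_true"] = phantom.make_head_mask(spec)
    art["b0_true"] = phantom.make_b0_map(spec, art["mask_true"])
    art["b1_true"] = phantom.make_b1_maps(spec, art["mask_true"])
    if outdir:
        phantom.write_phantom(spec, outdir / "phantom")
    return {
        "n_mask_voxels": art["mask_true"].n_voxels,
        "n_channels": spec.n_channels,
        "spec_hash": spec.spec_hash(),
    }


def _stage_b0map(config: WorkflowConfig, art: dict, outdir) -> dict:
    cfg = config.b0map
    spec = art["spec"]
    e1, e2 = phantom.simulate_dual_echo_gre(
        art["b0_true"], art["mask_true"], cfg.te1_s, cfg.te2_s,
        snr=spec.noise_snr, seed=config.seed + 1,
    )
    dte = cfg.te2_s - cfg.te1_s
    mask = b0map.threshold_mask(np.abs(e1), spec.affine, cfg.mask_fraction)
    fmap = b0map.phase_difference_fieldmap(e1, e2, dte, spec.affine)
    if cfg.unwrap:
        fmap = b0map.unwrap_phase(fmap, mask, dte)
    art["mask"] = mask
    art["b0_measured"] = b0map.FieldMap(fmap.values, spec.affine, mask)
    stats = b0map.field_statistics(art["b0_measured"], mask)
    if outdir:
        art["b0_measured"].save(outdir / "b0_measured_hz.nii")
        mask.save(outdir / "mask_measured.nii")
    return {"pre_shim_stats": stats.as_dict()}


def _stage_shim(config: WorkflowConfig, art: dict, outdir) -> dict:
    cal = phantom.make_shim_calibration(seed=config.seed + 2)
    b0_meas = art["b0_measured"]
    mask = art["mask"]
    first_second = ["X", "Y", "Z", "Z2", "ZX", "ZY", "X2Y2", "XY"]
    subset = cal.names() if config.shim.include_third_order else first_second
    setting = shim.optimize_shim_currents(b0_meas, cal, mask, subset)
    setting_12 = shim.optimize_shim_currents(b0_meas, cal, mask, first_second)
    predicted = shim.predict_shimmed_field(b0_meas, cal, setting, mask)
    if config.shim.post_shim_field == "resimulate":
        truth_shimmed = shim.predict_shimmed_field(art["b0_true"], cal, setting, mask)
        e1, e2 = phantom.simulate_dual_echo_gre(
            truth_shimmed, art["mask_true"],
            config.b0map.te1_s, config.b0map.te2_s,
            snr=art["spec"].noise_snr, seed=config.seed + 3,
        )
        dte = config.b0map.te2_s - config.b0map.te1_s
        fmap = b0map.phase_difference_fieldmap(e1, e2, dte, art["spec"].affine)
        post = b0map.unwrap_phase(fmap, mask, dte)
        art["b0_post"] = b0map.FieldMap(post.values, art["spec"].affine, mask)
    else:
        art["b0_post"] = predicted
    post_stats = b0map.field_statistics(art["b0_post"], mask)
    if outdir:
        art["b0_post"].save(outdir / "b0_post_shim_hz.nii")
        save_json(setting.as_dict(), outdir / "shim_setting.json")
    return {
        "currents": setting.currents,
        "post_shim_stats": post_stats.as_dict(),
        "post_shim_stats_first_second_only": setting_12.predicted_stats.as_dict(),
        "within_limits": all(
            abs(v) <= cal.coil(n).limit + 1e-9 for n, v in setting.currents.items()
        ),
    }


def _stage_b1map(config: WorkflowConfig, art: dict, outdir) -> dict:
    spec = art["spec"]
    enc = b1map.dft_encoding(spec.n_channels, config.b1map.n_encode_steps)
    signals = phantom.simulate_dream_signals(
        art["b1_true"], enc, config.b1map.prep_scale_deg_per_ut,
        snr=spec.noise_snr, seed=config.seed + 4,
    )
    decoded, cond = b1map.decode_dream(signals, spec.affine, art["mask"])
    art["b1_measured"] = b1map.reference_phases(decoded)
    if outdir:
        art["b1_measured"].save(outdir / "b1_measured")
    # relative error up to one global phase (re-referencing is part of recon)
    meas = art["b1_measured"].maps[:, art["mask"].data]
    true = art["b1_true"].maps[:, art["mask"].data]
    phi = np.angle(np.vdot(meas, true))
    rel = float(np.linalg.norm(meas * np.exp(1j * phi) - true) / np.linalg.norm(true))
    return {
        "encoding_condition_number": cond,
        "relative_map_error": rel,
    }


def _stage_design(config: WorkflowConfig, art: dict, outdir) -> dict:
    cfg = config.design
    traj = ktpulse.make_ktpoints_trajectory(cfg.k_radius_per_m, cfg.n_axis_points)
    b1 = art.get("b1_measured", art["b1_true"])
    mask = art.get("mask", art["mask_true"])
    b0_post = art.get("b0_post")
    system = ktpulse.build_sta_system(b1, b0_post, traj, mask)
    solver = ktpulse.region_growing_solve if cfg.region_growing else ktpulse.solve_mls
    weights = solver(
        system,
        cfg.target_fa_deg,
        lambda_global=cfg.lambda_global,
        lambda_local=cfg.lambda_local,
        seed=config.seed,
    )
    art["traj"] = traj
    art["system"] = system
    art["weights"] = weights
    designed = ktpulse.predict_flip_angle(system, weights)
    art["designed_fa"] = designed
    design_nrmse = ktpulse.nrmse(designed, cfg.target_fa_deg, mask)

    # CP-mode baseline: centre-point CP drive scaled to the same mean flip
    cp = np.abs(b1.cp_combined())[mask.data]
    cp_flip = cp * cfg.target_fa_deg / cp.mean()
    cp_nrmse = float(
        100.0 * np.sqrt(np.mean((cp_flip - cfg.target_fa_deg) ** 2)) / cfg.target_fa_deg
    )
    if outdir:
        designed.save(outdir / "designed_flip_deg.nii")
        ktpulse.export_pulse(weights, traj, outdir / "pulse")
    return {
        "pulse_duration_ms": traj.duration * 1e3,
        "design_nrmse_percent": design_nrmse,
        "cp_mode_nrmse_percent": cp_nrmse,
        "min_flip_fraction": weights.metadata.get("min_flip_fraction"),
        "iterations": weights.metadata.get("iterations"),
    }


def _stage_bloch(config: WorkflowConfig, art: dict, outdir) -> dict:
    cfg = config.bloch
    system, weights, traj = art["system"], art["weights"], art["traj"]
    mask = system.mask
    b1 = art.get("b1_measured", art["b1_true"])
    target = config.design.target_fa_deg
    # small-tip consistency check at a <=5 degree scaled target
    scale = cfg.sta_check_fa_deg / target
    small = ktpulse.RFWeights(weights.weights * scale)
    wave = ktpulse.assemble_waveforms(small, traj, cfg.raster_s)
    mag = bloch.bloch_simulate(wave, b1, art.get("b0_post"), mask)
    sta = system.flip(small.flat)
    rel = np.abs(mag.flip_deg - sta) / np.maximum(sta, 1e-9)
    # full-target validation
    wave_full = ktpulse.assemble_waveforms(weights, traj, cfg.raster_s)
    mag_full = bloch.bloch_simulate(wave_full, b1, art.get("b0_post"), mask)
    flip_map = mag_full.flip_angle_map(target)
    bloch_nrmse = ktpulse.nrmse(flip_map, target, mask)
    if outdir:
        flip_map.save(outdir / "bloch_flip_deg.nii")
    return {
        "sta_bloch_max_rel_error": float(rel.max()),
        "bloch_nrmse_percent": bloch_nrmse,
        "norm_error_max": float(np.abs(np.linalg.norm(mag_full.m, axis=1) - 1.0).max()),
    }


def _stage_inversion(config: WorkflowConfig, art: dict, outdir) -> dict:
    """Adiabatic inversion comparison on the CP-mode combined field."""
    b1 = art.get("b1_measured", art["b1_true"])
    mask = art.get("mask", art["mask_true"])
    # decimate for speed: adiabatic pulses are thousands of raster steps
    dec = np.zeros_like(mask.data)
    dec[::2, ::2, ::2] = True
    sub = b0map.Mask(mask.data & dec, mask.affine)
    cp = b1.cp_combined()[None]
    cp_set = b1map.B1MapSet(cp, b1.affine, sub)
    hs = bloch.hs_pulse(peak_v=166.0)
    foci = bloch.foci_pulse(peak_v=79.8)
    res = {}
    for name, wave in (("hyperbolic_secant", hs), ("foci", foci)):
        mag = bloch.bloch_simulate(wave, cp_set, art.get("b0_post"), sub)
        res[f"{name}_nrmse_percent"] = bloch.inversion_nrmse(mag)
        res[f"{name}_inverted_fraction"] = float(np.mean(mag.m[:, 2] < -0.9))
    return res


def _stage_sar(config: WorkflowConfig, art: dict, outdir) -> dict:
    cfg = config.sar
    spec = art["spec"]
    mats = sarmon.random_psd_matrices(
        cfg.n_fixture_matrices, spec.n_channels, seed=config.seed + 5, scale=1e-5
    )
    vops = sarmon.vop_compress(mats, cfg.vop_epsilon)
    report = sarmon.pulse_sar(
        art["weights"], vops, cfg.tr_s, subpulse_dur=art["traj"].subpulse_dur
    )
    seq = sarmon.sequence_lookahead(
        [(art["weights"], art["traj"].subpulse_dur)], vops, cfg.tr_s
    )
    if outdir:
        save_json(seq.as_dict(), outdir / "sar_report.json")
    return {
        "n_vops": vops.n_vops,
        "pulse": report.as_dict(),
        "sequence": seq.as_dict(),
    }
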