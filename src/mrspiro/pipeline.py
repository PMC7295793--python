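"""End-to-end orchestration: phantom/fields -> kinematics -> spirometry.

A :class:`RunConfig` fully describes one run and is serialized into the
output directory, so any run is reproducible from its own record. Stages are
executed in order with structured logging; any stage error aborts the run
with the stage name attached.
"""

from __future__ import annotations

import json
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grid_io, kinematics, phantom, selfgating, spirometry
from .grid_io import BinTiming, DisplacementField4D, ImageGrid, LungMask


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Reproducible description of one pipeline run."""

    mode: str = "phantom"               # "phantom" | "fields"
    out_dir: str = "mrspiro_run"
    n_bins: int = 32
    seed: int = 0
    # phantom mode
    breathing_mode: str = "normal"
    grid_size: int = 48
    spacing_mm: float = 4.0
    hysteresis_phase: float = 0.15
    render_volumes: bool = False
    selfgate_demo: bool = False
    # fields mode
    field_paths: list[str] = field(default_factory=list)
    mask_path: str | None = None
    timing_path: str | None = None
    displacement_convention: str = "lagrangian_forward"
    # processing
    smoothing: float | str = 0.0
    k_mad: float = 3.0
    sharing_fraction: float = 0.5
    softgate_sigma: float | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))


@contextmanager
def _stage(name: str, log: list[str]):
    t0 = time.perf_counter()
    try:
        yield
    except Exception as e:
        raise StageError(f"stage '{name}' failed: {e}") from e
    log.append(f"{name}: {time.perf_counter() - t0:.2f} s")


def _load_inputs(config: RunConfig):
    """Displacement field, mask, timing and (phantom only) analytic truth."""
    if config.mode == "phantom":
        spec = phantom.PhantomSpec.preset(
            config.breathing_mode,
            grid=ImageGrid(
                (config.grid_size,) * 3, (config.spacing_mm,) * 3
            ),
            n_bins=config.n_bins,
            hysteresis_phase=config.hysteresis_phase,
            seed=config.seed,
        )
        u, truth = phantom.make_displacement(spec)
        return u, truth.mask, truth.timing, spec, truth
    if config.mode == "fields":
        if not config.field_paths or not config.mask_path or not config.timing_path:
            raise ValueError(
                "fields mode requires field_paths, mask_path and timing_path"
            )
        mask = grid_io.read_mask(config.mask_path)
        timing = grid_io.read_bin_timing(config.timing_path)
        u = grid_io.read_displacement_fields(
            config.field_paths,
            convention=config.displacement_convention,
            mask=mask,
        )
        return u, mask, timing, None, None
    if config.mode == "volumes":
        raise ValueError(
            "volumes mode provides no displacement fields and image "
            "registration is outside this tool's scope; register externally "
            "and pass the fields via 'fields' mode"
        )
    raise ValueError(f"unknown pipeline mode {config.mode!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write every product to ``config.out_dir``.

    Returns the summary dict (also written as ``summary.json``): FA mean/sd
    over the mask, folding-voxel count, nonphysical-strain count, whole-lung
    cycle-closure residual, and small-strain residual quantiles.
    """
    out = Path(config.out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = []

    with _stage("inputs", log):
        u, mask, timing, spec, truth = _load_inputs(config)
        grid = u.grid
        grid_io.write_mask(mask, out / "mask.nii")
        grid_io.write_bin_timing(timing, out / "timing.csv")

    if config.mode == "phantom" and config.render_volumes:
        with _stage("render", log):
            vols = phantom.render_volumes(spec, u)
            grid_io.write_volume_series(vols, out / "volumes")

    selfgate_summary = {}
    if config.mode == "phantom" and config.selfgate_demo:
        with _stage("selfgating", log):
            stream, sg_truth = phantom.make_spoke_stream(
                spec, noise_sd=0.1, outlier_periods=(5, 12)
            )
            nav = selfgating.extract_navigator(stream)
            periods = selfgating.detect_periods(nav)
            kept, rejlog = selfgating.reject_outlier_periods(periods, config.k_mad)
            assignment = selfgating.assign_bins(
                nav,
                kept,
                n_bins=config.n_bins,
                sharing_fraction=config.sharing_fraction,
                softgate_sigma=config.softgate_sigma,
            )
            sg_timing = selfgating.timestamp_bins(assignment, kept, stream)
            selfgating.write_assignment(assignment, out / "bin_assignment.csv")
            grid_io.write_bin_timing(sg_timing, out / "selfgated_timing.csv")
            rejlog.to_csv(out / "period_rejection.csv", index=False)
            rho = np.corrcoef(nav.value, sg_truth["waveform"])[0, 1]
            selfgate_summary = {
                "navigator_abs_correlation": round(abs(float(rho)), 6),
                "periods_rejected": int(rejlog["rejected"].sum()),
                "empty_bins": len(assignment.empty_bins),
            }

    with _stage("smoothing", log):
        if config.smoothing != 0.0:
            u = kinematics.smooth_fields_temporally(u, config.smoothing)

    with _stage("kinematics", log):
        F = kinematics.deformation_gradient(u, mask)
        J = kinematics.jacobian(F)
        strain = kinematics.green_lagrange(F)
        principal = kinematics.principal_strains(strain)
        fa = kinematics.fractional_anisotropy(principal)
        ss = kinematics.check_small_strain(J, strain, region=F.interior)

    with _stage("spirometry", log):
        flow = spirometry.regional_flow(J, timing)
        loops = spirometry.build_loops(J, flow, mask, scope="whole")
        closure_signed, closure_mass = spirometry.cycle_closure(
            flow, region=F.interior
        )
        metrics = spirometry.spiro_metrics(J, timing, mask)
        sample = [tuple(v) for v in np.argwhere(mask.membership)[::200]]
        trajectories = spirometry.voxel_trajectories(u, sample, timing)

    with _stage("outputs", log):
        end_insp = int(np.argmax(J.J[:, mask.membership].mean(axis=1)))
        grid_io.write_map(np.moveaxis(J.J, 0, -1), grid, out / "maps" / "J.nii")
        grid_io.write_map(np.moveaxis(fa.FA, 0, -1), grid, out / "maps" / "FA.nii")
        grid_io.write_map(
            strain.eps[end_insp], grid, out / "maps" / "strain_end_insp.nii"
        )
        grid_io.write_map(
            principal.eps_principal[end_insp],
            grid,
            out / "maps" / "principal_strains_end_insp.nii",
        )
        grid_io.write_map(metrics.LTV, grid, out / "maps" / "LTV.nii")
        if metrics.lev1_defined:
            grid_io.write_map(metrics.LEV1, grid, out / "maps" / "LEV1.nii")
        kinematics.fa_summary(fa, mask).to_csv(out / "fa_summary.csv", index=False)
        whole = loops[0]
        pd.DataFrame(
            {
                "bin": np.arange(timing.n_bins),
                "time_s": timing.times,
                "phase": timing.phase,
                "V_mm3": whole.volume,
                "Q_mm3_per_s": whole.flow,
            }
        ).to_csv(out / "whole_lung_loop.csv", index=False)
        traj_rows = []
        for tr in trajectories:
            for k in range(u.n_bins):
                traj_rows.append(
                    {
                        "voxel": str(tr.index),
                        "bin": k,
                        "x_mm": tr.positions[k, 0],
                        "y_mm": tr.positions[k, 1],
                        "z_mm": tr.positions[k, 2],
                        "phase": tr.phase[k],
                    }
                )
        pd.DataFrame(traj_rows).to_csv(out / "trajectories.csv", index=False)

    m = mask.membership
    fa_end = fa.FA[end_insp][m]
    summary = {
        "mode": config.mode,
        "breathing_mode": config.breathing_mode if config.mode == "phantom" else None,
        "n_bins": int(timing.n_bins),
        "lung_voxels": int(mask.n_voxels),
        "end_inspiration_bin": end_insp,
        "fa_mean_end_insp": round(float(np.nanmean(fa_end)), 6),
        "fa_sd_end_insp": round(float(np.nanstd(fa_end)), 6),
        "folding_voxels": int(J.folding_mask.sum()),
        "nonphysical_strain_voxels": int(principal.nonphysical.sum()),
        "cycle_closure_relative": round(
            closure_signed / max(closure_mass, 1e-30), 8
        ),
        "small_strain_residual_median": round(
            float(ss.quantiles["median"].max()), 8
        ),
        "small_strain_residual_max": round(float(ss.quantiles["max"].max()), 8),
        "ltv_total_mm3": round(float(metrics.LTV[m].sum()), 3),
        **selfgate_summary,
    }
    if truth is not None:
        err = np.abs(J.J[:, F.interior] - truth.J_true[:, F.interior])
        summary["jacobian_max_abs_error_vs_truth"] = round(float(err.max()), 8)
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as f:
        f.write("\n".join(log) + "\n")
    return summary
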