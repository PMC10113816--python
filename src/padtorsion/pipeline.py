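"""Per-trial analysis pipeline and condition sweeps.

``analyze_trial`` ties the stages together in the order the data dictates:
smooth the tracked displacements, mesh the reference features, decide
per-frame contact membership from the masks, then derive strain fields,
slip propagation, contact accounting and the friction numbers from the
force/torque traces.  ``run_sweep`` repeats trials over force or velocity
ladders and fits the friction and contact-area power laws.

Disk artefacts are plain text (CSV tables, JSON/YAML key-value files) plus
a multipage TIFF for mask stacks, with a manifest recording config hash and
seed so a run is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import contact as contact_mod
from . import friction as friction_mod
from . import slip as slip_mod
from . import strain as strain_mod
from .config import PipelineConfig, config_hash
from .friction import PowerLawFit, TrialTraces
from .strain import ElasticParams, TrajectorySet
from .synth import GroundTruth, SimulatedTrial, SynthParams, simulate_trial

logger = logging.getLogger(__name__)

__all__ = [
    "TrialResult",
    "analyze_trial",
    "run_sweep",
    "write_trial",
    "read_trial",
    "write_results",
]


@dataclass
class TrialResult:
    """Everything the per-trial analysis derives."""

    strain_field: strain_mod.StrainField
    cumulative: dict
    slip: slip_mod.SlipSeries
    contact: contact_mod.ContactSeries
    decomposition: dict
    energy: dict
    t_slip_nm: float | None
    mu_rot_m: float | None
    work_j: float
    summary: dict


def analyze_trial(
    traj: TrajectorySet,
    masks: np.ndarray,
    traces: TrialTraces,
    config: PipelineConfig | None = None,
) -> TrialResult:
    """Run the full analysis chain on one trial's raw inputs."""
    cfg = config or PipelineConfig()
    smoothed = strain_mod.smooth_displacements(
        traj, cfg.smoothing_window, cfg.smoothing_sigma_frames
    )
    mesh = strain_mod.build_mesh(smoothed)
    mesh.in_contact = contact_mod.triangles_in_contact(mesh, masks)
    logger.info(
        "trial: %d features, %d triangles, %d frames",
        traj.n_features, mesh.n_triangles, traj.n_frames,
    )

    elastic = ElasticParams(
        E=cfg.young_modulus_pa, nu=cfg.poisson_ratio, p_depth=cfg.energy_depth_m
    )
    sf = strain_mod.compute_strain_field(mesh, elastic)
    cumulative = strain_mod.accumulate_strain(sf)
    energy = strain_mod.energy_series(mesh, traj.time_s, elastic, sf)

    slip_series = slip_mod.compute_slip_series(
        mesh, traj.plate_angle_deg, cfg.slip_threshold_deg_per_frame, cfg.stick_cutoff
    )
    contact_series = contact_mod.compute_contact_series(mesh, masks, cfg.px_per_mm)
    decomposition = contact_mod.area_reduction_decomposition(contact_series)

    filt = friction_mod.filter_signals(traces, cfg.butter_order, cfg.butter_cutoff_hz)
    t_slip = friction_mod.extract_t_slip(filt, cfg.tslip_anchor_deg, cfg.tslip_window_s)
    mu = friction_mod.mu_rot(t_slip, float(np.median(filt.fn_n))) if t_slip else None
    work, _ = friction_mod.external_work(filt)

    summary = {
        "n_features": traj.n_features,
        "n_triangles": mesh.n_triangles,
        "contact_area0_mm2": float(contact_series.area_mm2[0]),
        "area_change_rel": decomposition["total_change_rel"],
        "peeling_rel": decomposition["peeling_rel"],
        "deformation_rel": decomposition["deformation_rel"],
        "full_slip_frame": slip_series.full_slip_frame,
        "full_slip_angle_deg": slip_series.full_slip_angle_deg,
        "median_es_end": cumulative["median_es_end"],
        "median_ea_total": cumulative["median_ea_total"],
        "total_energy_j": float(energy["U"][-1]),
        "t_slip_nm": t_slip,
        "mu_rot_mm": None if mu is None else mu * 1e3,
        "external_work_j": work,
    }
    return TrialResult(
        strain_field=sf,
        cumulative=cumulative,
        slip=slip_series,
        contact=contact_series,
        decomposition=decomposition,
        energy=energy,
        t_slip_nm=t_slip,
        mu_rot_m=mu,
        work_j=work,
        summary=summary,
    )


def analyze_simulated(trial: SimulatedTrial, config: PipelineConfig | None = None) -> TrialResult:
    """Convenience wrapper: analyze a SimulatedTrial bundle."""
    return analyze_trial(trial.trajectories, trial.masks, trial.traces, config)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def run_sweep(
    conditions: list[SynthParams],
    config: PipelineConfig | None = None,
    analyze: bool = True,
) -> tuple[pd.DataFrame, dict[str, PowerLawFit]]:
    """Simulate and analyse a list of conditions; fit the power laws.

    Returns a tidy one-row-per-trial summary and, when at least three
    distinct force levels are present, least-squares fits of
    mu_rot = k F_N^(n-1) (k in mm) and A0 = a F_N^b.  With ``analyze``
    False only the trace- and mask-level quantities are computed (cheap).
    """
    if not conditions:
        raise ValueError("empty condition grid")
    cfg = config or PipelineConfig()
    rows = []
    for params in conditions:
        trial = simulate_trial(params)
        if analyze:
            res = analyze_simulated(trial, cfg)
            row = dict(res.summary)
        else:
            filt = friction_mod.filter_signals(
                trial.traces, cfg.butter_order, cfg.butter_cutoff_hz
            )
            t_slip = friction_mod.extract_t_slip(
                filt, cfg.tslip_anchor_deg, cfg.tslip_window_s
            )
            work, _ = friction_mod.external_work(filt)
            row = {
                "contact_area0_mm2": contact_mod.contact_area(
                    trial.masks[0], params.px_per_mm
                ),
                "t_slip_nm": t_slip,
                "mu_rot_mm": None
                if t_slip is None
                else friction_mod.mu_rot(t_slip, params.F_N) * 1e3,
                "external_work_j": work,
            }
        row.update(
            {
                "F_N": params.F_N,
                "omega_dps": params.omega,
                "direction": params.direction,
                "seed": params.seed,
                "gt_full_slip_angle_deg": trial.ground_truth.full_slip_angle_deg,
                "gt_torque_plateau_nm": trial.ground_truth.torque_plateau_nm,
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows)

    fits: dict[str, PowerLawFit] = {}
    forces = df["F_N"].to_numpy()
    if len(np.unique(forces)) >= 3:
        mu_mm = pd.to_numeric(df["mu_rot_mm"], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(mu_mm)
        if len(np.unique(forces[ok])) >= 3:
            fits["mu_rot"] = friction_mod.fit_power_law(
                forces[ok], mu_mm[ok], model="mu"
            )
        else:
            logger.warning("too few trials with a defined T_slip: mu_rot fit skipped")
        fits["area"] = friction_mod.fit_power_law(
            forces, df["contact_area0_mm2"].to_numpy(dtype=float), model="area"
        )
    else:
        logger.warning("fewer than 3 force levels: power-law fits skipped")
    return df, fits


# ---------------------------------------------------------------------------
# disk artefacts
# ---------------------------------------------------------------------------

def _file_checksums(paths: list[Path]) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16] for p in sorted(paths)
    }


def write_trial(trial: SimulatedTrial, out_dir: str | Path) -> Path:
    """Write a simulated trial's artefacts + manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj_path = out / "trajectories.csv"
    trial.trajectories.to_table().to_csv(traj_path, index=False, float_format="%.6f")
    traces_path = out / "traces.csv"
    trial.traces.to_table().to_csv(traces_path, index=False, float_format="%.9f")
    masks_path = out / "masks.tif"
    tifffile.imwrite(masks_path, (trial.masks.astype(np.uint8) * 255))
    gt = trial.ground_truth
    gt_payload = {k: _plain(v) for k, v in dataclasses.asdict(gt).items()}
    gt_path = out / "ground_truth.yaml"
    gt_path.write_text(yaml.safe_dump(gt_payload))
    params = {k: _plain(v) for k, v in dataclasses.asdict(trial.params).items()}
    (out / "params.yaml").write_text(yaml.safe_dump(params))
    manifest = {
        "config_hash": config_hash(params),
        "seed": trial.params.seed,
        "files": _file_checksums([traj_path, traces_path, masks_path, gt_path]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_trial(trial_dir: str | Path) -> SimulatedTrial:
    """Read a trial directory back into memory (schema errors name the file)."""
    d = Path(trial_dir)
    params_raw = yaml.safe_load((d / "params.yaml").read_text())
    params_raw["contact_law"] = tuple(params_raw["contact_law"])
    if params_raw.get("rotation_center_px") is not None:
        params_raw["rotation_center_px"] = tuple(params_raw["rotation_center_px"])
    params = SynthParams(**params_raw)
    try:
        traj = TrajectorySet.from_table(
            pd.read_csv(d / "trajectories.csv"), px_per_mm=params.px_per_mm
        )
    except ValueError as err:
        raise ValueError(f"{d / 'trajectories.csv'}: {err}") from err
    try:
        traces = TrialTraces.from_table(
            pd.read_csv(d / "traces.csv"), direction=params.direction
        )
    except ValueError as err:
        raise ValueError(f"{d / 'traces.csv'}: {err}") from err
    masks = tifffile.imread(d / "masks.tif") > 0
    if masks.ndim == 2:
        masks = masks[None]
    gt_raw = yaml.safe_load((d / "ground_truth.yaml").read_text())
    gt = GroundTruth(
        **{
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in gt_raw.items()
        }
    )
    gt.rotation_center_px = tuple(gt.rotation_center_px)
    return SimulatedTrial(
        params=params, trajectories=traj, masks=masks, traces=traces, ground_truth=gt
    )


def write_results(
    result: TrialResult,
    out_dir: str | Path,
    full_tables: bool = False,
    figure: bool = True,
) -> Path:
    """Write analysis outputs: summary, slip/contact series, optional big tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.yaml").write_text(
        yaml.safe_dump({k: _plain(v) for k, v in result.summary.items()})
    )
    result.slip.to_table().to_csv(out / "slip_series.csv", index=False)
    result.contact.to_table().to_csv(out / "contact_series.csv", index=False)
    pd.DataFrame(
        {
            "time_s": result.energy["time_s"],
            "U_j": result.energy["U"],
        }
    ).to_csv(out / "energy_series.csv", index=False)
    if full_tables:
        result.strain_field.to_table().to_csv(out / "strain_field.csv", index=False)
    if figure:
        _overview_figure(result, out / "overview.png")
    return out


def _plain(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer, np.bool_)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_plain(x) for x in v]
    return v


def _overview_figure(result: TrialResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=False)
    axes[0].plot(result.slip.twist_deg, result.slip.stick_ratio, "k-")
    axes[0].axhline(0.03, ls="--", c="grey")
    axes[0].set_ylabel("stick ratio")
    axes[0].set_xlabel("twist (deg)")
    axes[1].plot(result.contact.area_mm2, "k-")
    axes[1].set_ylabel("contact area (mm$^2$)")
    axes[1].set_xlabel("frame")
    axes[2].plot(result.energy["time_s"], 1e3 * result.energy["U"], "k-")
    axes[2].set_ylabel("strain energy (mJ)")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
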