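"""End-to-end orchestration: simulate or ingest → decimate → drift-correct
→ QC → mobility metrics → mixture fits → diagnostics, from a single config.

Every stage writes a CSV with a fixed header into the output directory and
a run log records the seed, thresholds and package versions, so a run is
reproducible from its log alone. Identical config + seed gives identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import (
    angle_uniformity_test,
    axis_bias_test,
    state_switch_flagger,
    stepsize_vs_time_test,
)
from .errors import NucleotrackError, ParameterError
from .io import load_manifest, write_trajectories
from .metrics import (
    average_msd,
    compute_msd,
    compute_steps,
    condition_summary,
    diffusion_per_trajectory,
    trajectory_summary,
    TRAJECTORY_SUMMARY_FIELDS,
)
from .mixture import fit_step_mixture, select_mixture, stuck_effective_diffusion, stuck_vs_d1_ftest
from .preprocess import QCRules, apply_drift_correction, decimate_frames, estimate_drift, qc_filter
from .synthetic import params_from_config, simulate_condition, write_ground_truth

log = logging.getLogger("nucleotrack")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one condition).

    Exactly one input mode is active: ``simulate`` generates a synthetic
    condition from motion parameters; ``files`` ingests a manifest of
    coordinate CSVs.
    """

    mode: str  # 'simulate' | 'files'
    outdir: str = "nucleotrack_out"
    seed: int = 0
    condition: str = "condition"
    simulate: dict = field(default_factory=dict)  # MotionParams keys + n_videos, n_particles
    manifest: str | None = None
    decimate: bool = False  # True when inputs are at the raw 1 s scan rate
    drift_correction: bool = True
    qc: dict = field(default_factory=dict)  # QCRules keys
    mixture: dict = field(default_factory=dict)  # delta_bic_threshold, n_starts, sigma_floor
    diagnostics: dict = field(default_factory=dict)  # n_bins, alpha
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ParameterError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and not self.manifest:
            raise ParameterError("files mode requires a manifest path")
        if self.mode == "simulate" and self.manifest:
            raise ParameterError("exactly one input mode may be active")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return str(path)


def _acquire(config: RunConfig, outdir: Path) -> tuple[list, list[str]]:
    """Return (videos, written files); simulate mode also writes its inputs."""
    written = []
    if config.mode == "simulate":
        params = params_from_config(config.simulate)
        n_videos = int(config.simulate.get("n_videos", 3))
        n_particles = int(config.simulate.get("n_particles", 80))
        videos, truths = simulate_condition(
            params, n_videos, n_particles, config.seed, condition=config.condition
        )
        written.append(str(write_trajectories(videos, outdir / "trajectories.csv")))
        merged_states = {}
        for gt in truths:
            merged_states.update(gt.states)
        # drift of the longest video covers the sidecar's per-frame rows
        drift = max((gt.drift for gt in truths), key=len)
        truths[0].states = merged_states
        truths[0].drift = drift
        written.append(str(write_ground_truth(truths[0], outdir / "ground_truth.csv")))
        return videos, written
    pairs = load_manifest(config.manifest)
    videos = []
    for ds, entry in pairs:
        ds._drift_corrected_upstream = bool(entry.get("drift_corrected", False))
        videos.append(ds)
    return videos, written


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for one condition; returns a manifest of outputs.

    Any stage failure is logged with its stage name and re-raised, so shell
    callers exit nonzero.
    """
    logging.basicConfig(level=config.verbosity, stream=sys.stderr, format="%(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "acquire"
    try:
        videos, written = _acquire(config, outdir)
        if written:
            outputs["trajectories"], outputs["ground_truth"] = written

        stage = "decimate"
        if config.decimate:
            videos = [decimate_frames(v) for v in videos]

        stage = "drift"
        if config.drift_correction:
            corrected = []
            for v in videos:
                if getattr(v, "_drift_corrected_upstream", False):
                    corrected.append(v)
                    continue
                corrected.append(apply_drift_correction(v, estimate_drift(v)))
            videos = corrected

        stage = "qc"
        rules = QCRules(**config.qc)
        accepted, stuck_by_video, qc_rows = [], {}, []
        for v in videos:
            res = qc_filter(v, rules)
            accepted.extend(res.accepted)
            stuck_by_video[v.video_id] = res.stuck
            for d in res.decisions:
                qc_rows.append({"video_id": v.video_id, **dataclasses.asdict(d)})
        outputs["qc_report"] = _write_csv(pd.DataFrame(qc_rows), outdir / "qc_report.csv")
        if not accepted:
            raise NucleotrackError("no trajectories accepted by QC")
        dt = videos[0].frame_interval
        log.info("QC: %d accepted, %d total", len(accepted), len(qc_rows))

        stage = "metrics"
        per_traj = pd.DataFrame([trajectory_summary(t) for t in accepted])[TRAJECTORY_SUMMARY_FIELDS]
        outputs["trajectory_metrics"] = _write_csv(per_traj, outdir / "trajectory_metrics.csv")
        summary = condition_summary(accepted, condition=config.condition)
        outputs["condition_summary"] = _write_csv(
            pd.DataFrame([summary]), outdir / "condition_summary.csv"
        )
        avg = average_msd([compute_msd(t) for t in accepted])
        msd_df = pd.DataFrame(
            {
                "condition": config.condition,
                "lag_s": avg.lags,
                "msd_nm2": avg.msd,
                "se_nm2": avg.se,
                "n_trajectories": avg.n_pairs,
            }
        )
        outputs["msd_curves"] = _write_csv(msd_df, outdir / "msd_curves.csv")

        stage = "mixture"
        steps_by_traj = [compute_steps(t) for t in accepted]
        mix_rows, chosen = [], {}
        for axis in ("x", "y"):
            pooled = np.concatenate([getattr(s, "d" + axis) for s in steps_by_traj])
            fit1 = fit_step_mixture(pooled, 1, dt, seed=config.seed, axis=axis, **config.mixture.get("fit", {}))
            fit2 = fit_step_mixture(pooled, 2, dt, seed=config.seed, axis=axis, **config.mixture.get("fit", {}))
            sel = select_mixture(fit1, fit2, config.mixture.get("delta_bic_threshold", 10.0))
            chosen[axis] = fit2 if sel.chosen_k == 2 else fit1
            for f in (fit1, fit2):
                mix_rows.append(
                    {
                        "condition": config.condition,
                        "axis": axis,
                        "k": f.k,
                        "weight1": f.weights[0],
                        "sigma1_nm": f.sigmas[0],
                        "sigma2_nm": f.sigmas[1] if f.k == 2 else np.nan,
                        "d1_nm2_per_s": f.d_values[0],
                        "d2_nm2_per_s": f.d_values[1] if f.k == 2 else np.nan,
                        "log_likelihood": f.log_likelihood,
                        "bic": f.bic,
                        "n_steps": f.n,
                        "chosen_k": sel.chosen_k,
                        "delta_bic": sel.delta_bic,
                        "flagged": f.flagged,
                    }
                )
        outputs["mixture_fits"] = _write_csv(pd.DataFrame(mix_rows), outdir / "mixture_fits.csv")

        stage = "stuck"
        ftest_rows = []
        for vid, stuck in stuck_by_video.items():
            if not stuck:
                continue
            stuck_steps = [compute_steps(t) for t in stuck]
            for axis in ("x", "y"):
                pooled = np.concatenate([getattr(s, "d" + axis) for s in stuck_steps])
                try:
                    est = stuck_effective_diffusion(pooled, dt, axis=axis)
                except NucleotrackError as exc:
                    log.info("stuck analysis skipped for video %s axis %s: %s", vid, axis, exc)
                    continue
                fit = chosen[axis]
                if fit.k == 2:
                    var_d1 = float(fit.sigmas[0] ** 2)
                    n_d1 = max(2, int(round(fit.weights[0] * fit.n)))
                    ft = stuck_vs_d1_ftest(float(np.mean(pooled**2)), len(pooled), var_d1, n_d1)
                    ftest_rows.append(
                        {
                            "video_id": vid,
                            "axis": axis,
                            "stuck_d_nm2_per_s": est.value,
                            "stuck_n_steps": len(pooled),
                            "d1_nm2_per_s": fit.d_values[0],
                            "f_statistic": ft.f_statistic,
                            "p_value": ft.p_value,
                            "significant": ft.significant,
                        }
                    )
        outputs["ftest_report"] = _write_csv(
            pd.DataFrame(
                ftest_rows,
                columns=[
                    "video_id",
                    "axis",
                    "stuck_d_nm2_per_s",
                    "stuck_n_steps",
                    "d1_nm2_per_s",
                    "f_statistic",
                    "p_value",
                    "significant",
                ],
            ),
            outdir / "ftest_report.csv",
        )

        stage = "diagnostics"
        alpha = float(config.diagnostics.get("alpha", 0.05))
        n_bins = int(config.diagnostics.get("n_bins", 24))
        angles = np.concatenate([s.angles for s in steps_by_traj])
        rsteps = np.concatenate([s.r_step for s in steps_by_traj])
        times = np.concatenate([s.step_times for s in steps_by_traj])
        reports = []
        long_enough = [t for t in accepted if len(t) >= 3]
        with np.errstate(all="ignore"):
            candidates = (
                lambda: angle_uniformity_test(angles, n_bins=n_bins, alpha=alpha),
                lambda: axis_bias_test(
                    diffusion_per_trajectory(long_enough, coords="x"),
                    diffusion_per_trajectory(long_enough, coords="y"),
                    alpha=alpha,
                ),
                lambda: stepsize_vs_time_test(rsteps, times, alpha=alpha),
            )
            for make_report in candidates:
                try:
                    reports.append(make_report())
                except NucleotrackError as exc:
                    log.info("diagnostic skipped: %s", exc)
        diag_df = pd.DataFrame(
            [
                {
                    "condition": config.condition,
                    "test": r.test_name,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n": r.n,
                    "alpha": r.alpha,
                    "reject": r.reject,
                    **{f"effect_{k}": v for k, v in r.effect.items()},
                }
                for r in reports
            ]
        )
        outputs["diagnostics"] = _write_csv(diag_df, outdir / "diagnostics.csv")
        angle_report = next((r for r in reports if r.test_name == "angle_uniformity"), None)
        outputs["angle_histogram"] = _write_csv(
            pd.DataFrame(angle_report.table if angle_report else {"bin_left_deg": [], "count": []}),
            outdir / "angle_histogram.csv",
        )

        stage = "switching"
        switch_rows = []
        for axis in ("x", "y"):
            if chosen[axis].k != 2:
                continue
            for s in steps_by_traj:
                labels, n_switch = state_switch_flagger(s, chosen[axis])
                switch_rows.append(
                    {
                        "trajectory_id": s.trajectory_id,
                        "axis_fit": axis,
                        "n_steps": len(s),
                        "fraction_state1": float(np.mean(labels == 1)),
                        "n_switches": n_switch,
                    }
                )
            break  # one selected fit suffices for the descriptive check
        outputs["switch_counts"] = _write_csv(
            pd.DataFrame(
                switch_rows,
                columns=["trajectory_id", "axis_fit", "n_steps", "fraction_state1", "n_switches"],
            ),
            outdir / "switch_counts.csv",
        )

        stage = "log"
        run_log = {
            "nucleotrack_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "qc_rules": dataclasses.asdict(rules),
            "outputs": outputs,
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
        outputs["run_log"] = str(outdir / "run_log.json")
        return outputs
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise


def compare_conditions(summary_paths, out_path) -> Path:
    """Concatenate per-condition summary CSVs into one comparison table."""
    frames = [pd.read_csv(p) for p in summary_paths]
    if not frames:
        raise ParameterError("no summaries to compare")
    table = pd.concat(frames, ignore_index=True)
    out_path = Path(out_path)
    table.to_csv(out_path, index=False, float_format="%.10g")
    return out_path
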