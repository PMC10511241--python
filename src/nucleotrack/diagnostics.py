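"""Tip-artifact and robustness diagnostics.

A raster-scanning AFM tip that drags particles would leave fingerprints in
the trajectory statistics: a directional bias in the angle between
successive steps, a difference between diffusion along the fast-scan (x)
and slow-scan (y) axes, or a step-size trend over imaging time. Each check
is formalized as a hypothesis test so the pipeline yields machine-checkable
decisions; the underlying histograms and means are returned alongside so
the equivalent visual judgment can be reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EstimationError, ParameterError
from .metrics import StepSeries
from .mixture import MixtureFit


@dataclass
class DiagnosticReport:
    """Outcome of one diagnostic test with its supporting table."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    alpha: float
    reject: bool
    effect: dict = field(default_factory=dict)
    table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError("p-value must lie in [0, 1]")
        if self.reject != (self.p_value < self.alpha):
            raise ParameterError("decision inconsistent with p and alpha")


def angle_uniformity_test(angles, n_bins: int = 24, alpha: float = 0.05) -> DiagnosticReport:
    """Chi-square goodness of fit of binned turning angles against uniformity.

    Angles are binned on (−180, 180] (default 24 × 15° bins). The circular
    mean resultant length is reported as an effect size: 0 for perfect
    isotropy, 1 for all steps turning the same way.
    """
    angles = np.asarray(angles, dtype=float)
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if len(angles) < n_bins:
        raise EstimationError(f"need at least {n_bins} angles, got {len(angles)}")
    if len(angles) < 10 * n_bins:
        warnings.warn(
            f"only {len(angles)} angles for {n_bins} bins; expected counts are low",
            stacklevel=2,
        )
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # shift +180 exactly onto the last edge's closed side
    counts, _ = np.histogram(np.clip(angles, -179.9999999, 180.0), bins=edges)
    chi2, p = stats.chisquare(counts)
    rad = np.radians(angles)
    resultant = float(np.hypot(np.mean(np.cos(rad)), np.mean(np.sin(rad))))
    return DiagnosticReport(
        test_name="angle_uniformity",
        statistic=float(chi2),
        p_value=float(p),
        n=len(angles),
        alpha=alpha,
        reject=bool(p < alpha),
        effect={"mean_resultant_length": resultant},
        table={"bin_left_deg": edges[:-1].tolist(), "count": counts.tolist()},
    )


def axis_bias_test(d_x, d_y, alpha: float = 0.05) -> DiagnosticReport:
    """Paired two-sided t-test of per-trajectory D_x − D_y.

    Identical per-axis estimates (zero-variance differences) are reported
    as no difference (p = 1) rather than an error.
    """
    d_x = np.asarray(d_x, dtype=float)
    d_y = np.asarray(d_y, dtype=float)
    if len(d_x) != len(d_y):
        raise ParameterError("d_x and d_y must be paired per trajectory")
    if len(d_x) < 3:
        raise EstimationError("need at least 3 paired estimates")
    diff = d_x - d_y
    if np.allclose(diff.std(ddof=1), 0.0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_rel(d_x, d_y)

    def mse(v):
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))

    mx, sx = mse(d_x)
    my, sy = mse(d_y)
    return DiagnosticReport(
        test_name="axis_bias",
        statistic=float(stat),
        p_value=float(p),
        n=len(d_x),
        alpha=alpha,
        reject=bool(p < alpha),
        effect={"d_x_mean": mx, "d_x_se": sx, "d_y_mean": my, "d_y_se": sy},
    )


def stepsize_vs_time_test(r_steps, times, alpha: float = 0.05) -> DiagnosticReport:
    """Least-squares regression of R-step on time since the video start.

    A drift of mobility over the recording (e.g., progressive surface
    adhesion or tip damage) shows as a nonzero slope. Constant step sizes
    give slope 0 and p = 1.
    """
    r = np.asarray(r_steps, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(r) != len(t):
        raise ParameterError("r_steps and times must align")
    if len(r) < 3 or np.allclose(t.std(), 0.0):
        raise EstimationError("steps must span more than one time point")
    if np.allclose(r.std(), 0.0):
        slope, se, p = 0.0, 0.0, 1.0
    else:
        res = stats.linregress(t, r)
        slope, se, p = res.slope, res.stderr, res.pvalue
    return DiagnosticReport(
        test_name="stepsize_vs_time",
        statistic=float(slope / se) if se > 0 else 0.0,
        p_value=float(p),
        n=len(r),
        alpha=alpha,
        reject=bool(p < alpha),
        effect={"slope_nm_per_s": float(slope), "slope_se_nm_per_s": float(se)},
    )


def state_switch_flagger(steps: StepSeries, fit: MixtureFit) -> tuple[np.ndarray, int]:
    """Label each step by maximum posterior under a selected two-state fit.

    Both axis displacements of a step are scored against isotropic zero-mean
    components (shared σ per axis), and the step takes the component with
    the larger posterior; exact ties go to state 1. Returns the per-step
    labels (1/2) and the number of label changes. This is a descriptive aid
    mirroring a visual switching check — no temporal smoothing is applied,
    so counts overstate true switching when states overlap.
    """
    if fit.k != 2:
        raise ParameterError("state_switch_flagger requires a two-component fit")
    x2 = steps.dx**2 + steps.dy**2
    var = fit.sigmas**2
    # log posterior per component for the 2D step, isotropic per-axis sigma
    logp = np.log(fit.weights) - np.log(2.0 * np.pi * var) - 0.5 * x2[:, None] / var
    labels = np.where(logp[:, 1] > logp[:, 0], 2, 1).astype(np.int8)
    switches = int(np.sum(labels[1:] != labels[:-1]))
    return labels, switches
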