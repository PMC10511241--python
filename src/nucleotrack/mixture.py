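"""Zero-mean Gaussian mixture fits of pooled step displacements.

After drift correction, per-axis single-frame displacements of a diffusing
particle are zero-mean Gaussian with variance 2·D·Δt, so a population with
two mobility states pools into a two-component zero-mean mixture. Fitting
the pooled displacements with one- and two-component models and comparing
them separates a slow (paused, D1) from a fast (mobile, D2) state; each
fitted width maps back to a diffusion constant via D = σ²/(2Δt).

Component means are fixed at zero throughout: free means are
unidentifiable from symmetric displacement histograms, and fixing them is
what makes the σ → D mapping exact. EM with zero means reduces to
responsibility-weighted second moments, implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ComparisonError, EstimationError, ParameterError
from .metrics import DiffusionEstimate

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureFit:
    """A k-component zero-mean Gaussian fit of pooled step displacements."""

    axis: str  # 'x', 'y' or 'pooled'
    k: int
    weights: np.ndarray  # sum to 1, ordered by ascending sigma
    sigmas: np.ndarray  # nm, strictly positive, ascending
    frame_interval: float  # s
    log_likelihood: float
    n: int
    converged: bool = True
    flagged: str = ""  # non-empty if the fit needed a variance floor

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ParameterError("mixture weights must sum to 1")
        if np.any(self.sigmas <= 0) or np.any(np.diff(self.sigmas) < 0):
            raise ParameterError("sigmas must be positive and ascending")

    @property
    def d_values(self) -> np.ndarray:
        """Implied diffusion constants, D_i = σ_i² / (2Δt), nm²/s."""
        return self.sigmas**2 / (2.0 * self.frame_interval)

    @property
    def n_parameters(self) -> int:
        return 2 * self.k - 1  # k sigmas + (k-1) free weights

    @property
    def bic(self) -> float:
        return self.n_parameters * np.log(self.n) - 2.0 * self.log_likelihood


@dataclass
class MixtureSelection:
    """Choice between the one- and two-component fits of the same steps."""

    chosen_k: int
    delta_bic: float  # BIC(k=1) − BIC(k=2); positive favors two components
    lr_statistic: float  # 2·(logL2 − logL1)
    threshold: float


@dataclass
class FTestResult:
    """Two-sided variance-ratio F-test between two Gaussian widths."""

    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _zero_mean_loglik(x2: np.ndarray, weights: np.ndarray, var: np.ndarray) -> float:
    comp = np.log(weights) - 0.5 * (_LOG_2PI + np.log(var)) - 0.5 * x2[:, None] / var
    m = comp.max(axis=1)
    return float(np.sum(m + np.log(np.sum(np.exp(comp - m[:, None]), axis=1))))


def _em_zero_mean(
    x2: np.ndarray,
    w0: np.ndarray,
    var0: np.ndarray,
    var_floor: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """EM for a zero-mean Gaussian mixture on squared observations.

    Returns (weights, variances, log-likelihood, converged). The M-step for
    each component is its responsibility-weighted mean square. Log-likelihood
    is non-decreasing across iterations by EM construction.
    """
    w, var = w0.copy(), np.maximum(var0, var_floor)
    n = len(x2)
    ll_prev = -np.inf
    converged = False
    tiny = np.finfo(float).tiny
    for _ in range(max_iter):
        # direct-domain E-step; densities underflowing to 0 are floored so a
        # point infinitely unlikely under both components cannot divide by 0
        dens = (w / np.sqrt(2.0 * np.pi * var)) * np.exp(-0.5 * x2[:, None] / var)
        tot = np.maximum(dens.sum(axis=1), tiny)
        ll = float(np.log(tot).sum())
        resp = dens / tot[:, None]
        nk = resp.sum(axis=0)
        w = nk / n
        var = np.maximum((resp * x2[:, None]).sum(axis=0) / np.maximum(nk, tiny), var_floor)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return w, var, ll_prev, converged


def fit_step_mixture(
    steps: np.ndarray,
    k: int,
    frame_interval: float,
    seed: int = 0,
    axis: str = "pooled",
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    sigma_floor: float = 0.05,
    min_steps_k2: int = 50,
) -> MixtureFit:
    """Maximum-likelihood zero-mean Gaussian mixture fit of pooled steps.

    For k = 1 the MLE is closed-form (σ² = mean of squares). For k = 2, EM
    is run from ``n_starts`` seeded initializations (quantile splits of |x|
    at randomized split points) and the best likelihood is kept, making the
    fit deterministic given ``seed``. A component collapsing below
    ``sigma_floor`` (nm) is refit with that floor and the fit is flagged.
    """
    x = np.asarray(steps, dtype=float)
    if x.ndim != 1 or len(x) < 2 or not np.all(np.isfinite(x)):
        raise ParameterError("steps must be a finite 1D array with >= 2 values")
    if frame_interval <= 0:
        raise ParameterError("frame_interval must be > 0")
    if k not in (1, 2):
        raise ParameterError("k must be 1 or 2")
    x2 = x**2
    var_floor = sigma_floor**2

    if k == 1:
        var = max(float(x2.mean()), var_floor)
        ll = _zero_mean_loglik(x2, np.array([1.0]), np.array([var]))
        return MixtureFit(
            axis=axis,
            k=1,
            weights=np.array([1.0]),
            sigmas=np.array([np.sqrt(var)]),
            frame_interval=frame_interval,
            log_likelihood=ll,
            n=len(x),
            flagged="variance floor" if x2.mean() < var_floor else "",
        )

    if len(x) < min_steps_k2:
        raise ParameterError(f"k=2 fit needs at least {min_steps_k2} steps, got {len(x)}")
    rng = np.random.default_rng(seed)
    ax = np.abs(x)
    best = None
    for s in range(n_starts):
        q = 0.5 if s == 0 else float(rng.uniform(0.2, 0.8))
        cut = np.quantile(ax, q)
        lo, hi = x2[ax <= cut], x2[ax > cut]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0 = np.array([len(lo), len(hi)], dtype=float) / len(x)
        var0 = np.array([max(lo.mean(), var_floor), max(hi.mean(), var_floor)])
        w, var, ll, conv = _em_zero_mean(x2, w0, var0, 0.0, max_iter, tol)
        if best is None or ll > best[2]:
            best = (w, var, ll, conv)
    if best is None:  # all |x| identical: every quantile split is one-sided
        best = (np.array([0.5, 0.5]), np.full(2, max(float(x2.mean()), var_floor)), -np.inf, False)
    w, var, ll, conv = best
    flagged = ""
    if not np.isfinite(ll) or np.any(var < var_floor) or np.any(w < 1e-4):
        flagged = "degenerate component; refit with sigma floor"
        w0 = np.array([0.5, 0.5])
        var0 = np.array([var_floor, max(float(x2.mean()), var_floor * 4)])
        w, var, ll, conv = _em_zero_mean(x2, w0, var0, var_floor, max_iter, tol)
    order = np.argsort(var)
    return MixtureFit(
        axis=axis,
        k=2,
        weights=w[order],
        sigmas=np.sqrt(var[order]),
        frame_interval=frame_interval,
        log_likelihood=ll,
        n=len(x),
        converged=conv,
        flagged=flagged,
    )


def select_mixture(fit1: MixtureFit, fit2: MixtureFit, delta_bic_threshold: float = 10.0) -> MixtureSelection:
    """Prefer the two-component fit only when ΔBIC = BIC₁ − BIC₂ exceeds the threshold.

    Ties and small improvements resolve to one component (parsimony). The
    likelihood-ratio statistic is reported alongside so other criteria can
    be applied externally.
    """
    if fit1.n != fit2.n:
        raise ComparisonError("fits compare different step sets (n mismatch)")
    if (fit1.k, fit2.k) != (1, 2):
        raise ComparisonError("select_mixture expects (k=1 fit, k=2 fit)")
    delta = fit1.bic - fit2.bic
    lr = 2.0 * (fit2.log_likelihood - fit1.log_likelihood)
    return MixtureSelection(
        chosen_k=2 if delta > delta_bic_threshold else 1,
        delta_bic=float(delta),
        lr_statistic=float(lr),
        threshold=delta_bic_threshold,
    )


def stuck_effective_diffusion(
    steps: np.ndarray, frame_interval: float, min_steps: int = 20, axis: str = "pooled"
) -> DiffusionEstimate:
    """Effective D of stuck trajectories from a single zero-mean Gaussian fit.

    Fits the per-axis displacements of the rejected (stuck) population with
    one zero-mean Gaussian and converts the fitted σ to D = σ²/(2Δt). With
    pure localization noise of sd σ_loc, differencing doubles the variance,
    so the expected effective D is σ_loc²/Δt.
    """
    x = np.asarray(steps, dtype=float)
    if len(x) < min_steps:
        raise EstimationError(f"need at least {min_steps} stuck steps, got {len(x)}")
    var = float(np.mean(x**2))
    note = "degenerate: sigma ~ 0" if var < 1e-12 else ""
    d = var / (2.0 * frame_interval)
    se = d * np.sqrt(2.0 / len(x))  # delta method on the chi-square variance of s²
    return DiffusionEstimate(
        value=d, se=float(se), dimensionality=1, method=f"gaussian-sigma ({axis})", n=len(x), note=note
    )


def stuck_vs_d1_ftest(
    var_stuck: float, n_stuck: int, var_d1: float, n_d1_effective: int, alpha: float = 0.05
) -> FTestResult:
    """Two-sided F-test comparing the stuck-population and D1 Gaussian variances.

    F is the larger variance over the smaller with (n−1) degrees of freedom
    each; the two-sided p doubles the upper tail (capped at 1).
    """
    if var_stuck <= 0 or var_d1 <= 0:
        raise ParameterError("variances must be positive")
    if n_stuck < 2 or n_d1_effective < 2:
        raise ParameterError("counts must be >= 2")
    if var_stuck >= var_d1:
        f, df_num, df_den = var_stuck / var_d1, n_stuck - 1, n_d1_effective - 1
    else:
        f, df_num, df_den = var_d1 / var_stuck, n_d1_effective - 1, n_stuck - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, df_num, df_den)))
    return FTestResult(f_statistic=float(f), p_value=p, df_num=df_num, df_den=df_den, alpha=alpha)
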