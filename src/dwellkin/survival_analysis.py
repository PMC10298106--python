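"""Survival-probability analysis of dwell-time sets.

Builds the normalized survival curve S(t) = P(dwell >= t), fits a fixed-
amplitude single exponential S(t) = exp(-t/tau) by unweighted least squares
(the characteristic lifetime), attaches a bootstrap SD, and compares
conditions with the two-sample Kolmogorov-Smirnov test.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import DwellTimeSet

DEFAULT_BOOTSTRAP = 200
MLE_DISAGREEMENT_WARN = 0.10


class FitError(RuntimeError):
    """Exponential fit failed; carries solver diagnostics."""


@dataclass
class SurvivalCurve:
    """Right-continuous step survival curve evaluated at sorted dwell values."""

    times: np.ndarray
    survival: np.ndarray
    n_events: int
    dwells: np.ndarray | None = None  # retained for bootstrap resampling

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have equal length")
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "survival": self.survival})


@dataclass
class SurvivalFit:
    """Characteristic lifetime from a single-exponential survival fit."""

    tau: float
    tau_sd: float
    n_events: int
    method: str = "lsq-survival"
    tau_mle: float = float("nan")
    tau_cov_sd: float = float("nan")
    goodness: dict = field(default_factory=dict)
    bootstrap_seed: int | None = None
    n_boot: int = 0

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.tau_sd < 0:
            raise ValueError("tau_sd must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "tau_s": self.tau,
            "tau_sd_s": self.tau_sd,
            "n_events": self.n_events,
            "method": self.method,
            "tau_mle_s": self.tau_mle,
            "tau_cov_sd_s": self.tau_cov_sd,
            "goodness": self.goodness,
            "bootstrap_seed": self.bootstrap_seed,
            "n_boot": self.n_boot,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    alpha: float
    reject: bool


def survival_curve(dwells: DwellTimeSet | np.ndarray) -> SurvivalCurve:
    """S(t) = (# dwells >= t) / n at each sorted unique dwell value."""
    values = dwells.dwells if isinstance(dwells, DwellTimeSet) else np.asarray(dwells, float)
    if values.size == 0:
        raise ValueError("cannot build a survival curve from an empty dwell set")
    n = values.size
    times = np.unique(values)
    # (# >= t) at unique sorted t: n minus the count strictly below t
    below = np.searchsorted(np.sort(values), times, side="left")
    survival = (n - below) / n
    return SurvivalCurve(times=times, survival=survival, n_events=n, dwells=values)


def _lsq_tau(times: np.ndarray, survival: np.ndarray) -> float:
    scale = max(float(np.max(times)), 1e-30)

    def sse(log_tau: float) -> float:
        resid = survival - np.exp(-times / np.exp(log_tau))
        return float(resid @ resid)

    guess = np.log(max(float(np.mean(times)), 1e-12))
    res = optimize.minimize_scalar(
        sse,
        bounds=(np.log(scale) - 25.0, np.log(scale) + 25.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success or not np.isfinite(res.x):
        raise FitError(f"exponential survival fit did not converge: {res}")
    # one Brent polish around the bounded optimum for full precision
    log_tau = res.x
    try:
        res2 = optimize.minimize_scalar(
            sse, bracket=(res.x - 0.5, res.x, res.x + 0.5), method="brent"
        )
        if res2.success and sse(res2.x) <= sse(res.x):
            log_tau = res2.x
    except ValueError:
        pass  # bracket not a local minimum (tiny samples); keep bounded result
    return float(np.exp(log_tau))


def fit_exponential(
    curve: SurvivalCurve,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> SurvivalFit:
    """Least-squares fit of S(t) = exp(-t/tau), amplitude fixed at 1.

    tau_sd is a nonparametric bootstrap over events (when the curve retains
    its dwells); the covariance-based SD and the exponential MLE cross-check
    (the sample mean) are reported alongside.
    """
    if curve.n_events < 10:
        warnings.warn(
            f"only {curve.n_events} events; exponential fit may be unstable",
            UserWarning,
            stacklevel=2,
        )
    tau = _lsq_tau(curve.times, curve.survival)

    resid = curve.survival - np.exp(-curve.times / tau)
    jac = np.exp(-curve.times / tau) * curve.times / tau**2
    jtj = float(jac @ jac)
    dof = max(curve.times.size - 1, 1)
    tau_cov_sd = float(np.sqrt((resid @ resid) / dof / jtj)) if jtj > 0 else float("nan")

    tau_mle = float("nan")
    tau_sd = tau_cov_sd
    bootstrap_seed = None
    n_boot_done = 0
    if curve.dwells is not None:
        tau_mle = float(np.mean(curve.dwells))
        if np.isfinite(tau_mle) and abs(tau - tau_mle) / tau_mle > MLE_DISAGREEMENT_WARN:
            warnings.warn(
                f"LSQ tau {tau:.3g} and MLE tau {tau_mle:.3g} disagree by more "
                f"than {MLE_DISAGREEMENT_WARN:.0%}; dwell data may not be "
                "single-exponential",
                UserWarning,
                stacklevel=2,
            )
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            bootstrap_seed = seed
            taus = np.empty(n_boot)
            n = curve.dwells.size
            for b in range(n_boot):
                resample = curve.dwells[rng.integers(0, n, n)]
                c = survival_curve(resample)
                taus[b] = _lsq_tau(c.times, c.survival)
            tau_sd = float(np.std(taus, ddof=1))
            n_boot_done = n_boot

    return SurvivalFit(
        tau=tau,
        tau_sd=tau_sd,
        n_events=curve.n_events,
        tau_mle=tau_mle,
        tau_cov_sd=tau_cov_sd,
        goodness={
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "max_abs_residual": float(np.max(np.abs(resid))),
        },
        bootstrap_seed=bootstrap_seed,
        n_boot=n_boot_done,
    )


def ks_compare(
    a: DwellTimeSet, b: DwellTimeSet, alpha: float = 0.001
) -> KSResult:
    """Two-sample KS test between dwell distributions (asymptotic p-value)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("both dwell sets need at least 2 events")
    res = stats.ks_2samp(a.dwells, b.dwells, method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        alpha=alpha,
        reject=bool(res.pvalue < alpha),
    )


def plot_survival(
    curve: SurvivalCurve, fit: SurvivalFit | None = None, path: str | Path | None = None
):
    """Simple static survival plot (step curve plus fitted exponential)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(curve.times, curve.survival, where="post", label=f"data (n={curve.n_events})")
    if fit is not None:
        grid = np.linspace(0, curve.times.max(), 200)
        ax.plot(grid, np.exp(-grid / fit.tau), "--",
                label=f"exp fit, tau={fit.tau:.1f}±{fit.tau_sd:.1f} s")
    ax.set_xlabel("lifetime (s)")
    ax.set_ylabel("survival probability")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
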