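"""Cleavage kinetics fitting and measure/rate correlation.

The fraction cleaved follows a first-order approach to a plateau,

    F(t) = F_max - (F_max - F0) * exp(-K_obs * t),

fitted by nonlinear least squares over points pooled across technical
replicates (constant error model).  The 95% confidence band is the
first-order (delta-method) band from the Jacobian at the optimum.
K_obs is reported positive; the decaying exponential is the only
parameterization for which approach to a plateau is bounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


class FitError(RuntimeError):
    """Non-convergence or degenerate kinetics data."""

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best or {}


@dataclass(frozen=True)
class CleavageSeries:
    """One technical replicate: times in minutes, fraction cleaved."""

    replicate: str
    times: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.size != f.size:
            raise ValueError("times and fractions differ in length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class KineticsFit:
    k_obs: float
    f_max: float
    f0: float
    mse: float
    n_points: int
    covariance: np.ndarray
    ci_band: np.ndarray  # rows (t, fit, lower, upper)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _model(np.asarray(t, dtype=float), self.k_obs, self.f_max, self.f0)

    def ci_contains(self, k_true: float, level_df: int | None = None) -> bool:
        """Whether the 95% parameter CI on K_obs covers ``k_true``."""
        se = float(np.sqrt(self.covariance[0, 0]))
        dof = max(self.n_points - 3, 1)
        tcrit = stats.t.ppf(0.975, dof)
        return abs(self.k_obs - k_true) <= tcrit * se


def _model(t: np.ndarray, k: float, fmax: float, f0: float) -> np.ndarray:
    return fmax - (fmax - f0) * np.exp(-k * t)


def _pool(series: Sequence[CleavageSeries]) -> tuple[np.ndarray, np.ndarray]:
    t = np.concatenate([np.asarray(s.times, dtype=float) for s in series])
    f = np.concatenate([np.asarray(s.fractions, dtype=float) for s in series])
    order = np.argsort(t, kind="stable")
    return t[order], f[order]


def fit_cleavage(
    series: Sequence[CleavageSeries], init: tuple[float, float, float] | None = None
) -> KineticsFit:
    """Least-squares fit of the plateau model over pooled replicates.

    ``init`` optionally supplies (K_obs, F_max, F0); otherwise F0 = min F,
    F_max = max F and K_obs comes from a log-linear fit of F_max - F(t).
    """
    if not series:
        raise FitError("no series supplied")
    t, f = _pool(series)
    if np.unique(t).size < 3:
        raise FitError("need at least 3 distinct time points")
    if np.ptp(f) < 1e-12:
        raise FitError("degenerate data: fraction cleaved is constant")

    if init is None:
        f0_init = float(f.min())
        fmax_init = float(f.max())
        # log-linear rate guess from the decaying residual amplitude
        resid = np.clip(fmax_init + 1e-3 - f, 1e-6, None)
        slope = np.polyfit(t, np.log(resid), 1)[0]
        k_init = max(1e-4, -float(slope))
        init = (k_init, fmax_init, f0_init)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model(t, *theta) - f

    res = optimize.least_squares(
        residuals,
        x0=np.asarray(init, dtype=float),
        bounds=([0.0, 0.0, 0.0], [np.inf, 1.0, 1.0]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise FitError(
            f"fit did not converge: {res.message}",
            best={"theta": res.x.tolist(), "cost": float(res.cost)},
        )
    k, fmax, f0 = (float(v) for v in res.x)
    n = t.size
    rss = float(2 * res.cost)
    mse = rss / n
    dof = max(n - 3, 1)
    jac = res.jac
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * (rss / dof)
    tcrit = stats.t.ppf(0.975, dof)
    tgrid = np.unique(t)
    g = np.column_stack([
        (fmax - f0) * tgrid * np.exp(-k * tgrid),          # d/dk
        1.0 - np.exp(-k * tgrid),                          # d/dfmax
        np.exp(-k * tgrid),                                # d/df0
    ])
    se_pred = np.sqrt(np.einsum("ij,jk,ik->i", g, cov, g))
    fit_vals = _model(tgrid, k, fmax, f0)
    band = np.column_stack([tgrid, fit_vals, fit_vals - tcrit * se_pred,
                            fit_vals + tcrit * se_pred])
    return KineticsFit(k, fmax, f0, mse, n, cov, band)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; errors on degenerate input."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("vectors differ in length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise ValueError("zero variance in correlation input")
    return float(stats.pearsonr(xa, ya)[0])


def correlation_table(
    kobs: dict[str, float], measures: pd.DataFrame, id_column: str = "id"
) -> pd.DataFrame:
    """Pearson r between K_obs and every numeric measure column.

    Rows are sorted by |r| descending; degenerate (constant) columns are
    flagged in an ``error`` column rather than silently reported as NaN.
    """
    if id_column not in measures.columns:
        raise ValueError(f"measure table lacks id column {id_column!r}")
    ids = list(measures[id_column])
    missing = [i for i in ids if i not in kobs]
    if missing or len(ids) != len(kobs):
        raise ValueError(f"candidate id mismatch (missing {missing})")
    kv = np.asarray([kobs[i] for i in ids], dtype=float)
    rows = []
    for col in measures.columns:
        if col == id_column or not pd.api.types.is_numeric_dtype(measures[col]):
            continue
        vals = measures[col].to_numpy(dtype=float)
        try:
            r = pearson(kv, vals)
            rows.append({"measure": col, "r": r, "error": ""})
        except ValueError as exc:
            rows.append({"measure": col, "r": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows)
    return df.reindex(
        df["r"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)
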