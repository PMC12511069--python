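"""Model evaluation: errors, correlations, confidence intervals and Taylor
diagram geometry.

Conventions:

* RMSE CIs come from a non-parametric bootstrap (default 1,000 resamples) that
  recomputes, per resample, the centered error
  E' = sqrt(sd(y)^2 + sd(yhat)^2 - 2 sd(y) sd(yhat) |r|)
  and takes the 2.5/97.5 empirical percentiles.  A residual-bootstrap variant
  recomputing plain RMSE per resample is available for comparison.
* Pearson r CIs use the Fisher z-transform with se = 1/sqrt(n-3) and are
  reported as missing when n < 4.
* Degenerate correlations (either side constant) are rendered as 0 with a
  degenerate (0, 0) interval and an explicit flag.
* Cross-participant aggregation is a mean with a t-distribution CI from the
  standard error of the mean; never computed from fewer than 2 participants.
* Significance flags in contrast tables mean "95% CIs disjoint in the
  favorable direction" — an interval-based criterion, not a formal test.

Standard deviations in Taylor/bootstrap geometry are population (ddof=0), so
the law-of-cosines identity holds exactly against centered residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DASH = "—"


@dataclass
class PairedPredictions:
    y: np.ndarray
    y_hat: np.ndarray
    participant_id: str = ""
    scale_id: str = ""
    interpolation: str = ""
    paradigm: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if self.y.shape != self.y_hat.shape:
            raise ValueError("y and y_hat must have equal length")
        if self.y.size < 1:
            raise ValueError("need at least one pair")
        if not (np.isfinite(self.y).all() and np.isfinite(self.y_hat).all()):
            raise ValueError("non-finite values in paired predictions")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class MetricReport:
    rmse: float
    rmse_ci: tuple[float, float] | None
    r: float
    r_ci: tuple[float, float] | None
    n: int
    r_degenerate: bool = False


@dataclass
class TaylorPoint:
    sigma_ref: float
    sigma_pred: float
    r: float
    centered_rmse: float

    @property
    def polar_xy(self) -> tuple[float, float]:
        """Cartesian plotting coordinates (sigma_pred*r, sigma_pred*sqrt(1-r^2))."""
        return (self.sigma_pred * self.r,
                self.sigma_pred * float(np.sqrt(max(0.0, 1.0 - self.r ** 2))))


def rmse(pair: PairedPredictions) -> float:
    return float(np.sqrt(np.mean((pair.y - pair.y_hat) ** 2)))


def pearson_r(pair: PairedPredictions) -> tuple[float, bool]:
    """Sample correlation; degenerate (either side constant, or n < 2) is
    reported as 0 with a flag, matching the 0 (0-0) table convention."""
    if pair.n < 2 or np.std(pair.y) == 0 or np.std(pair.y_hat) == 0:
        return 0.0, True
    r = float(stats.pearsonr(pair.y, pair.y_hat).statistic)
    return r, False


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float] | None:
    """Fisher z-transform CI: tanh(atanh(r) +- z * 1/sqrt(n-3)); missing for
    n < 4; degenerate (r, r) at |r| = 1."""
    if n < 4:
        return None
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zq = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se)))


def centered_rmse(sd_ref: float, sd_pred: float, r_abs: float) -> float:
    return float(np.sqrt(max(0.0,
        sd_ref ** 2 + sd_pred ** 2 - 2.0 * sd_ref * sd_pred * r_abs)))


def bootstrap_rmse_ci(pair: PairedPredictions, B: int = 1000, seed: int = 0,
                      level: float = 0.95, residual: bool = False
                      ) -> tuple[float, float]:
    """Bootstrap CI for the prediction error.

    Pairs are resampled with replacement; per resample the error is recomputed
    from the standard deviations of true and predicted values and their
    absolute correlation (``residual=True`` recomputes plain RMSE instead).
    Bounds are the (1-level)/2 and (1+level)/2 empirical percentiles.
    """
    if pair.n < 2:
        raise ValueError("bootstrap requires n >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pair.n, size=(B, pair.n))
    ys = pair.y[idx]
    ps = pair.y_hat[idx]
    if residual:
        vals = np.sqrt(np.mean((ys - ps) ** 2, axis=1))
    else:
        sd_y = ys.std(axis=1)
        sd_p = ps.std(axis=1)
        cov = np.mean((ys - ys.mean(axis=1, keepdims=True))
                      * (ps - ps.mean(axis=1, keepdims=True)), axis=1)
        denom = sd_y * sd_p
        r_abs = np.where(denom > 0, np.abs(cov) / np.where(denom > 0, denom, 1.0), 0.0)
        r_abs = np.where(r_abs > 1.0 - 1e-12, 1.0, r_abs)
        # law-of-cosines form that is exact at sd_y == sd_p, |r| == 1
        vals = np.sqrt((sd_y - sd_p) ** 2 + 2 * denom * (1.0 - r_abs))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def taylor_point(pair: PairedPredictions) -> TaylorPoint:
    """Taylor coordinates of one evaluated cell; the reference series sits at
    (sigma_ref, 0) and a zero-variance prediction at the origin."""
    if pair.n < 2:
        raise ValueError("taylor geometry requires n >= 2")
    sd_ref = float(pair.y.std())
    sd_pred = float(pair.y_hat.std())
    r, degen = pearson_r(pair)
    e_centered = float(np.sqrt(np.mean(
        ((pair.y - pair.y.mean()) - (pair.y_hat - pair.y_hat.mean())) ** 2)))
    return TaylorPoint(sd_ref, sd_pred, r, e_centered)


def evaluate_pair(pair: PairedPredictions, B: int = 1000, seed: int = 0,
                  level: float = 0.95) -> MetricReport:
    r, degen = pearson_r(pair)
    r_ci = (0.0, 0.0) if degen else fisher_ci(r, pair.n, level)
    if degen and pair.n < 4:
        r_ci = None
    rm_ci = bootstrap_rmse_ci(pair, B=B, seed=seed, level=level) if pair.n >= 2 else None
    return MetricReport(rmse(pair), rm_ci, r, r_ci, pair.n, degen)


@dataclass
class AggregateCI:
    mean: float
    ci: tuple[float, float] | None
    n: int


def aggregate_mean_tci(values, level: float = 0.95) -> AggregateCI:
    """Cross-participant mean with a t-interval from the SEM; no interval is
    fabricated at n = 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    mean = float(v.mean())
    if v.size < 2:
        return AggregateCI(mean, None, int(v.size))
    sem = v.std(ddof=1) / np.sqrt(v.size)
    tq = stats.t.ppf(0.5 + level / 2, df=v.size - 1)
    return AggregateCI(mean, (mean - float(tq * sem), mean + float(tq * sem)), int(v.size))


# ---------------------------------------------------------------------------
# contrast tables
# ---------------------------------------------------------------------------

def _fmt(report: MetricReport | None, metric: str) -> str:
    if report is None:
        return DASH
    val = getattr(report, metric)
    ci = report.rmse_ci if metric == "rmse" else report.r_ci
    if ci is None:
        return f"{val:.2f} (—)"
    return f"{val:.2f} ({ci[0]:.2f}–{ci[1]:.2f})"


def _ci_of(report: MetricReport, metric: str):
    return report.rmse_ci if metric == "rmse" else report.r_ci


def contrast_table(grid: dict[str, dict[str, MetricReport | None]],
                   metric: str = "rmse") -> pd.DataFrame:
    """Best-per-row comparison across methods (columns) for each row key.

    ``grid`` maps row label -> method -> MetricReport (or None for screened
    cells).  The best cell per row (minimum RMSE or maximum r) is marked; a
    method is flagged significantly better than another when their 95% CIs
    are disjoint in the favorable direction.  All-missing rows are emitted
    with dash markers.
    """
    if metric not in ("rmse", "r"):
        raise ValueError("metric must be 'rmse' or 'r'")
    better = (lambda a, b: a < b) if metric == "rmse" else (lambda a, b: a > b)
    rows = []
    for row_key, cells in grid.items():
        methods = list(cells)
        present = {m: rep for m, rep in cells.items() if rep is not None}
        rec: dict[str, object] = {"row": row_key}
        if len(present) == 0:
            for m in methods:
                rec[m] = DASH
            rec["best"] = DASH
            rec["significant"] = ""
            rows.append(rec)
            continue
        vals = {m: getattr(rep, metric) for m, rep in present.items()}
        best_val = min(vals.values()) if metric == "rmse" else max(vals.values())
        best = sorted(m for m, v in vals.items() if v == best_val)
        flags = []
        for m, rep in present.items():
            for other, orep in present.items():
                if m == other:
                    continue
                ci_m, ci_o = _ci_of(rep, metric), _ci_of(orep, metric)
                if ci_m is None or ci_o is None:
                    continue
                if metric == "rmse":
                    disjoint_better = ci_m[1] < ci_o[0]
                else:
                    disjoint_better = ci_m[0] > ci_o[1]
                if disjoint_better:
                    flags.append(f"{m}>{other}")
        for m in methods:
            rec[m] = _fmt(cells.get(m), metric)
        rec["best"] = "tie: " + ", ".join(best) if len(best) > 1 else best[0]
        rec["significant"] = "; ".join(sorted(flags))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("row")
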