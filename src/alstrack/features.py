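"""Daily day/night summary-statistic features from high-frequency sensor streams.

Each (calendar date, channel, period) cell of raw samples is reduced to 17
summary statistics; columns are named ``<channel>__<period>__<stat>``.
Collinear and constant columns are removed on training rows only, and the
surviving columns are min-max normalized with training-row statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

STAT_NAMES = [
    "count", "min", "max", "mean", "median", "mode", "variance", "range",
    "skew", "kurtosis", "q10", "q25", "q75", "q90", "iqr", "cv", "entropy",
]

DEFAULT_DAY_WINDOW = (6, 22)  # [06:00, 22:00) local, half-open
ENTROPY_BINS = 10


def segment_day_night(stream: pd.DataFrame, day_window=DEFAULT_DAY_WINDOW) -> pd.DataFrame:
    """Tag each sample 'day' if its clock time falls in [start, end) else 'night'.

    ``day_window`` is a pair of hours (possibly fractional). The partition is
    exhaustive and disjoint by construction.
    """
    start, end = day_window
    if not start < end:
        raise ValueError("inverted day window: start must precede end")
    ts = pd.to_datetime(stream["timestamp"])
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    out = stream.copy()
    out["period"] = np.where((hours >= start) & (hours < end), "day", "night")
    return out


def _cell_stats(v: np.ndarray) -> dict[str, float]:
    """The 17 summary statistics of one (date, channel, period) cell.

    Variance is the population variance; skew/kurtosis are the standardized
    third/fourth central moments (kurtosis as excess), zero for constant
    cells; entropy is the Shannon entropy (nats) of a 10-bin histogram; the
    mode is the most frequent 2-decimal rounding (ties -> smallest value);
    CV is sd/mean with a zero-mean guard.
    """
    n = v.size
    mean = float(v.mean())
    m2 = float(np.mean((v - mean) ** 2))
    sd = np.sqrt(m2)
    if m2 > 1e-15:
        skew = float(np.mean((v - mean) ** 3)) / m2 ** 1.5
        kurt = float(np.mean((v - mean) ** 4)) / m2 ** 2 - 3.0
    else:
        skew = kurt = 0.0
    q10, q25, q75, q90 = np.quantile(v, [0.10, 0.25, 0.75, 0.90])
    uniq, counts = np.unique(np.round(v, 2), return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # np.unique is sorted -> smallest tie wins
    # equal-width bins over [min, max]; bin index floor(B*(x-min)/span),
    # the maximum lands in the last bin; constant cells -> one bin
    span = float(v.max() - v.min())
    if span == 0.0:
        entropy = 0.0
    else:
        idx = np.minimum((ENTROPY_BINS * (v - v.min()) / span).astype(int),
                         ENTROPY_BINS - 1)
        counts_h = np.bincount(idx, minlength=ENTROPY_BINS)
        p = counts_h[counts_h > 0] / n
        entropy = float(-(p * np.log(p)).sum())
    return {
        "count": float(n),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": mean,
        "median": float(np.median(v)),
        "mode": mode,
        "variance": m2,
        "range": float(v.max() - v.min()),
        "skew": skew,
        "kurtosis": kurt,
        "q10": float(q10),
        "q25": float(q25),
        "q75": float(q75),
        "q90": float(q90),
        "iqr": float(q75 - q25),
        "cv": float(sd / mean) if abs(mean) >= 1e-12 else 0.0,
        "entropy": entropy,
    }


def summarize_daily(tagged: pd.DataFrame) -> pd.DataFrame:
    """Unnormalized DailyFeatureMatrix: one row per date, one column per
    channel x period x statistic.  Days containing non-finite samples are
    excluded with a log entry; empty cells are left missing (count 0 is only
    emitted for period cells of days that have data in the other period).
    """
    df = tagged.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()

    bad = ~np.isfinite(df["value"].to_numpy(dtype=float))
    if bad.any():
        bad_dates = df.loc[bad, "date"].unique()
        log.warning("excluding %d day(s) with non-finite samples", len(bad_dates))
        df = df[~df["date"].isin(bad_dates)]

    records: dict[pd.Timestamp, dict[str, float]] = {}
    for (date, channel, period), grp in df.groupby(["date", "channel_id", "period"], sort=True):
        stats = _cell_stats(grp["value"].to_numpy(dtype=float))
        row = records.setdefault(date, {})
        for stat, val in stats.items():
            row[f"{channel}__{period}__{stat}"] = val
    mat = pd.DataFrame.from_dict(records, orient="index").sort_index()
    mat.index.name = "date"
    # a period with no samples on an otherwise-covered day: count 0, stats missing
    count_cols = [c for c in mat.columns if c.endswith("__count")]
    mat[count_cols] = mat[count_cols].fillna(0.0)
    return mat[sorted(mat.columns)]


class CollinearityFilter(BaseEstimator, TransformerMixin):
    """Greedy keep-first removal of highly collinear feature columns.

    Scanning columns in fixed order, a column is dropped when its absolute
    Pearson correlation with any earlier *retained* column exceeds
    ``threshold``; zero-variance columns are dropped with reason "constant".
    Fit on training rows only.
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        cols = list(X.columns)
        arr = X.to_numpy(dtype=float)
        std = np.nanstd(arr, axis=0)
        finite_any = np.isfinite(arr).any(axis=0)
        corr = X.corr().to_numpy()  # pairwise-complete Pearson
        kept_idx: list[int] = []
        kept: list[str] = []
        dropped: list[dict] = []
        for j, col in enumerate(cols):
            if std[j] == 0.0 or not finite_any[j]:
                dropped.append({"dropped": col, "kept": None, "r": np.nan,
                                "reason": "constant"})
                continue
            r_row = corr[j, kept_idx] if kept_idx else np.empty(0)
            hits = np.flatnonzero(np.abs(r_row) > self.threshold)
            if hits.size:
                k = kept_idx[hits[0]]
                dropped.append({"dropped": col, "kept": cols[k],
                                "r": float(corr[j, k]), "reason": "collinear"})
            else:
                kept_idx.append(j)
                kept.append(col)
        self.kept_ = kept
        self.dropped_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped_, columns=["dropped", "kept", "r", "reason"])


class MinMaxColumnScaler(BaseEstimator, TransformerMixin):
    """Column-wise x' = (x - min) / (max - min), fit on training rows only.

    Constant columns map to 0; the fitted transform is applied unchanged to
    later rows, which may therefore leave [0, 1] (no clipping).
    """

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) == 0:
            raise ValueError("cannot fit scaler on empty training rows")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        rng = (self.data_max_ - self.data_min_).to_numpy(dtype=float)
        self.scale_ = pd.Series(np.where(rng == 0, 0.0, 1.0 / np.where(rng == 0, 1.0, rng)),
                                index=X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.data_min_) * self.scale_


def minmax_normalize(matrix: pd.DataFrame, fit_rows: pd.Index) -> tuple[pd.DataFrame, MinMaxColumnScaler]:
    scaler = MinMaxColumnScaler().fit(matrix.loc[fit_rows])
    return scaler.transform(matrix), scaler


def drop_collinear(matrix: pd.DataFrame, threshold: float = 0.95,
                   fit_rows: pd.Index | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    filt = CollinearityFilter(threshold)
    filt.fit(matrix if fit_rows is None else matrix.loc[fit_rows])
    return filt.transform(matrix), filt.report()


def assemble_supervised_table(features: pd.DataFrame, labels: pd.Series,
                              label_name: str = "label") -> pd.DataFrame:
    """Inner-join daily features with a pseudo-label series by exact date."""
    if features.index.duplicated().any():
        raise ValueError("no duplicate dates allowed in the feature matrix")
    if labels.index.duplicated().any():
        raise ValueError("no duplicate dates allowed in the label series")
    joined = features.join(labels.rename(label_name), how="inner")
    n_dropped = len(features) - len(joined)
    if n_dropped:
        log.info("dropped %d feature row(s) without labels", n_dropped)
    if joined.empty:
        raise ValueError("empty intersection between feature dates and label dates")
    return joined
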