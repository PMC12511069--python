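"""Daily pseudo-labels from sparse ALSFRS-R assessments.

Three interpolators expand sparse observed scores to one continuous value per
day so supervised learners can train at sensor frequency:

* ``linear``    piecewise-linear between assessment anchors (clinical slope
                baseline), constant extension outside the anchor span;
* ``cubic``     natural cubic spline through the anchors, clipped to range;
* ``attention`` a shallow transformer encoder regressing observed scores on
                date-indexed sensor feature vectors, fit per sensor-channel
                feature table and ensembled by pointwise averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, RegressorMixin

from ._autograd import Tensor, concat, relu, softmax

METHODS = ("linear", "cubic", "attention")


@dataclass
class PseudoLabelSeries:
    participant_id: str
    scale_id: str
    method: str
    series: pd.Series            # daily index -> continuous value
    anchor_dates: pd.DatetimeIndex

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy()


def scale_range(scale_id: str) -> tuple[float, float]:
    return (0.0, 48.0) if scale_id == "composite" else (0.0, 4.0)


def _check_anchors(dates: pd.DatetimeIndex, scores: np.ndarray) -> None:
    if len(dates) < 2:
        raise ValueError("insufficient anchors: need at least two assessments")
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValueError("anchor dates must be strictly increasing")


def _day_numbers(index: pd.DatetimeIndex, origin: pd.Timestamp) -> np.ndarray:
    return (index - origin).days.to_numpy(dtype=float)


def interpolate_linear(assessments: pd.DataFrame, scale_id: str,
                       daily_index: pd.DatetimeIndex,
                       participant_id: str = "") -> PseudoLabelSeries:
    """Piecewise-linear interpolation; constant extension beyond the anchors."""
    dates = pd.DatetimeIndex(assessments["date"])
    scores = assessments[scale_id].to_numpy(dtype=float)
    _check_anchors(dates, scores)
    x = _day_numbers(daily_index, dates[0])
    xp = _day_numbers(dates, dates[0])
    vals = np.interp(x, xp, scores)  # np.interp clamps to edge values outside
    return PseudoLabelSeries(participant_id, scale_id, "linear",
                             pd.Series(vals, index=daily_index), dates)


def interpolate_cubic(assessments: pd.DataFrame, scale_id: str,
                      daily_index: pd.DatetimeIndex,
                      participant_id: str = "") -> PseudoLabelSeries:
    """Natural cubic spline through the anchors, clipped to the scale range;
    constant extension outside the anchor span.  With exactly two anchors the
    natural boundary conditions reduce the spline to the linear interpolant.
    """
    dates = pd.DatetimeIndex(assessments["date"])
    scores = assessments[scale_id].to_numpy(dtype=float)
    _check_anchors(dates, scores)
    xp = _day_numbers(dates, dates[0])
    spline = CubicSpline(xp, scores, bc_type="natural")
    x = _day_numbers(daily_index, dates[0])
    vals = spline(np.clip(x, xp[0], xp[-1]))
    lo, hi = scale_range(scale_id)
    vals = np.clip(vals, lo, hi)
    return PseudoLabelSeries(participant_id, scale_id, "cubic",
                             pd.Series(vals, index=daily_index), dates)


# ---------------------------------------------------------------------------
# self-attention interpolation
# ---------------------------------------------------------------------------

@dataclass
class AttentionConfig:
    d_model: int = 32
    n_heads: int = 2
    n_layers: int = 1
    ff_dim: int = 64
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    target_mode: str = "score"  # "score" | "delta"


class AttentionInterpolator(BaseEstimator, RegressorMixin):
    """Shallow transformer encoder mapping date-indexed sensor feature vectors
    to a continuous score, trained by MSE on assessment (anchor) days only and
    evaluated on every day.

    Tokens are the daily feature vectors plus a sinusoidal encoding of the
    normalized day index; the encoder is intentionally shallow (default one
    layer, two heads) so it produces smooth continuous values rather than
    crisp labels.  Targets are standardized with anchor statistics before
    training and de-standardized at prediction; outputs are clipped to the
    scale range by the caller.  Deterministic given ``seed``.
    """

    def __init__(self, d_model=32, n_heads=2, n_layers=1, ff_dim=64,
                 epochs=200, learning_rate=1e-3, seed=0):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.ff_dim = ff_dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    # -- architecture -----------------------------------------------------
    def _init_params(self, n_features: int, rng: np.random.Generator) -> dict[str, Tensor]:
        def glorot(shape):
            lim = np.sqrt(6.0 / sum(shape))
            return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

        d, f = self.d_model, self.ff_dim
        p = {"We": glorot((n_features, d)), "be": Tensor(np.zeros(d), requires_grad=True)}
        for layer in range(self.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{name}{layer}"] = glorot((d, d))
            p[f"W1{layer}"] = glorot((d, f))
            p[f"b1{layer}"] = Tensor(np.zeros(f), requires_grad=True)
            p[f"W2{layer}"] = glorot((f, d))
            p[f"b2{layer}"] = Tensor(np.zeros(d), requires_grad=True)
            for ln in ("a", "b"):
                p[f"g{ln}{layer}"] = Tensor(np.ones(d), requires_grad=True)
                p[f"o{ln}{layer}"] = Tensor(np.zeros(d), requires_grad=True)
        # zero-initialized head: the initial prediction is the anchor mean
        p["Wh"] = Tensor(np.zeros((d, 1)), requires_grad=True)
        p["bh"] = Tensor(np.zeros(1), requires_grad=True)
        return p

    @staticmethod
    def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=1, keepdims=True)
        return (x - mu) * ((var + 1e-6) ** -0.5) * gain + bias

    def _forward(self, p: dict[str, Tensor], X: np.ndarray) -> Tensor:
        d = self.d_model
        dh = d // self.n_heads
        h = Tensor(X) @ p["We"] + p["be"]
        h = h + self._pos_encoding(X.shape[0])
        for layer in range(self.n_layers):
            q = h @ p[f"Wq{layer}"]
            k = h @ p[f"Wk{layer}"]
            v = h @ p[f"Wv{layer}"]
            heads = []
            for i in range(self.n_heads):
                sl = (slice(None), slice(i * dh, (i + 1) * dh))
                scores = (q[sl] @ k[sl].T) * (1.0 / np.sqrt(dh))
                heads.append(softmax(scores, axis=-1) @ v[sl])
            att = concat(heads, axis=1) @ p[f"Wo{layer}"]
            h = self._layer_norm(h + att, p[f"ga{layer}"], p[f"oa{layer}"])
            ff = relu(h @ p[f"W1{layer}"] + p[f"b1{layer}"]) @ p[f"W2{layer}"] + p[f"b2{layer}"]
            h = self._layer_norm(h + ff, p[f"gb{layer}"], p[f"ob{layer}"])
        return (h @ p["Wh"] + p["bh"])[:, 0]

    def _pos_encoding(self, n_days: int) -> np.ndarray:
        pos = np.linspace(0.0, 1.0, n_days)[:, None]  # normalized day index
        k = np.arange(1, self.d_model // 2 + 1)[None, :]
        pe = np.empty((n_days, self.d_model))
        pe[:, 0::2] = np.sin(np.pi * pos * k)
        pe[:, 1::2] = np.cos(np.pi * pos * k)
        return pe

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, anchor_idx: np.ndarray | None = None):
        """Train on rows ``anchor_idx`` of the daily feature matrix ``X``
        against targets ``y`` (one per anchor).  If ``anchor_idx`` is None,
        every row is a target (plain supervised fit)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if anchor_idx is None:
            anchor_idx = np.arange(len(X))
        anchor_idx = np.asarray(anchor_idx, dtype=int)
        if len(anchor_idx) < 2:
            raise ValueError("insufficient anchors: need at least two")
        if not np.isfinite(X[anchor_idx]).all():
            raise ValueError("anchor days are missing sensor features")

        self._y_mu = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        yt = (y - self._y_mu) / self._y_sd

        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(X.shape[1], rng)
        names = list(self.params_)
        m = {n: np.zeros_like(self.params_[n].data) for n in names}
        v = {n: np.zeros_like(self.params_[n].data) for n in names}
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.loss_curve_ = []
        for step in range(1, self.epochs + 1):
            for n in names:
                self.params_[n].grad = None
            pred = self._forward(self.params_, X)[anchor_idx]
            loss = ((pred - yt) ** 2.0).mean()
            loss.backward()
            self.loss_curve_.append(float(loss.data))
            for n in names:
                g = self.params_[n].grad
                if g is None:
                    continue
                m[n] = b1 * m[n] + (1 - b1) * g
                v[n] = b2 * v[n] + (1 - b2) * g * g
                mh = m[n] / (1 - b1 ** step)
                vh = v[n] / (1 - b2 ** step)
                self.params_[n].data -= self.learning_rate * mh / (np.sqrt(vh) + eps)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = self._forward(self.params_, X).data
        return out * self._y_sd + self._y_mu


def _channel_tables(feature_matrix: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a DailyFeatureMatrix into one table per sensor channel
    (day + night statistics of that channel)."""
    channels = sorted({c.split("__")[0] for c in feature_matrix.columns})
    return {ch: feature_matrix[[c for c in feature_matrix.columns if c.startswith(ch + "__")]]
            for ch in channels}


def fit_attention_interpolator(feature_table: pd.DataFrame, assessments: pd.DataFrame,
                               scale_id: str, config: AttentionConfig,
                               participant_id: str = "") -> pd.Series:
    """Daily estimates from one sensor-channel feature table.

    Feature columns are min-max scaled over the table's own daily span (this
    is label construction, upstream of any train/test split), missing days
    are filled with the column median, and the encoder is trained against the
    observed scores on anchor days only.
    """
    dates = pd.DatetimeIndex(assessments["date"])
    scores = assessments[scale_id].to_numpy(dtype=float)
    _check_anchors(dates, scores)
    daily_index = feature_table.index
    X = feature_table.to_numpy(dtype=float)
    col_min = np.nanmin(X, axis=0)
    col_rng = np.nanmax(X, axis=0) - col_min
    col_rng[col_rng == 0] = 1.0
    X = (X - col_min) / col_rng
    med = np.nanmedian(X, axis=0)
    X = np.where(np.isfinite(X), X, med)

    covered = np.isin(dates, daily_index)
    if covered.sum() < 2:
        raise ValueError("anchor days are missing sensor features")
    anchor_idx = daily_index.get_indexer(dates[covered])
    y = scores[covered]

    model = AttentionInterpolator(
        d_model=config.d_model, n_heads=config.n_heads, n_layers=config.n_layers,
        ff_dim=config.ff_dim, epochs=config.epochs,
        learning_rate=config.learning_rate, seed=config.seed)

    if config.target_mode == "delta":
        # regress anchor-to-anchor per-day change, then integrate from the
        # most recent observation
        model.fit(X, _delta_targets(anchor_idx, y), anchor_idx=anchor_idx)
        daily_delta = model.predict(X)
        vals = _integrate_deltas(daily_delta, anchor_idx, y)
    else:
        model.fit(X, y, anchor_idx=anchor_idx)
        vals = model.predict(X)
    lo, hi = scale_range(scale_id)
    return pd.Series(np.clip(vals, lo, hi), index=daily_index)


def _delta_targets(anchor_idx: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-day rate of change of the interval ending at each anchor (first
    anchor gets the first interval's rate)."""
    rates = np.diff(y) / np.maximum(np.diff(anchor_idx), 1)
    return np.concatenate([[rates[0] if len(rates) else 0.0], rates]) if len(y) > 1 else np.zeros(1)


def _integrate_deltas(daily_delta: np.ndarray, anchor_idx: np.ndarray, y: np.ndarray) -> np.ndarray:
    vals = np.empty_like(daily_delta)
    cum = np.concatenate([[0.0], np.cumsum(daily_delta)])
    prev = anchor_idx[0]
    prev_y = y[0]
    vals[: anchor_idx[0] + 1] = y[0]
    for a, ya in list(zip(anchor_idx[1:], y[1:])) + [(len(daily_delta) - 1, None)]:
        for t in range(prev + 1, a + 1):
            vals[t] = prev_y + (cum[t] - cum[prev])
        if ya is not None:
            prev, prev_y = a, ya
            vals[a] = ya
    return vals


def ensemble_attention(series_list: list[pd.Series], participant_id: str = "",
                       scale_id: str = "") -> PseudoLabelSeries:
    """Pointwise arithmetic mean of per-channel-table attention estimates."""
    if not series_list:
        raise ValueError("cannot ensemble an empty list of series")
    index = series_list[0].index
    for s in series_list[1:]:
        if not s.index.equals(index):
            raise ValueError("all member series must share the daily index")
    mean = pd.concat(series_list, axis=1).mean(axis=1)
    return PseudoLabelSeries(participant_id, scale_id, "attention", mean,
                             pd.DatetimeIndex([]))


def interpolate_attention(feature_matrix: pd.DataFrame, assessments: pd.DataFrame,
                          scale_id: str, config: AttentionConfig | None = None,
                          participant_id: str = "") -> PseudoLabelSeries:
    """Full self-attention pseudo-labeling: one interpolator per sensor-channel
    table, ensembled by averaging."""
    config = config or AttentionConfig()
    members = [
        fit_attention_interpolator(tbl, assessments, scale_id, config, participant_id)
        for _, tbl in sorted(_channel_tables(feature_matrix).items())
    ]
    out = ensemble_attention(members, participant_id, scale_id)
    out.anchor_dates = pd.DatetimeIndex(assessments["date"])
    return out


def pseudo_label(method: str, assessments: pd.DataFrame, scale_id: str,
                 daily_index: pd.DatetimeIndex,
                 feature_matrix: pd.DataFrame | None = None,
                 attention_config: AttentionConfig | None = None,
                 participant_id: str = "") -> PseudoLabelSeries:
    if method == "linear":
        return interpolate_linear(assessments, scale_id, daily_index, participant_id)
    if method == "cubic":
        return interpolate_cubic(assessments, scale_id, daily_index, participant_id)
    if method == "attention":
        if feature_matrix is None:
            raise ValueError("attention interpolation requires a feature matrix")
        out = interpolate_attention(feature_matrix.loc[daily_index.intersection(feature_matrix.index)],
                                    assessments, scale_id, attention_config, participant_id)
        return out
    raise ValueError(f"unknown method {method!r}")
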