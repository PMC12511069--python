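"""Gradient-boosted progression models under three learning paradigms.

* individual batch: fit once on the holdout participant's chronological
  training rows;
* cohort transfer + batch fine-tune: fit a base model on the shuffled pooled
  rows of the leave-in participants, then resume boosting with one pass over
  the holdout participant's training rows;
* cohort transfer + incremental fine-tune: prequential predict-then-fit loop
  over the holdout training rows in date order, resuming boosting on a short
  trailing window after each prediction.

Hyperparameters come from a randomized search over the fixed candidate lists
in ``SEARCH_SPACE``; feature subsets from an iterative precision-rounding
screener over split-frequency importances (capped at 200 features).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import ParameterSampler

log = logging.getLogger(__name__)

#: Candidate lists for the nine tuned hyperparameters.
SEARCH_SPACE: dict[str, list] = {
    "learning_rate": [0.001, 0.01, 0.1, 0.3, 0.5],
    "n_estimators": [32, 64, 128, 192, 256, 384, 512],
    "gamma": [0, 0.25, 0.5, 1],
    "max_depth": [2, 3, 4, 6, 8, 10, 12, 16, 24],
    "min_child_weight": [0.5, 1, 3, 5, 7, 10],
    "subsample": [0.8, 0.9, 1.0],
    "colsample_bytree": [0.6, 0.7, 0.8, 0.9],
    "reg_lambda": [0.01, 0.1, 1, 5, 10, 50, 100],
    "reg_alpha": [0, 0.001, 0.01, 0.1],
}

DEFAULT_PARAMS = {
    "learning_rate": 0.1, "n_estimators": 128, "gamma": 0, "max_depth": 3,
    "min_child_weight": 1, "subsample": 1.0, "colsample_bytree": 0.9,
    "reg_lambda": 1, "reg_alpha": 0,
}

MAX_FEATURES = 200  # screener cap


# ---------------------------------------------------------------------------
# splits and screening
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    participant_id: str
    train_dates: pd.DatetimeIndex
    test_dates: pd.DatetimeIndex
    train_fraction: float


def split_sequential(table: pd.DataFrame, train_fraction: float = 0.8,
                     participant_id: str = "") -> SplitSpec:
    """Chronological 80/20 partition: earliest floor(f*N) rows train, rest test."""
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 observations to split")
    dates = pd.DatetimeIndex(table.index).sort_values()
    n_train = int(np.floor(train_fraction * n))
    return SplitSpec(participant_id, dates[:n_train], dates[n_train:], train_fraction)


@dataclass
class ScreenDecision:
    model: bool
    reason: str = ""
    static: bool = False  # exactly-zero variance: transfer models are skipped too


def screen_variance(train_labels: np.ndarray | pd.Series, epsilon: float = 0.01) -> ScreenDecision:
    """Exclude targets whose training labels carry (near-)no signal.

    Zero variance: no model of any paradigm (the score is static).  Variance
    below ``epsilon``: individual batch models are skipped.
    """
    v = float(np.var(np.asarray(train_labels, dtype=float)))
    if v == 0.0:
        return ScreenDecision(False, "zero variance", static=True)
    if v < epsilon:
        return ScreenDecision(False, "near-zero variance")
    return ScreenDecision(True)


# ---------------------------------------------------------------------------
# native-booster wrapper (supports checkpointed continuation)
# ---------------------------------------------------------------------------

class BoostedRegressor(BaseEstimator, RegressorMixin):
    """sklearn-style regressor over a native XGBoost booster.

    The native API is used so that fine-tuning can resume boosting from a
    serialized checkpoint (``xgb.train(..., xgb_model=...)``), which the
    sklearn estimator cannot round-trip faithfully.  Single-threaded and
    seeded for determinism.
    """

    def __init__(self, learning_rate=0.1, n_estimators=128, gamma=0, max_depth=3,
                 min_child_weight=1, subsample=1.0, colsample_bytree=0.9,
                 reg_lambda=1, reg_alpha=0, seed=0):
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.gamma = gamma
        self.max_depth = max_depth
        self.min_child_weight = min_child_weight
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.reg_lambda = reg_lambda
        self.reg_alpha = reg_alpha
        self.seed = seed

    def _xgb_params(self) -> dict:
        return {
            "objective": "reg:squarederror",
            "eta": self.learning_rate,
            "gamma": self.gamma,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "lambda": self.reg_lambda,
            "alpha": self.reg_alpha,
            "seed": self.seed,
            # re-seed the column sampler each round: boosting continuation is
            # otherwise nondeterministic with colsample_bytree < 1
            "seed_per_iteration": True,
            "nthread": 1,
            "tree_method": "hist",
        }

    def _dmatrix(self, X: pd.DataFrame, y=None) -> xgb.DMatrix:
        if hasattr(self, "feature_names_") and list(X.columns) != self.feature_names_:
            raise ValueError("feature-name mismatch with the fitted model")
        return xgb.DMatrix(X.to_numpy(dtype=float), label=y,
                           feature_names=[str(c) for c in X.columns])

    def fit(self, X: pd.DataFrame, y):
        self.feature_names_ = list(X.columns)
        dtrain = self._dmatrix(X, np.asarray(y, dtype=float))
        self.booster_ = xgb.train(self._xgb_params(), dtrain,
                                  num_boost_round=self.n_estimators)
        return self

    def resume(self, X: pd.DataFrame, y, n_rounds: int) -> "BoostedRegressor":
        """Continue boosting for ``n_rounds`` on new data; returns self."""
        if n_rounds == 0:
            return self
        dtrain = self._dmatrix(X, np.asarray(y, dtype=float))
        self.booster_ = xgb.train(self._xgb_params(), dtrain,
                                  num_boost_round=n_rounds, xgb_model=self.booster_)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.booster_.predict(self._dmatrix(X))

    def importances(self) -> pd.Series:
        """Split-frequency ("weight") importances, normalized to sum to 1."""
        score = self.booster_.get_score(importance_type="weight")
        imp = pd.Series({f: score.get(f, 0.0) for f in self.feature_names_}, dtype=float)
        total = imp.sum()
        return imp / total if total > 0 else imp

    def copy(self) -> "BoostedRegressor":
        clone = BoostedRegressor(**self.get_params())
        if hasattr(self, "booster_"):
            clone.booster_ = xgb.Booster(model_file=bytearray(self.booster_.save_raw("ubj")))
            clone.feature_names_ = list(self.feature_names_)
        return clone


# ---------------------------------------------------------------------------
# randomized search + precision-rounding screener
# ---------------------------------------------------------------------------

@dataclass
class ScreenerTrace:
    precisions: list[int] = field(default_factory=list)
    subsets: list[list[str]] = field(default_factory=list)
    rmses: list[float] = field(default_factory=list)
    chosen: int = -1


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y, float) - np.asarray(yhat, float)) ** 2)))


def _cv_folds(n: int, n_folds: int, chronological: bool, seed: int):
    """Chronological block folds (train on past, validate on the block) or
    shuffled K-fold indices."""
    idx = np.arange(n)
    if chronological:
        blocks = np.array_split(idx, n_folds + 1)
        for i in range(1, n_folds + 1):
            train = np.concatenate(blocks[:i])
            yield train, blocks[i]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(idx)
        for block in np.array_split(perm, n_folds):
            yield np.setdiff1d(idx, block), block


def precision_rounding_subsets(importances: pd.Series, start_precision: int = 6,
                               max_features: int = MAX_FEATURES) -> list[tuple[int, list[str]]]:
    """Feature subsets from rounding importances at increasing decimal
    precision: a feature enters the subset at precision p when its importance,
    rounded at p decimals, is non-zero.  Subsets are nondecreasing in size and
    capped at the ``max_features`` largest importances.
    """
    nonzero = importances[importances > 0]
    order = nonzero.sort_values(ascending=False, kind="stable")
    capped = set(order.index[:max_features])
    out = []
    p = start_precision
    prev: set[str] = set()
    while True:
        subset = [f for f in importances.index
                  if round(float(importances[f]), p) > 0 and f in capped]
        if subset and set(subset) != prev:
            out.append((p, subset))
            prev = set(subset)
        if len(subset) >= min(len(nonzero), max_features) or p > 16:
            break
        p += 1
    return out


def tune_and_select(train_table: pd.DataFrame, label_col: str = "label",
                    n_draws: int = 50, n_folds: int = 3,
                    selection_frac: float = 0.2, seed: int = 0,
                    chronological: bool = True,
                    selection_rows: pd.DataFrame | None = None
                    ) -> tuple[dict, list[str], ScreenerTrace]:
    """Randomized hyperparameter search followed by the precision-rounding
    feature screener.

    1. ``n_draws`` configurations sampled from ``SEARCH_SPACE`` are scored by
       cross-validated RMSE on the training rows; the best is kept.
    2. Split-frequency importances from a refit define nested feature subsets
       at precision 6, 7, 8, ... decimals (<= 200 features).
    3. Each subset is refit and scored on the selection rows (by default the
       last ``selection_frac`` of the training rows, held out from the
       screener refits); the lowest-RMSE subset wins, ties to the smaller.

    Passing explicit ``selection_rows`` reproduces the test-set-based
    selection variant.
    """
    X = train_table.drop(columns=[label_col])
    y = train_table[label_col].to_numpy(dtype=float)

    if n_draws > 0:
        sampler = ParameterSampler(SEARCH_SPACE, n_iter=n_draws, random_state=seed % (2**32))
        configs = list(sampler)
        best_params, best_cv = None, np.inf
        for params in configs:
            scores = []
            for tr, va in _cv_folds(len(X), n_folds, chronological, seed):
                mdl = BoostedRegressor(**params, seed=seed).fit(X.iloc[tr], y[tr])
                scores.append(_rmse(y[va], mdl.predict(X.iloc[va])))
            cv = float(np.mean(scores))
            if cv < best_cv:
                best_cv, best_params = cv, dict(params)
    else:
        best_params = dict(DEFAULT_PARAMS)

    # selection slice
    if selection_rows is None:
        n_sel = max(1, int(np.floor(selection_frac * len(X))))
        fit_X, fit_y = X.iloc[:-n_sel], y[:-n_sel]
        sel_X, sel_y = X.iloc[-n_sel:], y[-n_sel:]
    else:
        fit_X, fit_y = X, y
        sel_X = selection_rows.drop(columns=[label_col])
        sel_y = selection_rows[label_col].to_numpy(dtype=float)

    base = BoostedRegressor(**best_params, seed=seed).fit(fit_X, fit_y)
    imp = base.importances()
    trace = ScreenerTrace()
    if float(imp.sum()) == 0.0:
        log.warning("all importances zero; keeping all features")
        selected = list(X.columns)
        trace.precisions, trace.subsets = [6], [selected]
        trace.rmses = [_rmse(sel_y, base.predict(sel_X))]
        trace.chosen = 0
        return best_params, selected, trace

    for p, subset in precision_rounding_subsets(imp):
        mdl = BoostedRegressor(**best_params, seed=seed).fit(fit_X[subset], fit_y)
        r = _rmse(sel_y, mdl.predict(sel_X[subset]))
        trace.precisions.append(p)
        trace.subsets.append(subset)
        trace.rmses.append(r)
    rmses = np.array(trace.rmses)
    sizes = np.array([len(s) for s in trace.subsets])
    # lowest RMSE; equal RMSE -> smaller subset
    order = np.lexsort((sizes, np.round(rmses, 12)))
    trace.chosen = int(order[0])
    return best_params, trace.subsets[trace.chosen], trace


# ---------------------------------------------------------------------------
# paradigms
# ---------------------------------------------------------------------------

def _take_features(table: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise ValueError(
            f"feature-name mismatch with the fitted model: missing {missing[:5]}")
    return table[names]


@dataclass
class ModelArtifact:
    model: BoostedRegressor
    feature_names: list[str]
    hyperparameters: dict
    provenance: dict

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(_take_features(X, self.feature_names))


def _row_id_hashes(table: pd.DataFrame) -> list[str]:
    pid = table.attrs.get("participant_id", "")
    return [hashlib.sha1(f"{pid}:{d.isoformat()}".encode()).hexdigest()
            for d in table.index]


def fit_individual_batch(train_table: pd.DataFrame, params: dict,
                         features: list[str] | None = None, label_col: str = "label",
                         seed: int = 0, provenance: dict | None = None) -> ModelArtifact:
    """Batch fit on the holdout participant's chronological training rows."""
    decision = screen_variance(train_table[label_col])
    if not decision.model:
        raise ValueError(f"target screened out: {decision.reason}")
    features = features or [c for c in train_table.columns if c != label_col]
    mdl = BoostedRegressor(**params, seed=seed).fit(
        train_table[features], train_table[label_col])
    prov = {"paradigm": "individual_batch", "seed": seed, **(provenance or {})}
    return ModelArtifact(mdl, features, params, prov)


def fit_cohort_base(leave_in_tables: dict[str, pd.DataFrame], params: dict,
                    features: list[str] | None = None, label_col: str = "label",
                    seed: int = 0, provenance: dict | None = None) -> ModelArtifact:
    """Cohort transfer base: pooled leave-in rows, shuffled, fit once.

    The artifact's provenance records a hash of every training row id so that
    leave-one-participant-out integrity can be audited afterwards.
    """
    if len(leave_in_tables) < 2:
        raise ValueError("LOPO requires >=2 leave-in participants")
    parts = []
    row_hashes: list[str] = []
    for pid in sorted(leave_in_tables):
        t = leave_in_tables[pid].copy()
        t.attrs["participant_id"] = pid
        row_hashes.extend(_row_id_hashes(t))
        parts.append(t)
    pooled = pd.concat(parts, axis=0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pooled))
    pooled = pooled.iloc[order]
    features = features or [c for c in pooled.columns if c != label_col]
    mdl = BoostedRegressor(**params, seed=seed).fit(pooled[features], pooled[label_col])
    prov = {"paradigm": "cohort_base", "seed": seed,
            "leave_in": sorted(leave_in_tables),
            "train_row_hashes": sorted(row_hashes), **(provenance or {})}
    return ModelArtifact(mdl, features, params, prov)


def finetune_batch(base: ModelArtifact, holdout_train: pd.DataFrame,
                   n_rounds: int | None = None, label_col: str = "label") -> ModelArtifact:
    """Resume boosting from the cohort checkpoint with a single pass over the
    holdout participant's full training set.  Hyperparameters are held fixed;
    ``n_rounds`` defaults to the base model's tree count."""
    if n_rounds is None:
        n_rounds = base.hyperparameters.get("n_estimators", DEFAULT_PARAMS["n_estimators"])
    mdl = base.model.copy()
    if n_rounds > 0:
        mdl.resume(_take_features(holdout_train, base.feature_names),
                   holdout_train[label_col], n_rounds)
    prov = {**base.provenance, "paradigm": "transfer_batch",
            "parent": checkpoint_id(base), "finetune_rounds": n_rounds}
    prov.pop("train_row_hashes", None)
    return ModelArtifact(mdl, base.feature_names, base.hyperparameters, prov)


def finetune_incremental(base: ModelArtifact, holdout_train: pd.DataFrame,
                         k_rounds: int = 1, window_days: int = 14,
                         label_col: str = "label") -> tuple[ModelArtifact, pd.Series]:
    """Prequential fine-tuning: for each training row in date order, predict
    with the model state *before* seeing that row, then resume boosting for
    ``k_rounds`` on the trailing window of the most recent ``window_days``
    rows (including the new one).  Returns the adapted model and the
    prequential prediction sequence."""
    dates = pd.DatetimeIndex(holdout_train.index)
    if not dates.is_monotonic_increasing:
        raise ValueError("holdout rows must be in strictly increasing date order")
    mdl = base.model.copy()
    X = _take_features(holdout_train, base.feature_names)
    y = holdout_train[label_col]
    preds = np.empty(len(holdout_train))
    for t in range(len(holdout_train)):
        preds[t] = mdl.predict(X.iloc[[t]])[0]
        if k_rounds > 0:
            lo = max(0, t - window_days + 1)
            mdl.resume(X.iloc[lo:t + 1], y.iloc[lo:t + 1], k_rounds)
    prov = {**base.provenance, "paradigm": "transfer_incremental",
            "parent": checkpoint_id(base), "k_rounds": k_rounds,
            "window_days": window_days}
    prov.pop("train_row_hashes", None)
    artifact = ModelArtifact(mdl, base.feature_names, base.hyperparameters, prov)
    return artifact, pd.Series(preds, index=holdout_train.index)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def checkpoint_id(artifact: ModelArtifact) -> str:
    raw = bytes(artifact.model.booster_.save_raw("ubj"))
    return hashlib.sha256(raw).hexdigest()[:16]


def save_checkpoint(artifact: ModelArtifact, path: str | Path) -> Path:
    """Serialized booster + sidecar JSON (provenance, features, params, hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    blob = pickle.dumps({
        "booster_raw": bytes(artifact.model.booster_.save_raw("ubj")),
        "params": artifact.model.get_params(),
    })
    path.write_bytes(blob)
    sidecar = {
        "feature_names": artifact.feature_names,
        "hyperparameters": artifact.hyperparameters,
        "provenance": artifact.provenance,
        "sha256": hashlib.sha256(blob).hexdigest(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path) -> ModelArtifact:
    path = Path(path)
    blob = path.read_bytes()
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    digest = hashlib.sha256(blob).hexdigest()
    if digest != sidecar["sha256"]:
        raise ValueError(
            f"corrupt checkpoint {path}: sha256 {digest} != recorded {sidecar['sha256']}")
    payload = pickle.loads(blob)
    mdl = BoostedRegressor(**payload["params"])
    mdl.booster_ = xgb.Booster(model_file=bytearray(payload["booster_raw"]))
    mdl.feature_names_ = list(sidecar["feature_names"])
    return ModelArtifact(mdl, list(sidecar["feature_names"]),
                         dict(sidecar["hyperparameters"]), dict(sidecar["provenance"]))
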