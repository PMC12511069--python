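"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: synthetic cohort (or CSV
ingest) -> day/night daily features -> collinearity removal and min-max
normalization (training rows only) -> pseudo-labels per scale and
interpolation -> leave-one-participant-out model fitting under the three
paradigms -> metric, Taylor and contrast tables.  One master seed derives all
stage seeds through ``derive_seed`` so identical config + seed reproduces
identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import features as ft
from . import models as md
from . import pseudolabels as pl
from . import synthetic as sy
from .synthetic import derive_seed

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    cohort: sy.CohortConfig | str = "tiny"   # CohortConfig, preset name, or CSV dir
    interpolations: tuple[str, ...] = ("linear", "cubic", "attention")
    paradigms: tuple[str, ...] = ("individual_batch", "transfer_batch", "transfer_incremental")
    scales: tuple[str, ...] = tuple(sy.SCALES)
    seed: int = 0
    out_dir: str | None = None
    paper_faithful: bool = False
    train_fraction: float = 0.8
    collinearity_threshold: float = 0.95
    day_window: tuple[float, float] = (6, 22)
    n_draws: int = 50
    n_folds: int = 3
    k_rounds: int = 1
    window_days: int = 14
    finetune_rounds: int | None = None
    epsilon_variance: float = 0.01
    bootstrap_B: int = 1000
    attention: pl.AttentionConfig = field(default_factory=pl.AttentionConfig)

    def validate(self) -> None:
        if not self.interpolations:
            raise ValueError("at least one interpolation required")
        if not self.paradigms:
            raise ValueError("at least one paradigm required")
        if not self.scales:
            raise ValueError("at least one scale required")
        unknown = set(self.interpolations) - set(pl.METHODS)
        if unknown:
            raise ValueError(f"unknown interpolations: {sorted(unknown)}")
        unknown = set(self.scales) - set(sy.SCALES)
        if unknown:
            raise ValueError(f"unknown scales: {sorted(unknown)}")


@dataclass
class ParticipantData:
    participant_id: str
    features_raw: pd.DataFrame        # unnormalized daily matrix (all rows)
    features: pd.DataFrame            # collinearity-filtered + normalized
    split: md.SplitSpec
    assessments: pd.DataFrame
    labels: dict[tuple[str, str], pd.Series]  # (scale, method) -> daily series


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    taylor: pd.DataFrame
    contrasts: pd.DataFrame
    screened: list[dict]
    participants: dict[str, ParticipantData]
    artifacts: dict[tuple, md.ModelArtifact]
    out_dir: Path | None


def _resolve_cohort(config: ExperimentConfig) -> sy.Cohort:
    c = config.cohort
    if isinstance(c, sy.CohortConfig):
        return sy.generate_cohort(c)
    if isinstance(c, str) and c in sy.PRESETS:
        return sy.generate_cohort(sy.preset_config(c, seed=derive_seed(config.seed, "cohort")))
    path = Path(c)
    if path.is_dir():
        return _load_cohort_csv(path)
    raise ValueError(f"unknown cohort source {c!r}")


def _load_cohort_csv(path: Path) -> sy.Cohort:
    sensors = pd.read_csv(path / "sensors.csv", parse_dates=["timestamp"])
    assess = pd.read_csv(path / "assessments.csv", parse_dates=["date"])
    assessments = {pid: grp.reset_index(drop=True)
                   for pid, grp in assess.groupby("participant_id")}
    n = len(assessments)
    cfg = sy.CohortConfig(n_participants=n, enrollment_days=tuple([1] * n))
    return sy.Cohort(cfg, {}, assessments, sensors)


def prepare_participant(pid: str, sensors: pd.DataFrame, assessments: pd.DataFrame,
                        config: ExperimentConfig) -> ParticipantData:
    tagged = ft.segment_day_night(sensors[sensors["participant_id"] == pid],
                                  config.day_window)
    mat = ft.summarize_daily(tagged)
    split = md.split_sequential(mat, config.train_fraction, pid)
    fit_rows = mat.index if config.paper_faithful else split.train_dates
    filt = ft.CollinearityFilter(config.collinearity_threshold).fit(mat.loc[fit_rows])
    reduced = filt.transform(mat)
    scaler = ft.MinMaxColumnScaler().fit(reduced.loc[fit_rows])
    normalized = scaler.transform(reduced)

    anchors = pd.DatetimeIndex(assessments["date"])
    daily_index = pd.date_range(min(anchors.min(), mat.index.min()),
                                max(anchors.max(), mat.index.max()), freq="D")
    labels: dict[tuple[str, str], pd.Series] = {}
    for scale in config.scales:
        for method in config.interpolations:
            att_seed = derive_seed(config.seed, f"attention:{pid}:{scale}")
            att_cfg = dataclasses.replace(config.attention, seed=att_seed)
            series = pl.pseudo_label(method, assessments, scale, daily_index,
                                     feature_matrix=mat, attention_config=att_cfg,
                                     participant_id=pid)
            labels[(scale, method)] = series.series
    return ParticipantData(pid, mat, normalized, split, assessments, labels)


def _tables_for(data: ParticipantData, scale: str, method: str) -> pd.DataFrame:
    return ft.assemble_supervised_table(data.features, data.labels[(scale, method)])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    config.validate()
    cohort = _resolve_cohort(config)
    pids = sorted(cohort.assessments)

    participants: dict[str, ParticipantData] = {}
    for pid in pids:
        participants[pid] = prepare_participant(
            pid, cohort.sensors, cohort.assessments[pid], config)

    metric_rows: list[dict] = []
    taylor_rows: list[dict] = []
    screened: list[dict] = []
    artifacts: dict[tuple, md.ModelArtifact] = {}

    for holdout in pids:
        data = participants[holdout]
        leave_in = [p for p in pids if p != holdout]
        for scale in config.scales:
            for method in config.interpolations:
                table = _tables_for(data, scale, method)
                train = table.loc[table.index.isin(data.split.train_dates)]
                test = table.loc[table.index.isin(data.split.test_dates)]
                if len(test) == 0 or len(train) < 5:
                    screened.append({"participant": holdout, "scale": scale,
                                     "interpolation": method,
                                     "reason": "insufficient rows"})
                    continue
                decision = md.screen_variance(train["label"], config.epsilon_variance)

                tune_seed = derive_seed(config.seed, f"tune:{holdout}:{scale}:{method}")
                sel_rows = test if config.paper_faithful else None
                if decision.model:
                    ind_params, ind_feats, _ = md.tune_and_select(
                        train, n_draws=config.n_draws, n_folds=config.n_folds,
                        seed=tune_seed, chronological=True, selection_rows=sel_rows)
                else:
                    screened.append({"participant": holdout, "scale": scale,
                                     "interpolation": method,
                                     "paradigm": "individual_batch",
                                     "reason": decision.reason})
                    log.info("screened %s/%s/%s individual_batch: %s",
                             holdout, scale, method, decision.reason)

                reports: dict[str, ev.MetricReport | None] = {}
                for paradigm in config.paradigms:
                    key = (holdout, scale, method, paradigm)
                    report = None
                    pred = None
                    if paradigm == "individual_batch":
                        if decision.model:
                            art = md.fit_individual_batch(
                                train, ind_params, ind_feats,
                                seed=tune_seed,
                                provenance={"fold": holdout, "scale": scale,
                                            "interpolation": method})
                            artifacts[key] = art
                            pred = art.predict(test)
                            report = _evaluate(pred, test, config,
                                               holdout, scale, method, paradigm)
                    else:
                        if len(leave_in) < 2 or decision.static:
                            reason = ("static target" if decision.static
                                      else "LOPO requires >=2 leave-in")
                            screened.append({"participant": holdout, "scale": scale,
                                             "interpolation": method,
                                             "paradigm": paradigm, "reason": reason})
                        else:
                            base = _cohort_base(participants, leave_in, scale, method,
                                                data, config, holdout)
                            artifacts[(holdout, scale, method, "cohort_base")] = base
                            if paradigm == "transfer_batch":
                                art = md.finetune_batch(base, train,
                                                        config.finetune_rounds)
                                pred = art.predict(test)
                            else:
                                # predict-then-fit continues through the test
                                # period: each test-day prediction uses only
                                # earlier observations (prequential evaluation)
                                art, _preq = md.finetune_incremental(
                                    base, train, config.k_rounds, config.window_days)
                                art, test_preq = md.finetune_incremental(
                                    art, test, config.k_rounds, config.window_days)
                                pred = test_preq.to_numpy()
                            artifacts[key] = art
                            report = _evaluate(pred, test, config,
                                               holdout, scale, method, paradigm)
                    reports[paradigm] = report
                    if report is not None:
                        metric_rows.append(_metric_row(holdout, scale, method,
                                                       paradigm, report))
                        pair = ev.PairedPredictions(
                            test["label"].to_numpy(), pred,
                            holdout, scale, method, paradigm)
                        tp = ev.taylor_point(pair)
                        taylor_rows.append({
                            "participant": holdout, "scale": scale,
                            "interpolation": method, "paradigm": paradigm,
                            "sigma_ref": tp.sigma_ref, "sigma_pred": tp.sigma_pred,
                            "r": tp.r, "abs_r": abs(tp.r),
                            "negative_r": tp.r < 0,
                            "centered_rmse": tp.centered_rmse})

    metrics = pd.DataFrame(metric_rows, columns=[
        "participant", "scale", "interpolation", "paradigm", "rmse", "rmse_lo",
        "rmse_hi", "r", "r_lo", "r_hi", "n", "degenerate"])
    taylor = pd.DataFrame(taylor_rows, columns=[
        "participant", "scale", "interpolation", "paradigm", "sigma_ref",
        "sigma_pred", "r", "abs_r", "negative_r", "centered_rmse"])
    contrasts = _build_contrasts(metrics, config)

    out_dir = None
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        taylor.to_csv(out_dir / "taylor.csv", index=False)
        contrasts.to_csv(out_dir / "contrasts.csv")
        with (out_dir / "screened.jsonl").open("w") as fh:
            for rec in screened:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        write_stage_artifacts(participants, out_dir)
        ckpt_dir = out_dir / "checkpoints"
        for key, art in artifacts.items():
            if art.provenance.get("paradigm") == "cohort_base":
                name = "__".join(str(k) for k in key)
                md.save_checkpoint(art, ckpt_dir / f"{name}.ckpt")
    return ExperimentResult(metrics, taylor, contrasts, screened, participants,
                            artifacts, out_dir)


_base_cache_key = tuple


def _cohort_base(participants: dict[str, ParticipantData], leave_in: list[str],
                 scale: str, method: str, holdout_data: ParticipantData,
                 config: ExperimentConfig, holdout: str) -> md.ModelArtifact:
    # transfer requires one shared feature space: per-participant collinearity
    # filters retain slightly different columns, so the cohort model is fit on
    # the intersection (which must also exist for the holdout participant)
    tables = {p: _tables_for(participants[p], scale, method) for p in leave_in}
    shared = set(holdout_data.features.columns)
    for t in tables.values():
        shared &= set(t.columns) - {"label"}
    cols = [c for c in holdout_data.features.columns if c in shared] + ["label"]
    tables = {p: t[cols] for p, t in tables.items()}
    seed = derive_seed(config.seed, f"cohort:{holdout}:{scale}:{method}")
    if config.n_draws > 0:
        pooled = pd.concat([t for t in tables.values()], axis=0)
        params, feats, _ = md.tune_and_select(
            pooled.reset_index(drop=True), n_draws=config.n_draws,
            n_folds=config.n_folds, seed=seed, chronological=False)
    else:
        params, feats = dict(md.DEFAULT_PARAMS), None
    return md.fit_cohort_base(tables, params, feats, seed=seed,
                              provenance={"fold": holdout, "scale": scale,
                                          "interpolation": method})


def _evaluate(pred: np.ndarray, test: pd.DataFrame, config: ExperimentConfig,
              pid: str, scale: str, method: str, paradigm: str) -> ev.MetricReport:
    pair = ev.PairedPredictions(test["label"].to_numpy(), pred, pid, scale,
                                method, paradigm)
    seed = derive_seed(config.seed, f"boot:{pid}:{scale}:{method}:{paradigm}")
    return ev.evaluate_pair(pair, B=config.bootstrap_B, seed=seed)


def _metric_row(pid, scale, method, paradigm, rep: ev.MetricReport) -> dict:
    return {
        "participant": pid, "scale": scale, "interpolation": method,
        "paradigm": paradigm, "rmse": rep.rmse,
        "rmse_lo": rep.rmse_ci[0] if rep.rmse_ci else np.nan,
        "rmse_hi": rep.rmse_ci[1] if rep.rmse_ci else np.nan,
        "r": rep.r,
        "r_lo": rep.r_ci[0] if rep.r_ci else np.nan,
        "r_hi": rep.r_ci[1] if rep.r_ci else np.nan,
        "n": rep.n, "degenerate": rep.r_degenerate,
    }


def _report_from_row(row) -> ev.MetricReport:
    rm_ci = None if pd.isna(row["rmse_lo"]) else (row["rmse_lo"], row["rmse_hi"])
    r_ci = None if pd.isna(row["r_lo"]) else (row["r_lo"], row["r_hi"])
    return ev.MetricReport(row["rmse"], rm_ci, row["r"], r_ci, int(row["n"]),
                           bool(row["degenerate"]))


def _build_contrasts(metrics: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Paradigm contrasts (averaged view left to the caller): one row per
    participant x scale x interpolation, best paradigm per metric."""
    frames = []
    for metric in ("rmse", "r"):
        grid: dict[str, dict[str, ev.MetricReport | None]] = {}
        for (pid, scale, interp), grp in metrics.groupby(
                ["participant", "scale", "interpolation"], sort=True):
            cells = {p: None for p in config.paradigms}
            for _, row in grp.iterrows():
                cells[row["paradigm"]] = _report_from_row(row)
            grid[f"{pid}|{scale}|{interp}"] = cells
        if grid:
            tab = ev.contrast_table(grid, metric=metric)
            tab.insert(0, "metric", metric)
            frames.append(tab)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, axis=0)


def write_stage_artifacts(participants: dict[str, ParticipantData],
                          out_dir: Path) -> None:
    """Per-participant feature matrices, dropped-column reports and
    pseudo-label series as CSV."""
    fdir = out_dir / "features"
    ldir = out_dir / "pseudolabels"
    fdir.mkdir(parents=True, exist_ok=True)
    ldir.mkdir(parents=True, exist_ok=True)
    for pid, data in participants.items():
        data.features.to_csv(fdir / f"features_{pid}.csv",
                             date_format="%Y-%m-%d")
        by_method: dict[str, list[pd.DataFrame]] = {}
        for (scale, method), series in data.labels.items():
            by_method.setdefault(method, []).append(pd.DataFrame({
                "date": series.index, "scale_id": scale, "value": series.values}))
        for method, frames in by_method.items():
            pd.concat(frames, ignore_index=True).to_csv(
                ldir / f"pseudolabels_{pid}_{method}.csv", index=False,
                date_format="%Y-%m-%d")


def compute_features(sensors: pd.DataFrame, config: ExperimentConfig
                     ) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-participant (normalized feature matrix, dropped-column report)."""
    out = {}
    for pid in sorted(sensors["participant_id"].unique()):
        tagged = ft.segment_day_night(sensors[sensors["participant_id"] == pid],
                                      config.day_window)
        mat = ft.summarize_daily(tagged)
        split = md.split_sequential(mat, config.train_fraction, pid)
        fit_rows = mat.index if config.paper_faithful else split.train_dates
        filt = ft.CollinearityFilter(config.collinearity_threshold).fit(mat.loc[fit_rows])
        reduced = filt.transform(mat)
        scaler = ft.MinMaxColumnScaler().fit(reduced.loc[fit_rows])
        out[pid] = (scaler.transform(reduced), filt.report())
    return out


def make_fixture(name: str, seed: int, out_dir: str | Path | None = None) -> sy.Cohort:
    """Deterministic small cohort fixtures for tests and examples."""
    cohort = sy.generate_cohort(sy.preset_config(name, seed=seed))
    if out_dir is not None:
        sy.write_cohort(cohort, out_dir)
    return cohort
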