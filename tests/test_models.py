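"""Progression models: split arithmetic, variance screening, the randomized
search + precision-rounding screener, the three paradigms, and checkpoints."""

import numpy as np
import pandas as pd
import pytest

from alstrack import models as md


def table(n, f=5, seed=0, label=None, start="2023-01-01"):
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=n, freq="D")
    X = pd.DataFrame(rng.normal(size=(n, f)),
                     columns=[f"x{i}" for i in range(f)], index=idx)
    X["label"] = label if label is not None else rng.normal(size=n)
    return X


class TestSplit:
    @pytest.mark.parametrize("n,train,test", [
        (10, 8, 2),
        (487, 389, 98),
        (161, 128, 33),
        (196, 156, 40),
    ])
    def test_sequential_80_20_sizes(self, n, train, test):
        spec = md.split_sequential(table(n), 0.8)
        assert len(spec.train_dates) == train and len(spec.test_dates) == test

    def test_train_strictly_precedes_test(self):
        spec = md.split_sequential(table(50), 0.8)
        assert spec.train_dates.max() < spec.test_dates.min()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            md.split_sequential(table(4), 0.8)


class TestVarianceScreen:
    def test_constant_labels_zero_variance_static(self):
        d = md.screen_variance(np.full(20, 4.0))
        assert not d.model and d.reason == "zero variance" and d.static

    def test_varying_labels_pass(self):
        assert md.screen_variance(np.array([1.0, 2.0, 1.5, 0.5])).model

    def test_near_zero_variance_threshold(self):
        labels = np.full(100, 2.0)
        labels[0] = 2.01
        d = md.screen_variance(labels, epsilon=0.01)
        assert not d.model and "near-zero" in d.reason and not d.static


class TestScreener:
    def test_precision_rounding_semantics(self):
        imp = pd.Series({"a": 0.5, "b": 4e-7, "c": 0.0})
        subsets = dict(md.precision_rounding_subsets(imp))
        assert subsets[6] == ["a"]
        assert set(subsets[7]) == {"a", "b"}
        assert all("c" not in s for s in subsets.values())

    def test_cap_at_200_features(self, rng):
        imp = pd.Series(rng.uniform(0.001, 1.0, size=250),
                        index=[f"f{i}" for i in range(250)])
        subsets = md.precision_rounding_subsets(imp)
        assert all(len(s) <= 200 for _, s in subsets)
        assert len(subsets[-1][1]) == 200

    def test_subset_sizes_nondecreasing(self, rng):
        imp = pd.Series(rng.uniform(0, 0.2, size=30) ** 4,
                        index=[f"f{i}" for i in range(30)])
        sizes = [len(s) for _, s in md.precision_rounding_subsets(imp)]
        assert sizes == sorted(sizes)

    def test_tune_and_select_is_seeded(self):
        t = table(60, f=6, seed=1)
        a = md.tune_and_select(t, n_draws=3, seed=9)
        b = md.tune_and_select(t, n_draws=3, seed=9)
        assert a[0] == b[0] and a[1] == b[1]
        for p, vals in a[0].items():
            assert vals in md.SEARCH_SPACE[p]

    def test_all_zero_importance_keeps_all_features(self):
        t = table(30, f=4, seed=2, label=np.zeros(30))
        t["label"] = 1.0  # constant target -> no splits anywhere
        params, feats, trace = md.tune_and_select(t, n_draws=0, seed=0)
        assert set(feats) == {"x0", "x1", "x2", "x3"}


class TestIndividualBatch:
    def test_recovers_linear_relationship(self):
        n = 200
        rng = np.random.default_rng(0)
        t = table(n, f=3, seed=0)
        t["label"] = 2.0 * t["x0"]
        art = md.fit_individual_batch(t, dict(md.DEFAULT_PARAMS, n_estimators=256))
        pred = art.predict(t)
        assert np.sqrt(np.mean((pred - t["label"]) ** 2)) < 0.05

    def test_fixed_seed_identical_predictions(self):
        t = table(80, seed=3)
        a = md.fit_individual_batch(t, md.DEFAULT_PARAMS, seed=5).predict(t)
        b = md.fit_individual_batch(t, md.DEFAULT_PARAMS, seed=5).predict(t)
        assert np.array_equal(a, b)

    def test_refuses_screened_target(self):
        t = table(30, seed=1, label=np.full(30, 4.0))
        with pytest.raises(ValueError, match="zero variance"):
            md.fit_individual_batch(t, md.DEFAULT_PARAMS)


class TestCohortBase:
    def _tables(self, pids, seed=0, n=60):
        return {p: table(n, seed=seed + i) for i, p in enumerate(pids)}

    def test_requires_two_leave_in(self):
        with pytest.raises(ValueError, match="LOPO"):
            md.fit_cohort_base(self._tables(["P2"]), md.DEFAULT_PARAMS)

    def test_same_seed_identical_model(self):
        tabs = self._tables(["P2", "P3"])
        t = tabs["P2"]
        a = md.fit_cohort_base(tabs, md.DEFAULT_PARAMS, seed=4).predict(t)
        b = md.fit_cohort_base(tabs, md.DEFAULT_PARAMS, seed=4).predict(t)
        assert np.array_equal(a, b)

    def test_provenance_records_fold_and_row_hashes(self):
        tabs = self._tables(["P2", "P3"])
        art = md.fit_cohort_base(tabs, md.DEFAULT_PARAMS,
                                 provenance={"fold": "P1"})
        assert art.provenance["fold"] == "P1"
        assert art.provenance["leave_in"] == ["P2", "P3"]
        assert len(art.provenance["train_row_hashes"]) == 120

    def test_holdout_row_injection_detected_by_hash_audit(self):
        """The participant-qualified row hashes expose holdout contamination:
        a clean base shares no hash with the holdout, while a base fit with
        the holdout's table included does."""
        tabs = self._tables(["P2", "P3"])
        holdout = table(10, seed=99)
        holdout.attrs["participant_id"] = "P1"
        holdout_hashes = set(md._row_id_hashes(holdout))
        art = md.fit_cohort_base(tabs, md.DEFAULT_PARAMS)
        assert not set(art.provenance["train_row_hashes"]) & holdout_hashes
        art_bad = md.fit_cohort_base({**tabs, "P1": holdout}, md.DEFAULT_PARAMS)
        assert set(art_bad.provenance["train_row_hashes"]) & holdout_hashes


class TestFineTuning:
    def _base(self, seed=0):
        tabs = {p: table(80, seed=s) for p, s in [("P2", 1), ("P3", 2)]}
        return md.fit_cohort_base(tabs, md.DEFAULT_PARAMS, seed=seed)

    def test_zero_rounds_identity(self):
        base = self._base()
        holdout = table(40, seed=5)
        art = md.finetune_batch(base, holdout, n_rounds=0)
        assert np.array_equal(art.predict(holdout), base.predict(holdout))

    def test_constant_shift_reduces_error(self):
        """A holdout whose labels are offset from the cohort is corrected by
        batch fine-tuning."""
        rng = np.random.default_rng(0)
        def make(n, seed, shift):
            t = table(n, f=3, seed=seed)
            t["label"] = t["x0"] + shift
            return t
        base = md.fit_cohort_base({"P2": make(120, 1, 0.0), "P3": make(120, 2, 0.0)},
                                  md.DEFAULT_PARAMS)
        holdout_train = make(80, 5, 3.0)
        holdout_test = make(40, 6, 3.0)
        art = md.finetune_batch(base, holdout_train)
        err_base = np.sqrt(np.mean((base.predict(holdout_test) - holdout_test["label"]) ** 2))
        err_ft = np.sqrt(np.mean((art.predict(holdout_test) - holdout_test["label"]) ** 2))
        assert err_ft < err_base

    def test_provenance_parent_is_base_checkpoint(self):
        base = self._base()
        art = md.finetune_batch(base, table(40, seed=5), n_rounds=4)
        assert art.provenance["parent"] == md.checkpoint_id(base)

    def test_feature_mismatch_rejected(self):
        base = self._base()
        bad = table(20, f=3, seed=7)
        with pytest.raises(ValueError, match="[Ff]eature"):
            md.finetune_batch(base, bad, n_rounds=2)

    def test_incremental_prequential_causality(self):
        """Prediction at step t is invariant to permutations of later rows."""
        base = self._base()
        holdout = table(20, seed=8)
        _, preds = md.finetune_incremental(base, holdout, k_rounds=1, window_days=5)
        cut = 12
        shuffled = pd.concat([holdout.iloc[:cut], holdout.iloc[cut:].iloc[::-1]])
        # rows must stay date-ordered for the API; emulate permutation by
        # truncation instead: predictions on the prefix are unchanged
        _, preds_prefix = md.finetune_incremental(base, holdout.iloc[:cut],
                                                  k_rounds=1, window_days=5)
        assert np.array_equal(preds.iloc[:cut].to_numpy(), preds_prefix.to_numpy())

    def test_incremental_k0_identity(self):
        base = self._base()
        holdout = table(15, seed=9)
        art, preds = md.finetune_incremental(base, holdout, k_rounds=0)
        assert np.array_equal(preds.to_numpy(), base.predict(holdout))
        assert np.array_equal(art.predict(holdout), base.predict(holdout))

    def test_incremental_requires_date_order(self):
        base = self._base()
        holdout = table(15, seed=9).iloc[::-1]
        with pytest.raises(ValueError, match="date order"):
            md.finetune_incremental(base, holdout)

    def test_incremental_adapts_to_shifted_stream(self):
        """On a level-shifted holdout, prequential squared error shrinks from
        the first quartile of the stream to the last in most seeds."""
        wins = 0
        for seed in range(10):
            def make(n, s, shift):
                t = table(n, f=3, seed=s)
                t["label"] = t["x0"] + shift
                return t
            base = md.fit_cohort_base({"P2": make(80, seed + 100, 0.0),
                                       "P3": make(80, seed + 200, 0.0)},
                                      md.DEFAULT_PARAMS, seed=seed)
            stream = make(60, seed, 2.0)
            _, preds = md.finetune_incremental(base, stream, k_rounds=1,
                                               window_days=14)
            se = (preds.to_numpy() - stream["label"].to_numpy()) ** 2
            q = len(se) // 4
            wins += se[-q:].mean() <= se[:q].mean()
        assert wins >= 8


class TestCheckpoints:
    def _artifact(self):
        t = table(50, seed=0)
        return md.fit_individual_batch(t, md.DEFAULT_PARAMS, seed=1), t

    def test_roundtrip_identical_predictions(self, tmp_path):
        art, t = self._artifact()
        path = md.save_checkpoint(art, tmp_path / "m.ckpt")
        loaded = md.load_checkpoint(path)
        assert np.array_equal(loaded.predict(t), art.predict(t))

    def test_corrupt_file_reports_checksum(self, tmp_path):
        art, _ = self._artifact()
        path = md.save_checkpoint(art, tmp_path / "m.ckpt")
        blob = bytearray(path.read_bytes())
        blob[10] ^= 0xFF
        path.write_bytes(bytes(blob))
        with pytest.raises(ValueError, match="sha256"):
            md.load_checkpoint(path)

    def test_sidecar_contains_provenance(self, tmp_path):
        art, _ = self._artifact()
        path = md.save_checkpoint(art, tmp_path / "m.ckpt")
        import json
        sidecar = json.loads(path.with_suffix(".ckpt.json").read_text())
        assert sidecar["provenance"]["paradigm"] == "individual_batch"
        assert sidecar["feature_names"] == art.feature_names

    def test_schema_mismatch_rejected_on_predict(self, tmp_path):
        art, t = self._artifact()
        loaded = md.load_checkpoint(md.save_checkpoint(art, tmp_path / "m.ckpt"))
        bad = t.rename(columns={"x0": "z0"})
        with pytest.raises(ValueError, match="[Ff]eature"):
            loaded.model.predict(bad[[c for c in bad.columns if c != "label"]])
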