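"""Synthetic cohort generator: determinism, trajectory shapes, assessment
sampling, sensor coupling, and the homogeneity/heterogeneity structure."""

import numpy as np
import pandas as pd
import pytest

from alstrack import synthetic as sy


def small_config(**kw):
    defaults = dict(n_participants=3, enrollment_days=(200, 200, 200),
                    channels={"respiration": sy.ChannelCoupling("respiratory", 18.0, -1.0, 0.5, 48)},
                    seed=0)
    defaults.update(kw)
    return sy.CohortConfig(**defaults)


class TestLatentTrajectories:
    def test_zero_rate_gives_constant_trajectory(self):
        cfg = small_config(rate_range=(0.0, 0.0), jitter=0.0, offset_sd=0.0)
        lat = sy.simulate_latent_trajectories(cfg)
        for s in sy.SUBSCALES:
            v = lat[("P1", s)].values
            assert np.allclose(v, v[0])

    def test_seeded_determinism(self):
        cfg = small_config(seed=42)
        a = sy.simulate_latent_trajectories(cfg)
        b = sy.simulate_latent_trajectories(small_config(seed=42))
        for key in a:
            assert np.array_equal(a[key].values, b[key].values)

    def test_plateau_drop_step_exceeds_10x_median_daily_change(self):
        cfg = small_config(profiles={"*": "plateau-drop"}, drop_days=(100,),
                          jitter=0.0)
        lat = sy.simulate_latent_trajectories(cfg)
        v = lat[("P1", "walking")].values
        step = abs(v[101] - v[99])
        daily = np.abs(np.diff(v))
        daily_excl = np.delete(daily, [99, 100])
        assert step > 10 * max(np.median(daily_excl), 1e-12)

    def test_values_stay_in_subscale_domain(self):
        lat = sy.simulate_latent_trajectories(small_config(seed=3))
        for s in sy.SUBSCALES:
            for pid in ("P1", "P2", "P3"):
                v = lat[(pid, s)].values
                assert v.min() >= 0.0 and v.max() <= 4.0

    def test_monotone_nonincreasing_up_to_jitter(self):
        cfg = small_config(seed=9, jitter=0.02)
        lat = sy.simulate_latent_trajectories(cfg)
        for s in sy.SUBSCALES:
            v = lat[("P2", s)].values
            assert np.diff(v).max() <= 2 * cfg.jitter + 1e-12

    def test_too_short_enrollment_rejected(self):
        cfg = small_config(enrollment_days=(40, 200, 200))
        with pytest.raises(ValueError, match="too short for two assessments"):
            sy.simulate_latent_trajectories(cfg)

    def test_homogeneous_rates_shared_heterogeneous_rates_spread(self):
        """The homogeneity knob is real: between-participant spread of fitted
        decline rates is smaller under the homogeneous profile."""
        def rate_spread(profile, seed):
            cfg = small_config(profiles={"*": profile}, seed=seed, jitter=0.0)
            lat = sy.simulate_latent_trajectories(cfg)
            spreads = []
            for s in sy.SUBSCALES:
                rates = []
                for pid in ("P1", "P2", "P3"):
                    v = lat[(pid, s)].values[:120]  # pre-floor window
                    rates.append(np.polyfit(np.arange(len(v)), v, 1)[0])
                spreads.append(np.var(rates))
            return np.mean(spreads)

        hom = np.mean([rate_spread("homogeneous", s) for s in range(10)])
        het = np.mean([rate_spread("heterogeneous", s) for s in range(10)])
        assert hom < het


class TestAssessments:
    def _latents_constant(self, cfg, level):
        return {(pid, s): sy.LatentTrajectory(pid, s, np.full(cfg.enrollment_days[i], level))
                for i, pid in enumerate(sy.participant_ids(cfg))
                for s in sy.SCALES}

    def test_constant_4_gives_scores_4_composite_48(self):
        cfg = small_config()
        out = sy.emit_assessments(self._latents_constant(cfg, 4.0), cfg)
        df = out["P1"]
        assert (df[sy.SUBSCALES].to_numpy() == 4).all()
        assert (df["composite"] == 48).all()

    def test_rounding_half_up(self):
        cfg = small_config()
        a = sy.emit_assessments(self._latents_constant(cfg, 2.4), cfg)
        b = sy.emit_assessments(self._latents_constant(cfg, 2.5), cfg)
        assert (a["P1"][sy.SUBSCALES].to_numpy() == 2).all()
        assert (b["P1"][sy.SUBSCALES].to_numpy() == 3).all()

    def test_219_day_enrollment_30_day_cadence_gives_8_assessments(self):
        cfg = small_config(n_participants=1, enrollment_days=(219,))
        lat = sy.simulate_latent_trajectories(cfg)
        out = sy.emit_assessments(lat, cfg)
        assert len(out["P1"]) == 8  # day 0 inclusive

    def test_composite_is_subscale_sum(self):
        cfg = small_config(seed=17)
        out = sy.emit_assessments(sy.simulate_latent_trajectories(cfg), cfg)
        for df in out.values():
            assert (df["composite"] == df[sy.SUBSCALES].sum(axis=1)).all()


class TestSensorStreams:
    def test_zero_loading_channel_is_uncoupled(self):
        cfg = small_config(
            channels={"pulse": sy.ChannelCoupling("walking", 80.0, 0.0, 1.0, 48)},
            dropout=0.0, seed=2)
        lat = sy.simulate_latent_trajectories(cfg)
        streams = sy.emit_sensor_streams(lat, cfg)
        s = streams[streams.participant_id == "P1"]
        daily = s.groupby(s["timestamp"].dt.normalize())["value"].mean()
        latent = lat[("P1", "walking")].values[: len(daily)]
        r = np.corrcoef(daily.to_numpy(), latent)[0, 1]
        assert abs(r) < 0.2

    def test_noiseless_unit_loading_daily_mean_is_exact(self):
        cfg = small_config(
            channels={"resp": sy.ChannelCoupling("speech", 10.0, 1.0, 0.0, 48)},
            dropout=0.0, seed=5)
        lat = sy.simulate_latent_trajectories(cfg)
        streams = sy.emit_sensor_streams(lat, cfg)
        s = streams[streams.participant_id == "P2"]
        daily = s.groupby(s["timestamp"].dt.normalize())["value"].mean()
        expected = 10.0 + lat[("P2", "speech")].values
        assert np.allclose(daily.to_numpy(), expected, atol=1e-9)

    def test_same_seed_bit_identical_streams(self):
        cfg = small_config(seed=7)
        a = sy.emit_sensor_streams(sy.simulate_latent_trajectories(cfg), cfg)
        b = sy.emit_sensor_streams(sy.simulate_latent_trajectories(cfg), cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_frequency_rejected(self):
        cfg = small_config(
            channels={"resp": sy.ChannelCoupling("speech", 10.0, 1.0, 0.5, -5)})
        with pytest.raises(ValueError, match="frequency"):
            cfg.validate()

    def test_ols_recovers_coupling_loading(self):
        """With known noise, regressing the daily channel mean on the latent
        level recovers the configured loading within 3 standard errors."""
        loading, noise = -1.5, 0.4
        cfg = small_config(
            n_participants=1, enrollment_days=(250,),
            channels={"resp": sy.ChannelCoupling("dressing", 20.0, loading, noise, 24)},
            dropout=0.0, seed=11)
        lat = sy.simulate_latent_trajectories(cfg)
        streams = sy.emit_sensor_streams(lat, cfg)
        daily = streams.groupby(streams["timestamp"].dt.normalize())["value"].mean()
        x = lat[("P1", "dressing")].values
        A = np.vstack([x, np.ones_like(x)]).T
        coef, res, *_ = np.linalg.lstsq(A, daily.to_numpy(), rcond=None)
        resid = daily.to_numpy() - A @ coef
        s2 = resid @ resid / (len(x) - 2)
        se = np.sqrt(s2 * np.linalg.inv(A.T @ A)[0, 0])
        assert abs(coef[0] - loading) < 3 * se


class TestCohortBundle:
    def test_default_cohort_shape(self):
        cfg = sy.preset_config("tiny", seed=0)
        cohort = sy.generate_cohort(cfg)
        assert len(cohort.assessments) == 2
        scales = {s for (_, s) in cohort.latents}
        assert scales == set(sy.SCALES)

    def test_single_participant_bundle_is_valid(self):
        cfg = small_config(n_participants=1, enrollment_days=(200,))
        cohort = sy.generate_cohort(cfg)
        assert cohort.participant_ids == ["P1"]

    def test_assessment_score_variances_within_reported_magnitude(self):
        """Integer assessment-score variances stay within the 0-2.5 band of
        observed ALSFRS-R case-series variances."""
        for seed in range(5):
            cohort = sy.generate_cohort(sy.preset_config("homogeneous", seed=seed))
            for df in cohort.assessments.values():
                v = df[sy.SUBSCALES].var(ddof=1)
                assert (v >= 0).all() and (v <= 2.5).all()

    def test_write_cohort_emits_sidecar_with_seed(self, tmp_path):
        cohort = sy.generate_cohort(sy.preset_config("tiny", seed=3))
        out = sy.write_cohort(cohort, tmp_path / "fix")
        assert (out / "sensors.csv").exists()
        assert (out / "assessments.csv").exists()
        assert (out / "latent.csv").exists()
        import json
        sidecar = json.loads((out / "cohort.json").read_text())
        assert sidecar["seed"] == 3 and "config_sha256" in sidecar

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="tiny"):
            sy.preset_config("nope")
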