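"""Seeded synthetic ALS cohort generator.

Produces the three data products the downstream pipeline consumes:

* latent daily functional trajectories per participant and ALSFRS-R scale
  (ground truth, on the 0-4 subscale domain);
* sparse integer ALSFRS-R assessment series sampled from the latent curves on
  a monthly cadence (every third assessment flagged as a clinic visit);
* high-frequency contactless sensor streams (bed-sensor respiration, pulse and
  restlessness plus per-room motion counts) whose daily mean is linearly
  coupled to a latent trajectory.

The generator emulates the structure of a small in-home monitoring case
series: a handful of participants, 150-600 days of coverage, monotone
non-increasing functional decline with either shared (homogeneous) or
participant-specific (heterogeneous) rates, or stability punctuated by sudden
drops (plateau-drop), and missing sensor days.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

SUBSCALES = [
    "speech", "salivation", "swallowing",
    "handwriting", "cutting", "dressing",
    "turning", "walking", "stairs",
    "dyspnea", "orthopnea", "respiratory",
]
COMPOSITE = "composite"
SCALES = SUBSCALES + [COMPOSITE]

START_DATE = pd.Timestamp("2023-01-01")

_DOMAIN_OF = {
    "speech": "bulbar", "salivation": "bulbar", "swallowing": "bulbar",
    "handwriting": "fine_motor", "cutting": "fine_motor", "dressing": "fine_motor",
    "turning": "gross_motor", "walking": "gross_motor", "stairs": "gross_motor",
    "dyspnea": "respiratory", "orthopnea": "respiratory", "respiratory": "respiratory",
}


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from one master seed."""
    return zlib.crc32(f"{master}:{label}".encode()) % (2 ** 31)


@dataclass(frozen=True)
class ChannelCoupling:
    """How one sensor channel loads on a latent trajectory.

    Daily channel mean = baseline + loading * latent_level + N(0, noise_sd).
    ``scale`` may be any subscale name or "composite" (composite levels are
    divided by 12 so loadings stay on the subscale scale).
    """

    scale: str
    baseline: float
    loading: float
    noise_sd: float = 0.5
    samples_per_day: int = 1440
    day_amplitude: float = 1.0


def default_channels() -> dict[str, ChannelCoupling]:
    return {
        "respiration": ChannelCoupling("respiratory", 18.0, -1.0, 0.5, 1440, 1.0),
        "pulse": ChannelCoupling("dyspnea", 80.0, -3.0, 1.0, 1440, 2.0),
        "restlessness": ChannelCoupling("turning", 28.0, -2.0, 1.0, 1440, 3.0),
        "motion_bedroom": ChannelCoupling("walking", 4.0, 1.5, 1.0, 24, 2.0),
        "motion_kitchen": ChannelCoupling("composite", 2.0, 2.0, 1.0, 24, 1.5),
        "motion_living": ChannelCoupling("dressing", 3.0, 1.2, 1.0, 24, 1.5),
    }


@dataclass
class CohortConfig:
    n_participants: int = 3
    enrollment_days: tuple[int, ...] | None = None  # None -> drawn U[150, 600]
    assessment_cadence: int = 30
    clinic_every: int = 3
    profiles: dict[str, str] | None = None  # scale -> homogeneous|heterogeneous|plateau-drop
    channels: dict[str, ChannelCoupling] = field(default_factory=default_channels)
    start_range: tuple[float, float] = (2.5, 4.0)
    rate_range: tuple[float, float] = (0.004, 0.015)
    hetero_multipliers: tuple[float, ...] = (1 / 3, 1.0, 3.0)
    offset_sd: float = 0.15
    jitter: float = 0.02
    dropout: float = 0.05
    drop_days: tuple[int, ...] | None = None  # fixed drop days for plateau-drop scales
    day_window: tuple[int, int] = (6, 22)
    seed: int = 0

    def resolved_profiles(self) -> dict[str, str]:
        base = {s: "homogeneous" for s in SUBSCALES}
        # respiratory-domain and speech decline is patient-specific by default
        for s in ("speech", "dyspnea", "orthopnea", "respiratory"):
            base[s] = "heterogeneous"
        if self.profiles:
            if set(self.profiles) == {"*"}:
                base = {s: self.profiles["*"] for s in SUBSCALES}
            else:
                base.update(self.profiles)
        return base

    def resolved_enrollment(self) -> list[int]:
        if self.enrollment_days is not None:
            days = list(self.enrollment_days)
            if len(days) != self.n_participants:
                raise ValueError("enrollment_days length must equal n_participants")
        else:
            rng = np.random.default_rng(derive_seed(self.seed, "enrollment"))
            days = [int(rng.integers(150, 601)) for _ in range(self.n_participants)]
        return days

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        for coup in self.channels.values():
            if coup.samples_per_day <= 0:
                raise ValueError("sampling frequency must be positive")
            if not np.isfinite(coup.loading):
                raise ValueError("all loadings must be finite")
            if coup.scale not in SCALES:
                raise ValueError(f"unknown coupled scale {coup.scale!r}")
        for days in self.resolved_enrollment():
            if days < 2 * self.assessment_cadence:
                raise ValueError("too short for two assessments")


@dataclass
class LatentTrajectory:
    participant_id: str
    scale_id: str
    values: np.ndarray  # one level per day, subscale domain [0, 4]


def participant_ids(config: CohortConfig) -> list[str]:
    return [f"P{i + 1}" for i in range(config.n_participants)]


# ---------------------------------------------------------------------------
# latent trajectories
# ---------------------------------------------------------------------------

def simulate_latent_trajectories(config: CohortConfig) -> dict[tuple[str, str], LatentTrajectory]:
    """One latent daily trajectory per participant x scale (incl. composite).

    Profiles:
      homogeneous    shared per-scale decline rate; participants differ only by
                     a small intercept offset.
      heterogeneous  per-participant rate = scale base rate x a fixed ladder of
                     multipliers (participant-specific decline speeds).
      plateau-drop   constant level with a few sudden step decreases.
    """
    config.validate()
    profiles = config.resolved_profiles()
    enrollment = config.resolved_enrollment()
    pids = participant_ids(config)
    out: dict[tuple[str, str], LatentTrajectory] = {}

    for scale in SUBSCALES:
        srng = np.random.default_rng(derive_seed(config.seed, f"latent:{scale}"))
        start = srng.uniform(*config.start_range)
        base_rate = srng.uniform(*config.rate_range)
        profile = profiles[scale]
        for p_idx, pid in enumerate(pids):
            prng = np.random.default_rng(derive_seed(config.seed, f"latent:{scale}:{pid}"))
            days = enrollment[p_idx]
            t = np.arange(days, dtype=float)
            offset = prng.normal(0.0, config.offset_sd)
            # steep rates are capped so the trajectory reaches its floor no
            # earlier than the end of enrollment (keeps late scores informative)
            cap = max(1e-6, (start + offset - 0.2) / max(days - 1, 1))
            if profile == "homogeneous":
                base = start + offset - min(base_rate, cap) * t
            elif profile == "heterogeneous":
                mult = config.hetero_multipliers[p_idx % len(config.hetero_multipliers)]
                base = start + offset - min(base_rate * mult, cap) * t
            elif profile == "plateau-drop":
                if config.drop_days is not None:
                    drops = [d for d in config.drop_days if 0 < d < days]
                else:
                    n_drops = int(prng.integers(2, 5))
                    drops = sorted(prng.integers(20, max(21, days - 20), size=n_drops).tolist())
                base = np.full(days, start + offset)
                for d in drops:
                    base[d:] -= prng.uniform(0.5, 1.2)
            else:
                raise ValueError(f"unknown profile {profile!r}")
            noise = prng.uniform(-config.jitter, config.jitter, size=days)
            values = np.clip(base + noise, 0.0, 4.0)
            out[(pid, scale)] = LatentTrajectory(pid, scale, values)

    for p_idx, pid in enumerate(pids):
        comp = np.sum([out[(pid, s)].values for s in SUBSCALES], axis=0)
        out[(pid, COMPOSITE)] = LatentTrajectory(pid, COMPOSITE, comp)
    return out


# ---------------------------------------------------------------------------
# assessments
# ---------------------------------------------------------------------------

def emit_assessments(
    latents: dict[tuple[str, str], LatentTrajectory], config: CohortConfig
) -> dict[str, pd.DataFrame]:
    """Sparse integer ALSFRS-R series: latent value at each assessment day,
    rounded half-up and clipped to [0, 4]; composite recomputed as the sum.

    Day 0 (enrollment) is always assessed; every ``clinic_every``-th visit is
    flagged as a clinic (quarterly) assessment, the rest as telephone.
    """
    config.validate()
    out: dict[str, pd.DataFrame] = {}
    for p_idx, pid in enumerate(participant_ids(config)):
        days = len(latents[(pid, SUBSCALES[0])].values)
        assess_days = np.arange(0, days, config.assessment_cadence)
        rows = {"date": [START_DATE + pd.Timedelta(days=int(d)) for d in assess_days]}
        rows["clinic"] = [(i % config.clinic_every) == 0 and i > 0 for i in range(len(assess_days))]
        for scale in SUBSCALES:
            lv = latents[(pid, scale)].values[assess_days]
            rows[scale] = np.clip(np.floor(lv + 0.5), 0, 4).astype(int)
        df = pd.DataFrame(rows)
        df[COMPOSITE] = df[SUBSCALES].sum(axis=1)
        df.insert(0, "participant_id", pid)
        out[pid] = df
    return out


# ---------------------------------------------------------------------------
# sensor streams
# ---------------------------------------------------------------------------

def emit_sensor_streams(
    latents: dict[tuple[str, str], LatentTrajectory], config: CohortConfig
) -> pd.DataFrame:
    """Long-format sensor samples (participant_id, channel_id, timestamp, value).

    For each day, the channel's sample mean equals
    ``baseline + loading * latent + N(0, noise_sd)`` exactly: day/night
    amplitude modulation and within-day noise are mean-centred per day so the
    daily mean carries the coupling signal undistorted.  A seeded dropout mask
    removes whole days across all channels, emulating missing sensor coverage.
    """
    config.validate()
    frames = []
    day_start, day_end = config.day_window
    for p_idx, pid in enumerate(participant_ids(config)):
        days = len(latents[(pid, SUBSCALES[0])].values)
        drng = np.random.default_rng(derive_seed(config.seed, f"dropout:{pid}"))
        dropped = set()
        if config.dropout > 0:
            n_drop = int(round(config.dropout * days))
            dropped = set(drng.choice(days, size=n_drop, replace=False).tolist())
        kept_days = np.array([d for d in range(days) if d not in dropped], dtype=int)
        for channel, coup in config.channels.items():
            crng = np.random.default_rng(derive_seed(config.seed, f"sensor:{pid}:{channel}"))
            latent = latents[(pid, coup.scale)].values
            level = latent / 12.0 if coup.scale == COMPOSITE else latent
            daily_mean = coup.baseline + coup.loading * level + crng.normal(0.0, coup.noise_sd, days)

            m = coup.samples_per_day
            frac = (np.arange(m) + 0.5) / m  # fraction of day
            hours = frac * 24.0
            is_day = (hours >= day_start) & (hours < day_end)
            n_day, n_night = int(is_day.sum()), int((~is_day).sum())
            mod = np.where(is_day, coup.day_amplitude, 0.0)
            if n_night > 0:
                mod = mod - np.where(is_day, 0.0, coup.day_amplitude * n_day / n_night)
            mod = mod - mod.mean()  # exact zero daily mean

            intra = crng.normal(0.0, coup.noise_sd, size=(days, m))
            intra -= intra.mean(axis=1, keepdims=True)
            values = daily_mean[:, None] + mod[None, :] + intra
            values = values[kept_days]

            day_offsets = kept_days[:, None] * 86400.0 + (frac * 86400.0)[None, :]
            ts = START_DATE + pd.to_timedelta(day_offsets.ravel(), unit="s")
            frames.append(pd.DataFrame({
                "participant_id": pid,
                "channel_id": channel,
                "timestamp": ts,
                "value": values.ravel(),
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: CohortConfig
    latents: dict[tuple[str, str], LatentTrajectory]
    assessments: dict[str, pd.DataFrame]
    sensors: pd.DataFrame

    @property
    def participant_ids(self) -> list[str]:
        return participant_ids(self.config)


def generate_cohort(config: CohortConfig) -> Cohort:
    latents = simulate_latent_trajectories(config)
    assessments = emit_assessments(latents, config)
    sensors = emit_sensor_streams(latents, config)
    return Cohort(config, latents, assessments, sensors)


def _config_digest(config: CohortConfig) -> str:
    def _enc(o):
        if isinstance(o, ChannelCoupling):
            return asdict(o)
        raise TypeError(type(o))

    blob = json.dumps(asdict(config), default=_enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write sensors.csv / assessments.csv / latent.csv plus a sidecar JSON
    recording the seed and a config hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.sensors.to_csv(out / "sensors.csv", index=False)
    pd.concat(cohort.assessments.values(), ignore_index=True).to_csv(
        out / "assessments.csv", index=False)
    lat_rows = []
    for (pid, scale), traj in sorted(cohort.latents.items()):
        days = np.arange(len(traj.values))
        lat_rows.append(pd.DataFrame({
            "participant_id": pid,
            "scale_id": scale,
            "date": [START_DATE + pd.Timedelta(days=int(d)) for d in days],
            "value": traj.values,
        }))
    pd.concat(lat_rows, ignore_index=True).to_csv(out / "latent.csv", index=False)
    sidecar = {"seed": cohort.config.seed, "config_sha256": _config_digest(cohort.config)}
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return out


# ---------------------------------------------------------------------------
# named presets (desk-scale study conditions)
# ---------------------------------------------------------------------------

def _coarse_channels() -> dict[str, ChannelCoupling]:
    coarse = {}
    for name, c in default_channels().items():
        spd = 144 if c.samples_per_day >= 1440 else 24
        coarse[name] = ChannelCoupling(c.scale, c.baseline, c.loading, c.noise_sd,
                                       spd, c.day_amplitude)
    return coarse


PRESETS = ("tiny", "homogeneous", "heterogeneous", "plateau-drop")


def preset_config(name: str, seed: int = 0) -> CohortConfig:
    """Named deterministic study conditions used by tests and examples."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    if name == "tiny":
        return CohortConfig(n_participants=2, enrollment_days=(60, 60),
                            channels=_coarse_channels(), seed=seed)
    profile = {"*": name}
    return CohortConfig(n_participants=3, enrollment_days=(200, 200, 200),
                        profiles=profile, channels=_coarse_channels(), seed=seed)
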