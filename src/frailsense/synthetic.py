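"""Synthetic frailty-study cohort generator.

Emits everything the scoring pipeline consumes — UWB walk and task
trajectories, grip trials, questionnaire answers, clinical scale
totals — for participants with *known* ground-truth frailty profiles,
so every downstream stage is testable end to end without access to
study data.

What the generator emulates
---------------------------
* a short straight 15-ft-class walk with a sinusoidal lateral zigzag
  (unsteady gait wanders about the marked line) and isotropic Gaussian
  positioning noise per axis, default sd 0.20 m — the dynamic accuracy
  scale of UWB indoor positioning;
* two timed household tasks performed inside named kitchen/disposal
  zones, with profile-dependent dwell durations (low-activity
  participants take markedly longer);
* sex-stratified demographics, grip-strength and questionnaire
  distributions whose means/SDs follow a small mixed-age validation
  cohort (11 male / 10 female, mean age ~52);
* the sample-relative nature of the low-activity criterion: the flag
  is assigned to (by default) the slowest fifth of the cohort, matching
  a lowest-quintile operational definition, so the 80th-percentile
  scoring rule can recover it exactly at zero noise.

All randomness flows from one seed through a single generator, so a
given (config, seed) pair reproduces a byte-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import InvalidConfigError
from .models import (
    CRITERIA,
    FIFTEEN_FEET_M,
    FrailtyProfile,
    GripTrial,
    Participant,
    Trajectory,
    ZoneMap,
)
from . import champs
from .scoring import grip_cutoff

FRAILTY_CATEGORIES = ("robust", "pre_frail", "frail")

# Sex-stratified demographic distributions: mean, sd, (lo, hi) clip.
AGE_DIST = {"male": (43.45, 25.41, (21.0, 90.0)), "female": (61.10, 25.68, (21.0, 90.0))}
HEIGHT_DIST = {"male": (176.18, 9.59, (150.0, 200.0)), "female": (164.76, 8.78, (150.0, 200.0))}
WEIGHT_DIST = {"male": (79.21, 16.40, (48.0, 135.0)), "female": (77.21, 23.67, (48.0, 135.0))}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults reproduce the reference cohort conditions: n = 21 with a
    7/11/3 robust / pre-frail / frail mix, slightly male-leaning sex
    ratio, 10 Hz UWB sampling, 0.20 m positional noise, 0.15 m zigzag
    amplitude with a 2 m period. ``response_noise`` is the probability
    that a sensor-channel answer or task performance contradicts the
    ground-truth profile (0 = faithful sensors).
    """

    n_participants: int = 21
    frailty_mix: dict[str, float] = field(
        default_factory=lambda: {"robust": 7 / 21, "pre_frail": 11 / 21, "frail": 3 / 21}
    )
    seed: int = 0
    male_fraction: float = 11 / 21

    sampling_rate_hz: float = 10.0
    position_noise_sd_m: float = 0.20
    zigzag_amplitude_m: float = 0.15
    zigzag_period_m: float = 2.0
    walk_distance_m: float = 6.0
    walk_speed_normal_ms: float = 1.2
    walk_speed_slow_ms: float = 0.55
    walk_speed_jitter_ms: float = 0.05

    # Uniform (lo, hi) total task-duration ranges, seconds. The wide
    # gap keeps the clusters separable by a cohort percentile rule.
    task_duration_normal_s: tuple[float, float] = (40.0, 80.0)
    task_duration_low_activity_s: tuple[float, float] = (150.0, 220.0)
    task_zones: tuple[str, str] = ("kitchen", "disposal")

    grip_mean_sd_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (38.87, 8.91), "female": (27.04, 6.73)}
    )

    low_activity_quota_q: float = 0.20
    response_noise: float = 0.0
    clinical_noise_sd: float = 1.0
    n_missing_grip_standard: int = 0
    base_epoch_s: float = 1.7e9

    def validate(self) -> None:
        if self.n_participants < 2:
            raise InvalidConfigError("need n_participants >= 2")
        if set(self.frailty_mix) - set(FRAILTY_CATEGORIES):
            raise InvalidConfigError(f"frailty_mix keys must be {FRAILTY_CATEGORIES}")
        if abs(sum(self.frailty_mix.values()) - 1.0) > 1e-6:
            raise InvalidConfigError("frailty_mix proportions must sum to 1")
        if min(self.frailty_mix.values()) < 0:
            raise InvalidConfigError("frailty_mix proportions must be >= 0")
        if self.sampling_rate_hz <= 0:
            raise InvalidConfigError("sampling_rate_hz must be positive")
        if self.position_noise_sd_m < 0 or self.zigzag_amplitude_m < 0:
            raise InvalidConfigError("noise/zigzag amplitudes must be >= 0")
        if min(self.walk_speed_normal_ms, self.walk_speed_slow_ms) <= 0:
            raise InvalidConfigError("walk speeds must be positive")
        if self.walk_distance_m < FIFTEEN_FEET_M:
            raise InvalidConfigError(
                f"walk distance must cover 15 ft ({FIFTEEN_FEET_M} m)"
            )
        if not 0 <= self.response_noise <= 1:
            raise InvalidConfigError("response_noise must lie in [0, 1]")
        if not 0 <= self.low_activity_quota_q <= 1:
            raise InvalidConfigError("low_activity_quota_q must lie in [0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


def default_zonemap() -> ZoneMap:
    """Floor plan used by task simulation: kitchen and garbage-disposal
    zones separated by a corridor (metres)."""
    return ZoneMap.from_dict(
        {
            "kitchen": {"x_min": 0.0, "x_max": 3.0, "y_min": 0.0, "y_max": 3.0},
            "disposal": {"x_min": 6.0, "x_max": 9.0, "y_min": 0.0, "y_max": 2.0},
            "bedroom": {"x_min": 0.0, "x_max": 3.0, "y_min": 6.0, "y_max": 9.0},
        }
    )


@dataclass(frozen=True)
class QuestionnaireBundle:
    """Already-transcribed questionnaire/dialogue answers.

    ``weight_loss_answer`` is the standard interview answer;
    ``weight_loss_answer_sensor`` the smart-speaker one. CES-D item
    codes feed the standard exhaustion rule, the days category the
    sensor rule. ``champs`` maps activity_id -> duration category 0-6.
    """

    weight_loss_answer: str
    weight_loss_answer_sensor: str
    cesd_item7: int
    cesd_item8: int
    exhaustion_days_category: str
    champs: dict[str, int]


def _largest_remainder_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    quotas = {k: n * mix.get(k, 0.0) for k in FRAILTY_CATEGORIES}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(
        FRAILTY_CATEGORIES, key=lambda k: (quotas[k] - counts[k]), reverse=True
    )
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _draw_clipped_normal(rng, mean, sd, lo, hi) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_cohort(config: SimulationConfig) -> list[tuple[Participant, FrailtyProfile]]:
    """Generate participants with ground-truth frailty profiles.

    Category counts follow ``frailty_mix`` by largest remainder;
    per-participant totals are 0 (robust), 1-2 (pre-frail) or 3-4
    (frail). The low-activity flag is allotted to a fixed cohort quota
    (default the lowest fifth, weighted toward higher totals) because
    the criterion is defined relative to the sample; the other criteria
    fill each participant's total at random.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    counts = _largest_remainder_counts(n, config.frailty_mix)

    categories = (
        ["robust"] * counts["robust"]
        + ["pre_frail"] * counts["pre_frail"]
        + ["frail"] * counts["frail"]
    )
    rng.shuffle(categories)
    totals = np.array(
        [
            0 if c == "robust" else int(rng.integers(1, 3)) if c == "pre_frail"
            else int(rng.integers(3, 5))
            for c in categories
        ]
    )

    # Low-activity quota: the flag marks the cohort's slowest fifth.
    # ceil(q*(n-1)) places the (1-q) interpolated percentile of any
    # well-separated duration clusters between the two clusters, so a
    # percentile-threshold scorer can recover the flags exactly.
    k = int(math.ceil(config.low_activity_quota_q * (n - 1) - 1e-9))
    candidates = np.flatnonzero(totals >= 1)
    k = min(k, len(candidates))
    low_activity = np.zeros(n, dtype=int)
    if k > 0:
        w = totals[candidates].astype(float)
        chosen = rng.choice(candidates, size=k, replace=False, p=w / w.sum())
        low_activity[chosen] = 1

    other = [c for c in CRITERIA if c != "low_activity"]
    profiles: list[FrailtyProfile] = []
    for i in range(n):
        need = int(totals[i]) - low_activity[i]
        flags = dict.fromkeys(CRITERIA, 0)
        flags["low_activity"] = int(low_activity[i])
        picked = rng.choice(len(other), size=need, replace=False)
        for j in picked:
            flags[other[j]] = 1
        profiles.append(FrailtyProfile(**flags))

    n_male = int(round(config.male_fraction * n))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)
    rng.shuffle(sexes)

    cohort: list[tuple[Participant, FrailtyProfile]] = []
    for i, (sex, profile) in enumerate(zip(sexes, profiles)):
        participant = Participant(
            id=f"P{i + 1:03d}",
            sex=sex,
            age=round(_draw_clipped_normal(rng, *AGE_DIST[sex][:2], *AGE_DIST[sex][2]), 1),
            height_cm=round(
                _draw_clipped_normal(rng, *HEIGHT_DIST[sex][:2], *HEIGHT_DIST[sex][2]), 1
            ),
            weight_kg=round(
                _draw_clipped_normal(rng, *WEIGHT_DIST[sex][:2], *WEIGHT_DIST[sex][2]), 1
            ),
            inpatient=bool(rng.random() < (7 / 10 if sex == "female" else 2 / 11)),
        )
        cohort.append((participant, profile))
    return cohort


def draw_walk_speed(profile: FrailtyProfile, config: SimulationConfig, rng) -> float:
    """Ground-truth gait speed (m/s) for a profile, with jitter."""
    base = config.walk_speed_slow_ms if profile.slowness else config.walk_speed_normal_ms
    speed = base + float(rng.uniform(-1, 1)) * config.walk_speed_jitter_ms
    if speed <= 0:
        raise InvalidConfigError("drawn walk speed is non-positive")
    return speed


def simulate_walk(
    participant: Participant,
    profile: FrailtyProfile,
    config: SimulationConfig,
    rng=None,
    speed: Optional[float] = None,
    t0: Optional[float] = None,
) -> Trajectory:
    """Simulate a straight marked walk observed by UWB positioning.

    The participant advances along x at constant ground-truth ``speed``
    while the lateral coordinate oscillates sinusoidally around the
    marked line (zigzag); isotropic Gaussian noise of sd
    ``position_noise_sd_m`` is added to every axis.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if speed is None:
        speed = draw_walk_speed(profile, config, rng)
    if speed <= 0:
        raise InvalidConfigError("walk speed must be positive")
    if t0 is None:
        t0 = config.base_epoch_s
    duration = config.walk_distance_m / speed
    dt = 1.0 / config.sampling_rate_hz
    n = int(math.floor(duration / dt)) + 1
    t_rel = np.arange(n) * dt
    x_true = speed * t_rel
    if config.zigzag_amplitude_m > 0:
        y_true = config.zigzag_amplitude_m * np.sin(
            2 * np.pi * x_true / config.zigzag_period_m
        )
    else:
        y_true = np.zeros(n)
    z_true = np.full(n, 1.0)
    sd = config.position_noise_sd_m
    noise = rng.normal(0.0, sd, size=(n, 3)) if sd > 0 else np.zeros((n, 3))
    return Trajectory(
        participant_id=participant.id,
        t=t0 + t_rel,
        x=x_true + noise[:, 0],
        y=y_true + noise[:, 1],
        z=z_true + noise[:, 2],
        label="walk_15ft",
    )


def draw_task_duration(profile: FrailtyProfile, config: SimulationConfig, rng) -> float:
    """Ground-truth total duration (s) of the two timed tasks."""
    slow_cluster = bool(profile.low_activity)
    if config.response_noise > 0 and rng.random() < config.response_noise:
        slow_cluster = not slow_cluster
    lo, hi = (
        config.task_duration_low_activity_s if slow_cluster
        else config.task_duration_normal_s
    )
    return float(rng.uniform(lo, hi))


def _grid_ceil(t: float, dt: float) -> float:
    return math.ceil(round(t / dt, 9)) * dt


def simulate_task_session(
    participant: Participant,
    profile: FrailtyProfile,
    zonemap: ZoneMap,
    config: SimulationConfig,
    rng=None,
    total_duration: Optional[float] = None,
    t0: Optional[float] = None,
) -> Trajectory:
    """Simulate the two timed household tasks as a zone-dwelling path.

    The participant starts in a corridor, walks into each task zone in
    turn, performs the task near the zone centre, and leaves. Zone
    boundary crossings are aligned to the sampling grid so that, at
    zero noise, zone-occupancy extraction recovers the intended dwell
    durations to within two sample intervals.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(zonemap) == 0:
        raise InvalidConfigError("zone map is empty")
    for name in config.task_zones:
        if name not in zonemap.zones:
            raise InvalidConfigError(f"zone map lacks required task zone {name!r}")
    if total_duration is None:
        total_duration = draw_task_duration(profile, config, rng)
    if t0 is None:
        t0 = config.base_epoch_s + 3600.0

    dt = 1.0 / config.sampling_rate_hz
    split = float(rng.uniform(0.55, 0.70))
    durations = (split * total_duration, (1 - split) * total_duration)

    corridor_y = max(z.y_max for n_, z in zonemap.zones.items() if n_ in config.task_zones) + 1.5
    waypoints: list[tuple[float, float, float]] = []  # (t, x, y)
    t = 0.0
    zone0 = zonemap[config.task_zones[0]]
    cx0 = 0.5 * (zone0.x_min + zone0.x_max)
    start = (cx0, corridor_y)
    if zone0.contains(np.array([start[0]]), np.array([start[1]]))[0]:
        raise InvalidConfigError("task zones cover the corridor; cannot start outside")
    waypoints.append((t, *start))
    pos = start
    for name, dwell in zip(config.task_zones, durations):
        zone = zonemap[name]
        cx, cy = zone.center
        entry = (cx, zone.y_max)  # boundary point approached from above
        # corridor transit to above the zone
        t = _grid_ceil(t + max(abs(pos[0] - cx) / 1.2, dt), dt)
        waypoints.append((t, cx, corridor_y))
        # descend: cross the boundary exactly on a grid time
        t = _grid_ceil(t + (corridor_y - zone.y_max) / 1.2, dt)
        waypoints.append((t, *entry))
        t_entry = t
        inner = min(1.0, dwell / 4)
        waypoints.append((t_entry + inner, cx, cy))
        waypoints.append((t_entry + dwell - inner, cx, cy))
        t = t_entry + dwell
        waypoints.append((t, *entry))  # back on the boundary at exit
        t = _grid_ceil(t + (corridor_y - zone.y_max) / 1.2 + dt, dt)
        waypoints.append((t, cx, corridor_y))
        pos = (cx, corridor_y)
    t_end = t + 1.0

    wt = np.array([w[0] for w in waypoints])
    wx = np.array([w[1] for w in waypoints])
    wy = np.array([w[2] for w in waypoints])
    n = int(math.floor(t_end / dt)) + 1
    t_rel = np.arange(n) * dt
    x = np.interp(t_rel, wt, wx)
    y = np.interp(t_rel, wt, wy)
    z = np.full(n, 1.0)
    sd = config.position_noise_sd_m
    noise = rng.normal(0.0, sd, size=(n, 3)) if sd > 0 else np.zeros((n, 3))
    return Trajectory(
        participant_id=participant.id,
        t=t0 + t_rel,
        x=x + noise[:, 0],
        y=y + noise[:, 1],
        z=z + noise[:, 2],
        label="pass_tasks",
    )


def _maybe_flip(flag: int, config: SimulationConfig, rng) -> int:
    if config.response_noise > 0 and rng.random() < config.response_noise:
        return 1 - flag
    return flag


def simulate_questionnaires(
    participant: Participant,
    profile: FrailtyProfile,
    config: SimulationConfig,
    rng=None,
    met_table: Optional[dict[str, float]] = None,
) -> QuestionnaireBundle:
    """Emit questionnaire/dialogue answers consistent with the profile.

    Standard-instrument answers are faithful to the profile; sensor
    (speaker) answers contradict it with probability
    ``response_noise``. CHAMPS categories are sampled and then nudged
    until the implied weekly kcal lands on the profile's side of the
    sex cutoff with a 25% safety margin.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if met_table is None:
        met_table = champs.default_met_table()

    wl = profile.weight_loss
    weight_loss_answer = "yes" if wl else "no"
    weight_loss_answer_sensor = "yes" if _maybe_flip(wl, config, rng) else "no"

    if profile.exhaustion:
        hi_item = int(rng.integers(0, 2))  # which of items 7/8 is elevated
        codes = [int(rng.integers(0, 2)), int(rng.integers(2, 4))]
        if hi_item == 0:
            codes.reverse()
        item7, item8 = codes
    else:
        item7, item8 = int(rng.integers(0, 2)), int(rng.integers(0, 2))
    days_flag = _maybe_flip(profile.exhaustion, config, rng)
    days_category = "3-7" if days_flag else "0-2"

    responses = {
        aid: (int(rng.integers(1, 4)) if rng.random() < 0.3 else 0)
        for aid in sorted(met_table)
    }
    cutoff = champs.LOW_ACTIVITY_KCAL_CUTOFF[participant.sex]
    kcal_per_cat = {
        aid: [
            champs.activity_kcal(h, met_table[aid], participant.weight_kg)
            for h in champs.DURATION_CATEGORY_HOURS
        ]
        for aid in responses
    }
    total = sum(kcal_per_cat[aid][cat] for aid, cat in responses.items())
    aids = sorted(responses)
    if profile.low_activity:
        while total >= 0.75 * cutoff:
            nonzero = [a for a in aids if responses[a] > 0]
            a = nonzero[int(rng.integers(len(nonzero)))]
            total -= kcal_per_cat[a][responses[a]] - kcal_per_cat[a][responses[a] - 1]
            responses[a] -= 1
    else:
        while total < 1.25 * cutoff:
            room = [a for a in aids if responses[a] < 6]
            a = room[int(rng.integers(len(room)))]
            total += kcal_per_cat[a][responses[a] + 1] - kcal_per_cat[a][responses[a]]
            responses[a] += 1

    return QuestionnaireBundle(
        weight_loss_answer=weight_loss_answer,
        weight_loss_answer_sensor=weight_loss_answer_sensor,
        cesd_item7=item7,
        cesd_item8=item8,
        exhaustion_days_category=days_category,
        champs=responses,
    )


def simulate_grip_trials(
    participant: Participant,
    profile: FrailtyProfile,
    config: SimulationConfig,
    rng=None,
    source: str = "standard",
) -> list[GripTrial]:
    """Six dynamometer trials (three per hand).

    The dominant-hand maximum is drawn from the sex-stratified strength
    distribution, then pulled to the correct side of the participant's
    sex/BMI weakness cutoff with a safety margin so the flag matches
    the profile.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean, sd = config.grip_mean_sd_by_sex[participant.sex]
    cutoff = grip_cutoff(participant.sex, participant.bmi)
    base = float(np.clip(rng.normal(mean, sd), 8.0, 70.0))
    if profile.weakness:
        dom_peak = min(base, cutoff * float(rng.uniform(0.60, 0.90)))
    else:
        dom_peak = max(base, cutoff + float(rng.uniform(3.0, 10.0)))
    nd_peak = dom_peak * float(rng.uniform(0.80, 0.95))
    trials: list[GripTrial] = []
    for hand, peak in (("dominant", dom_peak), ("nondominant", nd_peak)):
        factors = [1.0, float(rng.uniform(0.88, 0.98)), float(rng.uniform(0.85, 0.97))]
        for i, f in enumerate(factors, start=1):
            trials.append(
                GripTrial(
                    participant_id=participant.id,
                    hand=hand,
                    trial=i,
                    peak_kg=round(peak * f, 2),
                    source=source,
                )
            )
    return trials


def simulate_clinical_scales(
    profile: FrailtyProfile, config: SimulationConfig, rng=None
) -> tuple[int, int]:
    """Edmonton Frail Scale total (0-17) and Clinical Frailty Scale
    level (1-9), monotone in the profile's implied total plus integer
    noise, clamped to their valid ranges."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = profile.total
    sd = config.clinical_noise_sd
    efs = int(np.clip(round(2.8 * t + (rng.normal(0, sd) if sd > 0 else 0)), 0, 17))
    cfs = int(np.clip(round(1 + 1.2 * t + (rng.normal(0, 0.6 * sd) if sd > 0 else 0)), 1, 9))
    return efs, cfs
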