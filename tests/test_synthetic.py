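"""Synthetic cohort generator: determinism, structure, flag consistency."""

import numpy as np
import pytest

from frailsense import champs, scoring, synthetic
from frailsense.errors import InvalidConfigError
from frailsense.kinematics import (
    cumulative_distance,
    estimate_walk_time,
    fit_distance_time,
    zone_total_durations,
)
from frailsense.models import FIFTEEN_FEET_M, FrailtyProfile, ZoneMap
from frailsense.synthetic import (
    SimulationConfig,
    default_zonemap,
    draw_task_duration,
    generate_cohort,
    simulate_clinical_scales,
    simulate_grip_trials,
    simulate_questionnaires,
    simulate_task_session,
    simulate_walk,
)


class TestGenerateCohort:
    def test_reference_cohort_composition(self):
        cfg = SimulationConfig(n_participants=21, seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 21
        n_male = sum(p.sex == "male" for p, _ in cohort)
        assert n_male == 11
        totals = [pr.total for _, pr in cohort]
        assert sum(t == 0 for t in totals) == 7  # robust
        assert sum(1 <= t <= 2 for t in totals) == 11  # pre-frail
        assert sum(t >= 3 for t in totals) == 3  # frail

    def test_determinism_same_seed(self):
        cfg = SimulationConfig(n_participants=30, seed=9)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_participants=30, seed=1))
        b = generate_cohort(SimulationConfig(n_participants=30, seed=2))
        assert a != b

    def test_degenerate_all_robust_mix(self):
        cfg = SimulationConfig(
            n_participants=2,
            frailty_mix={"robust": 1.0, "pre_frail": 0.0, "frail": 0.0},
            seed=0,
        )
        cohort = generate_cohort(cfg)
        assert all(pr.total == 0 for _, pr in cohort)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_cohort(SimulationConfig(n_participants=1))

    def test_bad_mix_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(
                frailty_mix={"robust": 0.5, "pre_frail": 0.2, "frail": 0.2}
            ).validate()

    def test_demographics_respect_invariants(self):
        cohort = generate_cohort(SimulationConfig(n_participants=60, seed=4))
        for p, _ in cohort:
            assert p.age >= 21 and p.height_cm > 0 and p.weight_kg > 0
            assert p.sex in ("male", "female")

    def test_low_activity_quota_is_slowest_fifth(self):
        cfg = SimulationConfig(n_participants=50, seed=2)
        cohort = generate_cohort(cfg)
        assert sum(pr.low_activity for _, pr in cohort) == 10


class TestSimulateWalk:
    def test_noiseless_straight_line(self, participant, robust_profile):
        cfg = SimulationConfig(
            position_noise_sd_m=0.0, zigzag_amplitude_m=0.0,
            walk_speed_normal_ms=1.2, walk_speed_jitter_ms=0.0,
        )
        tr = simulate_walk(participant, robust_profile, cfg, speed=1.2)
        assert len(tr) == 51
        assert cumulative_distance(tr)[-1] == pytest.approx(6.0)
        assert np.allclose(tr.y, 0.0)

    def test_empirical_noise_sd(self, participant, robust_profile):
        cfg = SimulationConfig(position_noise_sd_m=0.2, zigzag_amplitude_m=0.0)
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(300):
            tr = simulate_walk(participant, robust_profile, cfg, rng=rng, speed=1.2)
            t_rel = tr.t - tr.t[0]
            errs.append(tr.x - 1.2 * t_rel)
            errs.append(tr.y)
        errs = np.concatenate(errs)
        assert len(errs) >= 10_000
        assert np.std(errs) == pytest.approx(0.2, rel=0.05)

    def test_slow_profile_meets_slowness_cutoff(self, participant):
        cfg = SimulationConfig(position_noise_sd_m=0.0, walk_speed_slow_ms=0.6,
                               walk_speed_jitter_ms=0.0, zigzag_amplitude_m=0.0)
        tr = simulate_walk(participant, FrailtyProfile(slowness=1), cfg, speed=0.6)
        est = estimate_walk_time(fit_distance_time(tr))
        assert est == pytest.approx(FIFTEEN_FEET_M / 0.6, abs=1e-6)
        assert est >= 7.0

    def test_nonpositive_speed_rejected(self, participant, robust_profile):
        with pytest.raises(InvalidConfigError):
            simulate_walk(participant, robust_profile, SimulationConfig(), speed=0.0)

    def test_short_walk_distance_rejected(self, participant, robust_profile):
        cfg = SimulationConfig(walk_distance_m=3.0)
        with pytest.raises(InvalidConfigError):
            simulate_walk(participant, robust_profile, cfg)


class TestSimulateTaskSession:
    def test_zero_noise_duration_round_trip(self, participant, robust_profile):
        cfg = SimulationConfig(position_noise_sd_m=0.0)
        zm = default_zonemap()
        rng = np.random.default_rng(5)
        tr = simulate_task_session(
            participant, robust_profile, zm, cfg, rng=rng, total_duration=60.0
        )
        totals = zone_total_durations(tr, zm, min_dwell=2.0)
        measured = totals["kitchen"] + totals["disposal"]
        assert measured == pytest.approx(60.0, abs=2 / cfg.sampling_rate_hz)

    def test_low_activity_durations_dominate(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(1)
        slow = [draw_task_duration(FrailtyProfile(low_activity=1), cfg, rng)
                for _ in range(500)]
        fast = [draw_task_duration(FrailtyProfile(), cfg, rng) for _ in range(500)]
        # strict stochastic dominance given the disjoint ranges
        assert min(slow) > max(fast)

    def test_missing_task_zone_rejected(self, participant, robust_profile):
        zm = ZoneMap.from_dict({"pantry": {"x_min": 0, "x_max": 1, "y_min": 0, "y_max": 1}})
        with pytest.raises(InvalidConfigError):
            simulate_task_session(participant, robust_profile, zm, SimulationConfig())

    def test_empty_zonemap_rejected(self, participant, robust_profile):
        with pytest.raises(InvalidConfigError):
            simulate_task_session(participant, robust_profile, ZoneMap(), SimulationConfig())


class TestSimulateQuestionnaires:
    def _bundle(self, participant, profile, seed=0):
        cfg = SimulationConfig(seed=seed)
        return simulate_questionnaires(
            participant, profile, cfg, rng=np.random.default_rng(seed)
        )

    def test_exhaustion_raises_cesd_items(self, participant):
        qa = self._bundle(participant, FrailtyProfile(exhaustion=1))
        assert max(qa.cesd_item7, qa.cesd_item8) >= 2
        assert qa.exhaustion_days_category == "3-7"

    def test_all_zero_profile_consistent(self, participant):
        qa = self._bundle(participant, FrailtyProfile())
        assert qa.weight_loss_answer == "no"
        assert max(qa.cesd_item7, qa.cesd_item8) <= 1
        assert qa.exhaustion_days_category == "0-2"
        kcal = champs.total_kcal(
            qa.champs, champs.default_met_table(), participant.weight_kg
        )
        assert kcal >= champs.LOW_ACTIVITY_KCAL_CUTOFF[participant.sex]

    def test_low_activity_profile_below_cutoff(self, participant):
        qa = self._bundle(participant, FrailtyProfile(low_activity=1), seed=3)
        kcal = champs.total_kcal(
            qa.champs, champs.default_met_table(), participant.weight_kg
        )
        assert kcal < champs.LOW_ACTIVITY_KCAL_CUTOFF[participant.sex]

    def test_weight_loss_answer_tracks_profile(self, participant):
        qa = self._bundle(participant, FrailtyProfile(weight_loss=1))
        assert qa.weight_loss_answer == "yes"
        assert qa.weight_loss_answer_sensor == "yes"


class TestSimulateGripTrials:
    def test_six_trials_three_per_hand(self, participant, robust_profile):
        trials = simulate_grip_trials(
            participant, robust_profile, SimulationConfig(),
            rng=np.random.default_rng(0),
        )
        assert len(trials) == 6
        assert sum(t.hand == "dominant" for t in trials) == 3

    @pytest.mark.parametrize(
        "sex,weight,height,weak", [("female", 62.0, 164.0, 1), ("male", 83.0, 175.0, 0)]
    )
    def test_dominant_max_respects_cutoff(self, sex, weight, height, weak):
        from frailsense.models import Participant

        p = Participant(id="P", sex=sex, age=70, height_cm=height, weight_kg=weight)
        cutoff = scoring.grip_cutoff(sex, p.bmi)
        for seed in range(10):
            trials = simulate_grip_trials(
                p, FrailtyProfile(weakness=weak), SimulationConfig(),
                rng=np.random.default_rng(seed),
            )
            dom_max = max(t.peak_kg for t in trials if t.hand == "dominant")
            assert (dom_max <= cutoff) == bool(weak)


class TestClinicalScales:
    def test_all_zero_profile_minimal_at_zero_noise(self):
        cfg = SimulationConfig(clinical_noise_sd=0.0)
        efs, cfs = simulate_clinical_scales(FrailtyProfile(), cfg)
        assert efs == 0 and cfs == 1

    def test_outputs_within_ranges(self):
        cfg = SimulationConfig(clinical_noise_sd=3.0)
        rng = np.random.default_rng(0)
        for total in range(6):
            flags = [1] * total + [0] * (5 - total)
            profile = FrailtyProfile(*flags)
            for _ in range(50):
                efs, cfs = simulate_clinical_scales(profile, cfg, rng=rng)
                assert 0 <= efs <= 17 and 1 <= cfs <= 9

    def test_rank_correlation_with_implied_total(self):
        cfg = SimulationConfig(n_participants=200, seed=8)
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(8)
        totals, efs_vals = [], []
        for _, profile in cohort:
            efs, _ = simulate_clinical_scales(profile, cfg, rng=rng)
            totals.append(profile.total)
            efs_vals.append(efs)
        from frailsense.agreement import spearman_rho

        assert spearman_rho(totals, efs_vals).rho > 0.5
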