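"""Study orchestration: simulate -> score -> validate.

``simulate_study`` renders a synthetic cohort into the tabular sensor
and questionnaire artifacts a real deployment would produce;
``score_study`` applies both the standard-instrument and the
sensor-based Fried criteria to those tables; ``validate_study``
computes the concurrent-validity layer (per-criterion kappa/rho, total
score agreement, and the cross-scale Spearman matrix). ``run_study``
chains the three and serializes every artifact, with the seed and a
config hash recorded so a run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import champs, io, scoring, synthetic
from .agreement import (
    AgreementReport,
    agreement_report,
    cohens_kappa_confusion,
    spearman_rho,
    stratified_agreement,
)
from .errors import DegenerateTableError, InvalidFitError, SchemaError
from .kinematics import (
    estimate_walk_time,
    fit_distance_time,
    zone_total_durations,
)
from .models import CRITERIA, FIFTEEN_FEET_M, CriterionFlags, Trajectory, ZoneMap
from .synthetic import SimulationConfig

__version__ = "0.1.0"


@dataclass
class StudyTables:
    """All tabular artifacts of one (simulated or loaded) study."""

    demographics: pd.DataFrame
    questionnaires: pd.DataFrame
    champs_responses: pd.DataFrame
    grip_trials: pd.DataFrame
    positions_walk: pd.DataFrame
    positions_tasks: pd.DataFrame
    clinical_scales: pd.DataFrame
    zonemap: ZoneMap
    profiles: Optional[pd.DataFrame] = None  # ground truth, simulation only
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> Path:
        out = io.ensure_dir(outdir)
        self.demographics.to_csv(out / "demographics.csv", index=False)
        self.questionnaires.to_csv(out / "questionnaires.csv", index=False)
        self.champs_responses.to_csv(out / "champs_responses.csv", index=False)
        self.grip_trials.to_csv(out / "grip_trials.csv", index=False)
        self.positions_walk.to_csv(out / "positions_walk.csv", index=False)
        self.positions_tasks.to_csv(out / "positions_tasks.csv", index=False)
        self.clinical_scales.to_csv(out / "clinical_scales.csv", index=False)
        io.write_zonemap(self.zonemap, out / "zonemap.yaml")
        if self.profiles is not None:
            self.profiles.to_csv(out / "profiles_ground_truth.csv", index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True, default=str)
        return out


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_study(
    config: SimulationConfig,
    zonemap: Optional[ZoneMap] = None,
    met_table: Optional[dict[str, float]] = None,
) -> StudyTables:
    """Generate a full synthetic study: cohort, trajectories, grip,
    questionnaires and clinical scales, as CSV-ready tables."""
    config.validate()
    if zonemap is None:
        zonemap = synthetic.default_zonemap()
    if met_table is None:
        met_table = champs.default_met_table()
    cohort = synthetic.generate_cohort(config)
    rng = np.random.default_rng([config.seed, 17])

    demo_rows, q_rows, champs_rows, grip_rows = [], [], [], []
    clinical_rows = []
    walks, tasks = [], []
    for i, (p, profile) in enumerate(cohort):
        speed = synthetic.draw_walk_speed(profile, config, rng)
        stopwatch = FIFTEEN_FEET_M / speed
        t0 = config.base_epoch_s + 7200.0 * i
        walks.append(
            synthetic.simulate_walk(p, profile, config, rng=rng, speed=speed, t0=t0)
        )
        tasks.append(
            synthetic.simulate_task_session(
                p, profile, zonemap, config, rng=rng, t0=t0 + 3600.0
            )
        )
        qa = synthetic.simulate_questionnaires(p, profile, config, rng=rng,
                                               met_table=met_table)
        efs, cfs = synthetic.simulate_clinical_scales(profile, config, rng=rng)
        grip_std = synthetic.simulate_grip_trials(p, profile, config, rng=rng,
                                                  source="standard")
        grip_sen = synthetic.simulate_grip_trials(p, profile, config, rng=rng,
                                                  source="sensor")
        if i >= config.n_participants - config.n_missing_grip_standard:
            grip_std = []  # emulate failed standard grip measurements
        demo_rows.append(
            {
                "participant_id": p.id,
                "sex": p.sex,
                "age": p.age,
                "height_cm": p.height_cm,
                "weight_kg": p.weight_kg,
                "bmi": round(p.bmi, 2),
                "inpatient": int(p.inpatient),
            }
        )
        q_rows.append(
            {
                "participant_id": p.id,
                "weight_loss_answer": qa.weight_loss_answer,
                "weight_loss_answer_sensor": qa.weight_loss_answer_sensor,
                "cesd_item7": qa.cesd_item7,
                "cesd_item8": qa.cesd_item8,
                "exhaustion_days_category": qa.exhaustion_days_category,
                "walk_time_stopwatch_s": round(stopwatch, 3),
            }
        )
        champs_rows.extend(
            {"participant_id": p.id, "activity_id": aid, "duration_category": cat}
            for aid, cat in qa.champs.items()
        )
        grip_rows.extend(
            {
                "participant_id": g.participant_id,
                "source": g.source,
                "hand": g.hand,
                "trial": g.trial,
                "peak_kg": g.peak_kg,
            }
            for g in [*grip_std, *grip_sen]
        )
        clinical_rows.append(
            {"participant_id": p.id, "efs_total": efs, "cfs_level": cfs}
        )

    profiles = pd.DataFrame(
        [
            {"participant_id": p.id, **profile.as_dict(), "total": profile.total}
            for p, profile in cohort
        ]
    )
    meta = {
        "seed": config.seed,
        "config": config.as_dict(),
        "config_hash": config_hash(config),
        "package_version": __version__,
    }
    return StudyTables(
        demographics=pd.DataFrame(demo_rows),
        questionnaires=pd.DataFrame(q_rows),
        champs_responses=pd.DataFrame(champs_rows),
        grip_trials=pd.DataFrame(grip_rows),
        positions_walk=pd.concat([w.to_frame() for w in walks], ignore_index=True),
        positions_tasks=pd.concat([t.to_frame() for t in tasks], ignore_index=True),
        clinical_scales=pd.DataFrame(clinical_rows),
        zonemap=zonemap,
        profiles=profiles,
        metadata=meta,
    )


def load_sensor_bundle(indir) -> StudyTables:
    """Load a study directory written by :meth:`StudyTables.write`
    (or hand-assembled to the same schemas)."""
    ind = Path(indir)
    demo = pd.read_csv(ind / "demographics.csv")
    io.require_columns(
        demo, ["participant_id", "sex", "age", "height_cm", "weight_kg"], "demographics"
    )
    io.check_unique_participants(demo, "demographics")
    questionnaires = pd.read_csv(ind / "questionnaires.csv")
    io.check_unique_participants(questionnaires, "questionnaires")
    champs_responses = pd.read_csv(ind / "champs_responses.csv")
    grip_path = ind / "grip_trials.csv"
    grip = (
        pd.read_csv(grip_path)
        if grip_path.exists()
        else pd.DataFrame(columns=["participant_id", "source", "hand", "trial", "peak_kg"])
    )
    positions_walk = io.read_positions(ind / "positions_walk.csv")
    positions_tasks = io.read_positions(ind / "positions_tasks.csv")
    clinical_path = ind / "clinical_scales.csv"
    clinical = (
        pd.read_csv(clinical_path)
        if clinical_path.exists()
        else pd.DataFrame(columns=["participant_id", "efs_total", "cfs_level"])
    )
    zonemap = io.read_zonemap(ind / "zonemap.yaml")
    profiles_path = ind / "profiles_ground_truth.csv"
    profiles = pd.read_csv(profiles_path) if profiles_path.exists() else None
    meta_path = ind / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return StudyTables(
        demographics=demo,
        questionnaires=questionnaires,
        champs_responses=champs_responses,
        grip_trials=grip,
        positions_walk=positions_walk,
        positions_tasks=positions_tasks,
        clinical_scales=clinical,
        zonemap=zonemap,
        profiles=profiles,
        metadata=metadata,
    )


def _grip_max(grip: pd.DataFrame, pid: str, source: str) -> Optional[float]:
    sub = grip[
        (grip["participant_id"] == pid)
        & (grip["source"] == source)
        & (grip["hand"] == "dominant")
    ]
    if sub.empty:
        return None
    return float(sub["peak_kg"].max())


def score_study(
    tables: StudyTables,
    met_table: Optional[dict[str, float]] = None,
    min_dwell: float = 2.0,
    percentile_q: float = 0.80,
) -> pd.DataFrame:
    """Apply standard and sensor Fried criteria to the study tables.

    Returns one row per participant with both flag sets, the measured
    quantities they derive from, and totals/categories per source. The
    sensor low-activity threshold is the cohort's ``percentile_q``
    task-duration percentile, mirroring the sample-relative cutoff.
    """
    if met_table is None:
        met_table = champs.default_met_table()
    demo = tables.demographics.set_index("participant_id")
    qa = tables.questionnaires.set_index("participant_id")
    pids = list(demo.index)

    task_durations: dict[str, float] = {}
    task_zone_names = set(tables.metadata.get("config", {}).get(
        "task_zones", ("kitchen", "disposal")
    ))
    for pid in pids:
        tr = Trajectory.from_frame(tables.positions_tasks, pid, label="pass_tasks")
        totals = zone_total_durations(tr, tables.zonemap, min_dwell=min_dwell)
        task_durations[pid] = sum(
            v for k, v in totals.items() if k in task_zone_names
        )
    threshold = scoring.percentile_threshold(
        list(task_durations.values()), q=percentile_q
    )

    rows = []
    for pid in pids:
        d = demo.loc[pid]
        q = qa.loc[pid]
        sex, height, bmi = str(d["sex"]), float(d["height_cm"]), float(
            d.get("bmi", d["weight_kg"] / (d["height_cm"] / 100) ** 2)
        )
        responses = champs.responses_from_frame(tables.champs_responses, pid)
        kcal = champs.total_kcal(responses, met_table, float(d["weight_kg"]))

        walk_tr = Trajectory.from_frame(tables.positions_walk, pid, label="walk_15ft")
        fit = fit_distance_time(walk_tr)
        try:
            walk_time_uwb = estimate_walk_time(fit)
        except InvalidFitError:
            walk_time_uwb = None  # walk not detectable; slowness missing

        grip_std = _grip_max(tables.grip_trials, pid, "standard")
        grip_sen = _grip_max(tables.grip_trials, pid, "sensor")

        standard = CriterionFlags(
            weight_loss=scoring.weight_loss_flag(answer=str(q["weight_loss_answer"])),
            exhaustion=scoring.exhaustion_flag_standard(
                int(q["cesd_item7"]), int(q["cesd_item8"])
            ),
            low_activity=champs.low_activity_flag_standard(kcal, sex),
            weakness=scoring.weakness_flag(grip_std, sex, bmi),
            slowness=scoring.slowness_flag(
                float(q["walk_time_stopwatch_s"]), sex, height
            ),
            source="standard",
        )
        sensor = CriterionFlags(
            weight_loss=scoring.weight_loss_flag(
                answer=str(q["weight_loss_answer_sensor"])
            ),
            exhaustion=scoring.exhaustion_flag_sensor(
                str(q["exhaustion_days_category"])
            ),
            low_activity=scoring.low_activity_flag_sensor(
                task_durations[pid], threshold
            ),
            weakness=scoring.weakness_flag(grip_sen, sex, bmi),
            slowness=(
                None if walk_time_uwb is None
                else scoring.slowness_flag(walk_time_uwb, sex, height)
            ),
            source="sensor",
        )
        res_std = scoring.total_and_categorize(standard)
        res_sen = scoring.total_and_categorize(sensor)
        row: dict = {
            "participant_id": pid,
            "sex": sex,
            "age": float(d["age"]),
            "kcal_week": round(kcal, 1),
            "task_duration_s": round(task_durations[pid], 2),
            "task_threshold_s": round(threshold, 2),
            "walk_time_stopwatch_s": float(q["walk_time_stopwatch_s"]),
            "walk_time_uwb_s": None if walk_time_uwb is None else round(walk_time_uwb, 3),
            "grip_max_standard_kg": grip_std,
            "grip_max_sensor_kg": grip_sen,
        }
        for crit in CRITERIA:
            row[f"{crit}_standard"] = getattr(standard, crit)
            row[f"{crit}_sensor"] = getattr(sensor, crit)
        row.update(
            {
                "total_standard": res_std.total,
                "category_standard": res_std.category,
                "dichotomous_standard": res_std.dichotomous,
                "complete_standard": res_std.complete,
                "total_sensor": res_sen.total,
                "category_sensor": res_sen.category,
                "dichotomous_sensor": res_sen.dichotomous,
                "complete_sensor": res_sen.complete,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _report_to_dict(rep: AgreementReport) -> dict:
    return {
        "kappa": rep.kappa,
        "kappa_p": rep.kappa_p,
        "rho": rep.rho,
        "rho_df": rep.rho_df,
        "rho_p": rep.rho_p,
        "n": rep.n,
        "degenerate": rep.degenerate,
    }


@dataclass
class StudyReport:
    """Concurrent-validity report for one scored study."""

    per_criterion: dict[str, AgreementReport]
    total_threeclass: dict
    total_dichotomous: AgreementReport
    scale_correlations: pd.DataFrame
    stratified_low_activity: dict[str, dict[str, AgreementReport]]
    n_participants: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "per_criterion": {
                k: _report_to_dict(v) for k, v in self.per_criterion.items()
            },
            "total_threeclass": self.total_threeclass,
            "total_dichotomous": _report_to_dict(self.total_dichotomous),
            "scale_correlations": self.scale_correlations.to_dict(),
            "stratified_low_activity": {
                strat: {k: _report_to_dict(v) for k, v in reps.items()}
                for strat, reps in self.stratified_low_activity.items()
            },
            "metadata": self.metadata,
        }

    def agreement_frame(self) -> pd.DataFrame:
        """Per-criterion agreement block as a tidy frame."""
        rows = []
        for crit, rep in self.per_criterion.items():
            rows.append({"measure": crit, **_report_to_dict(rep)})
        rows.append({"measure": "dichotomized_total",
                     **_report_to_dict(self.total_dichotomous)})
        return pd.DataFrame(rows)


def _flags_column(results: pd.DataFrame, col: str) -> list[Optional[int]]:
    out = []
    for v in results[col]:
        out.append(None if pd.isna(v) else int(v))
    return out


def validate_study(
    results: pd.DataFrame, clinical: Optional[pd.DataFrame] = None,
    metadata: Optional[dict] = None,
) -> StudyReport:
    """Concurrent-validity statistics between the two flag sources.

    Participants missing a criterion on either side are dropped
    pairwise for that criterion; incomplete totals are dropped from
    the score-level analyses.
    """
    per_criterion: dict[str, AgreementReport] = {}
    for crit in CRITERIA:
        per_criterion[crit] = agreement_report(
            _flags_column(results, f"{crit}_standard"),
            _flags_column(results, f"{crit}_sensor"),
        )

    complete = results[results["complete_standard"] & results["complete_sensor"]]
    cats = ["robust", "pre_frail", "frail", "very_frail"]
    # three-level classification folds very_frail into frail
    fold = {"robust": 0, "pre_frail": 1, "frail": 2, "very_frail": 2}
    conf = np.zeros((3, 3))
    for _, r in complete.iterrows():
        conf[fold[r["category_standard"]], fold[r["category_sensor"]]] += 1
    try:
        kr = cohens_kappa_confusion(conf)
        three_kappa, three_p = kr.kappa, kr.p
    except DegenerateTableError:
        three_kappa, three_p = None, None
    sr_tot = spearman_rho(
        complete["total_standard"].to_numpy(float),
        complete["total_sensor"].to_numpy(float),
    ) if complete["total_standard"].nunique() > 1 and complete["total_sensor"].nunique() > 1 else None
    total_threeclass = {
        "kappa": three_kappa,
        "kappa_p": three_p,
        "rho": sr_tot.rho if sr_tot else None,
        "rho_df": sr_tot.df if sr_tot else None,
        "rho_p": sr_tot.p if sr_tot else None,
        "n": int(len(complete)),
        "confusion": conf.tolist(),
    }

    dich = agreement_report(
        [int(v == "frail") for v in complete["dichotomous_standard"]],
        [int(v == "frail") for v in complete["dichotomous_sensor"]],
    )

    # Spearman matrix across the frailty scales (sensor total, standard
    # total, CFS, EFS), pairwise on complete totals.
    scale_cols: dict[str, np.ndarray] = {
        "sensor_total": complete["total_sensor"].to_numpy(float),
        "fried_total": complete["total_standard"].to_numpy(float),
    }
    if clinical is not None and len(clinical):
        clin = clinical.set_index("participant_id").loc[complete["participant_id"]]
        scale_cols["cfs"] = clin["cfs_level"].to_numpy(float)
        scale_cols["efs"] = clin["efs_total"].to_numpy(float)
    names = list(scale_cols)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if i < j:
                try:
                    r = spearman_rho(scale_cols[ni], scale_cols[nj]).rho
                except DegenerateTableError:
                    r = np.nan
                mat.loc[ni, nj] = mat.loc[nj, ni] = r

    strata: dict[str, dict[str, AgreementReport]] = {}
    la_std = _flags_column(results, "low_activity_standard")
    la_sen = _flags_column(results, "low_activity_sensor")
    strata["sex"] = stratified_agreement(la_std, la_sen, list(results["sex"]))
    age_group = ["older" if a > 60 else "younger" for a in results["age"]]
    strata["age_group"] = stratified_agreement(la_std, la_sen, age_group)

    return StudyReport(
        per_criterion=per_criterion,
        total_threeclass=total_threeclass,
        total_dichotomous=dich,
        scale_correlations=mat,
        stratified_low_activity=strata,
        n_participants=int(len(results)),
        metadata=metadata or {},
    )


def run_study(
    config: SimulationConfig,
    outdir: Optional[str] = None,
    mode: str = "all",
    indir: Optional[str] = None,
) -> StudyReport | StudyTables | pd.DataFrame:
    """One-call workflow. ``mode`` is one of simulate / score /
    validate / all; score and validate read ``indir`` when given,
    otherwise simulate in-memory first."""
    if mode not in ("simulate", "score", "validate", "all"):
        raise SchemaError(f"unknown mode {mode!r}")
    tables = load_sensor_bundle(indir) if indir else simulate_study(config)
    out = Path(outdir) if outdir else None
    if out:
        tables.write(out / "tables")
    if mode == "simulate":
        return tables
    results = score_study(tables)
    if out:
        results.to_csv(out / "results.csv", index=False)
    if mode == "score":
        return results
    report = validate_study(results, tables.clinical_scales,
                            metadata=tables.metadata)
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=str)
        report.agreement_frame().to_csv(out / "agreement_table.csv", index=False)
        report.scale_correlations.to_csv(out / "scale_correlations.csv")
    return report
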