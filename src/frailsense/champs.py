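"""CHAMPS-style weekly energy-expenditure scoring.

The low-physical-activity criterion compares weekly caloric expenditure
over the 28 exercise-related questionnaire activities against the
sex-specific Fried cutoffs. Self-reported durations arrive as ordinal
category codes 0-6, recoded to standardized hours/week; each activity
contributes

    kcal_i = D_i * MET_i * 3.5 * 60 * (W / 200)

where D_i is recoded hours/week, MET_i the activity's metabolic
equivalent, and W the participant's body weight in kg. The total is
the sum over reported activities.

MET assignments per activity live in an external codebook; the package
ships a synthetic 28-activity table (``data/champs_mets_synthetic.csv``,
METs in the light-to-moderate 1.5-6.0 range) used by the simulator and
tests. Supply your own table for real questionnaire data.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidConfigError, SchemaError

#: Standardized hours/week for duration-category codes 0..6.
DURATION_CATEGORY_HOURS = (0.0, 0.5, 1.75, 3.75, 5.75, 7.75, 9.75)

#: Sex-specific weekly-kcal cutoffs below which the criterion is met.
LOW_ACTIVITY_KCAL_CUTOFF = {"male": 383.0, "female": 270.0}


def recode_duration(category: int) -> float:
    """Map an ordinal duration-category code (0-6) to hours/week."""
    if category not in range(7):
        raise InvalidConfigError(f"duration category {category!r} not in 0..6")
    return DURATION_CATEGORY_HOURS[category]


def activity_kcal(d_hours_week: float, met: float, weight_kg: float) -> float:
    """Weekly kcal for one activity: D * MET * 3.5 * 60 * (W/200)."""
    if d_hours_week < 0:
        raise InvalidConfigError("duration must be non-negative")
    if met <= 0 or weight_kg <= 0:
        raise InvalidConfigError("MET and weight must be positive")
    return d_hours_week * met * 3.5 * 60.0 * (weight_kg / 200.0)


def total_kcal(
    responses: Mapping[str, int],
    met_table: Mapping[str, float],
    weight_kg: float,
) -> float:
    """Total weekly kcal over all reported activities.

    ``responses`` maps activity_id -> duration-category code; activities
    absent from ``responses`` count as category 0 (not undertaken).
    An activity_id not present in the MET table is an error.
    """
    unknown = set(responses) - set(met_table)
    if unknown:
        raise SchemaError(f"activity ids not in MET table: {sorted(unknown)}")
    return sum(
        activity_kcal(recode_duration(cat), met_table[aid], weight_kg)
        for aid, cat in responses.items()
    )


def low_activity_flag_standard(kcal_total: float, sex: str) -> int:
    """1 iff weekly kcal is strictly below the sex-specific cutoff."""
    try:
        cutoff = LOW_ACTIVITY_KCAL_CUTOFF[sex]
    except KeyError:
        raise InvalidConfigError(f"unknown sex {sex!r}") from None
    return int(kcal_total < cutoff)


def default_met_table() -> dict[str, float]:
    """The bundled synthetic 28-activity MET table (activity_id -> MET)."""
    with resources.files("frailsense.data").joinpath(
        "champs_mets_synthetic.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["activity_id"], df["met"].astype(float)))


def load_met_table(path) -> dict[str, float]:
    """Read a MET table CSV with columns ``activity_id,met``."""
    df = pd.read_csv(path)
    missing = {"activity_id", "met"} - set(df.columns)
    if missing:
        raise SchemaError(f"MET table missing columns: {sorted(missing)}")
    if (df["met"] <= 0).any():
        raise SchemaError("MET values must be positive")
    return dict(zip(df["activity_id"], df["met"].astype(float)))


def responses_from_frame(df: pd.DataFrame, participant_id: str) -> dict[str, int]:
    """Extract one participant's responses from a long-format CSV frame
    with columns ``participant_id,activity_id,duration_category``."""
    sub = df[df["participant_id"] == participant_id]
    return dict(zip(sub["activity_id"], sub["duration_category"].astype(int)))


def iter_participants(df: pd.DataFrame) -> Iterable[str]:
    return df["participant_id"].unique()
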