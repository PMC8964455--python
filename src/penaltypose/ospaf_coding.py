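"""Data model and I/O for the OSPAF observational coding scheme.

OSPAF (Observational System for Penalty-kick Analysis in Football) codes one
penalty event into 21 categorical variables covering the taker's run-up, the
goalkeeper's behaviour, the match context, the kick itself and the perceived
strategy of both actors.  This module defines the canonical level sets
(snake_case tokens), normalizes the verbose phrases used in coding sheets,
validates records, and merges notational, pose-derived and ball-speed
variables into the per-penalty analysis table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import LevelValidationError, MergeError, SchemaError

#: canonical level sets, verbatim structure of the coding scheme
OSPAF_LEVELS: dict[str, tuple[str, ...]] = {
    "run_up_speed": ("fast", "slow"),
    "run_up_fluency": ("continuous", "with_pauses"),
    "run_up_angle": ("frontal", "diagonal"),
    "number_of_steps": ("1-3", "3-5", "5+"),
    "kicking_technique": ("side_foot", "instep"),
    "foot_used": ("right", "left"),
    "kicker_gaze": ("at_ball", "not_at_ball"),
    "gk_initial_posture": ("arms_raised", "arms_down", "arms_perpendicular"),
    "deception": ("yes", "no"),
    "gk_tactical_action": ("guess", "await"),
    "gk_performance": ("0", "1", "2", "3", "4", "5"),
    "match_moment": ("first_half", "second_half", "extra_time_or_shootout"),
    "location": ("home", "neutral", "away"),
    "momentary_result_kicker": ("winning", "drawing", "losing"),
    "momentary_result_gk": ("winning", "drawing", "losing"),
    "match_importance": (
        "final",
        "decisive_knockout",
        "group_stage",
        "early_season",
        "season_final_stages",
    ),
    "kick_direction": ("left", "center", "right"),
    "kick_height": ("upper", "center", "down"),
    "outcome": ("goal", "saved", "missed"),
    "taker_strategy": ("gk_dependent", "unclear", "gk_independent"),
    "gk_strategy": ("kicker_independent", "unclear", "kicker_dependent"),
}

OSPAF_VARIABLES: tuple[str, ...] = tuple(OSPAF_LEVELS)
STRATEGY_VARIABLES: tuple[str, ...] = ("taker_strategy", "gk_strategy")

#: verbose coding-sheet phrases -> canonical tokens (applied after basic
#: lowercase/underscore normalization)
_SYNONYMS: dict[str, str] = {
    "continuous_running": "continuous",
    "running_with_pauses": "with_pauses",
    "with_pauses": "with_pauses",
    "side_foot_kick": "side_foot",
    "instep_kick": "instep",
    "gaze_at_the_ball": "at_ball",
    "gaze_at_ball": "at_ball",
    "not_at_the_ball": "not_at_ball",
    "arms_extended_perpendicular": "arms_perpendicular",
    "try_to_guess": "guess",
    "awaiting": "await",
    "awaiting_the_penalty_taker_action": "await",
    "extra_time": "extra_time_or_shootout",
    "shoot_out": "extra_time_or_shootout",
    "shootout": "extra_time_or_shootout",
    "visitor": "away",
    "championship_final_match": "final",
    "championship_final": "final",
    "decisive_knockout_match": "decisive_knockout",
    "group_stage_match": "group_stage",
    "early_season_game": "early_season",
    "match_in_final_stages_of_the_season": "season_final_stages",
    "saved_by_goalkeeper": "saved",
    "shot_misses_goal": "missed",
    "miss": "missed",
    "goalkeeper_dependent": "gk_dependent",
    "goalkeeper_independent": "gk_independent",
    "1_3": "1-3",
    "3_5": "3-5",
    "+5": "5+",
    "_5": "5+",
    "more_than_5": "5+",
}


def normalize_level(value: object) -> str:
    """Normalize a raw coded value to a canonical snake_case token."""
    token = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    # numeric-range levels keep their hyphen form
    if token in ("1_3", "3_5"):
        return _SYNONYMS[token]
    return _SYNONYMS.get(token, token)


def validate_record(record: Mapping[str, object]) -> list[str]:
    """Check one coded record against the level sets; returns violations.

    Total on arbitrary input: never raises, unknown values are reported as
    violations.  Only keys that are OSPAF variables are checked.
    """
    violations = []
    for var in OSPAF_VARIABLES:
        if var not in record:
            violations.append(f"{var}: missing")
            continue
        token = normalize_level(record[var])
        levels = OSPAF_LEVELS[var]
        if token not in levels:
            if var == "gk_performance":
                violations.append(
                    f"gk_performance: {record[var]!r} invalid (valid range 0-5)"
                )
            else:
                violations.append(
                    f"{var}: {record[var]!r} not in {{{', '.join(levels)}}}"
                )
    return violations


def read_ospaf_table(source: str | Path) -> pd.DataFrame:
    """Read and validate an OSPAF coding table (CSV, one row per penalty).

    Columns: ``penalty_id`` plus the 21 coded variables; extra *numeric*
    columns (e.g. ``ball_speed``) are passed through untouched.  Level
    strings are normalized case-insensitively to canonical tokens.

    Raises
    ------
    SchemaError
        Missing ``penalty_id``, unknown non-numeric column, or duplicate ids.
    LevelValidationError
        A value outside its legal level set, naming row and field.
    """
    df = pd.read_csv(source, dtype={"penalty_id": str})
    if "penalty_id" not in df.columns:
        raise SchemaError("OSPAF table lacks a penalty_id column")
    if df["penalty_id"].duplicated().any():
        dupes = df.loc[df["penalty_id"].duplicated(), "penalty_id"].tolist()
        raise SchemaError(f"duplicate penalty_id values: {dupes}")
    known = set(OSPAF_VARIABLES) | {"penalty_id"}
    for col in df.columns:
        if col not in known and not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"unknown OSPAF column {col!r}")
    for var in OSPAF_VARIABLES:
        if var not in df.columns:
            continue
        normalized = df[var].map(normalize_level)
        levels = OSPAF_LEVELS[var]
        bad = ~normalized.isin(levels)
        if bad.any():
            row = int(df.index[bad][0])
            raise LevelValidationError(
                f"row {row}, field {var!r}: {df.loc[row, var]!r} "
                f"not one of {{{', '.join(levels)}}}"
            )
        df[var] = normalized
    return df


def write_ospaf_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def ospaf_json_schema() -> dict:
    """JSON-schema description of one OSPAF record (documentation artefact)."""
    props: dict[str, object] = {"penalty_id": {"type": "string"}}
    for var, levels in OSPAF_LEVELS.items():
        props[var] = {"type": "string", "enum": list(levels)}
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "OSPAF penalty record",
        "type": "object",
        "properties": props,
        "required": ["penalty_id", *OSPAF_VARIABLES],
    }


def write_json_schema(path: str | Path) -> None:
    Path(path).write_text(json.dumps(ospaf_json_schema(), indent=2))


def merge_features(
    ospaf: pd.DataFrame,
    pose: pd.DataFrame,
    ball_speed: pd.DataFrame | None = None,
    how: str = "inner",
) -> pd.DataFrame:
    """Join notational, pose and ball-speed tables on ``penalty_id``.

    ``how='inner'`` (default) keeps penalties present in every input;
    ``how='outer'`` keeps all penalties and carries missing pose measures as
    NaN flags.  Unmatched ids are recorded in ``result.attrs['unmatched']``.

    Raises :class:`MergeError` when the id sets are disjoint.
    """
    if how not in ("inner", "outer"):
        raise MergeError(f"join policy must be 'inner' or 'outer', got {how!r}")
    tables = [t for t in (ospaf, pose, ball_speed) if t is not None]
    for t in tables:
        if "penalty_id" not in t.columns:
            raise MergeError("every input table needs a penalty_id column")
    id_sets = [set(t["penalty_id"].astype(str)) for t in tables]
    common = set.intersection(*id_sets)
    if not common:
        raise MergeError("no penalty_id overlaps across the input tables")
    merged = tables[0].copy()
    merged["penalty_id"] = merged["penalty_id"].astype(str)
    for t in tables[1:]:
        t = t.copy()
        t["penalty_id"] = t["penalty_id"].astype(str)
        merged = merged.merge(t, on="penalty_id", how=how)
    merged = merged.sort_values("penalty_id", kind="stable").reset_index(drop=True)
    union = set.union(*id_sets)
    merged.attrs["unmatched"] = sorted(union - common)
    return merged
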