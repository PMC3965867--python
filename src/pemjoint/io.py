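"""Flat-file input/output.

Two CSV tables describe a cohort (UTF-8, header row, "." decimal separator):

* longitudinal: ``subject_id, time_months, igg_titer, age, male, single,
  skin_phenotype, lymphocyte`` — baseline covariates repeated on every row;
* episodes: ``subject_id, episode, gap_months, event``.

Follow-up is not stored explicitly: because the episode gaps partition the
follow-up window, it is reconstructed as the per-subject sum of gap times.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_types import (
    Cohort,
    EpisodeRecord,
    LongitudinalObservation,
    SubjectCovariates,
    SubjectData,
    ValidationError,
    validate_cohort,
)

__all__ = ["read_cohort", "write_cohort", "LONG_COLUMNS", "EPISODE_COLUMNS"]

LONG_COLUMNS = ["subject_id", "time_months", "igg_titer", "age", "male", "single", "skin_phenotype", "lymphocyte"]
EPISODE_COLUMNS = ["subject_id", "episode", "gap_months", "event"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_cohort(longitudinal_path, episodes_path, validate: bool = True) -> Cohort:
    """Parse and join the two tables into a validated :class:`Cohort`."""
    long_df = pd.read_csv(longitudinal_path)
    epi_df = pd.read_csv(episodes_path)
    _check_columns(long_df, LONG_COLUMNS, longitudinal_path)
    _check_columns(epi_df, EPISODE_COLUMNS, episodes_path)
    if long_df.empty or epi_df.empty:
        raise ValidationError(
            f"empty cohort: {longitudinal_path} has {len(long_df)} rows, "
            f"{episodes_path} has {len(epi_df)} rows"
        )
    long_ids = set(long_df["subject_id"].astype(str))
    epi_ids = set(epi_df["subject_id"].astype(str))
    orphans = sorted(epi_ids - long_ids)
    if orphans:
        raise ValidationError(f"{episodes_path}: subject_ids without longitudinal rows: {orphans}")
    missing_epi = sorted(long_ids - epi_ids)
    if missing_epi:
        raise ValidationError(f"{longitudinal_path}: subject_ids without episodes: {missing_epi}")

    long_df = long_df.assign(subject_id=long_df["subject_id"].astype(str))
    epi_df = epi_df.assign(subject_id=epi_df["subject_id"].astype(str))
    follow_up = epi_df.groupby("subject_id")["gap_months"].sum()

    subjects = []
    epi_groups = {k: g for k, g in epi_df.groupby("subject_id", sort=False)}
    for sid, g in long_df.groupby("subject_id", sort=False):
        first = g.iloc[0]
        cov = SubjectCovariates(
            age=float(first["age"]),
            male=int(first["male"]),
            single=int(first["single"]),
            skin_phenotype=int(first["skin_phenotype"]),
            lymphocyte=float(first["lymphocyte"]),
            follow_up=float(follow_up[sid]),
        )
        obs = [
            LongitudinalObservation.from_titer(sid, float(row.time_months), float(row.igg_titer))
            for row in g.sort_values("time_months").itertuples()
        ]
        eg = epi_groups[sid].sort_values("episode")
        episodes = [
            EpisodeRecord(subject_id=sid, k=int(row.episode), w=float(row.gap_months), delta=int(row.event))
            for row in eg.itertuples()
        ]
        subjects.append(SubjectData(subject_id=sid, covariates=cov, observations=obs, episodes=episodes))

    cohort = Cohort(
        subjects=subjects,
        metadata={"longitudinal_path": str(longitudinal_path), "episodes_path": str(episodes_path)},
    )
    if validate:
        violations = validate_cohort(cohort)
        if violations:
            raise ValidationError(
                "invalid cohort: " + "; ".join(str(v) for v in violations[:20])
            )
    return cohort


def write_cohort(cohort: Cohort, longitudinal_path, episodes_path, manifest_path=None) -> None:
    """Write the two CSV tables (full float precision) and, optionally, a
    truth-manifest JSON carrying the generator seed and parameters."""
    long_rows = []
    epi_rows = []
    for s in cohort.subjects:
        c = s.covariates
        for o in s.observations:
            long_rows.append(
                (s.subject_id, o.t, o.titer, c.age, c.male, c.single, c.skin_phenotype, c.lymphocyte)
            )
        for e in s.episodes:
            epi_rows.append((s.subject_id, e.k, e.w, e.delta))
    pd.DataFrame(long_rows, columns=LONG_COLUMNS).to_csv(
        longitudinal_path, index=False, float_format="%.17g"
    )
    pd.DataFrame(epi_rows, columns=EPISODE_COLUMNS).to_csv(
        episodes_path, index=False, float_format="%.17g"
    )
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(cohort.metadata, indent=2, default=float))
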