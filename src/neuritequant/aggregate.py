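"""Replicate bookkeeping: fields → technical replicates → biological replicates.

The experiment design this mirrors: per condition, ten imaging fields of
3–5 technical replicates (wells) are recorded, and each biological
replicate is the mean of its technical replicates.  Figures plot the mean
± SD or SEM over biological replicates, so the averaging order is fixed
(fields → technical → biological) and permuting fields within a technical
replicate can never change the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Condition",
    "WellSpec",
    "ExperimentManifest",
    "AggregateResult",
    "aggregate",
    "timecourse_table",
]

ROLES = ("sample", "intact_control", "degenerated_control", "untreated_control")


class Condition(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    treatment: str = ""
    dose: float | None = None
    timepoint_h: float | None = Field(default=None, ge=0)
    role: Literal["sample", "intact_control", "degenerated_control", "untreated_control"] = (
        "sample"
    )


class WellSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    well_id: str
    condition_id: str
    biological_replicate: int
    technical_replicate: int
    fields: list[str]


class ExperimentManifest(BaseModel):
    """Condition → well → field mapping with control designations."""

    model_config = ConfigDict(extra="forbid")

    conditions: list[Condition]
    wells: list[WellSpec]

    @model_validator(mode="after")
    def _check(self) -> "ExperimentManifest":
        ids = [c.id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate condition ids in manifest")
        known = set(ids)
        for w in self.wells:
            if w.condition_id not in known:
                raise ValueError(
                    f"well {w.well_id!r} references unknown condition {w.condition_id!r}"
                )
        return self

    def condition(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.id == condition_id:
                return c
        raise KeyError(condition_id)

    def controls(self, role: str) -> list[Condition]:
        return [c for c in self.conditions if c.role == role]

    def anchor_condition(self, role: str) -> Condition:
        """The unique control condition with the given role.

        Degeneration normalization requires exactly one intact and one
        fully-degenerated control; ambiguity is an error.
        """
        found = self.controls(role)
        if len(found) != 1:
            raise ValueError(
                f"expected exactly one {role} condition, found "
                f"{[c.id for c in found]}"
            )
        return found[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentManifest":
        return cls.model_validate_json(Path(path).read_text())


@dataclass
class AggregateResult:
    """Per-level summary tables from :func:`aggregate`."""

    technical: pd.DataFrame
    biological: pd.DataFrame
    condition: pd.DataFrame
    excluded: pd.DataFrame


_REQUIRED = ["condition_id", "biological_replicate", "technical_replicate", "metric", "value"]


def aggregate(
    manifest: ExperimentManifest,
    field_rows: pd.DataFrame,
    min_fields_per_tech: int = 3,
) -> AggregateResult:
    """Collapse per-field metric rows into replicate-level summary tables.

    ``field_rows`` is a long table with one row per (field, metric):
    columns ``condition_id, biological_replicate, technical_replicate,
    metric, value`` and optionally ``flagged`` (bool; flagged rows are
    dropped before averaging).  Technical replicates with fewer than
    ``min_fields_per_tech`` usable fields are excluded and reported in
    ``excluded``.  The condition table carries the biological-replicate
    mean ± SD and ± SEM; with a single biological replicate SD and SEM are
    reported as missing (NaN) with n = 1.

    Raises
    ------
    ValueError
        If a manifest condition that has wells ends up with zero surviving
        fields.
    """
    missing = [c for c in _REQUIRED if c not in field_rows.columns]
    if missing:
        raise ValueError(f"field_rows missing required columns: {missing}")
    rows = field_rows.copy()
    if "flagged" in rows.columns:
        rows = rows[~rows["flagged"].astype(bool)]
    rows = rows.dropna(subset=["value"])

    keys_tech = ["condition_id", "biological_replicate", "technical_replicate", "metric"]
    tech = (
        rows.groupby(keys_tech, sort=True)["value"]
        .agg(mean="mean", n_fields="count")
        .reset_index()
    )
    bad = tech["n_fields"] < min_fields_per_tech
    excluded = tech[bad].reset_index(drop=True)
    tech = tech[~bad].reset_index(drop=True)

    keys_bio = ["condition_id", "biological_replicate", "metric"]
    bio = (
        tech.groupby(keys_bio, sort=True)["mean"]
        .agg(mean="mean", n_technical="count")
        .reset_index()
    )

    cond = (
        bio.groupby(["condition_id", "metric"], sort=True)["mean"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    cond["sem"] = cond["sd"] / np.sqrt(cond["n"])
    cond = cond[["condition_id", "metric", "mean", "sd", "sem", "n"]]

    referenced = {w.condition_id for w in manifest.wells}
    surviving = set(tech["condition_id"].unique())
    starved = sorted(referenced - surviving)
    if starved:
        raise ValueError(f"conditions with zero surviving fields: {starved}")

    return AggregateResult(technical=tech, biological=bio, condition=cond, excluded=excluded)


def timecourse_table(
    summaries: pd.DataFrame,
    timepoints: Mapping[str, float] | pd.DataFrame,
) -> pd.DataFrame:
    """Attach timepoints to a condition summary for time-course plotting.

    ``summaries`` is the condition-level table from :func:`aggregate`;
    ``timepoints`` maps condition id → hours after axotomy (mapping or a
    two-column DataFrame).  Returns a tidy long table sorted by metric and
    timepoint with columns ``condition_id, timepoint_h, metric, mean, sd,
    sem, n``.  Duplicate (condition, timepoint) assignments and negative
    timepoints are rejected.
    """
    if isinstance(timepoints, pd.DataFrame):
        tp = timepoints[["condition_id", "timepoint_h"]].copy()
    else:
        tp = pd.DataFrame(
            {"condition_id": list(timepoints.keys()), "timepoint_h": list(timepoints.values())}
        )
    if tp.duplicated(subset=["condition_id", "timepoint_h"]).any() or tp.duplicated(
        subset=["condition_id"]
    ).any():
        raise ValueError("duplicate (condition, timepoint) assignment")
    if (tp["timepoint_h"] < 0).any():
        raise ValueError("timepoints must be non-negative hours")
    if summaries.empty:
        return pd.DataFrame(
            columns=["condition_id", "timepoint_h", "metric", "mean", "sd", "sem", "n"]
        )
    out = summaries.merge(tp, on="condition_id", how="inner")
    out = out[["condition_id", "timepoint_h", "metric", "mean", "sd", "sem", "n"]]
    return out.sort_values(["metric", "timepoint_h", "condition_id"]).reset_index(drop=True)
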