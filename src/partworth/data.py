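"""Choice datasets: containers, effects coding, and the long-format file.

The estimation substrate is a :class:`ChoiceDataset` — the attribute
dictionary, the choice tasks respondents saw, and one chosen alternative
per respondent-task.  Tasks are effects-coded for conditional-logit
estimation: an attribute with K levels owns K-1 columns, level ``l < K``
is the unit indicator for its own column, and the last level is coded -1
on all K-1 columns, so level utilities are zero-centered within each
attribute.  Attributes not shown in a partial-profile task are coded 0
and cancel inside the task's softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AttributeSpec, ChoiceTask

__all__ = [
    "ChoiceObservation",
    "ChoiceDataset",
    "DataError",
    "effects_columns",
    "effects_code",
    "read_choices",
    "write_choices",
    "split_holdout",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent choice data."""


@dataclass(frozen=True)
class ChoiceObservation:
    """One respondent's choice on one task."""

    respondent_id: str
    version: int
    position: int
    chosen_alternative: int  # 1-based


def effects_columns(attributes: list[AttributeSpec]) -> list[tuple[int, int]]:
    """Ordered (attribute_id, level_index) pairs, one per effects column.

    Attribute ``a`` with K levels owns columns for levels 1..K-1, in
    attribute-list order; total width P = sum(K_a - 1).
    """
    cols = []
    for a in attributes:
        for level in range(1, a.n_levels):
            cols.append((a.attribute_id, level))
    return cols


def _column_offsets(attributes: list[AttributeSpec]) -> dict[int, int]:
    offsets, p = {}, 0
    for a in attributes:
        offsets[a.attribute_id] = p
        p += a.n_levels - 1
    return offsets


def effects_code(task: ChoiceTask, attributes: list[AttributeSpec]) -> np.ndarray:
    """Effects-code one task: (n_alternatives, P) array of {-1, 0, 1}."""
    by_id = {a.attribute_id: a for a in attributes}
    offsets = _column_offsets(attributes)
    p_total = sum(a.n_levels - 1 for a in attributes)
    rows = np.zeros((task.n_alternatives, p_total))
    for j, aid in enumerate(task.shown_attributes):
        attr = by_id.get(aid)
        if attr is None:
            raise DataError(f"task references unknown attribute {aid}")
        k = attr.n_levels
        base = offsets[aid]
        for i in range(task.n_alternatives):
            level = int(task.level_assignment[i, j])
            if not 1 <= level <= k:
                raise DataError(
                    f"level {level} out of range for attribute {attr.name!r}"
                )
            if level < k:
                rows[i, base + level - 1] = 1.0
            else:
                rows[i, base : base + k - 1] = -1.0
    return rows


@dataclass
class ChoiceDataset:
    """Attributes, tasks, and chosen alternatives; the estimation substrate."""

    attributes: list[AttributeSpec]
    tasks: dict[tuple[int, int], ChoiceTask]
    observations: list[ChoiceObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        version_of: dict[str, int] = {}
        for obs in self.observations:
            key = (obs.respondent_id, obs.version, obs.position)
            if key in seen:
                raise DataError(f"duplicate observation {key}")
            seen.add(key)
            task = self.tasks.get((obs.version, obs.position))
            if task is None:
                raise DataError(
                    f"observation references unknown task "
                    f"(version {obs.version}, position {obs.position})"
                )
            if not 1 <= obs.chosen_alternative <= task.n_alternatives:
                raise DataError(
                    f"chosen alternative {obs.chosen_alternative} out of range "
                    f"for task {task.key}"
                )
            prev = version_of.setdefault(obs.respondent_id, obs.version)
            if prev != obs.version:
                raise DataError(
                    f"respondent {obs.respondent_id!r} spans versions {prev} "
                    f"and {obs.version}"
                )

    # -- summaries ---------------------------------------------------------
    @property
    def respondent_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(obs.respondent_id)
        return list(seen)

    @property
    def n_respondents(self) -> int:
        return len({o.respondent_id for o in self.observations})

    @property
    def n_parameters(self) -> int:
        """Effects-coded width P = sum over attributes of (K - 1)."""
        return sum(a.n_levels - 1 for a in self.attributes)

    def holdout_positions(self) -> set[int]:
        return {t.position for t in self.tasks.values() if t.is_holdout}

    # -- estimation arrays -------------------------------------------------
    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Stack observations for estimation.

        Returns ``(X, chosen, resp_index, respondent_ids)`` where ``X`` has
        shape (n_obs, n_alternatives, P), ``chosen`` holds 0-based chosen
        indices and ``resp_index`` maps each observation to a respondent.
        Requires a constant alternative count across tasks.
        """
        if not self.observations:
            raise DataError("dataset has no observations")
        n_alts = {t.n_alternatives for t in self.tasks.values()}
        if len(n_alts) != 1:
            raise DataError("tasks have differing alternative counts")
        coded: dict[tuple[int, int], np.ndarray] = {}
        ids = self.respondent_ids
        idx_of = {r: i for i, r in enumerate(ids)}
        x_rows, chosen, resp = [], [], []
        for obs in self.observations:
            key = (obs.version, obs.position)
            if key not in coded:
                coded[key] = effects_code(self.tasks[key], self.attributes)
            x_rows.append(coded[key])
            chosen.append(obs.chosen_alternative - 1)
            resp.append(idx_of[obs.respondent_id])
        return (
            np.stack(x_rows),
            np.asarray(chosen, dtype=int),
            np.asarray(resp, dtype=int),
            ids,
        )


def split_holdout(dataset: ChoiceDataset) -> tuple[ChoiceDataset, ChoiceDataset]:
    """Partition into (estimation, holdout) by each task's holdout flag.

    The two partitions reconstruct the input exactly; with no holdout
    tasks the second partition is empty.
    """
    est_obs, hold_obs = [], []
    for obs in dataset.observations:
        task = dataset.tasks[(obs.version, obs.position)]
        (hold_obs if task.is_holdout else est_obs).append(obs)
    est_tasks = {k: t for k, t in dataset.tasks.items() if not t.is_holdout}
    hold_tasks = {k: t for k, t in dataset.tasks.items() if t.is_holdout}
    return (
        ChoiceDataset(dataset.attributes, est_tasks, est_obs),
        ChoiceDataset(dataset.attributes, hold_tasks, hold_obs),
    )


# ---------------------------------------------------------------------------
# Long-format interchange file
#
# Comma-delimited, UTF-8, header row; one row per (respondent, task,
# alternative): respondent_id, version, position, is_holdout, alternative,
# chosen (0/1), then one column per attribute holding the level (1-based
# index or text label; empty when the attribute is not shown).  A file must
# use indices or labels consistently — mixing the two is rejected.

_FIXED_COLS = ["respondent_id", "version", "position", "is_holdout", "alternative", "chosen"]


def write_choices(dataset: ChoiceDataset, path: str | Path) -> None:
    rows = []
    for obs in dataset.observations:
        task = dataset.tasks[(obs.version, obs.position)]
        for alt in range(1, task.n_alternatives + 1):
            row: dict[str, object] = {
                "respondent_id": obs.respondent_id,
                "version": obs.version,
                "position": obs.position,
                "is_holdout": int(task.is_holdout),
                "alternative": alt,
                "chosen": int(alt == obs.chosen_alternative),
            }
            for a in dataset.attributes:
                lv = task.level_of(a.attribute_id, alt)
                row[a.name] = "" if lv is None else lv
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_level(value: object, attr: AttributeSpec, line: int) -> tuple[int | None, bool]:
    """Return (1-based level or None, was_label)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None, False
    text = str(value).strip()
    if text == "":
        return None, False
    try:
        num = int(float(text))
    except ValueError:
        num = None
    if num is not None:
        if not 1 <= num <= attr.n_levels:
            raise DataError(
                f"line {line}: level index {num} out of range for {attr.name!r}"
            )
        return num, False
    if text in attr.levels:
        return attr.levels.index(text) + 1, True
    raise DataError(f"line {line}: unknown level {text!r} for attribute {attr.name!r}")


def read_choices(path: str | Path, attributes: list[AttributeSpec]) -> ChoiceDataset:
    """Read the long-format choice file; malformed rows raise with line numbers."""
    df = pd.read_csv(path, dtype={"respondent_id": str}, keep_default_na=False)
    missing = [c for c in _FIXED_COLS if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    by_name = {a.name: a for a in attributes}
    attr_cols = [c for c in df.columns if c in by_name]
    if len(attr_cols) != len(attributes):
        absent = [a.name for a in attributes if a.name not in df.columns]
        raise DataError(f"missing attribute columns: {absent}")

    saw_label = saw_index = False
    tasks: dict[tuple[int, int], ChoiceTask] = {}
    grids: dict[tuple[int, int], tuple] = {}
    observations: list[ChoiceObservation] = []

    df = df.copy()
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    grouped = df.groupby(["respondent_id", "version", "position"], sort=False)
    for (rid, version, position), grp in grouped:
        version, position = int(version), int(position)
        grp = grp.sort_values("alternative")
        line0 = int(grp["_line"].iloc[0])
        shown, columns = [], []
        for name in attr_cols:
            attr = by_name[name]
            levels = []
            for value, line in zip(grp[name], grp["_line"]):
                lv, was_label = _parse_level(value, attr, int(line))
                if lv is not None:
                    saw_label |= was_label
                    saw_index |= not was_label
                levels.append(lv)
            present = [lv is not None for lv in levels]
            if all(present):
                shown.append(attr.attribute_id)
                columns.append(levels)
            elif any(present):
                raise DataError(
                    f"line {line0}: attribute {name!r} shown for only some "
                    f"alternatives of task (version {version}, position {position})"
                )
        grid = tuple(zip(*columns)) if columns else ()
        key = (version, position)
        if key in grids:
            if grids[key] != (tuple(shown), grid):
                raise DataError(
                    f"line {line0}: task (version {version}, position {position}) "
                    f"redefined with different content"
                )
        else:
            grids[key] = (tuple(shown), grid)
            tasks[key] = ChoiceTask(
                version=version,
                position=position,
                is_holdout=bool(int(grp["is_holdout"].iloc[0])),
                shown_attributes=tuple(shown),
                level_assignment=np.asarray(grid, dtype=int).reshape(len(grp), len(shown)),
            )
        chosen_flags = grp["chosen"].astype(int).to_numpy()
        if chosen_flags.sum() != 1:
            raise DataError(
                f"line {line0}: task (respondent {rid!r}, version {version}, "
                f"position {position}) must have exactly one chosen alternative, "
                f"found {int(chosen_flags.sum())}"
            )
        chosen_alt = int(grp["alternative"].to_numpy()[chosen_flags == 1][0])
        observations.append(ChoiceObservation(str(rid), version, position, chosen_alt))

    if saw_label and saw_index:
        raise DataError("file mixes level labels and level indices; use one style")
    return ChoiceDataset(list(attributes), tasks, observations)
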