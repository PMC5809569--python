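"""Randomized partial-profile choice-task designs.

A partial-profile discrete choice experiment shows each respondent a
sequence of tasks; every task presents a small number of alternatives,
each described by the levels of a subset of the study's attributes (the
remaining attributes are implicitly held constant).  Within a task the
shown attributes take a *different* level in every alternative (a
"no-overlap" / main-effects design), so each task is maximally
informative about the shown attributes.

Designs are built per survey version: attributes cycle through a
shuffled queue so that within a version every attribute's show-count
differs by at most one, and levels are assigned preferring the
least-shown level of each attribute so exposure stays near-balanced.
Each version draws from its own RNG stream derived from
``(seed, version)``, making versions independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AttributeSpec",
    "DesignConfig",
    "ChoiceTask",
    "DesignError",
    "generate_design",
    "generate_holdout_tasks",
    "attach_holdouts",
    "design_balance_report",
    "read_attributes",
    "write_attributes",
    "write_design",
    "read_design",
]


class DesignError(ValueError):
    """Raised for infeasible or inconsistent design configurations."""


@dataclass(frozen=True)
class AttributeSpec:
    """One design dimension: an attribute and its ordered discrete levels."""

    attribute_id: int
    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise DesignError(f"attribute {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise DesignError(f"attribute {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class DesignConfig:
    """Layout of one survey instrument.

    ``holdout_positions`` are 1-based slots in the final task sequence
    (experimental tasks plus holdouts) at which fixed holdout tasks sit.
    """

    n_versions: int = 1
    tasks_per_version: int = 18
    alternatives_per_task: int = 3
    attributes_per_task: int = 3
    holdout_positions: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "holdout_positions", tuple(self.holdout_positions))
        if self.n_versions < 1 or self.tasks_per_version < 1:
            raise DesignError("n_versions and tasks_per_version must be >= 1")
        if self.alternatives_per_task < 2:
            raise DesignError("need >= 2 alternatives per task")
        if len(set(self.holdout_positions)) != len(self.holdout_positions):
            raise DesignError("duplicate holdout positions")
        n_total = self.tasks_per_version + len(self.holdout_positions)
        for p in self.holdout_positions:
            if not 1 <= p <= n_total:
                raise DesignError(f"holdout position {p} outside 1..{n_total}")

    def validate(self, attributes: list[AttributeSpec]) -> None:
        if self.attributes_per_task > len(attributes):
            raise DesignError(
                f"attributes_per_task={self.attributes_per_task} exceeds the "
                f"{len(attributes)} available attributes"
            )
        min_k = min(a.n_levels for a in attributes)
        if self.alternatives_per_task > min_k:
            raise DesignError(
                f"alternatives_per_task={self.alternatives_per_task} exceeds the "
                f"smallest level count ({min_k}); a no-overlap assignment is impossible"
            )


@dataclass(frozen=True)
class ChoiceTask:
    """One choice task: a grid of level indices, alternatives x shown attributes.

    ``level_assignment[i, j]`` is the 1-based level index of attribute
    ``shown_attributes[j]`` in alternative ``i``.
    """

    version: int
    position: int
    is_holdout: bool
    shown_attributes: tuple[int, ...]
    level_assignment: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.level_assignment, dtype=int)
        object.__setattr__(self, "level_assignment", grid)
        object.__setattr__(self, "shown_attributes", tuple(self.shown_attributes))
        if grid.ndim != 2 or grid.shape[1] != len(self.shown_attributes):
            raise DesignError("level_assignment shape does not match shown_attributes")
        if len(set(self.shown_attributes)) != len(self.shown_attributes):
            raise DesignError("shown_attributes contains duplicates")

    @property
    def n_alternatives(self) -> int:
        return int(self.level_assignment.shape[0])

    @property
    def key(self) -> tuple[int, int]:
        return (self.version, self.position)

    def level_of(self, attribute_id: int, alternative: int) -> int | None:
        """1-based level of ``attribute_id`` in 1-based ``alternative``, or None."""
        try:
            j = self.shown_attributes.index(attribute_id)
        except ValueError:
            return None
        return int(self.level_assignment[alternative - 1, j])

    def content_key(self) -> tuple:
        """Order-canonical task content (no version/position): the attribute ->
        level-column mapping, sorted by attribute id.  Two tasks showing the
        same attributes at the same levels compare equal regardless of the
        column order they were stored in."""
        pairs = sorted(
            (aid, tuple(int(v) for v in self.level_assignment[:, j]))
            for j, aid in enumerate(self.shown_attributes)
        )
        return tuple(pairs)


def _check_task_levels(task: ChoiceTask, by_id: dict[int, AttributeSpec]) -> None:
    for j, aid in enumerate(task.shown_attributes):
        if aid not in by_id:
            raise DesignError(f"task references unknown attribute {aid}")
        col = task.level_assignment[:, j]
        if col.min() < 1 or col.max() > by_id[aid].n_levels:
            raise DesignError(f"task has out-of-range level for attribute {aid}")


def _assign_levels(
    attr: AttributeSpec,
    n_alts: int,
    level_counts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick ``n_alts`` distinct 1-based levels, preferring least-shown ones."""
    order = np.lexsort((rng.random(attr.n_levels), level_counts))
    chosen = order[:n_alts].copy()
    rng.shuffle(chosen)  # random assignment of the chosen levels to alternatives
    level_counts[chosen] += 1
    return chosen + 1


def _version_tasks(
    attributes: list[AttributeSpec],
    config: DesignConfig,
    version: int,
    rng: np.random.Generator,
) -> list[ChoiceTask]:
    n_attr = len(attributes)
    m = config.attributes_per_task
    queue: list[int] = []
    level_counts = {a.attribute_id: np.zeros(a.n_levels, dtype=int) for a in attributes}
    ids = [a.attribute_id for a in attributes]
    by_id = {a.attribute_id: a for a in attributes}

    tasks = []
    for pos in range(1, config.tasks_per_version + 1):
        shown: list[int] = []
        while len(shown) < m:
            if not queue:
                queue = list(ids)
                rng.shuffle(queue)
            # skip attributes already taken for this task (possible at a
            # queue boundary); they stay due for the next task
            candidates = [a for a in queue if a not in shown]
            if not candidates:  # m > n_attr is excluded by validate()
                queue = []
                continue
            nxt = candidates[0]
            queue.remove(nxt)
            shown.append(nxt)
        grid = np.column_stack(
            [
                _assign_levels(
                    by_id[aid], config.alternatives_per_task, level_counts[aid], rng
                )
                for aid in shown
            ]
        )
        tasks.append(
            ChoiceTask(
                version=version,
                position=pos,
                is_holdout=False,
                shown_attributes=tuple(shown),
                level_assignment=grid,
            )
        )
    return tasks


def generate_design(
    attributes: list[AttributeSpec], config: DesignConfig
) -> dict[int, list[ChoiceTask]]:
    """Generate experimental tasks for every version, keyed by version number.

    Versions are numbered 1..n_versions; each uses an independent RNG
    stream seeded from ``(config.seed, version)``.
    """
    config.validate(attributes)
    design: dict[int, list[ChoiceTask]] = {}
    for version in range(1, config.n_versions + 1):
        rng = np.random.default_rng([config.seed, version])
        design[version] = _version_tasks(attributes, config, version, rng)
    return design


def generate_holdout_tasks(
    attributes: list[AttributeSpec],
    config: DesignConfig,
    n_tasks: int | None = None,
    seed: int | None = None,
) -> list[ChoiceTask]:
    """Generate fixed holdout tasks, identical for every version.

    Uses a dedicated RNG stream (default derived from ``config.seed``) so
    holdouts are stable regardless of how many versions are generated.
    Positions are taken from ``config.holdout_positions``.
    """
    if n_tasks is None:
        n_tasks = len(config.holdout_positions)
    if seed is None:
        seed = config.seed
    config.validate(attributes)
    rng = np.random.default_rng([seed, 999_983])  # fixed auxiliary stream
    by_id = {a.attribute_id: a for a in attributes}
    ids = [a.attribute_id for a in attributes]
    tasks = []
    positions = list(config.holdout_positions) or list(range(1, n_tasks + 1))
    for k in range(n_tasks):
        shown = list(rng.choice(ids, size=config.attributes_per_task, replace=False))
        counts = {aid: np.zeros(by_id[aid].n_levels, dtype=int) for aid in shown}
        grid = np.column_stack(
            [
                _assign_levels(by_id[aid], config.alternatives_per_task, counts[aid], rng)
                for aid in shown
            ]
        )
        tasks.append(
            ChoiceTask(
                version=0,
                position=positions[k] if k < len(positions) else k + 1,
                is_holdout=True,
                shown_attributes=tuple(int(a) for a in shown),
                level_assignment=grid,
            )
        )
    return tasks


def attach_holdouts(
    version_tasks: list[ChoiceTask],
    holdout_tasks: list[ChoiceTask],
    positions: list[int] | tuple[int, ...],
) -> list[ChoiceTask]:
    """Interleave fixed holdout tasks into a version's task sequence.

    Returns a sequence of length ``len(version_tasks) + len(holdout_tasks)``
    with holdouts at exactly the given 1-based positions; experimental
    tasks keep their relative order and are renumbered to fill the
    remaining slots.
    """
    positions = list(positions)
    if len(holdout_tasks) != len(positions):
        raise DesignError("need one position per holdout task")
    if len(set(positions)) != len(positions):
        raise DesignError("duplicate holdout positions")
    if not holdout_tasks:
        return list(version_tasks)
    n_total = len(version_tasks) + len(holdout_tasks)
    for p in positions:
        if not 1 <= p <= n_total:
            raise DesignError(f"holdout position {p} outside 1..{n_total}")
    version = version_tasks[0].version if version_tasks else holdout_tasks[0].version
    holdout_at = dict(zip(positions, holdout_tasks))
    sequence: list[ChoiceTask] = []
    it = iter(version_tasks)
    for pos in range(1, n_total + 1):
        if pos in holdout_at:
            h = holdout_at[pos]
            sequence.append(replace(h, version=version, position=pos, is_holdout=True))
        else:
            t = next(it)
            sequence.append(replace(t, position=pos))
    return sequence


def design_balance_report(
    design: dict[int, list[ChoiceTask]] | list[ChoiceTask],
    attributes: list[AttributeSpec],
) -> dict[str, pd.DataFrame]:
    """Tally level exposures and attribute co-occurrences in a design.

    Returns ``{"levels": ..., "cooccurrence": ...}``; the level table has
    one row per attribute and one column per 1-based level index (zero
    rows are kept for attributes never shown), the co-occurrence table
    counts tasks on which two attributes appear together.
    """
    if isinstance(design, dict):
        tasks = [t for v in design.values() for t in v]
    else:
        tasks = list(design)
    if not tasks:
        raise DesignError("empty design")
    by_id = {a.attribute_id: a for a in attributes}
    max_k = max(a.n_levels for a in attributes)
    ids = [a.attribute_id for a in attributes]
    level_counts = pd.DataFrame(
        0, index=pd.Index(ids, name="attribute_id"), columns=range(1, max_k + 1)
    )
    cooc = pd.DataFrame(0, index=pd.Index(ids, name="attribute_id"), columns=ids)
    for task in tasks:
        _check_task_levels(task, by_id)
        for j, aid in enumerate(task.shown_attributes):
            vals, counts = np.unique(task.level_assignment[:, j], return_counts=True)
            for lv, c in zip(vals, counts):
                level_counts.loc[aid, int(lv)] += int(c)
        for a in task.shown_attributes:
            for b in task.shown_attributes:
                if a != b:
                    cooc.loc[a, b] += 1
    return {"levels": level_counts, "cooccurrence": cooc}


# ---------------------------------------------------------------------------
# I/O

def read_attributes(path: str | Path) -> list[AttributeSpec]:
    """Read an attribute dictionary from a YAML/JSON config file.

    Expected layout::

        attributes:
          - id: 1            # optional; defaults to list order
            name: Supervisor support
            levels: [none, "33%", "67%", "100%"]
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, list):
        entries = data
    else:
        entries = data["attributes"]
    attrs = []
    for i, entry in enumerate(entries, start=1):
        attrs.append(
            AttributeSpec(
                attribute_id=int(entry.get("id", i)),
                name=str(entry["name"]),
                levels=tuple(str(v) for v in entry["levels"]),
            )
        )
    if len({a.attribute_id for a in attrs}) != len(attrs):
        raise DesignError("duplicate attribute ids in attribute file")
    return attrs


def write_attributes(attributes: list[AttributeSpec], path: str | Path) -> None:
    payload = {
        "attributes": [
            {"id": a.attribute_id, "name": a.name, "levels": list(a.levels)}
            for a in attributes
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _design_frame(
    tasks: list[ChoiceTask], attributes: list[AttributeSpec]
) -> pd.DataFrame:
    rows = []
    for task in tasks:
        for alt in range(1, task.n_alternatives + 1):
            row: dict[str, object] = {
                "version": task.version,
                "position": task.position,
                "is_holdout": int(task.is_holdout),
                "alternative": alt,
            }
            for a in attributes:
                lv = task.level_of(a.attribute_id, alt)
                row[a.name] = "" if lv is None else lv
            rows.append(row)
    return pd.DataFrame(rows)


def write_design(
    design: dict[int, list[ChoiceTask]] | list[ChoiceTask],
    attributes: list[AttributeSpec],
    path: str | Path,
) -> None:
    """Write a design as delimited text, one row per (version, position, alternative)."""
    if isinstance(design, dict):
        tasks = [t for v in sorted(design) for t in design[v]]
    else:
        tasks = list(design)
    _design_frame(tasks, attributes).to_csv(path, index=False)


def read_design(
    path: str | Path, attributes: list[AttributeSpec]
) -> dict[int, list[ChoiceTask]]:
    """Read a design written by :func:`write_design`, grouped by version."""
    df = pd.read_csv(path)
    by_id = {a.attribute_id: a for a in attributes}
    design: dict[int, list[ChoiceTask]] = {}
    for (version, position), grp in df.groupby(["version", "position"], sort=True):
        grp = grp.sort_values("alternative")
        shown = [
            a.attribute_id
            for a in attributes
            if grp[a.name].notna().all() and (grp[a.name].astype(str) != "").all()
        ]
        grid = np.column_stack(
            [grp[by_id[aid].name].astype(float).astype(int).to_numpy() for aid in shown]
        )
        task = ChoiceTask(
            version=int(version),
            position=int(position),
            is_holdout=bool(grp["is_holdout"].iloc[0]),
            shown_attributes=tuple(shown),
            level_assignment=grid,
        )
        _check_task_levels(task, by_id)
        design.setdefault(int(version), []).append(task)
    for v in design:
        design[v].sort(key=lambda t: t.position)
    return design
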