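"""Preference-share simulation: first choice and randomized first choice.

Given part-worth utilities, a *scenario* is a set of named product
profiles (full or partial attribute->level maps).  Deterministic first
choice credits each respondent's maximum-utility profile (ties split
equally).  Randomized first choice (RFC) repeats the exercise over many
iterations, perturbing the utilities with two sources of Gumbel error —
one on each attribute-level utility (shared across profiles that use
the level) and one on each profile total — and credits the argmax each
time.  With attribute error only, shares approach first choice smoothed
by attribute uncertainty; with product error of scale 1 only, shares
converge to the conditional-logit (softmax) shares of the profile
utilities.

Monte Carlo standard errors come from batching the iterations into 20
batches.  Sweeps reuse one seed across sweep points (common random
numbers), so a no-op sweep reproduces shares exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ChoiceDataset
from .design import AttributeSpec, ChoiceTask
from .postestimation import IndividualPartWorths, level_offsets

__all__ = [
    "Profile",
    "Scenario",
    "RFCConfig",
    "ShareResult",
    "ScenarioError",
    "read_scenario",
    "rfc_shares",
    "rfc_shares_by_class",
    "sensitivity_sweep",
    "predict_holdout_shares",
    "observed_holdout_shares",
    "mean_absolute_error",
    "holdout_mae",
]


class ScenarioError(ValueError):
    """Raised for profiles referencing unknown attributes or levels."""


@dataclass(frozen=True)
class Profile:
    """A named product profile: attribute -> level (possibly partial)."""

    name: str
    levels: dict[int | str, int | str] = field(default_factory=dict)


@dataclass(frozen=True)
class Scenario:
    """A share-simulation scenario: two or more competing profiles."""

    profiles: tuple[Profile, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if len(self.profiles) < 2:
            raise ScenarioError("a scenario needs at least two profiles")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ScenarioError("profile names must be unique")

    def resolve(self, attributes: list[AttributeSpec]) -> list[dict[int, int]]:
        """Map each profile to {attribute_id: 1-based level index}."""
        by_id = {a.attribute_id: a for a in attributes}
        by_name = {a.name: a for a in attributes}
        resolved = []
        for prof in self.profiles:
            levels: dict[int, int] = {}
            for akey, lkey in prof.levels.items():
                attr = by_id.get(akey) if isinstance(akey, int) else by_name.get(akey)
                if attr is None:
                    raise ScenarioError(f"profile {prof.name!r}: unknown attribute {akey!r}")
                if isinstance(lkey, str) and lkey in attr.levels:
                    level = attr.levels.index(lkey) + 1
                else:
                    try:
                        level = int(lkey)
                    except (TypeError, ValueError):
                        raise ScenarioError(
                            f"profile {prof.name!r}: unknown level {lkey!r} "
                            f"for attribute {attr.name!r}"
                        ) from None
                    if not 1 <= level <= attr.n_levels:
                        raise ScenarioError(
                            f"profile {prof.name!r}: level {level} out of range "
                            f"for attribute {attr.name!r}"
                        )
                if attr.attribute_id in levels:
                    raise ScenarioError(
                        f"profile {prof.name!r}: attribute {attr.name!r} repeated"
                    )
                levels[attr.attribute_id] = level
            resolved.append(levels)
        return resolved


def read_scenario(path: str | Path) -> Scenario:
    """Read a scenario config (YAML/JSON): list of named profiles."""
    data = yaml.safe_load(Path(path).read_text())
    entries = data["profiles"] if isinstance(data, dict) else data
    profiles = [
        Profile(name=str(e["name"]), levels=dict(e.get("levels", {}))) for e in entries
    ]
    return Scenario(tuple(profiles))


@dataclass(frozen=True)
class RFCConfig:
    """Randomized first choice settings.

    ``iterations`` is the total number of respondent-draws; each
    respondent receives ``iterations / n_respondents`` draws.  Error
    scales are Gumbel scale parameters; a scale of 0 disables that error
    source entirely (zero on both recovers deterministic first choice).
    """

    iterations: int = 200_000
    attribute_error_scale: float = 1.0
    product_error_scale: float = 0.0
    seed: int = 0
    n_batches: int = 20

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.attribute_error_scale < 0 or self.product_error_scale < 0:
            raise ValueError("error scales must be >= 0")
        if not (np.isfinite(self.attribute_error_scale) and np.isfinite(self.product_error_scale)):
            raise ValueError("error scales must be finite")


@dataclass
class ShareResult:
    """Preference shares (percent) with Monte Carlo standard errors."""

    profile_names: list[str]
    shares: np.ndarray                       # (J,) percent, overall
    se: np.ndarray                           # (J,)
    class_shares: dict[int, np.ndarray]      # per class label, percent
    class_se: dict[int, np.ndarray]
    n_draws_per_respondent: int
    config: RFCConfig

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"profile": n, "group": "total", "share": s, "se": e}
            for n, s, e in zip(self.profile_names, self.shares, self.se)
        ]
        for label in sorted(self.class_shares):
            rows.extend(
                {"profile": n, "group": f"class{label}", "share": s, "se": e}
                for n, s, e in zip(
                    self.profile_names, self.class_shares[label], self.class_se[label]
                )
            )
        return pd.DataFrame(rows)


def _profile_matrix(
    scenario: Scenario, attributes: list[AttributeSpec]
) -> tuple[np.ndarray, list[str]]:
    """0/1 indicator (n_levels_total, J): which flat levels each profile uses."""
    offsets = level_offsets(attributes)
    total = sum(a.n_levels for a in attributes)
    resolved = scenario.resolve(attributes)
    B = np.zeros((total, len(resolved)))
    for j, levels in enumerate(resolved):
        for aid, lv in levels.items():
            B[offsets[aid] + lv - 1, j] = 1.0
    return B, [p.name for p in scenario.profiles]


def _group_shares(
    credits: np.ndarray, weights: np.ndarray, labels: np.ndarray | None
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """credits: (N, J) per-respondent credit fractions summing to 1 per row."""
    total = 100.0 * (weights @ credits) / weights.sum()
    per_class: dict[int, np.ndarray] = {}
    if labels is not None:
        for lab in np.unique(labels):
            mask = labels == lab
            per_class[int(lab)] = 100.0 * (
                weights[mask] @ credits[mask]
            ) / weights[mask].sum()
    return total, per_class


def _first_choice_credits(base: np.ndarray) -> np.ndarray:
    """Deterministic argmax credits, ties split equally: (N, J) rows sum to 1."""
    best = base.max(axis=1, keepdims=True)
    is_max = np.isclose(base, best, rtol=0.0, atol=1e-12)
    return is_max / is_max.sum(axis=1, keepdims=True)


def _simulate(
    values: np.ndarray,
    weights: np.ndarray,
    labels: np.ndarray | None,
    scenario: Scenario,
    attributes: list[AttributeSpec],
    config: RFCConfig,
) -> ShareResult:
    B, names = _profile_matrix(scenario, attributes)
    n, n_levels = values.shape
    j = B.shape[1]
    base = values @ B  # (N, J)
    s_attr, s_prod = config.attribute_error_scale, config.product_error_scale

    if s_attr == 0.0 and s_prod == 0.0:
        credits = _first_choice_credits(base)
        total, per_class = _group_shares(credits, weights, labels)
        zeros = np.zeros(j)
        return ShareResult(
            names, total, zeros,
            per_class, {k: np.zeros(j) for k in per_class},
            n_draws_per_respondent=1, config=config,
        )

    draws = max(1, round(config.iterations / n))
    n_batches = min(config.n_batches, draws)
    per_batch = np.full(n_batches, draws // n_batches)
    per_batch[: draws % n_batches] += 1
    rng = np.random.default_rng([config.seed, 424_243])

    batch_total = np.empty((n_batches, j))
    batch_class: dict[int, np.ndarray] = {}
    if labels is not None:
        batch_class = {int(lab): np.empty((n_batches, j)) for lab in np.unique(labels)}
    rows = np.arange(n)
    for b, nb in enumerate(per_batch):
        counts = np.zeros((n, j))
        for _ in range(int(nb)):
            util = base.copy()
            if s_attr > 0.0:
                # noise on every level utility, shared across profiles
                # using that level; drawing the full level set keeps the
                # random-number stream aligned across sweep points
                eps = rng.gumbel(0.0, s_attr, size=(n, n_levels))
                util += eps @ B
            if s_prod > 0.0:
                util += rng.gumbel(0.0, s_prod, size=(n, j))
            counts[rows, util.argmax(axis=1)] += 1.0
        credits = counts / nb
        batch_total[b], per_class = _group_shares(credits, weights, labels)
        for lab, arr in per_class.items():
            batch_class[lab][b] = arr

    total = batch_total.mean(axis=0)
    se = batch_total.std(axis=0, ddof=1) / np.sqrt(n_batches) if n_batches > 1 else np.zeros(j)
    class_shares = {lab: m.mean(axis=0) for lab, m in batch_class.items()}
    class_se = {
        lab: (m.std(axis=0, ddof=1) / np.sqrt(n_batches) if n_batches > 1 else np.zeros(j))
        for lab, m in batch_class.items()
    }
    return ShareResult(
        names, total, se, class_shares, class_se,
        n_draws_per_respondent=draws, config=config,
    )


def rfc_shares(
    scenario: Scenario,
    partworths: IndividualPartWorths,
    config: RFCConfig | None = None,
    class_labels: np.ndarray | None = None,
) -> ShareResult:
    """Randomized first choice shares from individual part-worths.

    ``class_labels`` (1-based, one per respondent, e.g. from
    :func:`partworth.latent_class.posterior_assign`) adds per-class
    share breakdowns to the result.
    """
    config = config or RFCConfig()
    if class_labels is not None:
        class_labels = np.asarray(class_labels)
        if len(class_labels) != partworths.n_respondents:
            raise ValueError("class_labels length must match respondents")
    weights = np.ones(partworths.n_respondents)
    return _simulate(
        partworths.values, weights, class_labels, scenario, partworths.attributes, config
    )


def rfc_shares_by_class(
    scenario: Scenario,
    class_utilities: np.ndarray,
    shares: np.ndarray,
    attributes: list[AttributeSpec],
    config: RFCConfig | None = None,
) -> ShareResult:
    """Class-level mode: each class acts as one pseudo-respondent weighted
    by its share (for when posteriors/individual utilities are unavailable)."""
    config = config or RFCConfig()
    cu = np.atleast_2d(np.asarray(class_utilities, dtype=float))
    labels = np.arange(1, cu.shape[0] + 1)
    return _simulate(cu, np.asarray(shares, dtype=float), labels, scenario, attributes, config)


def sensitivity_sweep(
    scenario: Scenario,
    target_profile: str,
    attribute: int | str,
    levels: list[int | str],
    partworths: IndividualPartWorths,
    config: RFCConfig | None = None,
    class_labels: np.ndarray | None = None,
) -> dict[int | str, ShareResult]:
    """Re-simulate the scenario varying one attribute of one profile.

    All sweep points share the same seed (common random numbers), so
    differences between points reflect the level change, not Monte Carlo
    noise, and sweeping to the current level is a no-op.
    """
    config = config or RFCConfig()
    names = [p.name for p in scenario.profiles]
    if target_profile not in names:
        raise ScenarioError(f"unknown profile {target_profile!r}")
    out: dict[int | str, ShareResult] = {}
    for level in levels:
        profiles = []
        for p in scenario.profiles:
            if p.name == target_profile:
                new_levels = {k: v for k, v in p.levels.items()}
                new_levels[attribute] = level
                profiles.append(Profile(p.name, new_levels))
            else:
                profiles.append(p)
        out[level] = rfc_shares(Scenario(tuple(profiles)), partworths, config, class_labels)
    return out


# ---------------------------------------------------------------------------
# holdout validation

def _task_scenario(task: ChoiceTask) -> Scenario:
    profiles = []
    for alt in range(1, task.n_alternatives + 1):
        levels = {
            int(aid): int(task.level_assignment[alt - 1, j])
            for j, aid in enumerate(task.shown_attributes)
        }
        profiles.append(Profile(f"option {alt}", levels))
    return Scenario(tuple(profiles))


def predict_holdout_shares(
    partworths: IndividualPartWorths,
    holdout_tasks: list[ChoiceTask],
    config: RFCConfig | None = None,
    class_labels: np.ndarray | None = None,
) -> dict[int, ShareResult]:
    """Simulate each holdout task as a scenario of its alternatives.

    Holdout content is identical across versions, so tasks are keyed by
    position; duplicate (position, content) entries collapse to one.
    """
    config = config or RFCConfig()
    unique: dict[int, ChoiceTask] = {}
    for task in holdout_tasks:
        prev = unique.get(task.position)
        if prev is not None and prev.content_key() != task.content_key():
            raise ScenarioError(
                f"holdout tasks at position {task.position} differ across versions"
            )
        unique.setdefault(task.position, task)
    return {
        pos: rfc_shares(_task_scenario(task), partworths, config, class_labels)
        for pos, task in sorted(unique.items())
    }


def observed_holdout_shares(holdout: ChoiceDataset) -> dict[int, np.ndarray]:
    """Percent of respondents actually choosing each alternative, per task."""
    counts: dict[int, np.ndarray] = {}
    for obs in holdout.observations:
        task = holdout.tasks[(obs.version, obs.position)]
        arr = counts.setdefault(task.position, np.zeros(task.n_alternatives))
        arr[obs.chosen_alternative - 1] += 1
    return {
        pos: 100.0 * arr / arr.sum() for pos, arr in sorted(counts.items())
    }


def mean_absolute_error(predicted, observed) -> float:
    """Mean absolute difference between paired share vectors (percent)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"mismatched share vectors: {p.shape} vs {o.shape}")
    return float(np.abs(p - o).mean())


def holdout_mae(
    predicted: dict[int, ShareResult | np.ndarray],
    observed: dict[int, np.ndarray],
) -> tuple[dict[int, float], float]:
    """Per-task MAE of predicted vs observed shares and the overall mean."""
    if set(predicted) != set(observed):
        raise ValueError("predicted and observed tasks do not match")
    per_task = {}
    for pos in sorted(predicted):
        pred = predicted[pos]
        vec = pred.shares if isinstance(pred, ShareResult) else pred
        per_task[pos] = mean_absolute_error(vec, observed[pos])
    overall = float(np.mean(list(per_task.values())))
    return per_task, overall
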