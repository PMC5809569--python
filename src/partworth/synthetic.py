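"""Synthetic choice data: conditional-logit mixture respondents.

Generates datasets with the statistical structure the estimator assumes:
each respondent belongs to one of S preference segments, sees one
version of a partial-profile design (experimental tasks plus fixed
holdout tasks), and chooses within every task from the conditional-logit
probabilities implied by scale * (segment utilities).

The built-in :func:`ebp_preset` transcribes a published two-segment
solution from a discrete choice experiment on the implementation of
evidence-based children's mental health practices (EBPs): 14 attributes
x 4 levels, segment shares 12% / 88%, with zero-centered part-worth
utilities per segment.  With its defaults —  563 respondents, 18
experimental tasks plus holdouts at positions 6 and 14, three
alternatives showing three attributes each, 999 survey versions — the
generator emulates that study's instrument end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data import ChoiceDataset, ChoiceObservation, split_holdout
from .design import (
    AttributeSpec,
    ChoiceTask,
    DesignConfig,
    attach_holdouts,
    generate_design,
    generate_holdout_tasks,
)
from .latent_class import LatentClassSolution, fit_latent_class, posterior_assign
from .postestimation import class_utilities, level_offsets

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "RecoveryReport",
    "ebp_preset",
    "ebp_training_scenarios",
    "default_config",
    "simulate_respondents",
    "recovery_experiment",
]


# ---------------------------------------------------------------------------
# preset: published two-segment EBP implementation solution
#
# (attribute name, 4 level labels, segment-1 utilities, segment-2 utilities)
# Utilities are zero-centered part-worths as printed (2 dp); per-attribute
# sums deviate from 0 by at most 0.01 from rounding and are re-centered
# exactly on load.

_EBP_TABLE = [
    ("Supervisor support for EBP",
     ("My supervisor does not support this EBP",
      "My supervisor supports this EBP 33%",
      "My supervisor supports this EBP 67%",
      "My supervisor supports this EBP 100%"),
     (-0.97, -0.02, 0.12, 0.87), (-1.42, -0.19, 0.59, 1.02)),
    ("Colleague support for EBP",
     ("0% of my colleagues support this EBP",
      "33% of my colleagues support this EBP",
      "67% of my colleagues support this EBP",
      "100% of my colleagues support this EBP"),
     (-0.81, -0.37, 0.53, 0.65), (-1.59, 0.09, 0.70, 0.80)),
    ("Trainers expertise and engagingness",
     ("Trainer is not engaging nor an expert",
      "Trainer is engaging but not an expert",
      "Trainer is an expert but not engaging",
      "Trainer is an engaging expert"),
     (-0.57, -0.09, -0.06, 0.72), (-1.71, 0.02, 0.01, 1.68)),
    ("Percent of clients benefiting",
     ("Would benefit 25% of clients",
      "Would benefit 50% of clients",
      "Would benefit 75% of clients",
      "Would benefit 100% of clients"),
     (-0.92, -0.49, 0.57, 0.84), (-1.49, -0.24, 0.57, 1.17)),
    ("Effectiveness in other agencies",
     ("Proven in research settings, but untested in agencies",
      "Proven in research settings and 1 agency",
      "Proven in research settings and 5 agencies",
      "Proven in research settings and 10 agencies"),
     (-0.58, 0.02, 0.16, 0.40), (-1.22, -0.32, 0.57, 0.96)),
    ("Modifiability of EBP",
     ("Modifications in this EBP are not allowed",
      "Minor modifications in this EBP are allowed",
      "Moderate modifications in this EBP are allowed",
      "Major modifications in this EBP are allowed"),
     (-0.01, 0.26, -0.11, -0.14), (-1.28, 0.39, 0.75, 0.14)),
    ("Control over selection of EBPs",
     ("Individual professionals select the EBP they will learn",
      "Individual programs within agencies select the EBP",
      "Individual agencies select the EBP they will learn",
      "Provincial ministry mandates the EBP professionals will learn"),
     (-0.19, 0.18, 0.08, -0.07), (0.18, 0.44, 0.32, -0.94)),
    ("Percent change to current practice",
     ("Requires 25% change in current practice",
      "Requires 50% change in current practice",
      "Requires 75% change in current practice",
      "Requires 100% change in current practice"),
     (-0.11, 0.07, 0.02, 0.02), (0.76, 0.58, -0.11, -1.23)),
    ("Training focus on knowledge versus skill",
     ("Training focuses 100% on knowledge",
      "Training focuses 67% on knowledge, 33% on step-by-step skills",
      "Training focuses 33% on knowledge, 67% on step-by-step skills",
      "Training focuses 100% on step-by-step skills"),
     (-0.82, 0.02, 0.68, 0.12), (-1.15, 0.39, 0.66, 0.11)),
    ("Initial training via the internet",
     ("No internet learning option",
      "33% of initial training can be completed online",
      "66% of initial training can be completed online",
      "100% of initial training can be completed online"),
     (-0.80, -0.13, 0.38, 0.55), (0.19, 0.50, 0.03, -0.72)),
    ("Active versus passive training process",
     ("Participants don't observe, practice, nor get feedback",
      "Participants observe new skills",
      "Participants observe and practice new skills",
      "Participants observe, practice, and get feedback on new skills"),
     (-0.68, -0.17, 0.26, 0.60), (-1.70, -0.15, 0.75, 1.11)),
    ("Follow-up training",
     ("Includes 0 training follow-ups",
      "Includes a 1-day training follow-up",
      "Includes two 1-day training follow-ups",
      "Includes three 1-day training follow-ups"),
     (-0.69, 0.38, 0.12, 0.19), (-0.82, 0.21, 0.41, 0.20)),
    ("Training group size",
     ("I learn this alone",
      "I learn this in a group of 10",
      "I learn this in a group of 50",
      "I learn this in a group of 100"),
     (-0.06, 0.24, 0.05, -0.23), (-0.84, 0.89, 0.34, -0.39)),
    ("Initial training time demands",
     ("Initial training requires 1 day",
      "Initial training requires 2 days",
      "Initial training requires 3 days",
      "Initial training requires 4 days"),
     (-0.23, -0.05, 0.13, 0.15), (-0.03, 0.19, -0.01, -0.15)),
]

_EBP_SHARES = (0.12, 0.88)


def ebp_preset(
    recenter: bool = True,
) -> tuple[list[AttributeSpec], np.ndarray, np.ndarray]:
    """The built-in EBP implementation preset.

    Returns ``(attributes, segment_shares, segment_utilities)`` where
    ``segment_utilities`` has shape (2, 56): two segments by 14x4 flat
    expanded level utilities.  ``recenter=False`` returns the utilities
    as printed (per-attribute sums off zero by up to 0.01 from 2-dp
    rounding); the default subtracts each attribute's mean so sums are
    exactly zero.
    """
    attributes = [
        AttributeSpec(i + 1, name, levels)
        for i, (name, levels, _u1, _u2) in enumerate(_EBP_TABLE)
    ]
    raw = np.array(
        [
            [u for (_n, _l, u1, _u2) in _EBP_TABLE for u in u1],
            [u for (_n, _l, _u1, u2) in _EBP_TABLE for u in u2],
        ]
    )
    if recenter:
        out = raw.copy()
        pos = 0
        for _name, levels, _u1, _u2 in _EBP_TABLE:
            k = len(levels)
            block = out[:, pos : pos + k]
            out[:, pos : pos + k] = block - block.mean(axis=1, keepdims=True)
            pos += k
        raw = out
    return attributes, np.asarray(_EBP_SHARES), raw


def ebp_training_scenarios() -> tuple["Scenario", str]:
    """Basic vs enhanced training scenarios from the EBP study's simulations.

    Basic: 2 days initial training, two 1-day follow-ups, training 67%
    knowledge / 33% skills, 25% change in practice.  Enhanced: 4 days
    initial training, the maximum follow-up level (three 1-day
    follow-ups), 67% skills, 50% change.  Returns the scenario and the
    name of the supervisor-support attribute used for sensitivity sweeps.
    """
    from .simulate import Profile, Scenario

    basic = Profile(
        "Basic implementation",
        {
            "Initial training time demands": 2,
            "Follow-up training": 3,
            "Training focus on knowledge versus skill": 2,
            "Percent change to current practice": 1,
        },
    )
    enhanced = Profile(
        "Enhanced implementation",
        {
            "Initial training time demands": 4,
            "Follow-up training": 4,
            "Training focus on knowledge versus skill": 3,
            "Percent change to current practice": 2,
        },
    )
    return Scenario((basic, enhanced)), "Supervisor support for EBP"


# ---------------------------------------------------------------------------
# generator

@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults replicate the EBP study's structure: 563 respondents,
    segment shares 0.12/0.88, an 18-task 999-version partial-profile
    design with two fixed holdouts at positions 6 and 14, and utilities
    on the printed part-worth scale (``scale`` multiplies them; larger
    values mean less choice noise).  ``respondent_jitter`` adds optional
    N(0, jitter) respondent-level perturbation to each level utility, a
    misspecification toggle that defaults off.
    """

    attributes: list[AttributeSpec]
    segment_shares: np.ndarray
    segment_utilities: np.ndarray  # (S, sum_a K_a) expanded, zero-sum per attribute
    design: DesignConfig = field(
        default_factory=lambda: DesignConfig(
            n_versions=999,
            tasks_per_version=18,
            alternatives_per_task=3,
            attributes_per_task=3,
            holdout_positions=(6, 14),
            seed=0,
        )
    )
    n_respondents: int = 563
    scale: float = 1.0
    respondent_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.segment_shares = np.asarray(self.segment_shares, dtype=float)
        self.segment_utilities = np.atleast_2d(
            np.asarray(self.segment_utilities, dtype=float)
        )
        if not np.isclose(self.segment_shares.sum(), 1.0):
            raise ValueError("segment shares must sum to 1")
        total = sum(a.n_levels for a in self.attributes)
        if self.segment_utilities.shape != (len(self.segment_shares), total):
            raise ValueError(
                f"segment_utilities must be (n_segments, {total}), "
                f"got {self.segment_utilities.shape}"
            )
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Study-scale configuration from the EBP preset."""
    attributes, shares, utilities = ebp_preset()
    cfg = SyntheticConfig(
        attributes=attributes,
        segment_shares=shares,
        segment_utilities=utilities,
        seed=seed,
    )
    if "design" not in overrides:
        cfg.design = replace(cfg.design, seed=seed)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests.

    ``segments`` are 1-based generating labels; ``choice_probabilities``
    holds the generator's per-task choice probabilities, aligned with
    ``positions`` (the full task sequence each respondent saw).
    """

    respondent_ids: list[str]
    segments: np.ndarray     # (N,)
    versions: np.ndarray     # (N,)
    positions: list[int]
    choice_probabilities: np.ndarray  # (N, n_tasks, n_alternatives)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "respondent_id": self.respondent_ids,
                "segment": self.segments,
                "version": self.versions,
            }
        )


def _task_utilities(
    task: ChoiceTask,
    flat_utils: np.ndarray,
    offsets: dict[int, int],
) -> np.ndarray:
    """Sum of expanded level utilities per alternative, (n_alts,)."""
    u = np.zeros(task.n_alternatives)
    for j, aid in enumerate(task.shown_attributes):
        u += flat_utils[offsets[aid] + task.level_assignment[:, j] - 1]
    return u


def simulate_respondents(
    config: SyntheticConfig,
) -> tuple[ChoiceDataset, SyntheticTruth]:
    """Draw a full synthetic choice dataset plus its generating truth.

    Each respondent: segment ~ segment_shares, version ~ uniform, then a
    conditional-logit choice on every task (holdouts included) with
    utilities scale * (segment utilities).  Holdout tasks are generated
    once from an auxiliary stream, so every respondent sees the same
    holdout options regardless of version.
    """
    rng = np.random.default_rng([config.seed, 101])
    design = generate_design(config.attributes, config.design)
    holdouts = generate_holdout_tasks(config.attributes, config.design)
    sequences = {
        v: attach_holdouts(tasks, holdouts, config.design.holdout_positions)
        for v, tasks in design.items()
    }
    offsets = level_offsets(config.attributes)
    n = config.n_respondents
    n_seg = len(config.segment_shares)
    segments = rng.choice(n_seg, size=n, p=config.segment_shares) + 1
    versions = rng.integers(1, config.design.n_versions + 1, size=n)
    n_tasks = config.design.tasks_per_version + len(config.design.holdout_positions)
    n_alts = config.design.alternatives_per_task

    tasks: dict[tuple[int, int], ChoiceTask] = {}
    observations: list[ChoiceObservation] = []
    probs = np.empty((n, n_tasks, n_alts))
    width = len(str(n))
    positions = [t.position for t in next(iter(sequences.values()))]
    for i in range(n):
        rid = f"R{i + 1:0{width}d}"
        flat = config.segment_utilities[segments[i] - 1]
        if config.respondent_jitter > 0:
            flat = flat + rng.normal(0.0, config.respondent_jitter, size=flat.shape)
        seq = sequences[versions[i]]
        for t_idx, task in enumerate(seq):
            tasks.setdefault(task.key, task)
            u = config.scale * _task_utilities(task, flat, offsets)
            u = u - u.max()
            p = np.exp(u)
            p /= p.sum()
            probs[i, t_idx] = p
            chosen = int(rng.choice(n_alts, p=p)) + 1
            observations.append(
                ChoiceObservation(rid, int(versions[i]), task.position, chosen)
            )
    dataset = ChoiceDataset(list(config.attributes), tasks, observations)
    truth = SyntheticTruth(
        respondent_ids=[f"R{i + 1:0{width}d}" for i in range(n)],
        segments=segments,
        versions=versions,
        positions=positions,
        choice_probabilities=probs,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# recovery harness

@dataclass
class RecoveryReport:
    """How well estimation recovered the generating mixture."""

    true_shares: np.ndarray
    estimated_shares: np.ndarray       # reordered to match true segments
    share_error: float                 # max abs error over segments
    utility_correlations: np.ndarray   # Pearson r per matched segment
    classification_accuracy: float
    class_order: np.ndarray            # estimated class matched to each true segment
    solution: LatentClassSolution
    dataset: ChoiceDataset
    truth: SyntheticTruth


def recovery_experiment(
    config: SyntheticConfig,
    n_classes: int | None = None,
    n_starts: int = 10,
    fit_seed: int = 0,
    **fit_kwargs,
) -> RecoveryReport:
    """Simulate, fit, match labels, and score parameter recovery.

    Estimated classes are matched to generating segments by maximizing
    total Pearson correlation between expanded utilities (Hungarian
    assignment), which resolves label switching before scoring.
    """
    if len(config.segment_shares) < 2:
        raise ValueError("recovery experiment needs >= 2 segments")
    if n_classes is None:
        n_classes = len(config.segment_shares)
    dataset, truth = simulate_respondents(config)
    estimation, _holdout = split_holdout(dataset)
    fit_kwargs.setdefault("compute_se", False)
    solution = fit_latent_class(
        estimation, n_classes, n_starts=n_starts, seed=fit_seed, **fit_kwargs
    )
    est_utils = class_utilities(solution)
    true_utils = config.scale * config.segment_utilities
    n_seg, n_cls = true_utils.shape[0], est_utils.shape[0]
    corr = np.empty((n_seg, n_cls))
    for s in range(n_seg):
        for c in range(n_cls):
            corr[s, c] = np.corrcoef(true_utils[s], est_utils[c])[0, 1]
    row, col = linear_sum_assignment(-corr)
    order = col[np.argsort(row)]

    est_shares = solution.shares[order]
    share_error = float(np.abs(est_shares - config.segment_shares).max())
    matched_corr = corr[np.arange(n_seg), order]

    labels = posterior_assign(solution)  # 1-based estimated classes
    # translate estimated labels into true-segment space via the matching
    seg_of_class = {int(order[s]) + 1: s + 1 for s in range(n_seg)}
    mapped = np.array([seg_of_class.get(int(lab), -1) for lab in labels])
    id_to_seg = dict(zip(truth.respondent_ids, truth.segments))
    true_for_fit = np.array([id_to_seg[r] for r in solution.respondent_ids])
    accuracy = float(np.mean(mapped == true_for_fit))

    return RecoveryReport(
        true_shares=np.asarray(config.segment_shares),
        estimated_shares=est_shares,
        share_error=share_error,
        utility_correlations=matched_corr,
        classification_accuracy=accuracy,
        class_order=order,
        solution=solution,
        dataset=dataset,
        truth=truth,
    )
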