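"""Zero-centered utilities, attribute importance, individual part-worths.

Effects-coded coefficients hold K-1 free values per K-level attribute;
the omitted last level's utility is minus their sum, so every
attribute's K level utilities sum to zero.  An attribute's *importance*
within a class is its utility range (max - min level utility) as a
percentage of the sum of all attribute ranges — the share of the total
achievable utility swing the attribute controls.  Individual part-worths
are posterior-weighted mixtures of the class utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AttributeSpec
from .latent_class import LatentClassSolution

__all__ = [
    "expand_utilities",
    "class_utilities",
    "utilities_frame",
    "importance_scores",
    "IndividualPartWorths",
    "individual_partworths",
    "level_offsets",
]


def expand_utilities(coefficients: np.ndarray, n_levels: int) -> np.ndarray:
    """Expand one attribute's K-1 effects coefficients to K zero-sum utilities."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape[-1] != n_levels - 1:
        raise ValueError(f"expected {n_levels - 1} coefficients, got {coefficients.shape[-1]}")
    last = -coefficients.sum(axis=-1, keepdims=True)
    return np.concatenate([coefficients, last], axis=-1)


def level_offsets(attributes: list[AttributeSpec]) -> dict[int, int]:
    """Offset of each attribute's first level in the flat expanded vector."""
    offsets, pos = {}, 0
    for a in attributes:
        offsets[a.attribute_id] = pos
        pos += a.n_levels
    return offsets


def _total_levels(attributes: list[AttributeSpec]) -> int:
    return sum(a.n_levels for a in attributes)


def class_utilities(solution: LatentClassSolution) -> np.ndarray:
    """Expanded zero-centered level utilities, shape (C, sum_a K_a).

    Levels are laid out attribute by attribute in attribute-list order;
    use :func:`level_offsets` to index into the flat axis.
    """
    attrs = solution.attributes
    C = solution.n_classes
    out = np.empty((C, _total_levels(attrs)))
    col, pos = 0, 0
    for a in attrs:
        k = a.n_levels
        block = solution.coefficients[:, col : col + k - 1]
        out[:, pos : pos + k] = expand_utilities(block, k)
        col += k - 1
        pos += k
    return out


def utilities_frame(
    utilities: np.ndarray, attributes: list[AttributeSpec]
) -> pd.DataFrame:
    """Long-format view of an expanded-utility matrix (classes x levels)."""
    utilities = np.atleast_2d(utilities)
    offsets = level_offsets(attributes)
    rows = []
    for a in attributes:
        for lv in range(a.n_levels):
            row = {"attribute": a.name, "level": a.levels[lv]}
            for c in range(utilities.shape[0]):
                row[f"class{c + 1}"] = utilities[c, offsets[a.attribute_id] + lv]
            rows.append(row)
    return pd.DataFrame(rows)


def importance_scores(
    utilities: np.ndarray, attributes: list[AttributeSpec]
) -> pd.DataFrame:
    """Attribute importance and rank per class from expanded utilities.

    ``utilities`` is (C, sum_a K_a) as returned by :func:`class_utilities`
    (a single class may be passed as a 1-D vector).  For class c,
    ``I_a = 100 * range_a / sum_a' range_a'``; ranks order descending
    importance with ties going to the earlier-listed attribute.
    """
    utilities = np.atleast_2d(np.asarray(utilities, dtype=float))
    offsets = level_offsets(attributes)
    n_attr = len(attributes)
    C = utilities.shape[0]
    ranges = np.empty((C, n_attr))
    for j, a in enumerate(attributes):
        block = utilities[:, offsets[a.attribute_id] : offsets[a.attribute_id] + a.n_levels]
        ranges[:, j] = block.max(axis=1) - block.min(axis=1)
    totals = ranges.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("all attribute ranges are zero; importance undefined")
    importance = 100.0 * ranges / totals[:, None]
    frames = []
    for c in range(C):
        order = np.argsort(-importance[c], kind="stable")
        rank = np.empty(n_attr, dtype=int)
        rank[order] = np.arange(1, n_attr + 1)
        frames.append(
            pd.DataFrame(
                {
                    "attribute": [a.name for a in attributes],
                    "class": c + 1,
                    "range": ranges[c],
                    "importance": importance[c],
                    "rank": rank,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class IndividualPartWorths:
    """Per-respondent expanded level utilities (posterior-weighted)."""

    values: np.ndarray  # (n_resp, sum_a K_a)
    respondent_ids: list[str]
    attributes: list[AttributeSpec]

    @property
    def offsets(self) -> dict[int, int]:
        return level_offsets(self.attributes)

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]


def individual_partworths(solution: LatentClassSolution) -> IndividualPartWorths:
    """Posterior-weighted individual utilities: u_i = sum_c h_ic u_c.

    A weighted average of zero-sum vectors, so each respondent's per-
    attribute zero-sum is preserved.
    """
    cu = class_utilities(solution)  # (C, L)
    values = solution.posterior @ cu
    return IndividualPartWorths(
        values=values,
        respondent_ids=list(solution.respondent_ids),
        attributes=list(solution.attributes),
    )
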