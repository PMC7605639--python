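"""Per-pair index systems: covariates screened by q-statistic.

A variable enters a pair's index system when its q exceeds a threshold
(default 0.3, strict inequality); the system keeps at most the top k
(default 4) by descending q, ties broken by ascending variable name so the
selection is deterministic.  If fewer than k variables pass, the shorter
system is returned with a warning flag rather than padded below threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .grid_model import PairSpec


class EmptyIndexSystemError(ValueError):
    """No variable exceeded the q threshold."""


@dataclass
class IndexSystem:
    pair: PairSpec | None
    variables: list[str]
    q_values: dict[str, float]
    threshold: float = 0.3
    k: int = 4
    short: bool = False  # fewer than k variables passed the threshold

    def __post_init__(self) -> None:
        if len(self.variables) > self.k:
            raise ValueError("index system longer than k")
        qs = [self.q_values[v] for v in self.variables]
        if any(q <= self.threshold for q in qs):
            raise ValueError("index system contains a variable at or below threshold")
        if qs != sorted(qs, reverse=True):
            raise ValueError("index system not sorted by descending q")


def select_index_system(
    qcolumn: Mapping[str, float],
    threshold: float = 0.3,
    k: int = 4,
    pair: PairSpec | None = None,
) -> IndexSystem:
    """Apply the strict-threshold / top-k rule to one pair's q column."""
    if not qcolumn:
        raise ValueError("qcolumn must be nonempty")
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    passed = [(name, q) for name, q in qcolumn.items() if q > threshold]
    if not passed:
        raise EmptyIndexSystemError(
            f"no variable has q > {threshold}: empty index system"
        )
    passed.sort(key=lambda item: (-item[1], item[0]))
    short = len(passed) < k
    if short:
        warnings.warn(
            f"only {len(passed)} of the requested {k} variables exceed "
            f"q > {threshold}",
            stacklevel=2,
        )
    chosen = passed[:k]
    return IndexSystem(
        pair=pair,
        variables=[name for name, _ in chosen],
        q_values=dict(chosen),
        threshold=threshold,
        k=k,
        short=short,
    )
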