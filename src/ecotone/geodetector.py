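"""Factor-detector q-statistic over stratified samples.

The q-statistic measures spatial stratified heterogeneity: how much of a
variable's variance a stratification explains,

    q = 1 - (sum_h N_h * sigma_h^2) / (N * sigma^2),

with *population* variances (denominators N_h and N), so that q reduces
exactly to 1 - SSW/SST, the one-way-ANOVA eta-squared.  q = 0 means the
strata explain nothing; q = 1 means every stratum is internally constant.
Here the strata are vegetation classes (2 strata for a pair, 3 for the
zone characterisation) and y is an environmental covariate.

Significance is assessed with a seeded permutation test: stratum labels
are shuffled uniformly and the observed q is compared against the null
distribution of permuted q values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_model import CovariateStack, VegetationOccurrence, extract_labeled_pixels


class InsufficientStrataError(ValueError):
    """q needs at least two strata, each with at least one sample."""


@dataclass
class StratifiedSample:
    """A numeric variable y partitioned into L strata by labels h.

    Stratum labels may be any integers; L is the number of distinct labels
    present.  Population variances (divide-by-N) are used throughout.
    """

    y: np.ndarray
    h: np.ndarray
    strata: np.ndarray = field(init=False)
    N: int = field(init=False)
    N_h: np.ndarray = field(init=False)
    sigma2: float = field(init=False)
    sigma2_h: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.h = np.asarray(self.h).ravel()
        if self.y.shape != self.h.shape:
            raise ValueError("y and h must have the same length")
        if not np.isfinite(self.y).all():
            raise ValueError("y contains non-finite values")
        self.strata, inverse = np.unique(self.h, return_inverse=True)
        self.N = self.y.size
        self.N_h = np.bincount(inverse)
        self.sigma2 = float(np.var(self.y))
        means = np.bincount(inverse, weights=self.y) / self.N_h
        dev2 = (self.y - means[inverse]) ** 2
        self.sigma2_h = np.bincount(inverse, weights=dev2) / self.N_h

    @property
    def L(self) -> int:
        return self.strata.size


def factor_q(sample: StratifiedSample) -> float:
    """The q-statistic of a stratified sample, clamped to [0, 1].

    A constant y (total variance zero) returns 0: there is no variance to
    explain.  Tiny negative rounding is clamped to 0.
    """
    if sample.L < 2:
        raise InsufficientStrataError(
            f"q requires at least 2 strata, got {sample.L}"
        )
    sst = sample.N * sample.sigma2
    if sst == 0.0:
        return 0.0
    ssw = float(np.dot(sample.N_h, sample.sigma2_h))
    q = 1.0 - ssw / sst
    return min(1.0, max(0.0, q))


def permutation_p(sample: StratifiedSample, B: int = 999, seed: int = 0) -> float:
    """One-sided Monte-Carlo permutation p-value for the observed q.

    Labels are permuted uniformly at random B times;
    p = (1 + #{q_perm >= q_obs}) / (B + 1).
    """
    if B < 99:
        raise ValueError(f"B must be at least 99, got {B}")
    q_obs = factor_q(sample)
    rng = np.random.default_rng(seed)
    hits = 0
    h = sample.h
    for _ in range(B):
        perm = StratifiedSample(sample.y, rng.permutation(h))
        if factor_q(perm) >= q_obs:
            hits += 1
    return (1 + hits) / (B + 1)


def q_table(
    stack: CovariateStack,
    occ: VegetationOccurrence,
    variables: list[str] | None = None,
    B: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-covariate q (and permutation p) for one vegetation pair.

    The strata are the pair's two classes at labelled pixels; y is the
    covariate at those pixels.  Pixels masked in a covariate are dropped
    for that covariate only.  ``B=0`` skips the permutation test
    (p reported as NaN).

    Returns a DataFrame indexed by variable with columns ``q``, ``p_value``.
    """
    if variables is None:
        variables = stack.names
    if not variables:
        raise ValueError("variables must be nonempty")
    occ.require_usable()
    rows = {}
    for i, name in enumerate(variables):
        feats, labels, _ = extract_labeled_pixels(stack, occ, [name])
        sample = StratifiedSample(feats[:, 0], labels + 1)
        q = factor_q(sample)
        p = permutation_p(sample, B, seed + i) if B else float("nan")
        rows[name] = {"q": q, "p_value": p}
    table = pd.DataFrame.from_dict(rows, orient="index").loc[variables]
    table.index.name = "variable"
    return table
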