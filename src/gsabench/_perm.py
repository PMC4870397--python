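"""Subject-sampling (label-permutation) machinery shared by all tests.

A "split" assigns each sample to phenotype group 1 or 2, preserving the
observed group sizes.  When the number of distinct splits is small enough
they are enumerated exhaustively (for balanced groups, complementary splits
are collapsed because every statistic in this package is invariant to
swapping the two groups); otherwise a fixed budget of uniformly random
splits is drawn.  P-values use the add-one convention
``p = (1 + #{null >= observed}) / (1 + B)`` in random mode and the exact
enumeration fraction in exhaustive mode, so ``p > 0`` always.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TestConfig", "GeneSetTestResult", "split_masks", "pvalues_from_null"]


@dataclass(frozen=True)
class TestConfig:
    """Settings shared by all permutation tests.

    Attributes
    ----------
    alpha : significance level in (0, 1).
    n_perm : random-permutation budget (>= 99), used when exhaustive
        enumeration is not feasible.
    exhaustive_threshold : enumerate all distinct label splits when their
        number is at most this.
    s0_policy : SAM-GS small-variance constant policy: ``"zero"``,
        ``"median_sd"`` (median of gene-wise pooled SDs) or ``"fixed:<x>"``.
    seed : master seed for the random splits.
    """

    __test__ = False  # not a test case despite the name

    alpha: float = 0.05
    n_perm: int = 1000
    exhaustive_threshold: int = 2000
    s0_policy: str = "median_sd"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.s0_policy not in ("zero", "median_sd") and not self.s0_policy.startswith(
            "fixed:"
        ):
            raise ValueError("s0_policy must be 'zero', 'median_sd' or 'fixed:<value>'")

    def s0_value(self, pooled_sds: np.ndarray) -> float:
        """Resolve the SAM-GS s0 constant for a dataset's pooled SDs."""
        if self.s0_policy == "zero":
            return 0.0
        if self.s0_policy == "median_sd":
            return float(np.median(pooled_sds))
        return float(self.s0_policy.split(":", 1)[1])

    def replace(self, **kwargs) -> "TestConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class GeneSetTestResult:
    """Per-set outcome of one permutation test."""

    set_name: str
    statistic: float
    p_value: float
    method: str
    n_perm_used: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


def n_distinct_splits(n1: int, n2: int) -> int:
    """Number of distinct group-1 subsets, halving when n1 == n2 because
    complementary splits give the same statistic for symmetric tests."""
    total = math.comb(n1 + n2, n1)
    return total // 2 if n1 == n2 else total


def split_masks(
    labels: np.ndarray, config: TestConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, bool]:
    """Boolean group-1 masks, observed split first.

    Returns ``(masks, exhaustive)`` with ``masks`` of shape ``(1 + B, N)``:
    row 0 is the observed labeling, rows 1..B are the null splits.  In
    exhaustive mode the null rows enumerate every distinct split (the
    observed one included); in random mode they are ``config.n_perm``
    uniform draws from the generator.
    """
    labels = np.asarray(labels)
    obs = labels == 1
    n1 = int(obs.sum())
    n2 = labels.size - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("each phenotype group needs at least 2 samples")
    n_splits = n_distinct_splits(n1, n2)
    if n_splits <= config.exhaustive_threshold:
        combos = itertools.combinations(range(labels.size), n1)
        if n1 == n2:
            # collapse complement pairs: keep splits containing sample 0
            combos = (c for c in combos if c[0] == 0)
        null = np.zeros((n_splits, labels.size), dtype=bool)
        for row, c in enumerate(combos):
            null[row, list(c)] = True
        return np.vstack([obs[None, :], null]), True
    if rng is None:
        rng = np.random.default_rng(config.seed)
    null = rng.permuted(np.tile(obs, (config.n_perm, 1)), axis=1)
    return np.vstack([obs[None, :], null]), False


def pvalues_from_null(stats: np.ndarray, exhaustive: bool) -> np.ndarray:
    """P-values from a ``(n_items, 1 + B)`` statistic matrix (column 0 is
    the observed value).  Ties are counted as at-least-as-extreme, with a
    small relative tolerance so float round-off cannot drop exact ties."""
    stats = np.atleast_2d(stats)
    obs = stats[:, :1]
    tol = 1e-12 * (1.0 + np.abs(obs))
    ge = (stats[:, 1:] >= obs - tol).sum(axis=1)
    B = stats.shape[1] - 1
    if exhaustive:
        return ge / B
    return (1.0 + ge) / (1.0 + B)
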