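"""Vectorised group moments over many label splits at once.

All permutation loops in this package reduce to the same primitive: given an
expression matrix ``E`` (genes x samples) and a stack of group-1 masks
(splits x samples), compute per-gene, per-split group means and variances
via matrix products.  Splits are processed in chunks to bound memory.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

DEFAULT_CHUNK = 256


def iter_mask_chunks(masks: np.ndarray, chunk: int = DEFAULT_CHUNK) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(offset, mask_block)`` pairs over the split axis."""
    for start in range(0, masks.shape[0], chunk):
        yield start, masks[start : start + chunk]


def group_moments(E: np.ndarray, masks: np.ndarray):
    """Per-gene group means and sample variances for each split.

    Parameters
    ----------
    E : (G, N) float matrix.
    masks : (B, N) boolean group-1 indicators; all rows must have the same
        group sizes (label permutation preserves them).

    Returns
    -------
    m1, v1, m2, v2 : (G, B) arrays of group means and variances
        (ddof=1 within each group); n1, n2 : ints.
    """
    M = masks.astype(float).T  # (N, B)
    n1 = int(masks[0].sum())
    n2 = masks.shape[1] - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    S1 = E @ M
    Q1 = (E * E) @ M
    S_tot = E.sum(axis=1, keepdims=True)
    Q_tot = (E * E).sum(axis=1, keepdims=True)
    m1 = S1 / n1
    m2 = (S_tot - S1) / n2
    v1 = np.maximum(Q1 - n1 * m1 * m1, 0.0) / (n1 - 1)
    v2 = np.maximum((Q_tot - Q1) - n2 * m2 * m2, 0.0) / (n2 - 1)
    return m1, v1, m2, v2, n1, n2


def set_row_blocks(index_lists: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-set gene-row indices for ``np.add.reduceat``.

    Returns ``(rows, starts)`` such that summing a per-gene column over
    ``rows[starts[k]:starts[k+1]]`` aggregates set ``k``.
    """
    sizes = np.array([len(ix) for ix in index_lists])
    rows = np.concatenate(index_lists) if index_lists else np.empty(0, dtype=np.intp)
    starts = np.r_[0, np.cumsum(sizes)[:-1]].astype(np.intp)
    return rows, starts
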