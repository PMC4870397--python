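"""Count normalizations consumed by the gene-set tests.

RPKM (reads per kilobase per million) feeds the multivariate self-contained
tests, which work on expression profiles in R^p.  log-CPM with small offsets
(the convention popularised by the limma/voom pipeline, without the
precision weights) feeds SAM-GS, the gene-level tests and the rank-based
competitive scoring, where a roughly normal scale is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gsabench.simulate import CountDataset

__all__ = ["ExpressionMatrix", "rpkm", "log_cpm"]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of normalized expression values."""

    values: np.ndarray
    scale_tag: str  # one of {"rpkm", "log_cpm", "raw_rank"}
    gene_ids: list[str]
    sample_ids: list[str]


def _check_library_sizes(dataset: CountDataset) -> np.ndarray:
    lib = dataset.library_sizes
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = [dataset.sample_ids[j] for j in zero[:5]]
        raise ValueError(f"zero library size for sample(s) {names}")
    return lib.astype(float)


def rpkm(dataset: CountDataset) -> ExpressionMatrix:
    """Reads per kilobase per million:
    ``10^9 * count / (library_size * gene_length)``."""
    lib = _check_library_sizes(dataset)
    values = 1e9 * dataset.counts / (lib[None, :] * dataset.gene_lengths[:, None])
    return ExpressionMatrix(values, "rpkm", list(dataset.gene_ids), list(dataset.sample_ids))


def log_cpm(dataset: CountDataset) -> ExpressionMatrix:
    """Offset log2 counts per million:
    ``log2((count + 0.5) / (library_size + 1) * 10^6)``."""
    lib = _check_library_sizes(dataset)
    values = np.log2((dataset.counts + 0.5) / (lib[None, :] + 1.0) * 1e6)
    return ExpressionMatrix(values, "log_cpm", list(dataset.gene_ids), list(dataset.sample_ids))
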