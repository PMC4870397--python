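"""Null and alternative count-data simulation.

Datasets are gene-by-sample matrices of NB counts with two balanced
phenotype groups.  Under the null every gene's counts are identically
distributed in both groups.  Under the alternative a fraction ``beta`` of
the gene sets carry truly differentially expressed (DE) genes: in each DE
set a fraction ``gamma`` of the genes has its mean multiplied by ``fc`` in
one phenotype.  In the ``balanced`` design half of the DE genes are up in
phenotype 2 and half are up in phenotype 1; in the ``one_sided`` design all
are up in phenotype 2.  The simulator emits non-overlapping gene sets that
partition the genes, together with ground-truth DE flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gsabench.paramgen import NBGeneParam, NBParamPool, sample_param_indices

__all__ = [
    "CountDataset",
    "GeneSetCollection",
    "SimulationDesign",
    "nb_draw",
    "simulate_null_dataset",
    "simulate_power_dataset",
]


class CountDataset:
    """Gene-by-sample integer counts with lengths and two-group labels.

    Parameters
    ----------
    counts : (n_genes, n_samples) array of non-negative integers.
    gene_ids : unique gene identifiers, one per row.
    gene_lengths : gene lengths in bp, one per row.
    labels : per-sample phenotype tag, values in {1, 2}; both present.
    sample_ids : optional sample identifiers (default ``s001`` ...).
    """

    def __init__(self, counts, gene_ids, gene_lengths, labels, sample_ids=None):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x sample matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        gene_ids = list(gene_ids)
        if len(gene_ids) != counts.shape[0]:
            raise ValueError("gene_ids length must match the number of rows")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        gene_lengths = np.asarray(gene_lengths, dtype=np.int64)
        if gene_lengths.shape != (counts.shape[0],):
            raise ValueError("gene_lengths must have one entry per gene")
        if (gene_lengths < 1).any():
            raise ValueError("gene_lengths must be >= 1")
        labels = np.asarray(labels, dtype=np.int64)
        if labels.shape != (counts.shape[1],):
            raise ValueError("labels must have one entry per sample")
        if not set(np.unique(labels)) <= {1, 2}:
            raise ValueError("labels must take values in {1, 2}")
        if not ({1, 2} <= set(np.unique(labels))):
            raise ValueError("both phenotype tags 1 and 2 must be present")
        if sample_ids is None:
            sample_ids = [f"s{j + 1:03d}" for j in range(counts.shape[1])]
        sample_ids = list(sample_ids)
        if len(sample_ids) != counts.shape[1] or len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique, one per column")
        self.counts = counts
        self.gene_ids = gene_ids
        self.gene_lengths = gene_lengths
        self.labels = labels
        self.sample_ids = sample_ids
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums of the raw counts."""
        return self.counts.sum(axis=0)

    @property
    def group_sizes(self) -> tuple[int, int]:
        return int((self.labels == 1).sum()), int((self.labels == 2).sum())

    def gene_indices(self, gene_ids) -> np.ndarray:
        """Row indices for a list of gene ids; unknown ids raise KeyError."""
        try:
            return np.array([self._gene_index[g] for g in gene_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"gene id not in dataset: {e.args[0]!r}") from None

    def subset_samples(self, column_indices) -> "CountDataset":
        """New dataset keeping only the given sample columns (library sizes
        are recomputed from the retained columns)."""
        idx = np.asarray(column_indices, dtype=np.intp)
        return CountDataset(
            self.counts[:, idx],
            self.gene_ids,
            self.gene_lengths,
            self.labels[idx],
            [self.sample_ids[j] for j in idx],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountDataset):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.gene_lengths, other.gene_lengths)
            and np.array_equal(self.labels, other.labels)
            and self.sample_ids == other.sample_ids
        )


class GeneSetCollection:
    """Named lists of gene identifiers, optionally with ground-truth flags.

    ``truth`` maps set names to ``"null"`` or ``"DE"`` for simulator output;
    user-supplied collections may leave it ``None``.
    """

    def __init__(self, sets: dict[str, list[str]], truth: dict[str, str] | None = None):
        for name, genes in sets.items():
            if len(genes) < 2:
                raise ValueError(f"gene set {name!r} has fewer than 2 genes")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate gene ids")
        if truth is not None:
            unknown = set(truth) - set(sets)
            if unknown:
                raise ValueError(f"truth flags for unknown sets: {sorted(unknown)[:5]}")
            bad = {v for v in truth.values()} - {"null", "DE"}
            if bad:
                raise ValueError(f"truth flags must be 'null' or 'DE', got {bad}")
        self.sets = dict(sets)
        self.truth = dict(truth) if truth is not None else None

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def de_names(self) -> list[str]:
        if self.truth is None:
            raise ValueError("collection carries no ground-truth flags")
        return [n for n in self.sets if self.truth[n] == "DE"]

    def null_names(self) -> list[str]:
        if self.truth is None:
            raise ValueError("collection carries no ground-truth flags")
        return [n for n in self.sets if self.truth[n] == "null"]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.truth == other.truth


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of an alternative-hypothesis simulation.

    Attributes
    ----------
    N : total number of samples (even; N/2 per phenotype).
    p : genes per set.
    S : number of non-overlapping sets.
    beta : fraction of sets carrying DE genes, in [0, 1].
    gamma : fraction of DE genes within each DE set, in (0, 1].
    fc : fold change applied to DE gene means, >= 1.
    balance : ``"balanced"`` (half up / half down) or ``"one_sided"``
        (all DE genes up in phenotype 2).
    """

    N: int
    p: int
    S: int
    beta: float
    gamma: float
    fc: float
    balance: str = "balanced"

    def __post_init__(self) -> None:
        if self.N < 4 or self.N % 2:
            raise ValueError("N must be an even integer >= 4")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.fc < 1.0:
            raise ValueError("fc must be >= 1")
        if self.balance not in ("balanced", "one_sided"):
            raise ValueError("balance must be 'balanced' or 'one_sided'")
        if self.beta > 0 and round(self.gamma * self.p) < 1:
            raise ValueError("round(gamma * p) must be >= 1 for DE sets")

    @property
    def n_de_sets(self) -> int:
        return int(round(self.beta * self.S))

    @property
    def n_de_genes_per_set(self) -> int:
        return int(round(self.gamma * self.p))


def _nb_counts(rng: np.random.Generator, mean, phi, size=None) -> np.ndarray:
    """Vectorised NB draws with mean ``mean`` and variance
    ``mean * (1 + mean * phi)``; ``phi == 0`` entries fall back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    if size is not None:
        mean = np.broadcast_to(mean, size)
        phi = np.broadcast_to(phi, size)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        # numpy parametrisation: n successes, success probability q;
        # mean = n (1-q)/q, so n = 1/phi and q = n / (n + mean)
        n = 1.0 / phi[nb]
        q = n / (n + mean[nb])
        out[nb] = rng.negative_binomial(n, q)
    return out


def nb_draw(param: NBGeneParam, n: int, fc: float = 1.0, seed: int = 0) -> np.ndarray:
    """``n`` independent NB draws with mean ``fc * mu`` and dispersion ``phi``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if fc < 1.0:
        raise ValueError("fc must be >= 1")
    rng = np.random.default_rng(seed)
    return _nb_counts(rng, np.full(n, fc * param.mu), np.full(n, param.phi))


def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:06d}" for i in range(n)]


def _partition_sets(gene_ids: list[str], S: int, p: int) -> dict[str, list[str]]:
    return {f"set{k + 1:04d}": gene_ids[k * p : (k + 1) * p] for k in range(S)}


def simulate_null_dataset(
    pool: NBParamPool, N: int, p: int, S: int, seed: int = 0
) -> tuple[CountDataset, GeneSetCollection]:
    """Simulate an H0 dataset: ``S * p`` genes, each with one pooled triplet
    generating identically distributed counts for all ``N`` samples; labels
    split N/2 vs N/2; sets partition the genes into S blocks of p."""
    design = SimulationDesign(N=N, p=p, S=S, beta=0.0, gamma=1.0, fc=1.0)
    return simulate_power_dataset(pool, design, seed=seed)


def simulate_power_dataset(
    pool: NBParamPool, design: SimulationDesign, seed: int = 0
) -> tuple[CountDataset, GeneSetCollection]:
    """Simulate a dataset under the (beta, gamma, fc) alternative design.

    The first ``round(beta * S)`` sets are flagged DE.  Within each DE set
    the first ``g = round(gamma * p)`` genes are DE: under ``balanced`` the
    first ``ceil(g/2)`` have mean ``fc * mu`` in phenotype 2 and ``mu`` in
    phenotype 1 and the remaining ``floor(g/2)`` the reverse; under
    ``one_sided`` all ``g`` are up in phenotype 2.
    """
    if design.beta > 0 and design.n_de_sets == 0:
        raise ValueError(
            f"beta * S = {design.beta * design.S:.3g} rounds to 0 DE sets; "
            "increase S (or beta) so that at least one set is DE"
        )
    N, p, S = design.N, design.p, design.S
    G = S * p
    rng = np.random.default_rng(seed)
    pool_seed = int(rng.integers(0, 2**31))
    idx = sample_param_indices(pool, G, seed=pool_seed)
    mu = pool.mu[idx]
    phi = pool.phi[idx]
    lengths = pool.length[idx]

    n_half = N // 2
    labels = np.r_[np.ones(n_half, dtype=int), np.full(n_half, 2, dtype=int)]

    # per-gene, per-phenotype fold change multipliers
    fc1 = np.ones(G)
    fc2 = np.ones(G)
    n_de_sets = design.n_de_sets
    g_de = design.n_de_genes_per_set
    for k in range(n_de_sets):
        start = k * p
        if design.balance == "balanced":
            n_up = (g_de + 1) // 2  # up-regulated in phenotype 2
            fc2[start : start + n_up] = design.fc
            fc1[start + n_up : start + g_de] = design.fc
        else:
            fc2[start : start + g_de] = design.fc

    counts = np.empty((G, N), dtype=np.int64)
    counts[:, :n_half] = _nb_counts(
        rng, (fc1 * mu)[:, None], phi[:, None], size=(G, n_half)
    )
    counts[:, n_half:] = _nb_counts(
        rng, (fc2 * mu)[:, None], phi[:, None], size=(G, n_half)
    )

    gene_ids = _gene_ids(G)
    dataset = CountDataset(counts, gene_ids, lengths, labels)
    sets = _partition_sets(gene_ids, S, p)
    # flags follow the design: at fc=1 the "DE" sets carry no actual signal,
    # which is exactly what the power-at-boundary check needs
    truth = {
        name: ("DE" if k < n_de_sets else "null") for k, name in enumerate(sets)
    }
    return dataset, GeneSetCollection(sets, truth)
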