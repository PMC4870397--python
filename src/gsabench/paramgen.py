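"""Per-gene negative-binomial parameter pools.

Every simulation in this package draws per-gene parameter triplets
``(mu, phi, length)`` — mean read count, NB dispersion and gene length in
base pairs — with replacement from a pool.  Real RNA-seq studies derive such
a pool from a reference count matrix; here a stated synthetic generator
produces one with the same qualitative structure (log-normal means, a
mean-dependent dispersion trend ``phi = b + a/mu`` with multiplicative
jitter, log-uniform lengths), so no external data are required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NBGeneParam",
    "NBParamPool",
    "generate_parameter_pool",
    "load_parameter_pool",
    "save_parameter_pool",
    "sample_params",
]


@dataclass(frozen=True)
class NBGeneParam:
    """NB parameters for one gene.

    Attributes
    ----------
    mu : float
        Mean read count, > 0.
    phi : float
        NB dispersion, >= 0; the implied variance is ``mu * (1 + mu * phi)``,
        so ``phi = 0`` degenerates to Poisson.
    length : int
        Gene length in base pairs, >= 1.
    """

    mu: float
    phi: float
    length: int

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not self.phi >= 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")
        if not (self.length >= 1 and float(self.length).is_integer()):
            raise ValueError(f"length must be an integer >= 1, got {self.length}")

    @property
    def variance(self) -> float:
        return self.mu * (1.0 + self.mu * self.phi)


class NBParamPool:
    """Ordered, non-empty pool of :class:`NBGeneParam` triplets.

    Internally stored as parallel numpy arrays (``mu``, ``phi``, ``length``)
    so that simulations can draw thousands of triplets vectorised.
    """

    def __init__(self, mu, phi, length, source_tag: str = "user-supplied"):
        mu = np.asarray(mu, dtype=float)
        phi = np.asarray(phi, dtype=float)
        length = np.asarray(length, dtype=np.int64)
        if mu.ndim != 1 or mu.shape != phi.shape or mu.shape != length.shape:
            raise ValueError("mu, phi and length must be 1-D arrays of equal size")
        if mu.size == 0:
            raise ValueError("parameter pool must be non-empty")
        bad = np.flatnonzero(~((mu > 0) & (phi >= 0) & (length >= 1)))
        if bad.size:
            raise ValueError(
                "invalid parameter rows (need mu>0, phi>=0, length>=1): "
                f"rows {bad[:10].tolist()}"
            )
        self.mu = mu
        self.phi = phi
        self.length = length
        self.source_tag = source_tag

    def __len__(self) -> int:
        return self.mu.size

    def __getitem__(self, i: int) -> NBGeneParam:
        return NBGeneParam(float(self.mu[i]), float(self.phi[i]), int(self.length[i]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, NBParamPool):
            return NotImplemented
        return (
            np.array_equal(self.mu, other.mu)
            and np.array_equal(self.phi, other.phi)
            and np.array_equal(self.length, other.length)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu, "phi": self.phi, "length": self.length})


#: defaults spanning low to high expression with realistic over-dispersion
DEFAULT_MU_LOG_MEAN = float(np.log(100.0))
DEFAULT_MU_LOG_SD = 1.5
DEFAULT_PHI_TREND = (3.0, 0.05)
DEFAULT_PHI_NOISE_SD = 0.3
DEFAULT_LENGTH_RANGE = (200, 20_000)


def generate_parameter_pool(
    n_genes: int,
    mu_log_mean: float = DEFAULT_MU_LOG_MEAN,
    mu_log_sd: float = DEFAULT_MU_LOG_SD,
    phi_trend: tuple[float, float] = DEFAULT_PHI_TREND,
    phi_noise_sd: float = DEFAULT_PHI_NOISE_SD,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    seed: int = 0,
) -> NBParamPool:
    """Generate a synthetic NB parameter pool.

    ``mu`` is drawn log-normally (``log mu ~ N(mu_log_mean, mu_log_sd^2)``),
    ``phi = b + a/mu`` with ``phi_trend = (a, b)`` jittered multiplicatively
    by log-normal noise of standard deviation ``phi_noise_sd`` on the log
    scale, and ``length`` is drawn log-uniformly from ``length_range``.
    The output is a pure function of the arguments including ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mu_log_sd < 0:
        raise ValueError("mu_log_sd must be >= 0")
    a, b = phi_trend
    if a < 0 or b < 0:
        raise ValueError("phi_trend coefficients must be >= 0")
    if phi_noise_sd < 0:
        raise ValueError("phi_noise_sd must be >= 0")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("length_range must satisfy 1 <= min <= max")

    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(mu_log_mean, mu_log_sd, size=n_genes))
    phi = (b + a / mu) * np.exp(rng.normal(0.0, phi_noise_sd, size=n_genes)) \
        if phi_noise_sd > 0 else (b + a / mu)
    length = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    length = np.clip(np.rint(length).astype(np.int64), lo, hi)
    return NBParamPool(mu, phi, length, source_tag="synthetic")


def save_parameter_pool(pool: NBParamPool, path) -> None:
    """Write a pool as a tab-separated ``mu<TAB>phi<TAB>length`` table."""
    pool.to_frame().to_csv(path, sep="\t", index=False)


def load_parameter_pool(path) -> NBParamPool:
    """Read a pool from a tab-separated table with columns mu, phi, length.

    Row order is preserved.  Rows violating the parameter invariants raise
    with the offending row numbers; non-numeric cells raise with location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mu", "phi", "length") if c not in df.columns]
    if missing:
        raise ValueError(f"pool file {path} is missing columns: {missing}")
    for col in ("mu", "phi", "length"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"pool file {path}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 2} (1-based, counting the header)"
            )
        df[col] = coerced
    if df[["mu", "phi", "length"]].isna().any().any():
        raise ValueError(f"pool file {path}: empty or missing cells")
    ok = (df["mu"] > 0) & (df["phi"] >= 0) & (df["length"] >= 1)
    if not ok.all():
        rows = (df.index[~ok] + 2).tolist()[:10]
        raise ValueError(
            f"pool file {path}: invalid parameter rows (need mu>0, phi>=0, "
            f"length>=1) at file rows {rows}"
        )
    return NBParamPool(
        df["mu"].to_numpy(),
        df["phi"].to_numpy(),
        df["length"].to_numpy(),
        source_tag="user-supplied",
    )


def sample_params(pool: NBParamPool, count: int, seed: int) -> list[NBGeneParam]:
    """Sample ``count`` triplets uniformly with replacement from the pool."""
    idx = sample_param_indices(pool, count, seed)
    return [pool[i] for i in idx]


def sample_param_indices(pool: NBParamPool, count: int, seed: int) -> np.ndarray:
    """Vectorised core of :func:`sample_params`: pool row indices."""
    if len(pool) == 0:  # pragma: no cover - unreachable, pool is non-empty
        raise RuntimeError("cannot sample from an empty pool")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, len(pool), size=count)
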