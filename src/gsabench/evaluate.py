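"""Evaluation experiments: Type I error, power, robustness, detection bias.

The protocols mirror the standard benchmarking designs for gene-set tests:

* **Type I error** — simulate null datasets of S equally sized sets, run a
  method on every set, report the detected fraction at level alpha averaged
  over replicate datasets.
* **Power** — the same over a (beta, gamma, fc) alternative design, with
  the detected fraction among truth-DE sets (power) and among truth-null
  sets (empirical false positive rate) reported separately.
* **Subsampling robustness** — a surrogate gold standard is fixed by
  running the method on the full dataset (detected sets are the
  "true positives" GS_TP, undetected ones GS_TN); B balanced subsets per
  subset size then yield per-set detection rates m(i, n) and e(i, n) and
  their averages TPR(n) and FPR(n).
* **CCDS** — from a set-by-subset detection matrix, s_k counts the sets
  detected in exactly k subsets, Q = sum(k * s_k) is the total number of
  detection events, and CCDS(b) = sum_{k<=b} k * s_k / Q is the fraction of
  detection events contributed by sets found in b or fewer subsets.  A
  rapid early rise flags sensitivity to sample heterogeneity.
* **Detection-bias summaries** — mean set size, mean proportion of DE
  genes and mean gene length among each method's detected sets, with
  rank-based pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from gsabench._perm import TestConfig
from gsabench.genelevel import gene_pvalues
from gsabench.methods import MethodFn, get_method
from gsabench.normalize import log_cpm
from gsabench.paramgen import NBParamPool
from gsabench.simulate import (
    CountDataset,
    GeneSetCollection,
    SimulationDesign,
    simulate_null_dataset,
    simulate_power_dataset,
)

__all__ = [
    "DetectionMatrix",
    "CCDSCurve",
    "RobustnessSummary",
    "Type1Result",
    "PowerResult",
    "type1_experiment",
    "power_experiment",
    "surrogate_gold_standard",
    "subsample_robustness",
    "ccds_curve",
    "bias_summaries",
]


@dataclass
class DetectionMatrix:
    """Boolean set-by-subset detections at level alpha."""

    detect: np.ndarray
    set_names: list[str]
    alpha: float
    subset_size: int

    @property
    def B(self) -> int:
        return self.detect.shape[1]


@dataclass
class CCDSCurve:
    """Cumulative common detection per subset.

    ``s_k[k-1]`` sets were detected in exactly k of the B subsets;
    ``Q = sum(k * s_k)`` is the total number of detection events;
    ``ccds[b-1] = sum_{k<=b} k * s_k / Q``.
    """

    b_values: np.ndarray
    ccds: np.ndarray
    s_k: np.ndarray
    Q: int


@dataclass
class RobustnessSummary:
    """Per-set detection rates against the surrogate gold standard."""

    gs_tp: list[str]
    gs_tn: list[str]
    m: pd.Series  # detection rate per GS_TP set
    e: pd.Series  # detection rate per GS_TN set
    tpr: float
    fpr: float
    n: int


@dataclass
class Type1Result:
    rate: float
    per_replicate: list[float] = field(default_factory=list)


@dataclass
class PowerResult:
    power: float
    empirical_fpr: float
    per_replicate_power: list[float] = field(default_factory=list)
    per_replicate_fpr: list[float] = field(default_factory=list)


def _resolve(method) -> MethodFn:
    return get_method(method) if isinstance(method, str) else method


def _spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2**31."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31, size=n)


def _detected(results: pd.DataFrame, alpha: float) -> pd.Series:
    return pd.Series(
        (results["p_value"] < alpha).to_numpy(), index=results["set_name"].to_numpy()
    )


def type1_experiment(
    pool: NBParamPool,
    method,
    N: int,
    p: int,
    S: int,
    replicates: int = 10,
    config: TestConfig = TestConfig(),
) -> Type1Result:
    """Type I error rate: detected fraction over S null sets at level alpha,
    averaged over replicate null datasets (fresh pool draws per replicate)."""
    fn = _resolve(method)
    seeds = _spawn_seeds(config.seed, 2 * replicates)
    rates = []
    for r in range(replicates):
        dataset, sets = simulate_null_dataset(pool, N, p, S, seed=int(seeds[2 * r]))
        res = fn(dataset, sets, config.replace(seed=int(seeds[2 * r + 1])))
        rates.append(float((res["p_value"] < config.alpha).mean()))
    return Type1Result(rate=float(np.mean(rates)), per_replicate=rates)


def power_experiment(
    pool: NBParamPool,
    method,
    design: SimulationDesign,
    replicates: int = 10,
    config: TestConfig = TestConfig(),
) -> PowerResult:
    """Power (detected fraction among truth-DE sets) and the accompanying
    empirical FPR (among truth-null sets) under a (beta, gamma, fc) design.

    Competitive and gene-level methods rank or summarise against the whole
    simulated dataset of S*p genes; self-contained methods only ever see
    each set's own genes — both framings emerge naturally from running the
    method on the full dataset with its set collection.
    """
    fn = _resolve(method)
    seeds = _spawn_seeds(config.seed, 2 * replicates)
    powers, fprs = [], []
    for r in range(replicates):
        dataset, sets = simulate_power_dataset(pool, design, seed=int(seeds[2 * r]))
        res = fn(dataset, sets, config.replace(seed=int(seeds[2 * r + 1])))
        det = _detected(res, config.alpha)
        de = sets.de_names()
        null = sets.null_names()
        powers.append(float(det[de].mean()) if de else np.nan)
        fprs.append(float(det[null].mean()) if null else np.nan)
    return PowerResult(
        power=float(np.nanmean(powers)) if powers else np.nan,
        empirical_fpr=float(np.nanmean(fprs)) if fprs else np.nan,
        per_replicate_power=powers,
        per_replicate_fpr=fprs,
    )


def surrogate_gold_standard(
    dataset: CountDataset,
    sets: GeneSetCollection,
    method,
    config: TestConfig = TestConfig(),
) -> tuple[list[str], list[str]]:
    """Partition set names by detection on the full dataset: detected sets
    become the surrogate "true positives" GS_TP, the rest GS_TN."""
    fn = _resolve(method)
    det = _detected(fn(dataset, sets, config), config.alpha)
    gs_tp = [name for name in sets.names() if det[name]]
    gs_tn = [name for name in sets.names() if not det[name]]
    return gs_tp, gs_tn


def subsample_robustness(
    dataset: CountDataset,
    sets: GeneSetCollection,
    method,
    subset_sizes: list[int],
    B: int = 100,
    config: TestConfig = TestConfig(),
) -> dict[int, tuple[DetectionMatrix, RobustnessSummary]]:
    """Detection stability under balanced subsampling without replacement.

    For each subset size n, B subsets of n/2 samples per phenotype are
    drawn, the method is run on every subset, and per-set detection rates
    m(i, n) (over GS_TP) and e(i, n) (over GS_TN) are averaged into TPR(n)
    and FPR(n).
    """
    fn = _resolve(method)
    if B < 1:
        raise ValueError("B must be >= 1")
    g1 = np.flatnonzero(dataset.labels == 1)
    g2 = np.flatnonzero(dataset.labels == 2)
    for n in subset_sizes:
        if n % 2:
            raise ValueError(f"subset size {n} must be even")
        if n // 2 > min(g1.size, g2.size):
            raise ValueError(
                f"subset size {n} exceeds the per-group sample count "
                f"({g1.size} vs {g2.size})"
            )
    gs_tp, gs_tn = surrogate_gold_standard(dataset, sets, fn, config)
    names = sets.names()
    rng = np.random.default_rng(config.seed)
    out: dict[int, tuple[DetectionMatrix, RobustnessSummary]] = {}
    for n in subset_sizes:
        detect = np.zeros((len(names), B), dtype=bool)
        for j in range(B):
            cols = np.r_[
                rng.choice(g1, size=n // 2, replace=False),
                rng.choice(g2, size=n // 2, replace=False),
            ]
            sub = dataset.subset_samples(np.sort(cols))
            cfg = config.replace(seed=int(rng.integers(0, 2**31)))
            detect[:, j] = (fn(sub, sets, cfg)["p_value"] < config.alpha).to_numpy()
        dm = DetectionMatrix(detect, names, config.alpha, n)
        rate = pd.Series(detect.mean(axis=1), index=names)
        m = rate[gs_tp]
        e = rate[gs_tn]
        out[n] = (
            dm,
            RobustnessSummary(
                gs_tp=gs_tp,
                gs_tn=gs_tn,
                m=m,
                e=e,
                tpr=float(m.mean()) if len(m) else np.nan,
                fpr=float(e.mean()) if len(e) else np.nan,
                n=n,
            ),
        )
    return out


def ccds_curve(detect) -> CCDSCurve:
    """CCDS curve from a detection matrix (or raw boolean array)."""
    mat = detect.detect if isinstance(detect, DetectionMatrix) else np.asarray(detect)
    mat = mat.astype(bool)
    B = mat.shape[1]
    k_per_set = mat.sum(axis=1)
    s_k = np.bincount(k_per_set, minlength=B + 1)[1:]
    k = np.arange(1, B + 1)
    Q = int((k * s_k).sum())
    if Q == 0:
        raise ValueError("no detections: the CCDS curve is undefined")
    ccds = np.cumsum(k * s_k) / Q
    return CCDSCurve(b_values=k, ccds=ccds, s_k=s_k, Q=Q)


def bias_summaries(
    results: dict[str, list[str]],
    sets: GeneSetCollection,
    dataset: CountDataset,
    per_gene_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection-bias summaries per method and pairwise rank-test contrasts.

    ``results`` maps method names to lists of detected set names.  For each
    detected set the summary uses its size, the fraction of its genes
    called DE by a per-gene Welch test on log-CPM at ``per_gene_alpha`` and
    its mean gene length; per-method means are reported (NaN rows for
    methods that detected nothing) together with two-sided Wilcoxon
    rank-sum contrasts between every method pair for each measure.
    """
    E = log_cpm(dataset).values
    g1 = dataset.labels == 1
    pg = gene_pvalues(E[:, g1], E[:, ~g1])
    de_flag = pg < per_gene_alpha

    per_set = {}
    for name in sets.names():
        idx = dataset.gene_indices(sets.sets[name])
        per_set[name] = (
            len(idx),
            float(de_flag[idx].mean()),
            float(dataset.gene_lengths[idx].mean()),
        )

    metrics = ("set_size", "frac_de", "gene_length")
    values: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for method, detected in results.items():
        unknown = set(detected) - set(per_set)
        if unknown:
            raise ValueError(f"detections reference unknown sets: {sorted(unknown)[:5]}")
        cols = {
            met: np.array([per_set[s][i] for s in detected])
            for i, met in enumerate(metrics)
        }
        values[method] = cols
        rows.append(
            {
                "method": method,
                "n_detected": len(detected),
                "mean_set_size": cols["set_size"].mean() if detected else np.nan,
                "mean_frac_de": cols["frac_de"].mean() if detected else np.nan,
                "mean_gene_length": cols["gene_length"].mean() if detected else np.nan,
            }
        )
    summary = pd.DataFrame(rows)

    contrast_rows = []
    names = list(results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for met in metrics:
                xa, xb = values[a][met], values[b][met]
                if xa.size and xb.size:
                    pv = float(sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
                else:
                    pv = np.nan
                contrast_rows.append(
                    {"method_a": a, "method_b": b, "metric": met, "p_value": pv}
                )
    contrasts = pd.DataFrame(contrast_rows)
    return summary, contrasts
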