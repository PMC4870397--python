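"""Readers and writers for the plain-text formats the toolkit touches.

Gene sets travel as GMT (one set per line: name, description, then gene
ids, tab-separated).  Counts are a TSV gene-by-sample table with a header
row of sample ids and a leading ``gene_id`` column; gene lengths and sample
labels are two-column TSVs keyed by id.  Result tables are tidy TSVs with a
provenance comment header (tool version, resolved seed) — deliberately no
timestamp, so identical invocations produce byte-identical files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from gsabench.simulate import CountDataset, GeneSetCollection

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_counts",
    "write_dataset",
    "write_results",
]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Duplicate gene ids within a set are collapsed with a warning; sets with
    fewer than 2 distinct genes are dropped with a warning; a line with
    fewer than 3 fields raises with its line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        warnings.warn(f"GMT file {path} is empty", stacklevel=2)
        return GeneSetCollection({})
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one gene id ({len(fields)} fields found)"
            )
        name = fields[0]
        genes: list[str] = []
        seen = set()
        for g in fields[2:]:
            if not g:
                continue
            if g in seen:
                continue
            seen.add(g)
            genes.append(g)
        if len(genes) < len([g for g in fields[2:] if g]):
            warnings.warn(
                f"{path}:{lineno}: duplicate gene ids in set {name!r} collapsed",
                stacklevel=2,
            )
        if len(genes) < 2:
            warnings.warn(
                f"{path}:{lineno}: set {name!r} has fewer than 2 genes; dropped",
                stacklevel=2,
            )
            continue
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets.names():
            fh.write("\t".join([name, description, *sets.sets[name]]) + "\n")


def read_counts(counts_path, lengths_path, labels_path) -> CountDataset:
    """Assemble a validated :class:`CountDataset` from three TSV files.

    Library sizes are always recomputed from the counts; label and length
    rows are joined by id, so their row order does not matter.
    """
    counts_df = pd.read_csv(counts_path, sep="\t", index_col=0)
    raw = counts_df.to_numpy()
    if raw.dtype.kind not in "iu":
        bad = np.argwhere(~(np.mod(raw.astype(float), 1) == 0) | (raw.astype(float) < 0))
        if bad.size == 0 and np.issubdtype(raw.dtype, np.floating):
            raw = raw.astype(np.int64)
        else:
            i, j = bad[0]
            raise ValueError(
                f"{counts_path}: non-integer or negative count at gene "
                f"{counts_df.index[i]!r}, sample {counts_df.columns[j]!r}"
            )
    if (raw < 0).any():
        i, j = np.argwhere(raw < 0)[0]
        raise ValueError(
            f"{counts_path}: negative count at gene {counts_df.index[i]!r}, "
            f"sample {counts_df.columns[j]!r}"
        )
    gene_ids = [str(g) for g in counts_df.index]
    sample_ids = [str(s) for s in counts_df.columns]

    lengths_df = pd.read_csv(lengths_path, sep="\t")
    if lengths_df.shape[1] < 2:
        raise ValueError(f"{lengths_path}: expected columns gene id and length")
    lengths_df.columns = ["gene_id", "length", *lengths_df.columns[2:]]
    length_map = dict(zip(lengths_df["gene_id"].astype(str), lengths_df["length"]))
    missing = [g for g in gene_ids if g not in length_map]
    if missing:
        raise ValueError(
            f"{lengths_path}: no length for gene ids {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )

    labels_df = pd.read_csv(labels_path, sep="\t")
    if labels_df.shape[1] < 2:
        raise ValueError(f"{labels_path}: expected columns sample and group")
    labels_df.columns = ["sample", "group", *labels_df.columns[2:]]
    label_map = dict(zip(labels_df["sample"].astype(str), labels_df["group"]))
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise ValueError(
            f"{labels_path}: no group for sample ids {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    labels = np.array([int(label_map[s]) for s in sample_ids])

    return CountDataset(
        raw.astype(np.int64),
        gene_ids,
        np.array([int(length_map[g]) for g in gene_ids]),
        labels,
        sample_ids,
    )


def write_dataset(dataset: CountDataset, counts_path, lengths_path, labels_path) -> None:
    """Write a dataset as the three TSV files :func:`read_counts` expects."""
    pd.DataFrame(
        dataset.counts, index=pd.Index(dataset.gene_ids, name="gene_id"),
        columns=dataset.sample_ids,
    ).to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"gene_id": dataset.gene_ids, "length": dataset.gene_lengths}
    ).to_csv(lengths_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample": dataset.sample_ids, "group": dataset.labels}
    ).to_csv(labels_path, sep="\t", index=False)


def write_results(df: pd.DataFrame, path, seed: int | None = None, **meta) -> None:
    """Write a tidy result table with a provenance comment header."""
    from gsabench import __version__

    parts = [f"gsabench v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in meta.items())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + " ".join(parts) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
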