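"""Core alternative-splicing statistics for long-read quantifications.

The central quantity is the *degree of splicing* (DS) of a gene in a sample:
the number of its transcript isoforms with abundance strictly above a chosen
TPM threshold, zero when none qualify.  Long-read sequencing quantifies
isoforms directly, which makes this simple count a natural per-gene splicing
metric; varying the TPM threshold trades off sensitivity against robustness
to uneven sequencing depth.

Also provided: the constrained (no-zero) variant restricting analysis to
genes expressed in every sample, the per-type *overall splicing* summary
(mean qualifying-isoform count over mean expressing-gene count), and binned
abundance distributions with 95% confidence intervals in the two averaging
modes (per-sample counts averaged within a type, or per-isoform mean
abundances binned once).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import IsoformAbundanceMatrix

__all__ = [
    "DSMatrix",
    "BinSpec",
    "degree_of_splicing",
    "restrict_nonzero",
    "overall_splicing",
    "make_log_bins",
    "bin_distribution",
]


@dataclasses.dataclass(frozen=True)
class DSMatrix:
    """Genes x samples integer isoform counts at a fixed TPM threshold."""

    ds: pd.DataFrame
    tpm_threshold: float

    def __post_init__(self) -> None:
        arr = self.ds.to_numpy()
        if arr.size and ((arr < 0).any() or not np.issubdtype(arr.dtype, np.integer)):
            raise ValueError("DS values must be non-negative integers")
        if self.tpm_threshold < 0:
            raise ValueError("tpm_threshold must be >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.ds.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.ds.columns

    def to_tsv(self, path) -> None:
        self.ds.to_csv(path, sep="\t", index_label="gene_id")


def degree_of_splicing(matrix: IsoformAbundanceMatrix, tpm_threshold: float) -> DSMatrix:
    """Count, per gene and sample, the isoforms with TPM strictly above the
    threshold.  Genes whose isoforms all fall below the threshold keep an
    all-zero row — the zero carries the "not expressed here" signal used by
    the constrained variant.
    """
    if tpm_threshold < 0:
        raise ValueError("tpm_threshold must be >= 0")
    above = matrix.tpm.gt(tpm_threshold)
    ds = above.groupby(matrix.gene_of).sum().astype(np.int64)
    ds.index.name = "gene_id"
    return DSMatrix(ds, float(tpm_threshold))


def restrict_nonzero(ds: DSMatrix) -> DSMatrix:
    """Constrained variant: keep exactly the genes with DS > 0 in every
    sample.  An empty result is returned with a warning, not an error."""
    mask = (ds.ds > 0).all(axis=1)
    if not mask.any():
        warnings.warn(
            "no gene has a positive isoform count in every sample; "
            "constrained DS matrix is empty",
            stacklevel=2,
        )
    return DSMatrix(ds.ds.loc[mask], ds.tpm_threshold)


def overall_splicing(
    matrix: IsoformAbundanceMatrix,
    metadata: pd.DataFrame,
    tpm_threshold: float,
) -> pd.Series:
    """Per-type overall splicing: the qualifying-isoform count averaged over
    the type's samples, divided by the expressing-gene count averaged over
    the same samples (a ratio of means, >= 1 whenever defined).

    A type with no expressed gene at the threshold yields NaN with a
    warning.
    """
    above = matrix.tpm.gt(tpm_threshold)
    iso_per_sample = above.sum(axis=0)
    genes_per_sample = above.groupby(matrix.gene_of).any().sum(axis=0)

    out = {}
    for type_label, group in metadata.groupby("type", sort=False):
        samples = group["sample_id"]
        mean_genes = genes_per_sample[samples].mean()
        if mean_genes == 0:
            warnings.warn(
                f"type '{type_label}' expresses no gene above TPM {tpm_threshold}; "
                "overall splicing undefined",
                stacklevel=2,
            )
            out[type_label] = np.nan
        else:
            out[type_label] = iso_per_sample[samples].mean() / mean_genes
    return pd.Series(out, name="overall_splicing")


@dataclasses.dataclass(frozen=True)
class BinSpec:
    """Abundance bins: strictly increasing positive edges, each bin the
    left-open right-closed interval (edge[i], edge[i+1]]."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.size < 2:
            raise ValueError("need at least 2 bin edges")
        if (edges <= 0).any() or (np.diff(edges) <= 0).any():
            raise ValueError("bin edges must be positive and strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def labels(self) -> list[str]:
        return [
            f"({left:.3g}, {right:.3g}]"
            for left, right in zip(self.edges[:-1], self.edges[1:])
        ]


def make_log_bins(start: float = 0.1, factor: float = 10 ** 0.5, stop: float = 1e5) -> BinSpec:
    """Geometric bin edges start, start*f, start*f^2, ... up to and covering
    ``stop``.  The default factor 10^0.5 makes consecutive bin means differ
    by about threefold; with start=0.1 the first bin is (0.1, 0.316].
    """
    if start <= 0 or factor <= 1 or stop <= start:
        raise ValueError("require start > 0, factor > 1, stop > start")
    edges = [start]
    i = 1
    while edges[-1] < stop * (1 - 1e-12):
        edges.append(start * factor**i)
        i += 1
    return BinSpec(np.asarray(edges))


def _bin_counts(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts per (left, right] bin; values <= edges[0] or > edges[-1] are
    excluded."""
    idx = np.searchsorted(edges, values, side="left")
    inside = (idx >= 1) & (idx <= edges.size - 1)
    return np.bincount(idx[inside] - 1, minlength=edges.size - 1)


def bin_distribution(
    matrix: IsoformAbundanceMatrix,
    metadata: pd.DataFrame,
    bins: BinSpec,
    mode: str = "per_sample",
) -> pd.DataFrame:
    """Distribution of isoform abundances over bins, per biospecimen type.

    mode="per_sample": count isoforms per bin in each sample, then report
    the mean and a Student-t 95% interval across the type's samples.  A
    one-sample type yields the point value with a warning.

    mode="per_isoform_mean": average each isoform's TPM across the type's
    samples first (zeros, i.e. undetected, included in the mean), then count
    the mean values per bin once; no interval applies.  Low-abundance bins
    are sensitive to this choice of averaging, which is why both modes
    exist.

    Returns a long-format frame: type, bin, bin_left, bin_right,
    mean_count, ci95_low, ci95_high, mode.
    """
    if mode not in ("per_sample", "per_isoform_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    edges = bins.edges
    labels = bins.labels()
    rows = []
    for type_label, group in metadata.groupby("type", sort=False):
        samples = list(group["sample_id"])
        if mode == "per_sample":
            counts = np.vstack(
                [_bin_counts(matrix.tpm[s].to_numpy(), edges) for s in samples]
            )
            n = len(samples)
            mean = counts.mean(axis=0)
            if n == 1:
                warnings.warn(
                    f"type '{type_label}' has a single sample; confidence "
                    "interval undefined, reporting the point value",
                    stacklevel=2,
                )
                low = high = mean
            else:
                sem = counts.std(axis=0, ddof=1) / np.sqrt(n)
                tcrit = stats.t.ppf(0.975, df=n - 1)
                low, high = mean - tcrit * sem, mean + tcrit * sem
        else:
            means = matrix.tpm[samples].mean(axis=1).to_numpy()
            mean = _bin_counts(means, edges).astype(float)
            low = high = np.full_like(mean, np.nan)
        for b in range(bins.n_bins):
            rows.append(
                {
                    "type": type_label,
                    "bin": labels[b],
                    "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "mean_count": mean[b],
                    "ci95_low": low[b],
                    "ci95_high": high[b],
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)
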