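"""Selection of genes driving the separation of biospecimen types.

Two filters applied in sequence, per principal component:

1. *Loading outliers*: genes whose loading falls outside the Tukey box-plot
   fences [Q1 - k*IQR, Q3 + k*IQR] (k = 1.5 by default, quartiles by linear
   interpolation) — the genes with unusually strong influence on the
   component.
2. *One-way ANOVA* across biospecimen types on each outlier gene's DS
   values, keeping genes with p below a raw significance threshold
   (0.01 by default; no multiple-testing correction, an optional
   Benjamini–Hochberg adjustment is available).

The surviving gene lists are exported one ID per line for external
enrichment tools.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import DSMatrix
from .pca import PCAResult, loadings

__all__ = [
    "GeneSelection",
    "tukey_outliers",
    "anova_per_gene",
    "select_genes",
    "export_gene_list",
]


def tukey_outliers(values: pd.Series, k: float = 1.5) -> pd.Index:
    """IDs whose value lies outside the box-plot whisker fences
    Q1 - k*IQR and Q3 + k*IQR, with quartiles by linear interpolation.

    Requires at least 4 values; all-identical values have zero IQR and
    yield an empty set.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if len(values) < 4:
        raise ValueError("need at least 4 values for box-plot fences")
    v = values.to_numpy(dtype=float)
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation (default)
    iqr = q3 - q1
    low, high = q1 - k * iqr, q3 + k * iqr
    return values.index[(v < low) | (v > high)]


def anova_per_gene(ds: DSMatrix | pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Classic one-way ANOVA of each gene's DS values grouped by type.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom.  With
    zero within-group variance: equal group means give F = 0, p = 1;
    unequal means give p = 0 with the ``degenerate`` flag set.  Returns a
    frame indexed by gene with columns F, p, degenerate.
    """
    frame = ds.ds if isinstance(ds, DSMatrix) else ds
    type_of = metadata.set_index("sample_id")["type"]
    groups = type_of.reindex(frame.columns)
    if groups.isna().any():
        raise ValueError("metadata does not cover all samples")
    labels = groups.unique()
    sizes = groups.value_counts()
    if len(labels) < 2 or (sizes < 2).any():
        raise ValueError("ANOVA requires >= 2 types with >= 2 samples each")

    X = frame.to_numpy(dtype=float)  # genes x samples
    n_total = X.shape[1]
    k = len(labels)
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for lab in labels:
        cols = (groups == lab).to_numpy()
        n_g = cols.sum()
        gmean = X[:, cols].mean(axis=1)
        ssb += n_g * (gmean - grand) ** 2
        ssw += ((X[:, cols] - gmean[:, None]) ** 2).sum(axis=1)

    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(F, df_b, df_w)

    degenerate = (ssw == 0) & (ssb > 0)
    all_equal = (ssw == 0) & (ssb == 0)
    F = np.where(all_equal, 0.0, F)
    p = np.where(all_equal, 1.0, p)
    F = np.where(degenerate, np.inf, F)
    p = np.where(degenerate, 0.0, p)
    return pd.DataFrame({"F": F, "p": p, "degenerate": degenerate}, index=frame.index)


@dataclasses.dataclass(frozen=True)
class GeneSelection:
    """Outcome of the loading-outlier + ANOVA filter for one component."""

    component: int
    loading: pd.Series
    outlier_genes: pd.Index
    f_stat: pd.Series
    p_value: pd.Series
    significant_genes: pd.Index
    alpha: float
    whisker_k: float

    def to_frame(self) -> pd.DataFrame:
        """Per-gene table: loading, outlier flag, F, p, selected flag."""
        df = pd.DataFrame({"loading": self.loading})
        df["component"] = self.component
        df["outlier"] = df.index.isin(self.outlier_genes)
        df["F"] = self.f_stat.reindex(df.index)
        df["p"] = self.p_value.reindex(df.index)
        df["selected"] = df.index.isin(self.significant_genes)
        df.index.name = "gene_id"
        return df


def select_genes(
    pca_result: PCAResult,
    ds: DSMatrix,
    metadata: pd.DataFrame,
    component: int = 1,
    whisker_k: float = 1.5,
    alpha: float = 0.01,
    fdr_correction: bool = False,
) -> GeneSelection:
    """Loading outliers of one component, filtered by per-gene one-way
    ANOVA at ``alpha``.

    ANOVA is run only on the outlier genes (the candidate set); with
    ``fdr_correction`` their p-values are Benjamini–Hochberg adjusted
    before thresholding (off by default — the conventional filter is the
    raw p < 0.01).
    """
    load = loadings(pca_result, component)
    outliers = tukey_outliers(load, k=whisker_k)
    if len(outliers):
        anova = anova_per_gene(DSMatrix(ds.ds.loc[outliers], ds.tpm_threshold), metadata)
        p = anova["p"]
        p_thresh = (
            pd.Series(stats.false_discovery_control(p.to_numpy()), index=p.index)
            if fdr_correction
            else p
        )
        significant = p.index[p_thresh < alpha]
        f_stat = anova["F"]
    else:
        f_stat = pd.Series(dtype=float)
        p = pd.Series(dtype=float)
        significant = pd.Index([])
    return GeneSelection(
        component=component,
        loading=load,
        outlier_genes=outliers,
        f_stat=f_stat,
        p_value=p,
        significant_genes=significant,
        alpha=alpha,
        whisker_k=whisker_k,
    )


def export_gene_list(selection: GeneSelection | pd.Index, path: str | Path) -> None:
    """Write selected gene IDs one per line (for external enrichment tools)."""
    ids = (
        selection.significant_genes
        if isinstance(selection, GeneSelection)
        else pd.Index(selection)
    )
    Path(path).write_text("".join(f"{g}\n" for g in ids))
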