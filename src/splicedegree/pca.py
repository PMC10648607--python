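"""PCA of degree-of-splicing profiles.

Samples (biospecimens) are the observations and genes the variables: the
genes x samples DS matrix is transposed, each gene is mean-centred across
samples (no variance scaling, so abundant-splicing genes retain their
weight), and a deterministic full SVD yields per-sample scores,
explained-variance ratios and per-gene loadings.  Loadings are the entries
of each component's unit eigenvector: they lie in [-1, 1] and their
magnitude measures how strongly a gene drives that component — the basis of
the downstream gene selection.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .metrics import DSMatrix

__all__ = ["PCAResult", "run_pca", "loadings", "scores_table", "plot_scores"]


@dataclasses.dataclass(frozen=True)
class PCAResult:
    """Scores (samples x components), explained-variance ratios, loadings
    (genes x components, unit norm per column) and the per-gene means used
    for centring."""

    scores: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    means: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _as_frame(ds: DSMatrix | pd.DataFrame) -> pd.DataFrame:
    return ds.ds if isinstance(ds, DSMatrix) else ds


def run_pca(ds: DSMatrix | pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a genes x samples DS matrix.

    Components are ordered by explained variance (sample variance,
    denominator n-1); each component's sign is fixed so its
    largest-magnitude loading is positive, removing the SVD sign ambiguity.
    A constant matrix yields all-zero ratios with a warning.
    """
    frame = _as_frame(ds)
    n_samples, n_genes = frame.shape[1], frame.shape[0]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_comp = min(n_samples - 1, n_genes)
    if n_components is None:
        n_components = max_comp
    if not (1 <= n_components <= max_comp):
        raise ValueError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )

    X = frame.T.to_numpy(dtype=float)  # samples x genes
    means = X.mean(axis=0)
    if np.allclose(X, X[0], atol=0):
        warnings.warn("constant DS matrix: all explained-variance ratios are 0",
                      stacklevel=2)
        scores = np.zeros((n_samples, n_components))
        comps = np.zeros((n_components, n_genes))
        comps[np.arange(n_components), np.arange(n_components)] = 1.0
        ev = np.zeros(n_components)
        evr = np.zeros(n_components)
    else:
        model = _SKPCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(X)
        comps = model.components_
        ev = model.explained_variance_
        evr = model.explained_variance_ratio_
        # sign convention: largest-|loading| entry positive per component
        flip = np.sign(comps[np.arange(n_components), np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        comps = comps * flip[:, None]
        scores = scores * flip[None, :]

    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=frame.columns, columns=pcs),
        explained_variance=ev,
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(comps.T, index=frame.index, columns=pcs),
        means=pd.Series(means, index=frame.index, name="mean_ds"),
    )


def loadings(result: PCAResult, component: int) -> pd.Series:
    """The unit-eigenvector entries of one component (1-based), keyed by
    gene ID."""
    if not (1 <= component <= result.n_components):
        raise ValueError(
            f"component must be in [1, {result.n_components}], got {component}"
        )
    return result.loadings[f"PC{component}"]


def scores_table(result: PCAResult, metadata: pd.DataFrame) -> pd.DataFrame:
    """Long-format plotting table: sample, type, one column per PC; axis
    labels with explained-variance percentages in ``df.attrs['axis_labels']``."""
    missing = result.scores.index.difference(metadata["sample_id"])
    if len(missing):
        raise ValueError(f"metadata does not cover samples: {list(missing)}")
    type_of = metadata.set_index("sample_id")["type"]
    df = result.scores.copy()
    df.insert(0, "type", type_of.reindex(df.index))
    df = df.reset_index(names="sample")
    df.attrs["axis_labels"] = {
        f"PC{i + 1}": f"PC{i + 1} ({100 * r:.1f}%)"
        for i, r in enumerate(result.explained_variance_ratio)
    }
    return df


def plot_scores(result: PCAResult, metadata: pd.DataFrame, path) -> None:
    """2D score plot (PC1 vs PC2) coloured by biospecimen type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = scores_table(result, metadata)
    fig, ax = plt.subplots(figsize=(5, 4))
    for type_label, grp in table.groupby("type", sort=False):
        ax.scatter(grp["PC1"], grp.get("PC2", 0.0), label=type_label, s=40)
    labels = table.attrs["axis_labels"]
    ax.set_xlabel(labels["PC1"])
    ax.set_ylabel(labels.get("PC2", "PC2"))
    ax.legend(title="type")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
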