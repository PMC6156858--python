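"""Expression summaries: variance-stabilized transform, scaling, PCA, and
per-community expression profiles.

The transform is log2(CPM + 1) — a simple variance-stabilizing choice that is
monotone in counts and invariant to library size; downstream scaling, PCA and
grouping are transform-agnostic. Rows (genes) are scaled either to [0, 1] or
to z-scores (mean 0, sd 1, sample sd as in R's ``scale``); PCA uses the top
500 most variable genes by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .enrich import AnnotationMap

__all__ = ["ScaledMatrix", "vst", "scale_rows", "pca_top_variance", "community_profiles"]


def vst(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount), genes x samples."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    return np.log2(counts * 1e6 / lib + pseudocount)


@dataclass
class ScaledMatrix:
    """Row-scaled expression matrix plus the rows that were constant."""

    values: pd.DataFrame
    mode: str
    degenerate_rows: frozenset


def scale_rows(m: pd.DataFrame, mode: str = "unit_interval") -> ScaledMatrix:
    """Scale each row to [0, 1] (min-max) or to mean 0 / sd 1 (``zscore``).

    Constant rows cannot be scaled; they are set to all zeros and reported in
    ``degenerate_rows``.
    """
    if mode not in ("unit_interval", "zscore"):
        raise ValueError(f"unknown scaling mode: {mode!r}")
    x = m.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite entries")
    if mode == "unit_interval":
        lo = x.min(axis=1, keepdims=True)
        span = x.max(axis=1, keepdims=True) - lo
        degenerate = span[:, 0] == 0
        span[degenerate] = 1.0
        scaled = (x - lo) / span
    else:
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        degenerate = sd[:, 0] == 0
        sd[degenerate] = 1.0
        scaled = (x - mean) / sd
    scaled[degenerate] = 0.0
    return ScaledMatrix(
        values=pd.DataFrame(scaled, index=m.index, columns=m.columns),
        mode=mode,
        degenerate_rows=frozenset(m.index[degenerate]),
    )


def pca_top_variance(m: pd.DataFrame, n_top: int = 500):
    """Sample coordinates on PC1/PC2 from the most variable genes.

    Rows are restricted to the ``n_top`` highest-variance genes, centered and
    scaled per gene (z-score), and the samples projected by SVD. The sign of
    each component is fixed so its largest-magnitude gene loading is
    positive, making the output reproducible. Returns (coordinates,
    variance_explained) with variance explained in percent over all PCs.
    """
    if m.shape[1] < 3:
        raise ValueError("PCA needs >= 3 samples")
    if n_top > m.shape[0]:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {m.shape[0]}; using all genes",
            stacklevel=2,
        )
        n_top = m.shape[0]
    variances = m.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[:n_top]
    scaled = scale_rows(m.loc[top], mode="zscore").values.to_numpy()
    # samples as observations: X is samples x genes with centered columns
    x = scaled.T
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for j in range(len(s)):  # sign convention: dominant loading positive
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u * s
    var_explained = 100.0 * s**2 / np.sum(s**2) if np.sum(s**2) > 0 else s * 0.0
    out = pd.DataFrame(
        coords[:, :2], index=m.columns, columns=["PC1", "PC2"]
    )
    return out, var_explained


def community_profiles(
    scaled: ScaledMatrix, annotations: AnnotationMap, communities: dict
):
    """Per-community expression summaries and a grouped heatmap row order.

    A community's genes are those annotated to any of its member terms and
    present in the matrix; a gene annotated into several communities appears
    in each (duplication is deliberate). Rows are grouped by community and
    ordered within by hierarchical clustering (Euclidean distance, average
    linkage). Returns (mean_profiles, row_order): mean_profiles is a
    community x sample DataFrame, row_order has columns (community, gene).
    """
    matrix = scaled.values
    comm_terms: dict[int, list] = {}
    for term, lab in communities.items():
        comm_terms.setdefault(lab, []).append(term)

    profiles = {}
    order_rows = []
    any_overlap = False
    for lab in sorted(comm_terms):
        genes: set[str] = set()
        for term in comm_terms[lab]:
            genes |= set(annotations.term_to_genes.get(term, ()))
        genes &= set(matrix.index)
        if not genes:
            warnings.warn(f"community {lab} has no genes in the matrix; dropped", stacklevel=2)
            continue
        any_overlap = True
        sub = matrix.loc[sorted(genes)]
        profiles[lab] = sub.mean(axis=0)
        if len(sub) > 2:
            z = linkage(pdist(sub.to_numpy(), metric="euclidean"), method="average")
            ordered = [sub.index[i] for i in leaves_list(z)]
        else:
            ordered = list(sub.index)
        order_rows.extend((lab, g) for g in ordered)
    if not any_overlap:
        raise ValueError("no community gene overlaps the expression matrix")
    mean_profiles = pd.DataFrame(profiles).T
    mean_profiles.index.name = "community"
    row_order = pd.DataFrame(order_rows, columns=["community", "gene"])
    return mean_profiles, row_order
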