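"""Expression normalisation, ordination, clustering, DEG calling, enrichment.

FPKM normalisation, sample-level PCA on log2(FPKM+1), k-means clustering of
z-scored expression profiles (size-ordered relabelling for determinism),
fold-change DEG calling for a no-replicate design, and classic hypergeometric
over-representation with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "fpkm",
    "pca",
    "cluster_profiles",
    "deg_pairwise",
    "term_enrichment",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (q_(i) = min_{j>=i} p_(j)*m/j)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_ij = counts_ij * 1e9 / (length_i * library_size_j); library sizes
    default to column sums.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def pca(matrix: pd.DataFrame, log_transform: bool = True,
        n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Sample-level PCA of an id x sample expression matrix.

    Samples are observations; features are log2(x+1)-transformed (optional)
    and centered.  Components come from the SVD of the centered sample x
    feature matrix; the sign of each component is fixed so that its
    largest-magnitude feature loading is positive, making scores
    deterministic.  Returns (scores, explained_variance_ratio, loadings).
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if log_transform:
        x = np.log2(x + 1)
    x = x - x.mean(axis=0, keepdims=True)
    n_components = min(n_components, min(x.shape))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = (s**2).sum()
    evr = (s**2 / total_var)[:n_components] if total_var > 0 else np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        evr,
        pd.DataFrame(loadings, index=cols, columns=matrix.index),
    )


def cluster_profiles(matrix: pd.DataFrame, k: int = 5,
                     seed: int = 0, n_init: int = 10) -> tuple[pd.Series, pd.DataFrame]:
    """k-means clustering of row-z-scored expression profiles.

    Zero-variance rows are dropped (they carry no profile shape).  Cluster
    labels are renumbered 1..k by descending cluster size (ties by original
    centroid order) so output is stable across runs with the same seed.
    Returns (id -> label, per-cluster mean z-profile).
    """
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    ids = matrix.index[keep]
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    k_eff = min(k, len(ids))
    if k_eff == 0:
        raise ValueError("no rows with nonzero variance to cluster")
    km = KMeans(n_clusters=k_eff, random_state=seed, n_init=n_init)
    raw = km.fit_predict(z)
    # renumber by descending size; ties broken by the smallest member id so
    # the numbering does not depend on row order
    members: dict[int, list] = {}
    for rid, lbl in zip(ids, raw):
        members.setdefault(int(lbl), []).append(str(rid))
    order = sorted(members, key=lambda lbl: (-len(members[lbl]),
                                             min(members[lbl])))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[r] for r in raw], index=ids, name="cluster")
    means = (
        pd.DataFrame(z, index=ids, columns=matrix.columns)
        .groupby(labels)
        .mean()
    )
    return labels, means


def deg_pairwise(matrix: pd.DataFrame,
                 sample_pairs: Sequence[tuple[str, str]],
                 min_fold: float = 1.0,
                 min_fpkm: float = 1.0) -> tuple[pd.DataFrame, set[str]]:
    """Fold-change DEG calls for a design without replicates.

    A gene is differential for a pair iff |log2((a+1)/(b+1))| >= ``min_fold``
    and max(a, b) >= ``min_fpkm``.  Returns the per-pair call table and the
    union DEG set over all pairs.  Symmetric in pair order.
    """
    rows = []
    union: set[str] = set()
    for s1, s2 in sample_pairs:
        a = matrix[s1].to_numpy(dtype=float)
        b = matrix[s2].to_numpy(dtype=float)
        lfc = np.log2((a + 1) / (b + 1))
        deg = (np.abs(lfc) >= min_fold) & (np.maximum(a, b) >= min_fpkm)
        for gid, l, d in zip(matrix.index, lfc, deg):
            rows.append(
                {
                    "gene_id": gid,
                    "sample_1": s1,
                    "sample_2": s2,
                    "log2_fc": float(l),
                    "deg": bool(d),
                }
            )
            if d:
                union.add(gid)
    return (
        pd.DataFrame(rows, columns=["gene_id", "sample_1", "sample_2", "log2_fc", "deg"]),
        union,
    )


def term_enrichment(selected: set[str], universe: set[str],
                    term_map: Mapping[str, set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term, with BH.

    For a term covering K of N universe genes and k of the n selected genes,
    p = P(X >= k) under the hypergeometric null.  ``selected`` must be a
    non-empty subset of ``universe``.  (Plain hypergeometric — no term-graph
    decorrelation.)
    """
    if not selected:
        raise ValueError("selected set is empty")
    if not selected <= universe:
        raise ValueError("selected set must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term, genes in sorted(term_map.items()):
        genes_in_universe = genes & universe
        K = len(genes_in_universe)
        if K == 0:
            continue
        k = len(genes_in_universe & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "term_size": K,
                "n_selected": n,
                "n_overlap": k,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "term_size", "n_selected", "n_overlap", "p_value"])
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"])
        df = df.sort_values(["p_value", "term"]).reset_index(drop=True)
    else:
        df["q_value"] = []
    return df
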