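"""Concordance metrics between quantification strategies.

Given two count matrices produced by alternative quantification routes,
concordance is measured at the level of cell clusterings: mutual
information and adjusted mutual information (AMI) between cluster
assignments, pairwise Jaccard similarity between clusters, greedy cluster
matching, marker-region selection (one-vs-rest Wilcoxon rank-sum) and the
genomic-distance concordance of markers, plus the AMI trend as a function
of how many regions enter the analysis.

AMI here uses the permutation (hypergeometric) model for the expected
mutual information, natural logarithms, and the arithmetic mean of the two
entropies as normalizer:

    AMI(U, V) = (I(U;V) - E[I]) / ((H(U) + H(V)) / 2 - E[I])

A labeling is a :class:`pandas.Series` of cluster labels indexed by cell
id.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.special import gammaln
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .bus_ops import CountMatrix
from .reference import RegionSet

__all__ = [
    "cluster_cells",
    "mutual_information",
    "expected_mutual_information",
    "ami",
    "match_clusters",
    "marker_regions",
    "marker_concordance",
    "ami_vs_cutoff",
    "jaccard_pairs",
    "read_labeling",
    "write_labeling",
]

logger = logging.getLogger(__name__)

Labeling = pd.Series


def read_labeling(path: str | Path) -> Labeling:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cluster"], dtype=str)
    return pd.Series(df["cluster"].values, index=df["cell_id"].values)


def write_labeling(labels: Labeling, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"cell_id": labels.index, "cluster": labels.values}).to_csv(
        path, sep="\t", header=False, index=False
    )
    return path


# --------------------------------------------------------------------------
# clustering


def cluster_cells(
    matrix: CountMatrix,
    min_regions_per_cell: int = 200,
    min_cells_per_region: int = 10,
    resolution: float = 0.2,
    seed: int = 0,
    n_top_regions: int = 15000,
    n_comps: int = 50,
    n_neighbors: int = 15,
) -> Labeling:
    """Filter, normalize and Leiden-cluster a cells x regions count matrix.

    Cells with fewer than ``min_regions_per_cell`` detected regions and
    regions detected in fewer than ``min_cells_per_region`` cells are
    removed; counts are normalized per cell to the median total, log(1+x)
    transformed; the most variable regions are kept; PCA, a k-nearest-
    neighbor graph and a Leiden partition at ``resolution`` follow.
    Deterministic under a fixed ``seed``.
    """
    adata = ad.AnnData(
        X=sp.csr_matrix(matrix.matrix, dtype=np.float64),
        obs=pd.DataFrame(index=matrix.barcodes),
        var=pd.DataFrame(index=matrix.features),
    )
    sc.pp.filter_cells(adata, min_genes=min_regions_per_cell)
    sc.pp.filter_genes(adata, min_cells=min_cells_per_region)
    if adata.n_obs == 0:
        raise ValueError("all cells removed by filtering")
    if adata.n_vars == 0:
        raise ValueError("all regions removed by filtering")
    sc.pp.normalize_total(adata)  # per-cell, to the median total count
    sc.pp.log1p(adata)
    if 0 < n_top_regions < adata.n_vars:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top_regions)
        adata = adata[:, adata.var["highly_variable"]].copy()
    n_comps_eff = min(n_comps, adata.n_obs - 1, adata.n_vars - 1)
    sc.pp.pca(adata, n_comps=n_comps_eff, random_state=seed)
    sc.pp.neighbors(
        adata, n_neighbors=min(n_neighbors, adata.n_obs - 1), random_state=seed
    )
    with warnings.catch_warnings():
        # the leidenalg backend is pinned deliberately; scanpy warns about
        # its future default change
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata, resolution=resolution, random_state=seed, flavor="leidenalg"
        )
    return pd.Series(adata.obs["leiden"].astype(str).values, index=adata.obs_names)


# --------------------------------------------------------------------------
# information-theoretic concordance


def _contingency(a: Labeling, b: Labeling) -> np.ndarray:
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("labelings share no cells")
    if len(shared) < len(a) or len(shared) < len(b):
        logger.warning(
            "labelings differ in cell sets; using %d shared cells", len(shared)
        )
    return pd.crosstab(a.loc[shared].values, b.loc[shared].values).to_numpy()


def _mi_from_contingency(c: np.ndarray) -> float:
    n = c.sum()
    nz = c > 0
    pij = c[nz] / n
    ai = c.sum(axis=1, keepdims=True) / n
    bj = c.sum(axis=0, keepdims=True) / n
    outer = (ai @ bj)[nz]
    return float(np.sum(pij * (np.log(pij) - np.log(outer))))


def mutual_information(a: Labeling, b: Labeling) -> float:
    """Mutual information (nats) of the joint label contingency table."""
    return max(0.0, _mi_from_contingency(_contingency(a, b)))


def expected_mutual_information(contingency: np.ndarray) -> float:
    """Expected MI under the permutation (hypergeometric) model.

    Averages the MI over all joint tables with the observed marginals,
    each cell count following a hypergeometric law.
    """
    c = np.asarray(contingency)
    a = c.sum(axis=1).astype(np.int64)
    b = c.sum(axis=0).astype(np.int64)
    n = int(c.sum())
    emi = 0.0
    gln_n = gammaln(n + 1)
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = (nij / n) * (np.log(n * nij) - np.log(ai * bj))
                # hypergeometric pmf via log-factorials
                logp = (
                    gammaln(ai + 1)
                    + gammaln(bj + 1)
                    + gammaln(n - ai + 1)
                    + gammaln(n - bj + 1)
                    - gln_n
                    - gammaln(nij + 1)
                    - gammaln(ai - nij + 1)
                    - gammaln(bj - nij + 1)
                    - gammaln(n - ai - bj + nij + 1)
                )
                emi += term * np.exp(logp)
    return float(emi)


def _entropy(marginal: np.ndarray) -> float:
    p = marginal[marginal > 0] / marginal.sum()
    return float(-np.sum(p * np.log(p)))


def ami(a: Labeling, b: Labeling) -> float:
    """Adjusted mutual information between two labelings.

    1 for identical partitions with at least two clusters; 0 when the
    chance-corrected denominator is zero (e.g. either partition is a
    single cluster).
    """
    c = _contingency(a, b)
    mi = _mi_from_contingency(c)
    emi = expected_mutual_information(c)
    h_mean = (_entropy(c.sum(axis=1)) + _entropy(c.sum(axis=0))) / 2
    denominator = h_mean - emi
    if denominator == 0.0:
        return 0.0
    return (mi - emi) / denominator


# --------------------------------------------------------------------------
# cluster matching and Jaccard


def match_clusters(a: Labeling, b: Labeling) -> dict:
    """Greedy maximum-overlap matching of a's clusters to b's clusters.

    Repeatedly pairs the (cluster_a, cluster_b) with the largest number of
    shared cells among still-unmatched clusters; ties are broken by the
    lexicographically smaller label pair.  Unmatched clusters map to
    ``None``.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("labelings share no cells")
    ct = pd.crosstab(a.loc[shared], b.loc[shared])
    mapping: dict = {}
    free_rows = sorted(ct.index, key=str)
    free_cols = sorted(ct.columns, key=str)
    while free_rows and free_cols:
        # max on count; ties -> smaller row label, then smaller column label
        best_count = max(ct.loc[i, j] for i in free_rows for j in free_cols)
        candidates = [
            (str(i), str(j), i, j)
            for i in free_rows
            for j in free_cols
            if ct.loc[i, j] == best_count
        ]
        _, _, i, j = min(candidates)
        mapping[i] = j
        free_rows.remove(i)
        free_cols.remove(j)
    for i in free_rows:
        mapping[i] = None
    return mapping


def jaccard_pairs(a: Labeling, b: Labeling) -> pd.DataFrame:
    """Pairwise Jaccard coefficients between clusters of two labelings.

    Entry (i, j) = |cells_i(a) ∩ cells_j(b)| / |cells_i(a) ∪ cells_j(b)|,
    over all cells present in either labeling.
    """
    clusters_a = {lab: set(a.index[a.values == lab]) for lab in pd.unique(a.values)}
    clusters_b = {lab: set(b.index[b.values == lab]) for lab in pd.unique(b.values)}
    rows = sorted(clusters_a, key=str)
    cols = sorted(clusters_b, key=str)
    out = pd.DataFrame(0.0, index=rows, columns=cols)
    for i in rows:
        for j in cols:
            inter = len(clusters_a[i] & clusters_b[j])
            union = len(clusters_a[i] | clusters_b[j])
            out.loc[i, j] = inter / union if union else 0.0
    return out


# --------------------------------------------------------------------------
# marker regions


def _normalize_log(matrix: CountMatrix) -> np.ndarray:
    X = np.asarray(matrix.matrix.todense(), dtype=np.float64)
    totals = X.sum(axis=1)
    target = np.median(totals[totals > 0])
    scale = np.divide(target, totals, out=np.ones_like(totals), where=totals > 0)
    return np.log1p(X * scale[:, None])


def marker_regions(
    matrix: CountMatrix,
    labels: Labeling,
    top_n: int = 1000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    Counts are median-normalized and log(1+x) transformed; per cluster and
    region a two-sided normal-approximation rank-sum test (with tie
    correction) compares the cluster's cells against the rest;
    Benjamini-Hochberg adjustment is applied within each cluster; regions
    with adjusted p < ``alpha`` are kept, ranked by descending test
    statistic (the z score), truncated to ``top_n``.

    Returns a DataFrame with columns (cluster, region_id, statistic, p_adj).
    """
    labels = labels.loc[labels.index.intersection(matrix.barcodes)]
    if labels.nunique() < 2:
        raise ValueError("marker selection needs at least 2 clusters")
    row = {cb: i for i, cb in enumerate(matrix.barcodes)}
    idx = np.array([row[c] for c in labels.index])
    X = _normalize_log(matrix)[idx]
    lab = np.asarray(labels.values)
    n_cells, n_regions = X.shape
    ranks = np.apply_along_axis(rankdata, 0, X)
    # tie correction term per region: sum(t^3 - t) over tie groups
    tie_term = np.zeros(n_regions)
    for j in range(n_regions):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)

    tables = []
    for cl in sorted(pd.unique(lab), key=str):
        mask = lab == cl
        n1 = int(mask.sum())
        n2 = n_cells - n1
        if n1 < 2:
            logger.warning("cluster %s has %d cell(s); skipped", cl, n1)
            continue
        r1 = ranks[mask].sum(axis=0)
        u = r1 - n1 * (n1 + 1) / 2
        mean_u = n1 * n2 / 2
        var_u = (n1 * n2 / 12) * (
            (n_cells + 1) - tie_term / (n_cells * (n_cells - 1))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(var_u > 0, (u - mean_u) / np.sqrt(var_u), 0.0)
        pvals = 2 * norm.sf(np.abs(z))
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        keep = p_adj < alpha
        tab = pd.DataFrame(
            {
                "cluster": cl,
                "region_id": np.asarray(matrix.features)[keep],
                "statistic": z[keep],
                "p_adj": p_adj[keep],
            }
        )
        tab = tab.sort_values(
            ["statistic", "region_id"], ascending=[False, True]
        ).head(top_n)
        tables.append(tab)
    if not tables:
        return pd.DataFrame(columns=["cluster", "region_id", "statistic", "p_adj"])
    return pd.concat(tables, ignore_index=True)


def marker_concordance(
    markers_a: Iterable[str],
    markers_b: Iterable[str],
    regions_a: RegionSet,
    regions_b: RegionSet,
    near: int = 20000,
) -> tuple[float, float, float]:
    """Distance concordance of marker set A against marker set B.

    For each marker of A, the gap distance to the nearest marker of B on
    the same chromosome is computed (0 when they overlap); markers are
    binned into overlap (distance 0), near (0 < distance <= ``near``) and
    none (farther, or no same-chromosome B marker).  Returns the three
    proportions, which sum to 1.
    """
    markers_a = list(markers_a)
    markers_b = list(markers_b)
    if not markers_a or not markers_b:
        raise ValueError("empty marker set")
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for mid in markers_b:
        iv = regions_b[mid]
        b_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    bins = np.zeros(3, dtype=np.int64)  # overlap, near, none
    for mid in markers_a:
        iv = regions_a[mid]
        candidates = b_by_chrom.get(iv.chrom)
        if not candidates:
            bins[2] += 1
            continue
        dist = min(
            0 if (bs < iv.end and iv.start < be) else max(bs - iv.end, iv.start - be) + 1
            for bs, be in candidates
        )
        if dist == 0:
            bins[0] += 1
        elif dist <= near:
            bins[1] += 1
        else:
            bins[2] += 1
    props = bins / bins.sum()
    return (float(props[0]), float(props[1]), float(props[2]))


# --------------------------------------------------------------------------
# AMI vs region cutoff


def ami_vs_cutoff(
    matrix: CountMatrix,
    reference_labels: Labeling,
    cutoffs: Sequence[int],
    seed: int = 0,
    **cluster_kwargs,
) -> pd.DataFrame:
    """AMI against reference labels as a function of the region cutoff.

    For each cutoff N, the N regions detected in the most cells are kept
    (ties broken by region id), cells are re-clustered and the AMI against
    ``reference_labels`` computed.  Returns a DataFrame (cutoff, ami).
    """
    n_regions = len(matrix.features)
    for c in cutoffs:
        if not (0 < c <= n_regions):
            raise ValueError(f"cutoff {c} outside (0, {n_regions}]")
    detection = np.asarray((matrix.matrix > 0).sum(axis=0)).ravel()
    order = sorted(range(n_regions), key=lambda j: (-detection[j], matrix.features[j]))
    rows = []
    for cutoff in cutoffs:
        keep = sorted(order[:cutoff])
        sub = CountMatrix(
            matrix=matrix.matrix[:, keep],
            barcodes=list(matrix.barcodes),
            features=[matrix.features[j] for j in keep],
        )
        labels = cluster_cells(sub, seed=seed, **cluster_kwargs)
        rows.append((cutoff, ami(labels, reference_labels)))
    return pd.DataFrame(rows, columns=["cutoff", "ami"])
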