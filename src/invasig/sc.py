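"""Single-cell processing: QC, normalization, covariate regression,
significant-PC selection, graph clustering and cell-cycle scoring.

All operations work on an :class:`anndata.AnnData` with cells as
observations.  Boundary semantics follow the droplet workflow the
pipeline emulates: barcodes with > 500 total counts are kept, then
cells with >= 2000 detected genes and <= 15% mitochondrial reads.
Normalization is counts-per-10k with a natural-log(1 + x) transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCConfig",
    "PCSelection",
    "compute_qc_metrics",
    "qc_filter",
    "normalize_log",
    "regress_out",
    "significant_pcs",
    "cluster_cells",
    "cell_cycle_scores",
]


@dataclass
class QCConfig:
    min_barcode_counts: int = 500   # strict >
    min_genes: int = 2000           # cells with fewer detected genes removed
    max_mito_fraction: float = 0.15  # cells above removed
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if self.min_barcode_counts <= 0 or self.min_genes <= 0 or self.scale_factor <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if sparse.issparse(x) else x, dtype=float)


def _mito_mask(adata: ad.AnnData) -> np.ndarray:
    if "is_mito" in adata.var:
        return adata.var["is_mito"].to_numpy(bool)
    return np.array([str(g).startswith("MT-") for g in adata.var_names])


def compute_qc_metrics(adata: ad.AnnData) -> ad.AnnData:
    """Attach total_counts, n_genes_detected and mito_fraction (raw counts)."""
    x = _dense(adata.X)
    if (x < 0).any():
        raise ValueError("raw counts must be non-negative")
    totals = x.sum(axis=1)
    adata.obs["total_counts"] = totals
    adata.obs["n_genes_detected"] = (x > 0).sum(axis=1)
    mito = _mito_mask(adata)
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, x[:, mito].sum(axis=1) / np.maximum(totals, 1), 0.0)
    adata.obs["mito_fraction"] = frac
    return adata


def qc_filter(raw: ad.AnnData, cfg: QCConfig | None = None) -> ad.AnnData:
    """Two-stage QC on raw counts, preserving cell order.

    Stage 1 keeps barcodes with total counts strictly above
    ``min_barcode_counts``; stage 2 keeps cells with at least
    ``min_genes`` detected genes and mitochondrial fraction at most
    ``max_mito_fraction``.  Raises if no cell survives, reporting the
    attrition at each stage.
    """
    cfg = cfg or QCConfig()
    raw = compute_qc_metrics(raw.copy())
    n0 = raw.n_obs
    barcode_ok = raw.obs["total_counts"] > cfg.min_barcode_counts
    stage1 = raw[barcode_ok.to_numpy()].copy()
    cell_ok = (stage1.obs["n_genes_detected"] >= cfg.min_genes) & (
        stage1.obs["mito_fraction"] <= cfg.max_mito_fraction
    )
    out = stage1[cell_ok.to_numpy()].copy()
    if out.n_obs == 0:
        raise ValueError(
            "no cells survive QC: "
            f"{n0} barcodes -> {stage1.n_obs} after count filter "
            f"(> {cfg.min_barcode_counts}) -> 0 after gene/mito filter "
            f"(>= {cfg.min_genes} genes, <= {cfg.max_mito_fraction:.0%} mito)"
        )
    return compute_qc_metrics(out)


def normalize_log(raw: ad.AnnData, cfg: QCConfig | None = None) -> ad.AnnData:
    """ln(1 + count / cell_total * scale_factor), keeping raw counts in a layer."""
    cfg = cfg or QCConfig()
    out = compute_qc_metrics(raw.copy())
    x = _dense(out.X)
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts cannot be normalized")
    out.layers["counts"] = x.astype(np.int64)
    out.X = np.log1p(x / totals[:, None] * cfg.scale_factor)
    return out


def regress_out(norm: ad.AnnData, covariate) -> ad.AnnData:
    """Replace each gene's values by OLS residuals on (1, covariates).

    ``covariate`` is an obs column name, a per-cell vector, or a list
    of either (e.g. mitochondrial load plus cell-cycle scores).  A
    constant covariate carries no information and is dropped with a
    warning; if none remain the data are returned unchanged.
    """
    out = norm.copy()
    if isinstance(covariate, (str, np.ndarray, pd.Series)):
        covariate = [covariate]
    cols = []
    for c in covariate:
        v = out.obs[c].to_numpy(float) if isinstance(c, str) else np.asarray(c, float)
        if not np.all(np.isfinite(v)):
            raise ValueError("covariate must be finite")
        if np.ptp(v) == 0:
            warnings.warn("constant covariate dropped: regression on it is an identity")
            continue
        cols.append(v)
    if not cols:
        return out
    x = _dense(out.X)
    design = np.column_stack([np.ones(x.shape[0])] + cols)
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    out.X = x - design @ beta
    return out


@dataclass(frozen=True)
class PCSelection:
    """Leading principal components judged significant by permutation."""

    n_components: int
    pvalues: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def _pca(x: np.ndarray, k: int):
    """Loadings (genes x k) and scores (cells x k) of the centered matrix."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(k, len(s))
    return vt[:k].T, u[:, :k] * s[:k]


def significant_pcs(
    norm: ad.AnnData,
    n_perm: int = 100,
    perm_gene_fraction: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
    max_components: int = 20,
    scale: bool = False,
) -> PCSelection:
    """Permutation (jackstraw-style) selection of significant PCs.

    For each permutation a random ``perm_gene_fraction`` of genes has
    its values shuffled across cells and the PCA recomputed; the
    shuffled genes' absolute loadings form the per-component null.
    Each gene gets an empirical (rank-based) p-value against that null;
    the per-component p-value is the binomial tail probability of the
    observed excess of genes with empirical p <= 0.01.  The selection
    is the leading contiguous run with p < alpha; when no component is
    significant, one component is returned with a warning.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20 for a stable null")
    x = _dense(norm.X)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    rng = np.random.default_rng(seed)
    k = min(max_components, x.shape[0] - 1, x.shape[1])
    loadings, _ = _pca(x, k)
    observed = np.abs(loadings)

    n_sub = max(1, int(round(perm_gene_fraction * x.shape[1])))
    null = [[] for _ in range(k)]
    for _ in range(n_perm):
        gsel = rng.choice(x.shape[1], size=n_sub, replace=False)
        xp = x.copy()
        for g in gsel:
            xp[:, g] = rng.permutation(xp[:, g])
        lp, _ = _pca(xp, k)
        for j in range(k):
            null[j].append(np.abs(lp[gsel, j]))

    tail = 0.01  # per-gene empirical-p threshold defining the enriched tail
    pvals = np.empty(k)
    n_genes = x.shape[1]
    for j in range(k):
        nj = np.sort(np.concatenate(null[j]))
        # empirical p per gene: share of null loadings at least as large
        emp_p = 1.0 - np.searchsorted(nj, observed[:, j], side="left") / (len(nj) + 1)
        n_hits = int((emp_p <= tail).sum())
        pvals[j] = stats.binom.sf(n_hits - 1, n_genes, tail)

    n_sig = 0
    for p in pvals:
        if p < alpha:
            n_sig += 1
        else:
            break
    if n_sig == 0:
        warnings.warn("no significant components; falling back to 1")
        n_sig = 1
    return PCSelection(n_components=n_sig, pvalues=pvals, alpha=alpha)


def _snn_graph(scores: np.ndarray, k_neighbors: int) -> nx.Graph:
    """Shared-nearest-neighbor graph: kNN edges weighted by Jaccard overlap."""
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self at position 0
    n = scores.shape[0]
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    adj = sparse.csr_matrix((np.ones(idx.size), (rows, idx.ravel())), shape=(n, n))
    shared = (adj @ adj.T).tocoo()  # counts of shared neighbors (incl. self)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ksz = k_neighbors + 1
    knn_pairs = set(zip(rows.tolist(), idx.ravel().tolist()))
    for i, j, s in zip(shared.row, shared.col, shared.data):
        if i < j and ((i, j) in knn_pairs or (j, i) in knn_pairs):
            w = s / (2 * ksz - s)  # Jaccard of the two neighbor sets
            if w > 0:
                g.add_edge(int(i), int(j), weight=float(w))
    return g


def cluster_cells(
    norm: ad.AnnData,
    pcs: PCSelection | int,
    k_neighbors: int = 90,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Louvain community detection on the SNN graph in PC space.

    Labels are dense integers from 0, assigned in decreasing
    cluster-size order so downstream results are invariant to the
    partition's internal ordering.
    """
    n_pcs = pcs.n_components if isinstance(pcs, PCSelection) else int(pcs)
    x = _dense(norm.X)
    if x.shape[0] <= k_neighbors:
        raise ValueError("need more cells than k_neighbors")
    _, scores = _pca(x, n_pcs)
    g = _snn_graph(scores, k_neighbors)
    comms = nx.community.louvain_communities(g, weight="weight",
                                             resolution=resolution, seed=int(seed))
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    if len(comms) == 1:
        warnings.warn("graph collapsed to a single cluster")
    labels = np.empty(x.shape[0], dtype=int)
    for lab, members in enumerate(comms):
        labels[list(members)] = lab
    return labels


def cell_cycle_scores(
    norm: ad.AnnData,
    s_genes: list,
    g2m_genes: list,
    n_bins: int = 24,
    ctrl_per_gene: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Phase scores by expression-matched control subtraction.

    Genes are binned into ``n_bins`` by mean expression; each phase
    score is the mean expression of the phase genes minus the mean of a
    pooled control set drawn from the same bins.  Phase is the argmax
    of (S, G2M) when the larger score is positive, else G1.
    """
    rng = np.random.default_rng(seed)
    x = _dense(norm.X)
    genes = list(norm.var_names)
    gene_idx = {g: i for i, g in enumerate(genes)}

    def present(gs, label):
        kept = [g for g in gs if g in gene_idx]
        if len(kept) < len(gs):
            warnings.warn(f"{len(gs) - len(kept)} {label} genes absent from the matrix")
        if not kept:
            raise ValueError(f"no {label} genes present after dropping missing ones")
        return kept

    s_genes = present(s_genes, "S-phase")
    g2m_genes = present(g2m_genes, "G2M-phase")

    means = x.mean(axis=0)
    order = np.argsort(means, kind="stable")
    bins = np.empty(len(genes), dtype=int)
    bins[order] = np.arange(len(genes)) * n_bins // len(genes)
    by_bin = {b: np.flatnonzero(bins == b) for b in range(n_bins)}

    def score(phase_genes: list) -> np.ndarray:
        pidx = np.array([gene_idx[g] for g in phase_genes])
        ctrl: set[int] = set()
        for gi in pidx:
            pool = by_bin[bins[gi]]
            take = min(ctrl_per_gene, len(pool))
            ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl -= set(pidx.tolist())
        if not ctrl:
            raise ValueError("empty control pool for phase scoring")
        return x[:, pidx].mean(axis=1) - x[:, sorted(ctrl)].mean(axis=1)

    s_score = score(s_genes)
    g2m_score = score(g2m_genes)
    phase = np.where(
        np.maximum(s_score, g2m_score) <= 0, "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=norm.obs_names,
    )
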