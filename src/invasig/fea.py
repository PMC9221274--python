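"""Functional enrichment of a gene signature across cell clusters.

A signature score per cell is the mean z-scored expression of the
signature genes; each cluster is then compared one-vs-rest with a
two-sided Mann-Whitney rank-sum test and a ROC-AUC computed from the
same U statistic.  A cluster is called enriched when AUC > 0.6 and
p < 0.01 jointly (raw p; no correction across clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FEAConfig", "gene_zscore", "signature_score", "cluster_enrichment"]

#: product of group sizes below which the exact rank-sum null is enumerated
EXACT_LIMIT = 400


@dataclass
class FEAConfig:
    auc_min: float = 0.6
    p_max: float = 0.01

    def __post_init__(self) -> None:
        if not (0.5 < self.auc_min <= 1):
            raise ValueError("auc_min must lie in (0.5, 1]")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must lie in (0, 1)")


def gene_zscore(norm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across cells (sample sd, ddof=1).

    Zero-variance genes get z = 0 everywhere, with a warning.
    """
    norm = pd.DataFrame(norm)
    if norm.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    x = norm.to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance genes set to z=0")
    z = (x - mu) / np.where(flat, 1.0, sd)
    z[:, flat] = 0.0
    return pd.DataFrame(z, index=norm.index, columns=norm.columns)


def signature_score(z: pd.DataFrame, genes) -> pd.Series:
    """Per-cell mean z over the signature genes present in the matrix."""
    genes = list(genes)
    present = [g for g in genes if g in z.columns]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} signature genes absent; scoring on {len(present)}")
    return z[present].mean(axis=1)


def _rank_sum(in_scores: np.ndarray, out_scores: np.ndarray) -> tuple[float, float]:
    """U (pairs with in > out, ties half) and two-sided p.

    Exact enumeration of the rank-sum null when n_in * n_out is small;
    otherwise the tie- and continuity-corrected normal approximation.
    """
    method = "exact" if len(in_scores) * len(out_scores) <= EXACT_LIMIT else "asymptotic"
    res = stats.mannwhitneyu(in_scores, out_scores, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cluster_enrichment(
    scores: pd.Series,
    labels,
    cfg: FEAConfig | None = None,
) -> pd.DataFrame:
    """One-vs-rest enrichment of the signature score per cluster.

    Returns one row per cluster with group sizes, median scores, the
    rank-sum U, AUC = U / (n_in * n_out), the two-sided p, and the
    enriched flag (AUC > auc_min and p < p_max).
    """
    cfg = cfg or FEAConfig()
    scores = pd.Series(scores)
    labels = np.asarray(labels)
    if len(labels) != len(scores):
        raise ValueError("labels and scores must align")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    s = scores.to_numpy(float)
    for c in uniq:
        mask = labels == c
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_out == 0:
            raise ValueError(f"cluster {c} equals the whole population")
        if n_in < 2:
            raise ValueError(f"cluster {c} has fewer than 2 cells")
        u, p = _rank_sum(s[mask], s[~mask])
        auc = u / (n_in * n_out)
        rows.append({
            "cluster": c,
            "n_in": n_in,
            "n_out": n_out,
            "median_score_in": float(np.median(s[mask])),
            "median_score_out": float(np.median(s[~mask])),
            "U": u,
            "auc": auc,
            "p": p,
            "enriched": bool(auc > cfg.auc_min and p < cfg.p_max),
        })
    return pd.DataFrame(rows).set_index("cluster")
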