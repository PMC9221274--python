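"""Signature derivation from the four-condition DE results.

Two signatures are derived from the ICI-vs-vehicle contrasts in invaded
(INV+) and noninvaded (INV-) cells:

* Signature 1 -- genes passing a strict filter (FDR < 0.001,
  |log2FC| >= 0.5) in INV+ and not significantly ICI-regulated in INV-
  at the base filter (FDR <= 0.05);
* Signature 2 -- the same construction at a relaxed filter
  (FDR < 0.01, |log2FC| >= 0.25) after removing a supplied list of
  proliferation genes.

Exclusivity is decided on gene ids: a gene regulated in both contrasts
is excluded regardless of direction.  The base filter uses FDR <= 0.05
(inclusive); refilters use strict inequalities on FDR and >= on |log2FC|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DerivationConfig",
    "GeneSignature",
    "select_regulated",
    "exclusive_regulated",
    "derive_signature1",
    "derive_signature2",
    "signature_partition",
    "direction_subset",
]

logger = logging.getLogger(__name__)


@dataclass
class DerivationConfig:
    base_fdr: float = 0.05
    sig1_fdr: float = 0.001
    sig1_lfc: float = 0.5
    sig2_fdr: float = 0.01
    sig2_lfc: float = 0.25
    prolif_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sig1_fdr > self.base_fdr or self.sig2_fdr > self.base_fdr:
            raise ValueError("refilter FDR thresholds must not exceed the base FDR")
        if self.sig1_lfc < 0 or self.sig2_lfc < 0:
            raise ValueError("log2FC thresholds must be non-negative")
        self.prolif_genes = frozenset(self.prolif_genes)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with per-gene ICI-regulation direction."""

    name: str
    members: dict  # gene_id -> "up" | "down"

    def __post_init__(self) -> None:
        bad = {d for d in self.members.values()} - {"up", "down"}
        if bad:
            raise ValueError(f"invalid directions: {bad}")

    @property
    def genes(self) -> frozenset:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


def select_regulated(
    de: pd.DataFrame,
    fdr_max: float,
    lfc_min: float,
    fdr_inclusive: bool = False,
) -> dict:
    """Genes passing the FDR and |log2FC| filter, with direction.

    Direction is ``"up"`` when log2fc > 0, else ``"down"``.  The FDR
    comparison is strict by default; the base filter passes
    ``fdr_inclusive=True`` for its "0.05 or below" rule.
    """
    if lfc_min < 0:
        raise ValueError("lfc_min must be non-negative")
    if "fdr" not in de.columns:
        raise ValueError("DE table must carry an 'fdr' column")
    fdr_ok = de["fdr"] <= fdr_max if fdr_inclusive else de["fdr"] < fdr_max
    hit = de[fdr_ok & (de["log2fc"].abs() >= lfc_min)]
    return {g: ("up" if lfc > 0 else "down") for g, lfc in hit["log2fc"].items()}


def exclusive_regulated(inv_plus: dict, inv_minus: dict) -> dict:
    """Members of ``inv_plus`` whose gene id is absent from ``inv_minus``.

    The comparison ignores direction: a gene moving opposite ways in the
    two contrasts is still regulated in both and therefore excluded.
    """
    return {g: d for g, d in inv_plus.items() if g not in inv_minus}


def _derive(
    de_invplus: pd.DataFrame,
    de_invminus: pd.DataFrame,
    cfg: DerivationConfig,
    fdr: float,
    lfc: float,
    drop: frozenset,
    name: str,
) -> GeneSignature:
    base_minus = select_regulated(de_invminus, cfg.base_fdr, 0.0, fdr_inclusive=True)
    refined_plus = select_regulated(de_invplus, fdr, lfc)
    base_plus = select_regulated(de_invplus, cfg.base_fdr, 0.0, fdr_inclusive=True)
    refined_plus = {g: d for g, d in refined_plus.items() if g in base_plus and g not in drop}
    members = exclusive_regulated(refined_plus, base_minus)
    if not members:
        logger.warning("%s is empty at the requested thresholds", name)
    return GeneSignature(name=name, members=members)


def derive_signature1(
    de_invplus: pd.DataFrame, de_invminus: pd.DataFrame, cfg: DerivationConfig | None = None
) -> GeneSignature:
    """Strictly filtered, INV+-exclusive ICI-regulated genes."""
    cfg = cfg or DerivationConfig()
    return _derive(de_invplus, de_invminus, cfg, cfg.sig1_fdr, cfg.sig1_lfc,
                   frozenset(), "Signature1")


def derive_signature2(
    de_invplus: pd.DataFrame, de_invminus: pd.DataFrame, cfg: DerivationConfig | None = None
) -> GeneSignature:
    """Relaxed-filter, proliferation-depleted, INV+-exclusive genes."""
    cfg = cfg or DerivationConfig()
    return _derive(de_invplus, de_invminus, cfg, cfg.sig2_fdr, cfg.sig2_lfc,
                   cfg.prolif_genes, "Signature2")


def signature_partition(sig1: GeneSignature, sig2: GeneSignature) -> tuple[int, int, int]:
    """(|sig2|, overlap with sig1, sig2-distinct count), on gene ids."""
    n_total = len(sig2)
    n_overlap = len(sig2.genes & sig1.genes)
    return n_total, n_overlap, n_total - n_overlap


def direction_subset(sig: GeneSignature, direction: str) -> GeneSignature:
    """Restrict a signature to one ICI-regulation direction."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    return GeneSignature(name=f"{sig.name}_{direction}",
                         members={g: d for g, d in sig.members.items() if d == direction})
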