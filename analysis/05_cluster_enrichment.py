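"""Signature enrichment across the invaded-cell clusters.

Scores each cell as the mean z-scored expression of a gene set, then
compares every cluster one-vs-rest (Mann-Whitney + ROC-AUC; enriched
when AUC > 0.6 and p < 0.01).  Scores the planted enriched set and the
ICI-downregulated subset of the derived Signature 2.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

import pandas as pd

from invasig import fea, io, sc

_spec = importlib.util.spec_from_file_location(
    "sc_step", Path(__file__).parent / "04_single_cell_clustering.py")
_sc_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_sc_step)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    adata = _sc_step.load_sc(args.data_dir)
    meta = pd.read_csv(args.out_dir / "cells.tsv", sep="\t", index_col=0)
    kept = adata[meta.index.to_list()].copy()
    norm = sc.normalize_log(kept)
    expr = pd.DataFrame(norm.X, index=norm.obs_names, columns=norm.var_names)
    z = fea.gene_zscore(expr)

    gene_sets = {"planted_enriched":
                 io.read_gmt(args.data_dir / "sc_gene_sets.gmt")["planted_enriched"]}
    sigs = io.read_gmt(args.out_dir / "signatures.gmt")
    gene_sets["signature2_down"] = sigs.get("Signature2_down", [])

    for name, genes in gene_sets.items():
        present = [g for g in genes if g in z.columns]
        if not present:
            print(f"{name}: no genes present in the single-cell matrix "
                  "(bulk and single-cell fixtures use separate gene universes)")
            continue
        scores = fea.signature_score(z, present)
        res = fea.cluster_enrichment(scores, meta["cluster"].to_numpy())
        res.to_csv(args.out_dir / f"enrichment_{name}.tsv", sep="\t")
        flagged = list(res.index[res["enriched"]])
        print(f"{name}: scored {len(present)} genes; enriched clusters {flagged}")
        print(res[["n_in", "auc", "p", "enriched"]].round(4).to_string())


if __name__ == "__main__":
    main()
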