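"""Generate the study's synthetic inputs with planted ground truth.

Writes, under results/data/:
  * four bulk count matrices (invaded/noninvaded x +/-ICI) plus the
    planted-gene truth table and a proliferation gene set (GMT);
  * a single-cell UMI matrix (Matrix Market + id sidecars), the planted
    per-cell truth, and the S/G2M phase gene lists;
  * a patient cohort table with expression z-scores, clinical labels
    and survival endpoints, plus its truth groups.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from invasig import io, simulate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    bulk_cfg = simulate.default_bulk_config(args.seed)
    mats, truth = simulate.gen_bulk(bulk_cfg)
    for (inv, treat), counts in mats.items():
        tag = f"{'invplus' if inv == 'INV+' else 'invminus'}_{treat}"
        io.write_counts(counts, out / f"bulk_{tag}.tsv")
    truth.to_csv(out / "bulk_truth.tsv", sep="\t", index=False)
    prolif = truth.loc[truth["module_label"] == "proliferation", "gene_id"].tolist()
    io.write_gmt({"proliferation": prolif}, out / "proliferation.gmt")
    print(f"bulk: 4 x {bulk_cfg.n_genes} genes x {bulk_cfg.n_reps_per_group} reps, "
          f"{len(truth)} planted genes ({len(prolif)} proliferation)")

    sc_cfg = simulate.default_sc_config(args.seed + 1, low_quality_fraction=0.1)
    adata, sc_truth = simulate.gen_sc(sc_cfg)
    counts = pd.DataFrame(np.asarray(adata.X).T, index=adata.var_names,
                          columns=adata.obs_names)
    io.write_counts(counts, out / "sc_counts.mtx", fmt="mtx")
    sc_truth.to_csv(out / "sc_truth.tsv", sep="\t", index_label="barcode")
    io.write_gmt({
        "s_phase": adata.uns["s_genes"],
        "g2m_phase": adata.uns["g2m_genes"],
        "planted_enriched": adata.uns["enriched_gene_set"],
    }, out / "sc_gene_sets.gmt")
    n_lq = int(sc_truth["low_quality"].sum())
    print(f"single-cell: {sc_cfg.n_cells} barcodes x {sc_cfg.n_genes} genes, "
          f"{sc_cfg.n_clusters} clusters, {n_lq} planted low-quality barcodes")

    co_cfg = simulate.default_cohort_config(args.seed + 2)
    cohort, co_truth = simulate.gen_cohort(co_cfg)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index_label="patient")
    co_truth.to_csv(out / "cohort_truth.tsv", sep="\t", index_label="patient")
    n_plus = int((co_truth["group"] == "+").sum())
    print(f"cohort: {co_cfg.n_patients} patients, {n_plus} outlier-positive, "
          f"hazard ratio {co_cfg.hazard_ratio}")


if __name__ == "__main__":
    main()
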