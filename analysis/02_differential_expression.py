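"""ICI-vs-vehicle differential expression within each invasion contrast.

Reads the bulk count matrices from step 01 and runs the full chain —
TMM effective library sizes, common NB dispersion by conditional
maximum likelihood, per-gene conditional exact test, BH-FDR — writing
one DE table per contrast under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from invasig import de, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for inv, tag in (("INV+", "invplus"), ("INV-", "invminus")):
        ctrl = io.read_counts(args.data_dir / f"bulk_{tag}_none.tsv")
        ici = io.read_counts(args.data_dir / f"bulk_{tag}_ici.tsv")
        counts = pd.concat([ctrl, ici], axis=1)
        table = de.de_table(counts, list(ctrl.columns), list(ici.columns))
        table.to_csv(args.out_dir / f"de_{tag}.tsv", sep="\t", index_label="gene_id")
        n_sig = int((table["fdr"] <= 0.05).sum())
        print(f"{inv}: {len(table)} genes tested, {n_sig} ICI-regulated at FDR<=0.05")


if __name__ == "__main__":
    main()
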