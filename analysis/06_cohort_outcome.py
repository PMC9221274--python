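"""Cohort stratification and outcome association.

Splits patients by the any-gene z > 3 outlier rule, then tests the two
groups against molecular subtype, grade and vital status (chi-squared)
and against overall/relapse-free survival (Kaplan-Meier + log-rank).
Writes the contingency tables and a JSON summary under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from invasig import cohort as co
from invasig.signatures import GeneSignature


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--direction", choices=["above_only", "two_sided"],
                    default="above_only")
    args = ap.parse_args()

    cohort = pd.read_csv(args.data_dir / "cohort.tsv", sep="\t", index_col=0)
    genes = [c[2:] for c in cohort.columns if c.startswith("z_")]
    sig = GeneSignature("cohort_signature", {g: "down" for g in genes})
    report = co.cohort_report(cohort, sig, co.StratConfig(direction=args.direction))

    n_plus = int((report.groups == "+").sum())
    print(f"stratification: {n_plus} signature-positive / "
          f"{len(report.groups) - n_plus} negative patients")

    summary = {"n_positive": n_plus, "n_patients": int(len(report.groups))}
    for var, assoc in report.associations.items():
        assoc.table.to_csv(args.out_dir / f"cohort_{var}_table.tsv", sep="\t")
        summary[var] = {"chi2": assoc.chi2, "df": assoc.df, "p": assoc.p}
        print(f"{var}: chi2={assoc.chi2:.2f} (df={assoc.df}), p={assoc.p:.3g}")
    for name, surv in report.survival.items():
        summary[name] = {"logrank_statistic": surv.statistic, "p": surv.p}
        print(f"{name.upper()} log-rank: statistic={surv.statistic:.2f}, p={surv.p:.3g}")

    (args.out_dir / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
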