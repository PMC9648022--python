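"""Stage-vs-normal differential expression, cross-study Sets1 and cross-stage Sets2.

Per dataset: Welch tests of each lesion stage against normal (BH-adjusted
p < 0.05 and |log2FC| > 1), then the direction-consistent cross-study unions
(Sets1) and, per dataset, the intersection of DEGs with Spearman-monotone
stepwise genes (Sets2).  Recovery of the planted gene roles is reported.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cervtrans.deg_meta import cross_stage_sets2, cross_study_sets1, deg_table, stepwise_genes
from cervtrans.io import read_expression


def write_gene_list(genes, path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/deg"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    truth = pd.read_csv(args.in_dir / "gene_truth.tsv", sep="\t")
    planted_up = set(truth.loc[truth.role == "stepwise_up", "gene"])
    planted_down = set(truth.loc[truth.role == "stepwise_down", "gene"])

    tables, sets2 = [], {}
    for matrix in sorted(args.in_dir.glob("*_expr.tsv")):
        ds = read_expression(matrix, args.in_dir / matrix.name.replace("_expr", "_meta"))
        t = deg_table(ds)
        t.table.to_csv(args.out_dir / f"{ds.dataset_id}_deg.tsv", sep="\t", index=False)
        tables.append(t)
        s2 = cross_stage_sets2(t, stepwise_genes(ds))
        sets2[ds.dataset_id] = s2
        write_gene_list(s2.up, args.out_dir / f"{ds.dataset_id}_sets2_up.txt")
        write_gene_list(s2.down, args.out_dir / f"{ds.dataset_id}_sets2_down.txt")
        print(
            f"{ds.dataset_id}: Sets2 {len(s2.up)} up / {len(s2.down)} down; "
            f"planted recovery up {len(s2.up & planted_up)}/{len(planted_up)}, "
            f"down {len(s2.down & planted_down)}/{len(planted_down)}"
        )

    s1 = cross_study_sets1(tables)
    for comp in s1.up:
        write_gene_list(s1.up[comp], args.out_dir / f"sets1_{comp}_up.txt")
        write_gene_list(s1.down[comp], args.out_dir / f"sets1_{comp}_down.txt")
    summary = {
        "sets1_counts": {c: {"up": len(s1.up[c]), "down": len(s1.down[c])} for c in s1.up},
        "inconsistent_removed": sorted(s1.removed_inconsistent),
        "sets2_counts": {d: {"up": len(s.up), "down": len(s.down)} for d, s in sets2.items()},
    }
    (args.out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"Sets1 removed {len(s1.removed_inconsistent)} direction-inconsistent genes")


if __name__ == "__main__":
    main()
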