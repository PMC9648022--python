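"""Positional (cytoband-style) over-representation of the cross-study gene sets.

Hypergeometric ORA of each Sets1 up/down list against the synthetic
positional gene-set collection, BH-adjusted across the collection
(q < 0.05).  The planted monotone genes occupy the first blocks, so those
bands should surface for the lesion-stage comparisons.
"""

import argparse
from pathlib import Path

from cervtrans.enrichment import enrich_collection
from cervtrans.io import read_gene_sets


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--deg-dir", type=Path, default=Path("results/deg"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--q-threshold", type=float, default=0.05)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    collection = read_gene_sets(args.in_dir / "positional_sets.gmt")
    for listing in sorted(args.deg_dir.glob("sets1_*_*.txt")):
        query = {g for g in listing.read_text().split() if g}
        if not query:
            continue
        df = enrich_collection(query, collection, q_threshold=args.q_threshold)
        df.to_csv(args.out_dir / f"{listing.stem}_ora.tsv", sep="\t", index=False)
        top = df.iloc[0]
        hits = df.loc[df.significant, "set_name"].tolist()
        print(
            f"{listing.stem}: {len(hits)} bands at q<{args.q_threshold}"
            f" (top: {top.set_name}, k/n={top.k}/{top.n}, q={top.q:.2e})"
        )


if __name__ == "__main__":
    main()
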