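"""Nine-method centrality ranking and cross-dataset consensus hub calling.

For each simulated network: score all nodes by the nine ranking methods,
take each method's top-10 (ties expanded), and union them into the dataset's
candidate sub-network.  Genes in at least two datasets' candidate sets are
consensus hubs; recovery of the planted hubs is reported.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cervtrans.hub_network import METHODS, CentralityParams, candidate_set, centrality, consensus_hubs
from cervtrans.io import read_network, write_network


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/hubs"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--top-k", type=int, default=10)
    ap.add_argument("--consensus-min", type=int, default=2)
    ap.add_argument("--epc-realizations", type=int, default=5000)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = CentralityParams(
        epc_realizations=args.epc_realizations,
        epc_seed=args.seed,
        top_k=args.top_k,
        consensus_min=args.consensus_min,
    )
    truth = json.loads((args.in_dir / "truth.json").read_text())
    planted = set(truth["planted_hubs"])

    sets = {}
    for path in sorted(args.in_dir.glob("network_d*.tsv")):
        g = read_network(path)
        name = path.stem
        scores = pd.DataFrame({m: centrality(g, m, params) for m in METHODS})
        scores.index.name = "node"
        scores.to_csv(args.out_dir / f"{name}_scores.tsv", sep="\t")
        cand, sub = candidate_set(g, params)
        sets[name] = cand
        write_network(sub, args.out_dir / f"{name}_subnetwork.tsv")
        print(f"{name}: {g.number_of_nodes()} nodes, candidate set {len(cand)}")

    hc = consensus_hubs(sets, consensus_min=args.consensus_min)
    (args.out_dir / "hubs.txt").write_text("".join(f"{h}\n" for h in sorted(hc.hubs)))
    pd.Series(hc.membership, name="n_datasets").rename_axis("node").sort_values(
        ascending=False
    ).to_csv(args.out_dir / "membership.tsv", sep="\t")
    print(
        f"consensus hubs (min {args.consensus_min}): {sorted(hc.hubs)}; "
        f"planted recovered {len(hc.hubs & planted)}/{len(planted)}, "
        f"false {len(hc.hubs - planted)}"
    )


if __name__ == "__main__":
    main()
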