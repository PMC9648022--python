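"""Hypergeometric over-representation analysis of flat gene-set collections.

Cytoband, GO and KEGG collections are treated as plain sets over a declared
universe (the genes measured on the platform).  For a query of size n drawn
from a universe of size N containing a K-member set, the enrichment p is the
upper tail P(X >= k) of Hypergeometric(N, K, n) at the observed overlap k;
q-values are BH-adjusted across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .deg_meta import bh_adjust
from .io import GeneSetCollection


@dataclass
class EnrichmentRecord:
    set_name: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q: float | None = None

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n if self.n else 0.0


def ora(query, target, universe) -> EnrichmentRecord:
    """Upper-tail hypergeometric over-representation test for one set."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    target = set(target) & universe
    N, K, n, k = len(universe), len(target), len(query), len(query & target)
    if n == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentRecord(set_name="", N=N, K=K, n=n, k=k, p=min(p, 1.0))


def enrich_collection(
    query, collection: GeneSetCollection, q_threshold: float = 0.05
) -> pd.DataFrame:
    """ORA of every set in a collection with BH q-values.

    Returns one row per set sorted by p, with a ``significant`` flag at
    q < q_threshold (0.05 for cytobands, 0.1 for GO/KEGG in the default
    pipeline configuration).
    """
    if not len(collection):
        raise ValueError("empty collection")
    records = []
    for name, members in collection.sets.items():
        rec = ora(query, members, collection.universe)
        rec.set_name = name
        records.append(rec)
    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in records],
            "N": [r.N for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "k": [r.k for r in records],
            "gene_ratio": [r.gene_ratio for r in records],
            "p": [r.p for r in records],
        }
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < q_threshold
    return df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
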