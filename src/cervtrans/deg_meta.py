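"""Stage-vs-normal differential expression and the cross-study / cross-stage set logic.

Each lesion stage is compared with normal tissue per dataset (Welch two-sample
t on log2 values; a gene is differential when BH-adjusted p < 0.05 and
|fold change| > 2, i.e. |log2FC| > 1).  Two derived constructions follow:

* Gene Sets1 ("cross-study"): per comparison, the union of up calls and the
  union of down calls over datasets, after removing any gene called in
  opposite directions in two datasets.
* Gene Sets2 ("cross-stage"): per dataset, the intersection of DEGs with
  "stepwise" genes, i.e. genes whose expression is Spearman-monotone in the
  ordinal stage code, with matching direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset, STAGE_NORMAL, logger

COMPARISON_NAMES = {1: "LN", 2: "HN", 3: "CN"}


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i}(m * p_(j) / j) over ascending-sorted p, capped at 1
    and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test (unpooled variance, Welch-Satterthwaite df).

    Degenerate rows: if both groups are constant, p = 1 when the means agree
    and p = 0 otherwise (infinite t).
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = np.ones_like(diff)
    ok = se2 > 0
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = ~ok
    p[degenerate & (diff != 0)] = 0.0
    return diff, p


@dataclass
class DEGTable:
    """Per-gene differential-expression records for one dataset (all comparisons)."""

    dataset_id: str
    table: pd.DataFrame  # columns: gene, comparison, log2fc, p, p_adj, direction

    def calls(self, comparison: str, direction: str) -> set[str]:
        t = self.table
        return set(t.loc[(t.comparison == comparison) & (t.direction == direction), "gene"])


def differential_expression(
    ds: ExpressionDataset,
    lesion_stage: int,
    alpha: float = 0.05,
    fc: float = 2.0,
) -> pd.DataFrame:
    """Welch t-test of one lesion stage against normal, gene-wise.

    Returns a frame with gene, comparison, log2fc (lesion mean - normal mean),
    p, BH-adjusted p across all genes of the comparison, and the direction call
    (up/down/none by p_adj < alpha and |log2FC| > log2(fc)).
    """
    if lesion_stage not in COMPARISON_NAMES:
        raise ValueError(f"lesion_stage must be 1, 2 or 3; got {lesion_stage}")
    lesion = ds.samples_at_stage(lesion_stage)
    normal = ds.samples_at_stage(STAGE_NORMAL)
    if len(lesion) < 2 or len(normal) < 2:
        raise ValueError("each group needs >= 2 samples")
    log2fc, p = _welch(ds.values[lesion].to_numpy(), ds.values[normal].to_numpy())
    p_adj = bh_adjust(p)
    lfc_cut = np.log2(fc)
    direction = np.where(
        (p_adj < alpha) & (log2fc > lfc_cut),
        "up",
        np.where((p_adj < alpha) & (log2fc < -lfc_cut), "down", "none"),
    )
    out = pd.DataFrame(
        {
            "gene": ds.genes,
            "comparison": COMPARISON_NAMES[lesion_stage],
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    )
    logger.info(
        "%s %s: %d up, %d down of %d genes",
        ds.dataset_id, COMPARISON_NAMES[lesion_stage],
        int((direction == "up").sum()), int((direction == "down").sum()), len(direction),
    )
    return out


def deg_table(ds: ExpressionDataset, alpha: float = 0.05, fc: float = 2.0) -> DEGTable:
    """All lesion-vs-normal comparisons available in the dataset."""
    frames = [
        differential_expression(ds, code, alpha=alpha, fc=fc)
        for code in ds.stages_present()
        if code != STAGE_NORMAL and len(ds.samples_at_stage(code)) >= 2
    ]
    return DEGTable(dataset_id=ds.dataset_id, table=pd.concat(frames, ignore_index=True))


@dataclass
class GeneSets1:
    """Cross-study direction-consistent unions of DEGs, per comparison."""

    up: dict[str, set[str]] = field(default_factory=dict)
    down: dict[str, set[str]] = field(default_factory=dict)
    removed_inconsistent: set[str] = field(default_factory=set)


def cross_study_sets1(tables: list[DEGTable], scope: str = "per_comparison") -> GeneSets1:
    """Union DEG calls across datasets, dropping direction-inconsistent genes.

    ``scope='per_comparison'`` removes a gene from a comparison's sets when two
    datasets call it in opposite directions *in that comparison*;
    ``scope='global'`` removes it from every comparison when any two datasets
    disagree in any comparison.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 datasets for a cross-study union")
    if scope not in ("per_comparison", "global"):
        raise ValueError("scope must be 'per_comparison' or 'global'")
    comparisons = sorted(
        {c for t in tables for c in t.table.comparison.unique()},
        key=lambda c: {"LN": 1, "HN": 2, "CN": 3}[c],
    )
    up = {c: set().union(*(t.calls(c, "up") for t in tables)) for c in comparisons}
    down = {c: set().union(*(t.calls(c, "down") for t in tables)) for c in comparisons}
    result = GeneSets1()
    if scope == "global":
        inconsistent = set().union(*(up[c] for c in comparisons)) & set().union(
            *(down[c] for c in comparisons)
        )
        for c in comparisons:
            result.up[c] = up[c] - inconsistent
            result.down[c] = down[c] - inconsistent
        result.removed_inconsistent = inconsistent
    else:
        for c in comparisons:
            inconsistent = up[c] & down[c]
            result.up[c] = up[c] - inconsistent
            result.down[c] = down[c] - inconsistent
            result.removed_inconsistent |= inconsistent
    for c in comparisons:
        assert not (result.up[c] & result.down[c])
    return result


def _exact_spearman_p(expr_ranks: np.ndarray, stage_ranks: np.ndarray, rho_obs: np.ndarray) -> np.ndarray:
    """Two-sided permutation p for Spearman rho at small n.

    Enumerates the distinct permutations of the stage-rank vector (a multiset,
    since stages repeat) once and scores every gene against all of them.
    """
    from sympy.utilities.iterables import multiset_permutations

    perms = np.array(list(multiset_permutations(list(stage_ranks))), dtype=float)
    sc = perms - perms.mean(axis=1, keepdims=True)
    sc /= np.linalg.norm(sc, axis=1, keepdims=True)
    rc = expr_ranks - expr_ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rc, axis=1, keepdims=True)
    ok = norms[:, 0] > 0
    rc[ok] /= norms[ok]
    rho_all = rc @ sc.T  # genes x perms
    p = (np.abs(rho_all) >= np.abs(rho_obs)[:, None] - 1e-12).mean(axis=1)
    p[~ok] = 1.0
    return p


def stepwise_genes(ds: ExpressionDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman trend of expression against the ordinal stage code, gene-wise.

    Average ranks handle ties; the two-sided p uses the t-approximation, or an
    exact multiset-permutation null when the total sample count is <= 10.
    Constant genes get rho = 0, p = 1.  ``monotone_direction`` is the sign of
    rho when p < alpha, else "none".
    """
    if len(ds.stages_present()) < 3:
        raise ValueError("stepwise detection needs >= 3 distinct stages")
    x = ds.values.to_numpy()
    n = x.shape[1]
    stage = ds.stage.to_numpy(dtype=float)
    expr_ranks = stats.rankdata(x, axis=1)
    stage_ranks = stats.rankdata(stage)
    rc = expr_ranks - expr_ranks.mean(axis=1, keepdims=True)
    sc = stage_ranks - stage_ranks.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(sc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ sc) / denom
    constant = denom == 0
    rho[constant] = 0.0
    if n <= 10:
        p = _exact_spearman_p(expr_ranks, stage_ranks, rho)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p[constant] = 1.0
    p = np.clip(p, 0.0, 1.0)
    direction = np.where(p < alpha, np.where(rho > 0, "up", "down"), "none")
    return pd.DataFrame({"gene": ds.genes, "rho": rho, "p": p, "monotone_direction": direction})


@dataclass
class GeneSets2:
    """Per-dataset DEG-and-stepwise intersections, direction-matched."""

    dataset_id: str
    up: set[str]
    down: set[str]


def cross_stage_sets2(
    deg: DEGTable, stepwise: pd.DataFrame, require_comparison: str | None = None
) -> GeneSets2:
    """Intersect DEG calls with stepwise-monotone genes of the same direction.

    A gene enters the up-set when it is DEG-up in at least one comparison
    (or the specific ``require_comparison``) and stepwise-up; symmetrically
    for down.
    """
    comps = list(deg.table.comparison.unique()) if require_comparison is None else [require_comparison]
    deg_up = set().union(*(deg.calls(c, "up") for c in comps))
    deg_down = set().union(*(deg.calls(c, "down") for c in comps))
    step_up = set(stepwise.loc[stepwise.monotone_direction == "up", "gene"])
    step_down = set(stepwise.loc[stepwise.monotone_direction == "down", "gene"])
    return GeneSets2(dataset_id=deg.dataset_id, up=deg_up & step_up, down=deg_down & step_down)
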