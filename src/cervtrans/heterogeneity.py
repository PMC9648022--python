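"""Inter-/intra-lesional heterogeneity assessment.

Carcinoma samples show higher within-stage transcriptional heterogeneity than
normal epithelium or intraepithelial lesions.  This module quantifies that:
PCA of the most variable genes, within-stage pairwise Pearson correlations,
and nonparametric comparison of the correlation distributions across stages
(Kruskal-Wallis followed by pairwise Wilcoxon rank-sum with Bonferroni
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset, STAGE_NAMES, logger


def top_variable_genes(ds: ExpressionDataset, n: int = 1000) -> list[str]:
    """Genes ranked by descending variance across all samples; top ``n``.

    Ties are broken by lexicographic gene symbol so the selection is
    deterministic on degenerate (e.g. constant) matrices.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > ds.n_genes:
        raise ValueError(f"n={n} exceeds the {ds.n_genes} genes available")
    var = ds.values.var(axis=1, ddof=1)
    order = sorted(ds.genes, key=lambda g: (-var[g], g))
    return order[:n]


def pca_embed(
    ds: ExpressionDataset, genes: list[str] | None = None, k: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA sample embedding of (a subset of) the expression matrix.

    Values are centered gene-wise and left unscaled; scores come from the SVD
    of the centered samples x genes matrix.  Returns the samples x k score
    frame and the fraction of variance explained per component.
    """
    sub = ds.values.loc[genes] if genes is not None else ds.values
    if ds.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if k > min(sub.shape):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(sub.shape)}")
    x = sub.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    total = (s**2).sum()
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(scores, index=sub.columns, columns=[f"PC{i+1}" for i in range(k)])
    return frame, frac


@dataclass
class StageCorrelations:
    """Per-stage vectors of pairwise Pearson r among that stage's samples."""

    by_stage: dict[int, np.ndarray]

    def mean(self, stage: int) -> float:
        return float(np.mean(self.by_stage[stage]))

    def stages(self) -> list[int]:
        return sorted(self.by_stage)


def within_stage_correlations(
    ds: ExpressionDataset, genes: list[str] | None = None
) -> StageCorrelations:
    """All unordered within-stage sample-pair Pearson correlations over genes.

    Stages with fewer than 2 samples are omitted with a warning.  By default r
    is computed across all genes; pass ``genes`` to restrict (e.g. the
    top-variable subset).
    """
    sub = ds.values.loc[genes] if genes is not None else ds.values
    out: dict[int, np.ndarray] = {}
    for code in ds.stages_present():
        members = ds.samples_at_stage(code)
        if len(members) < 2:
            logger.warning("stage %s has <2 samples; omitted from correlations", STAGE_NAMES[code])
            continue
        mat = sub[members].to_numpy().T  # samples x genes
        r = np.corrcoef(mat)
        iu = np.triu_indices(len(members), k=1)
        out[code] = r[iu]
    return StageCorrelations(by_stage=out)


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when both groups are small and
    tie-free, otherwise the tie-corrected normal approximation."""
    exact = len(x) <= 50 and len(y) <= 50 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def compare_stage_correlations(
    sc: StageCorrelations,
) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus p over stage groups plus a Bonferroni-corrected
    pairwise Wilcoxon rank-sum p matrix (p multiplied by the number of pairs,
    capped at 1)."""
    codes = sc.stages()
    if len(codes) < 2:
        raise ValueError("need at least 2 stages to compare")
    groups = [sc.by_stage[c] for c in codes]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty correlation group")
    omnibus = float(stats.kruskal(*groups).pvalue)
    n_pairs = len(codes) * (len(codes) - 1) // 2
    names = [STAGE_NAMES[c] for c in codes]
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            p = min(1.0, _ranksum_p(groups[i], groups[j]) * n_pairs)
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return omnibus, pmat
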