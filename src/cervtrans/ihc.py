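"""Immunohistochemistry scoring systems and diagnostic-test evaluation.

Noninvasive squamous epithelium is scored by stained cell-layer level
(Ki-67, TOP2A) or staining intensity (AURKA, CEP55, RFC4); invasive carcinoma
by percent positive cells and the semi-quantitative histologic score
HSCORE = 1*(% cells 1+) + 2*(% cells 2+) + 3*(% cells 3+), range 0-300.

Binary marker calls against the gold-standard histology feed a standard
diagnostic evaluation: sensitivity / specificity / PPV / NPV with exact
Clopper-Pearson 95% CIs, a binary-test AUC = (sens + spec)/2 with a
Hanley-McNeil interval, exact McNemar comparison of paired markers, Cohen's
kappa agreement, and serial/parallel marker combination.

Marker-positivity thresholds for noninvasive lesions are reconstructions
exposed through ``DEFAULT_RULES`` (the layer >= 2 / intensity >= 2
conventions); the carcinoma rule is strict > 10% positive cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding (the convention behind printed percentages)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# scoring systems
# ---------------------------------------------------------------------------

def hscore(pct1: float, pct2: float, pct3: float) -> float:
    """HSCORE = 1*pct1 + 2*pct2 + 3*pct3 for percentages of cells staining at
    intensities 1+, 2+ and 3+; bounded in [0, 300]."""
    for v in (pct1, pct2, pct3):
        if not 0 <= v <= 100:
            raise ValueError("intensity percentages must lie in [0, 100]")
    if pct1 + pct2 + pct3 > 100 + 1e-9:
        raise ValueError("intensity percentages must sum to at most 100")
    return 1 * pct1 + 2 * pct2 + 3 * pct3


def layer_score(stained_fraction: float, marker: str = "Ki-67", parabasal_only: bool = False) -> int:
    """Cell-layer score of epithelial staining height.

    Parabasal-layer-only staining scores 0; staining up to the lower third
    scores 1+, up to the lower two thirds 2+, beyond that 3+.  TOP2A's 3+ is
    collapsed into 2+ (its 2+ and 3+ grades are grouped).
    """
    if not 0 <= stained_fraction <= 1:
        raise ValueError("stained fraction must lie in [0, 1]")
    if parabasal_only or stained_fraction == 0:
        return 0
    if stained_fraction <= 1 / 3:
        score = 1
    elif stained_fraction <= 2 / 3:
        score = 2
    else:
        score = 3
    if marker.upper() == "TOP2A" and score == 3:
        score = 2
    return score


@dataclass
class PositivityRule:
    """Positivity rule for a marker's noninvasive score: ``field`` >= threshold,
    optionally requiring an auxiliary boolean flag column (e.g. diffuse block
    positivity for p16, beyond-basal distribution for RFC4)."""

    field: str
    threshold: float
    require_flag: str | None = None


#: Reconstructed noninvasive thresholds (the original scoring table is not
#: reproduced in the main text); all overridable per call.
DEFAULT_RULES: dict[str, PositivityRule] = {
    "p16": PositivityRule(field="block_positive_flag", threshold=1),
    "Ki-67": PositivityRule(field="layer", threshold=2),
    "TOP2A": PositivityRule(field="layer", threshold=2),
    "AURKA": PositivityRule(field="intensity", threshold=2),
    "CEP55": PositivityRule(field="intensity", threshold=2),
    "RFC4": PositivityRule(field="intensity", threshold=2, require_flag="beyond_basal_flag"),
}

SCC_PERCENT_POSITIVE_CUTOFF = 10.0  # strict >


def binarize_marker(
    score,
    marker: str,
    lesion_kind: str,
    rules: dict[str, PositivityRule] | None = None,
) -> str:
    """Binary call for one section's marker score.

    ``lesion_kind='SCC'`` uses the strict >10% positive-cell rule common to all
    markers in carcinoma; ``'noninvasive'`` applies the marker's configured
    layer/intensity threshold (and auxiliary flag where required).
    """
    if lesion_kind == "SCC":
        pct = float(score["percent_positive"])
        return "positive" if pct > SCC_PERCENT_POSITIVE_CUTOFF else "negative"
    if lesion_kind != "noninvasive":
        raise ValueError("lesion_kind must be 'noninvasive' or 'SCC'")
    rules = rules or DEFAULT_RULES
    rule = rules.get(marker)
    if rule is None:
        raise ValueError(f"no positivity rule configured for marker {marker!r}")
    value = float(score[rule.field])
    positive = value >= rule.threshold
    if rule.require_flag is not None:
        positive = positive and bool(score[rule.require_flag])
    return "positive" if positive else "negative"


# ---------------------------------------------------------------------------
# diagnostic evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionTable:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def controls(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_calls(cls, calls: pd.Series, truth: pd.Series) -> "ConfusionTable":
        """Build from paired positive(1)/negative(0) calls and disease truth,
        dropping missing calls pairwise."""
        ok = calls.notna() & truth.notna()
        c, t = calls[ok].astype(int), truth[ok].astype(int)
        return cls(
            tp=int(((c == 1) & (t == 1)).sum()),
            fn=int(((c == 0) & (t == 1)).sum()),
            tn=int(((c == 0) & (t == 0)).sum()),
            fp=int(((c == 1) & (t == 0)).sum()),
        )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial CI for a proportion k/n."""
    if n == 0:
        raise ValueError("empty margin")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class ProportionEstimate:
    value: float
    ci_low: float
    ci_high: float


@dataclass
class DiagnosticMetrics:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    auc: ProportionEstimate


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, alpha: float = 0.05) -> tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def diagnostic_metrics(ct: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV with exact Clopper-Pearson 95% CIs and
    the binary-test AUC = (sens + spec)/2 with a Hanley-McNeil interval."""
    if ct.diseased == 0 or ct.controls == 0:
        raise ValueError("need at least one diseased and one control subject")

    def prop(k: int, n: int) -> ProportionEstimate:
        lo, hi = clopper_pearson(k, n)
        return ProportionEstimate(k / n, lo, hi)

    sens = prop(ct.tp, ct.diseased)
    spec = prop(ct.tn, ct.controls)
    ppv = prop(ct.tp, ct.tp + ct.fp) if ct.tp + ct.fp else ProportionEstimate(np.nan, np.nan, np.nan)
    npv = prop(ct.tn, ct.tn + ct.fn) if ct.tn + ct.fn else ProportionEstimate(np.nan, np.nan, np.nan)
    auc_val = (sens.value + spec.value) / 2
    lo, hi = _hanley_mcneil_ci(auc_val, ct.diseased, ct.controls)
    return DiagnosticMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        auc=ProportionEstimate(auc_val, lo, hi),
    )


def roc_auc(scores, truth) -> float:
    """Empirical AUC = Mann-Whitney U / (n_case * n_control), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos, neg = scores[truth == 1], scores[truth == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one case and one control")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar p from the discordant-pair counts b (A+B-) and
    c (A-B+): p = min(1, 2 * P(X <= min(b,c))) for X ~ Bin(b+c, 1/2)."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    p = 2 * float(stats.binom.cdf(min(b, c), n, 0.5))
    return min(1.0, p)


def mcnemar_from_calls(calls_a: pd.Series, calls_b: pd.Series) -> float:
    ok = calls_a.notna() & calls_b.notna()
    a, b_ = calls_a[ok].astype(int), calls_b[ok].astype(int)
    return mcnemar_exact(int(((a == 1) & (b_ == 0)).sum()), int(((a == 0) & (b_ == 1)).sum()))


@dataclass
class AgreementResult:
    po: float
    pe: float
    kappa: float
    n: int


def cohens_kappa(calls_a: pd.Series, calls_b: pd.Series) -> AgreementResult:
    """Cohen's kappa for paired binary calls (missing excluded pairwise)."""
    ok = pd.Series(calls_a).notna() & pd.Series(calls_b).notna()
    a = pd.Series(calls_a)[ok].astype(int).to_numpy()
    b = pd.Series(calls_b)[ok].astype(int).to_numpy()
    n = len(a)
    if n == 0:
        raise ValueError("no paired observations")
    po = float((a == b).mean())
    pa1, pb1 = a.mean(), b.mean()
    pe = float(pa1 * pb1 + (1 - pa1) * (1 - pb1))
    if pe == 1.0:
        if po == 1.0:
            return AgreementResult(po=1.0, pe=1.0, kappa=1.0, n=n)
        raise ValueError("kappa undefined: both raters constant but discordant")
    return AgreementResult(po=po, pe=pe, kappa=(po - pe) / (1 - pe), n=n)


def kappa_from_table(a: int, b: int, c: int, d: int) -> AgreementResult:
    """Kappa from a 2x2 agreement table (a = both+, b = A+B-, c = A-B+, d = both-)."""
    calls_a = pd.Series([1] * (a + b) + [0] * (c + d), dtype=float)
    calls_b = pd.Series([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return cohens_kappa(calls_a, calls_b)


def combine_markers(calls_a: pd.Series, calls_b: pd.Series, mode: str) -> pd.Series:
    """Serial (positive iff both positive) or parallel (positive iff either)
    interpretation of a marker pair; missing in either member stays missing."""
    if mode not in ("serial", "parallel"):
        raise ValueError("mode must be 'serial' or 'parallel'")
    a, b = pd.Series(calls_a).astype(float), pd.Series(calls_b).astype(float)
    out = np.minimum(a, b) if mode == "serial" else np.maximum(a, b)
    out[a.isna() | b.isna()] = np.nan
    return out


# ---------------------------------------------------------------------------
# confusion-table reconstruction from printed summaries
# ---------------------------------------------------------------------------

def reconstruct_proportion(
    pct: float, ci_low_pct: float, ci_high_pct: float, n_max: int = 300
) -> list[tuple[int, int]]:
    """All (k, n) with n <= n_max whose point estimate and exact 95% CI all
    round (half-up, 1 decimal, in percent) to the printed values."""
    matches = []
    for n in range(1, n_max + 1):
        k_point = [k for k in range(n + 1) if round_half_up(100 * k / n) == pct]
        for k in k_point:
            lo, hi = clopper_pearson(k, n)
            if round_half_up(100 * lo) == ci_low_pct and round_half_up(100 * hi) == ci_high_pct:
                matches.append((k, n))
    return matches


def reconstruct_confusion(
    sens_pct: float, sens_ci: tuple[float, float],
    spec_pct: float, spec_ci: tuple[float, float],
    n_max: int = 300,
) -> ConfusionTable:
    """Invert a printed diagnostic row (rounded sens/spec with exact CIs) back
    to integer counts; raises unless each margin's solution is unique."""
    sens_matches = reconstruct_proportion(sens_pct, *sens_ci, n_max=n_max)
    spec_matches = reconstruct_proportion(spec_pct, *spec_ci, n_max=n_max)
    if len(sens_matches) != 1:
        raise ValueError(f"sensitivity row not uniquely invertible: {sens_matches}")
    if len(spec_matches) != 1:
        raise ValueError(f"specificity row not uniquely invertible: {spec_matches}")
    tp, diseased = sens_matches[0]
    tn, controls = spec_matches[0]
    return ConfusionTable(tp=tp, fn=diseased - tp, tn=tn, fp=controls - tn)
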