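"""Synthetic-data generators emulating the study's data structure.

Every pipeline stage can be exercised without downloads: several independent
expression datasets sharing gene identifiers, with planted monotone
("stepwise") genes, direction-inconsistent genes, null genes and inflated
carcinoma-stage noise; interaction networks with planted hubs; paired IHC
marker calls at specified operating points with copula-controlled
inter-marker dependence; and right-censored survival cohorts whose hazard
depends on a marker.

Defaults mirror the study design: three discovery datasets, a diagnostic
cohort of 68 high-grade lesions vs 101 normal/low-grade controls with the
published marker operating points, and a survival cohort of 252 carcinoma
patients with a protective marker (log-HR -0.7) under the 5-year horizon.
All generators are deterministic given a seed and return truth tables
sufficient to score the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset, MarkerCallTable, SurvivalCohort, parse_stage_label
from .ihc import hscore


@dataclass
class SimConfig:
    """Study-shaped simulation parameters (counts, effects, noise, rates)."""

    seed: int = 0
    # expression
    n_datasets: int = 3
    genes_total: int = 500
    n_per_stage: int = 8
    n_stepwise: int = 40
    n_inconsistent: int = 10
    delta: float = 1.0              # per-stage log2 shift of stepwise genes
    noise_sd: float = 0.5
    scc_inflation: float = 1.5      # SCC-stage noise multiplier
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    # network
    network_size: int = 60
    n_hubs: int = 4
    edge_p: float = 0.05
    hub_wiring: float = 0.4
    gene_pool: int = 20000  # genome-scale symbol pool non-hub nodes are drawn from
    # IHC (gold-stage section counts and per-marker operating points)
    ihc_n: dict = field(
        default_factory=lambda: {"Normal": 42, "CIN1": 59, "CIN2": 26, "CIN3": 42}
    )
    operating_points: dict = field(
        default_factory=lambda: {
            "p16": (0.926, 0.634),
            "Ki-67": (0.912, 0.802),
            "TOP2A": (0.882, 0.871),
            "RFC4": (0.882, 0.901),
        }
    )
    marker_dependence: float = 0.5  # Gaussian-copula loading on the shared latent
    # survival
    survival_n: int = 252
    marker_log_hr: float = -0.7
    covariate_log_hrs: dict = field(
        default_factory=lambda: {"age": 0.02, "figo_stage": 0.3, "grade": 0.2}
    )
    baseline_hazard: float = 0.01   # events per month
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_datasets, self.genes_total, self.n_per_stage) < 1:
            raise ValueError("counts must be positive")
        if self.n_stepwise + self.n_inconsistent > self.genes_total:
            raise ValueError("planted genes exceed genes_total")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 <= self.marker_dependence <= 1:
            raise ValueError("marker_dependence must lie in [0, 1]")
        if self.n_hubs >= self.network_size:
            raise ValueError("n_hubs must be below network_size")


def gen_expression_datasets(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[ExpressionDataset], pd.DataFrame]:
    """Independent stage-labelled expression datasets plus a gene-role truth table.

    Roles: ``stepwise_up`` / ``stepwise_down`` genes shift by +/- delta per
    ordinal stage step in every dataset; ``inconsistent`` genes flip effect
    sign between datasets; ``null`` genes are flat.  Carcinoma-stage samples
    receive noise inflated by ``scc_inflation``, reproducing the elevated
    within-carcinoma heterogeneity.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.genes_total)]
    n_up = cfg.n_stepwise // 2
    roles = (
        ["stepwise_up"] * n_up
        + ["stepwise_down"] * (cfg.n_stepwise - n_up)
        + ["inconsistent"] * cfg.n_inconsistent
        + ["null"] * (cfg.genes_total - cfg.n_stepwise - cfg.n_inconsistent)
    )
    truth = pd.DataFrame({"gene": genes, "role": roles})
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.genes_total)
    effect_sign = np.where(np.array(roles) == "stepwise_down", -1.0, 1.0)
    planted = np.isin(roles, ["stepwise_up", "stepwise_down", "inconsistent"])

    stage_codes = np.repeat([0, 1, 2, 3], cfg.n_per_stage)
    datasets = []
    for d in range(cfg.n_datasets):
        ds_id = f"SIM{d + 1}"
        sign = effect_sign.copy()
        flip = np.array(roles) == "inconsistent"
        sign[flip] = 1.0 if d % 2 == 0 else -1.0
        mean = baseline[:, None] + np.where(planted, sign, 0.0)[:, None] * cfg.delta * stage_codes[None, :]
        sd = np.where(stage_codes == 3, cfg.noise_sd * cfg.scc_inflation, cfg.noise_sd)
        values = mean + rng.normal(0.0, 1.0, mean.shape) * sd[None, :]
        samples = [f"{ds_id}_s{i:02d}" for i in range(len(stage_codes))]
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                values=pd.DataFrame(values, index=genes, columns=samples),
                stage=pd.Series(stage_codes, index=samples),
            )
        )
    return datasets, truth


def gen_network(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, list[str]]:
    """Erdos-Renyi background plus planted hubs each wired to a random
    ``hub_wiring`` fraction of all nodes; returns the graph and hub names.

    Non-hub node identities are drawn from a genome-scale symbol pool, so
    independently generated networks share their hubs but only incidentally
    share background genes — the situation the cross-dataset consensus step
    faces with per-dataset candidate gene sets.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    hubs = [f"HUB{i + 1}" for i in range(cfg.n_hubs)]
    pool_ids = rng.choice(cfg.gene_pool, size=cfg.network_size - cfg.n_hubs, replace=False)
    others = [f"GP{i:05d}" for i in pool_ids]
    nodes = hubs + others
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < cfg.edge_p:
                g.add_edge(nodes[i], nodes[j])
    n_wire = min(n - 1, max(1, int(round(cfg.hub_wiring * n))))
    for h in hubs:
        targets = rng.choice([v for v in nodes if v != h], size=n_wire, replace=False)
        g.add_edges_from((h, t) for t in targets)
    return g, hubs


def gen_ihc_cohort(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[MarkerCallTable, pd.DataFrame]:
    """Paired marker calls on a gold-staged section cohort.

    Each section carries a shared latent normal variable; each marker call
    thresholds a Gaussian-copula mixture of that latent and marker-specific
    noise so that P(positive | HSIL) = sens and P(positive | control) =
    1 - spec, with ``marker_dependence`` steering inter-marker agreement.
    Raw layer/intensity/HSCORE scores are generated consistently with the
    calls and the default positivity rules.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    rows = []
    truth_rows = []
    section = 0
    rho = cfg.marker_dependence
    for label, count in cfg.ihc_n.items():
        stage = parse_stage_label(label)
        diseased = stage >= 2
        for _ in range(count):
            sid = f"S{section:04d}"
            section += 1
            z = rng.normal()
            truth_rows.append({"section_id": sid, "gold_label": label, "diseased": diseased})
            for marker, (sens, spec) in cfg.operating_points.items():
                x = rho * z + np.sqrt(1 - rho**2) * rng.normal()
                u = stats.norm.cdf(x)
                pos = u < (sens if diseased else 1 - spec)
                layer = int(rng.integers(2, 4)) if pos else int(rng.integers(0, 2))
                if marker.upper() == "TOP2A":
                    layer = min(layer, 2)
                intensity = int(rng.integers(2, 4)) if pos else int(rng.integers(0, 2))
                pct3 = float(rng.uniform(30, 60)) if pos else float(rng.uniform(0, 5))
                pct2 = float(rng.uniform(10, 30))
                pct1 = float(rng.uniform(0, 100 - pct2 - pct3))
                rows.append(
                    {
                        "section_id": sid,
                        "gold_label": label,
                        "gold_stage": stage,
                        "marker": marker,
                        "score_kind": "layer" if marker in ("Ki-67", "TOP2A") else "intensity",
                        "layer": layer,
                        "intensity": intensity,
                        "pct1": pct1,
                        "pct2": pct2,
                        "pct3": pct3,
                        "hscore": hscore(pct1, pct2, pct3),
                        "block_positive_flag": bool(pos),
                        "beyond_basal_flag": bool(pos),
                        "call": "positive" if pos else "negative",
                    }
                )
    return MarkerCallTable(records=pd.DataFrame(rows)), pd.DataFrame(truth_rows)


def _calibrate_uniform_censoring(
    t_event: np.ndarray, rate: float, horizon: float = 60.0
) -> float:
    """Upper bound c of U(0, c) censoring achieving the target fraction of
    subjects censored by dropout before their event and before the
    administrative horizon, by bisection on mean(min(min(T, horizon)/c, 1))."""
    if rate <= 0:
        return np.inf
    t_eff = np.minimum(t_event, horizon)
    lo, hi = 1e-6, float(t_eff.max()) * 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.minimum(t_eff / mid, 1.0).mean())
        if frac > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_survival_cohort(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SurvivalCohort, dict]:
    """Exponential survival cohort with a dichotomous marker and clinical
    covariates in the hazard, uniform censoring calibrated to the target
    rate, and the 5-year administrative horizon applied."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.survival_n
    age = rng.normal(50, 10, n)
    figo = rng.choice([1, 2, 3, 4], size=n, p=[0.45, 0.3, 0.15, 0.1])
    grade = rng.choice([1, 2, 3], size=n, p=[0.2, 0.5, 0.3])
    marker_group = rng.integers(0, 2, n)
    marker_value = 100 + 60 * marker_group + rng.normal(0, 15, n)
    lp = (
        cfg.marker_log_hr * marker_group
        + cfg.covariate_log_hrs["age"] * (age - 50)
        + cfg.covariate_log_hrs["figo_stage"] * (figo - figo.mean())
        + cfg.covariate_log_hrs["grade"] * (grade - grade.mean())
    )
    t_event = rng.exponential(1.0 / (cfg.baseline_hazard * np.exp(lp)))
    c_max = _calibrate_uniform_censoring(t_event, cfg.censoring_rate)
    t_censor = rng.uniform(0, c_max, n) if np.isfinite(c_max) else np.full(n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "cohort": "SIM",
            "time_months": time,
            "event": event,
            "endpoint": "OS",
            "age": age,
            "figo_stage": figo,
            "grade": grade,
            "marker_group": marker_group,
            "marker_value": marker_value,
        }
    )
    cohort = SurvivalCohort(data=df, endpoint="OS")
    from .survival import apply_censor_rule

    cohort = apply_censor_rule(cohort)
    truth = {"marker_log_hr": cfg.marker_log_hr, "covariate_log_hrs": dict(cfg.covariate_log_hrs)}
    return cohort, truth
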