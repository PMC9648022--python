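"""Domain containers and text-format readers/writers shared by all pipeline stages.

The pipeline operates on four kinds of input: log2 expression matrices with
ordinal stage labels (Normal < LSIL < HSIL < SCC), gene-set collections (GMT),
undirected interaction networks (edge-list TSV), and tabular IHC / survival
records (CSV).  Everything here is plain pandas / networkx; the science lives
in the downstream modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("cervtrans")

#: Ordinal stage codes for the two-tier squamous-lesion grading system.
#: CIN sub-grades collapse onto the two-tier codes (CIN1 -> LSIL, CIN2/3 -> HSIL)
#: but the raw label is kept so IHC results can still be stratified by CIN grade.
STAGE_NORMAL, STAGE_LSIL, STAGE_HSIL, STAGE_SCC = 0, 1, 2, 3

STAGE_LABELS: dict[str, int] = {
    "normal": STAGE_NORMAL,
    "lsil": STAGE_LSIL,
    "cin1": STAGE_LSIL,
    "hsil": STAGE_HSIL,
    "cin2": STAGE_HSIL,
    "cin3": STAGE_HSIL,
    "scc": STAGE_SCC,
    "cancer": STAGE_SCC,
}

STAGE_NAMES = {STAGE_NORMAL: "Normal", STAGE_LSIL: "LSIL", STAGE_HSIL: "HSIL", STAGE_SCC: "SCC"}


def parse_stage_label(label: str) -> int:
    """Map a stage label (case-insensitive; two-tier or CIN grading) to its ordinal code."""
    code = STAGE_LABELS.get(str(label).strip().lower())
    if code is None:
        raise ValueError(f"unknown stage label {label!r}; expected one of {sorted(STAGE_LABELS)}")
    return code


@dataclass
class ExpressionDataset:
    """A genes x samples log2 expression matrix with per-sample ordinal stage codes.

    ``values`` is indexed by gene symbol with sample ids as columns; ``stage``
    is a Series over the same samples with codes in {0,1,2,3}; ``annotations``
    carries optional per-sample columns (raw stage label, HPV status, ...).
    """

    dataset_id: str
    values: pd.DataFrame
    stage: pd.Series
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.stage = self.stage.reindex(self.values.columns)
        if self.stage.isna().any():
            missing = list(self.stage.index[self.stage.isna()])
            raise ValueError(f"samples without a stage code: {missing}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        bad = set(self.stage.unique()) - {STAGE_NORMAL, STAGE_LSIL, STAGE_HSIL, STAGE_SCC}
        if bad:
            raise ValueError(f"invalid stage codes: {sorted(bad)}")
        self.stage = self.stage.astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_at_stage(self, code: int) -> list[str]:
        return list(self.stage.index[self.stage == code])

    def stages_present(self) -> list[int]:
        return sorted(self.stage.unique())


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe (cytobands, pathways, GO terms)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set (and the universe) with a new universe; logs drop counts."""
        uni = frozenset(universe)
        restricted = {}
        n_dropped = 0
        for name, members in self.sets.items():
            kept = members & uni
            n_dropped += len(members) - len(kept)
            restricted[name] = kept
        if n_dropped:
            logger.info("gene-set restriction dropped %d member entries", n_dropped)
        return GeneSetCollection(sets=restricted, universe=uni)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class MarkerCallTable:
    """Tidy per-section, per-marker IHC records paired with a gold-standard stage.

    ``records`` columns: section_id, gold_label (raw; Normal/CIN1/CIN2/CIN3/SCC),
    gold_stage (two-tier ordinal code), marker, score_kind, and the raw-score
    columns defined by the IHC module, plus ``call`` in {"positive","negative"}
    or missing (NaN).  Missing calls are excluded pairwise from paired statistics.
    """

    records: pd.DataFrame

    REQUIRED = ("section_id", "gold_label", "gold_stage", "marker", "call")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        per_section = self.records.groupby("section_id")["gold_stage"].nunique()
        conflicted = per_section[per_section > 1]
        if len(conflicted):
            raise ValueError(f"sections with conflicting gold stage: {list(conflicted.index)}")

    def calls_wide(self) -> pd.DataFrame:
        """Pivot to sections x markers call matrix (values 1/0/NaN), with gold columns."""
        wide = self.records.pivot_table(
            index="section_id",
            columns="marker",
            values="call",
            aggfunc="first",
        )
        wide = wide.apply(lambda col: col.map({"positive": 1.0, "negative": 0.0}))
        gold = self.records.drop_duplicates("section_id").set_index("section_id")[
            ["gold_label", "gold_stage"]
        ]
        return gold.join(wide)


@dataclass
class SurvivalCohort:
    """Per-patient right-censored survival records for one or more cohorts.

    ``data`` columns: patient_id, cohort, time_months (>= 0), event (0/1),
    endpoint (OS/PFI/DFS), covariates (age, figo_stage, grade) and marker_value.
    """

    data: pd.DataFrame
    endpoint: str = "OS"

    REQUIRED = ("patient_id", "time_months", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"survival table missing columns: {missing}")
        if self.data["time_months"].isna().any() or self.data["event"].isna().any():
            raise ValueError("time/event may not be missing")
        if (self.data["time_months"] < 0).any():
            raise ValueError("time_months must be >= 0")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(matrix_path, metadata_path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a genes x samples TSV plus a sample-metadata TSV into an ExpressionDataset.

    The metadata file must contain ``sample_id`` and ``stage`` columns; stage
    labels are parsed case-insensitively from the two-tier / CIN vocabularies.
    Sample order follows the matrix columns.  Extra metadata columns are kept
    as per-sample annotations.
    """
    matrix_path = Path(matrix_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = values.columns[[not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric expression value at gene {bad.index[0]!r}, sample {col!r}"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "stage" not in meta.columns:
        raise ValueError("metadata must have sample_id and stage columns")
    meta = meta.set_index("sample_id")
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ValueError(f"samples absent from metadata: {absent}")
    meta = meta.reindex(values.columns)
    stage = meta["stage"].map(parse_stage_label)
    annotations = meta.rename(columns={"stage": "stage_label"})
    ds = ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem,
        values=values.astype(float),
        stage=stage,
        annotations=annotations,
    )
    logger.info("read %s: %d genes x %d samples", ds.dataset_id, ds.n_genes, ds.n_samples)
    return ds


def write_expression(ds: ExpressionDataset, matrix_path, metadata_path) -> None:
    ds.values.to_csv(matrix_path, sep="\t", index_label="gene")
    meta = pd.DataFrame(
        {
            "sample_id": ds.samples,
            "stage": [
                ds.annotations["stage_label"][s]
                if ds.annotations is not None and "stage_label" in ds.annotations
                else STAGE_NAMES[int(ds.stage[s])]
                for s in ds.samples
            ],
        }
    )
    if ds.annotations is not None:
        for col in ds.annotations.columns:
            if col != "stage_label":
                meta[col] = ds.annotations[col].reindex(ds.samples).to_numpy()
    meta.to_csv(metadata_path, sep="\t", index=False)


def collapse_probes(values: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    A gene measured by several probes is represented by the probe with the
    highest row mean; on ties the probe first in file order wins (stable,
    order-deterministic).  Probes without a mapping are dropped.
    """
    if not probe_map:
        raise ValueError("empty probe map")
    genes = pd.Series([probe_map.get(p) for p in values.index], index=values.index)
    mapped = values.loc[genes.notna().to_numpy()]
    if mapped.empty:
        raise ValueError("no probe in the matrix is covered by the probe map")
    genes = genes.dropna()
    means = mapped.mean(axis=1)
    frame = pd.DataFrame({"gene": genes.to_numpy(), "mean": means.to_numpy()}, index=mapped.index)
    # idxmax returns the first occurrence of the maximum -> documented tie-break
    best_probes = frame.groupby("gene", sort=False)["mean"].idxmax()
    collapsed = mapped.loc[best_probes.to_numpy()]
    collapsed.index = pd.Index(best_probes.index, name="gene")
    logger.info(
        "collapsed %d probes to %d genes (%d unmapped probes dropped)",
        values.shape[0], collapsed.shape[0], values.shape[0] - mapped.shape[0],
    )
    return collapsed


def read_network(path, score_threshold: float | None = None) -> nx.Graph:
    """Read a 2-3 column (STRING-style) edge list into an undirected simple graph.

    Reversed duplicates merge; self-loops are dropped with a warning; when a
    third score column is present and ``score_threshold`` is given, only edges
    with score >= threshold are kept.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 tab-separated columns")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                n_self += 1
                continue
            if len(fields) >= 3 and score_threshold is not None:
                if float(fields[2]) < score_threshold:
                    continue
            g.add_edge(a, b)
    if n_self:
        logger.warning("dropped %d self-loop edges", n_self)
    if g.number_of_edges() == 0:
        logger.warning("network from %s is empty", path)
    return g


def write_network(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


def read_gene_sets(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, members...) into a GeneSetCollection.

    The universe defaults to the union of all members; a supplied universe
    restricts membership (dropped members are counted in the log).
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: GMT requires name, description, members")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            sets[name] = members
    coll = GeneSetCollection(sets=sets, universe=frozenset().union(*sets.values()) if sets else frozenset())
    if universe is not None:
        coll = coll.restrict(universe)
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_marker_table(path) -> MarkerCallTable:
    """Read the tidy IHC CSV (section_id, gold_label, marker, scores, call)."""
    df = pd.read_csv(path)
    if "gold_stage" not in df.columns:
        df["gold_stage"] = df["gold_label"].map(parse_stage_label)
    return MarkerCallTable(records=df)


def write_marker_table(table: MarkerCallTable, path) -> None:
    table.records.to_csv(path, index=False)


def read_survival_table(path, endpoint: str = "OS") -> SurvivalCohort:
    df = pd.read_csv(path)
    if "endpoint" in df.columns:
        df = df[df["endpoint"] == endpoint].reset_index(drop=True)
    return SurvivalCohort(data=df, endpoint=endpoint)


def write_survival_table(cohort: SurvivalCohort, path) -> None:
    cohort.data.to_csv(path, index=False)
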