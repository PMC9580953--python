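"""Annotation summaries over pan-genome subsets.

The functional annotations themselves (COG letters, KEGG classes,
bacteriocin predictions, subcellular localizations, adhesin probabilities,
host-protein interaction scores) come from external tools and are consumed
here as plain tables.  This module cross-tabulates them against the
pan-genome structure:

* COG/KEGG category percentage distributions per subset,
* presence/absence heatmap matrices for trait genes (e.g. bacteriocins),
* localization x adhesin-score cross-tabulation (SPAAN-style score with a
  strict > 0.7 cutoff for the adhesin call),
* score-filtered bacterium-host protein-protein interaction network
  summaries (edges kept at score >= 0.9765, the "minimum score" convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .matrix import PresenceAbsenceMatrix

__all__ = [
    "LOCALIZATION_CLASSES",
    "COG_LETTERS",
    "category_distribution",
    "presence_heatmap",
    "HeatmapResult",
    "adhesin_crosstab",
    "ppi_summary",
    "PPISummary",
    "read_annotation_table",
    "read_localization_table",
    "read_ppi_table",
]

logger = logging.getLogger(__name__)

#: subcellular localization classes: cytoplasmic, membrane,
#: potentially surface-exposed, secreted
LOCALIZATION_CLASSES = ("CYT", "ME", "PSE", "SE")

COG_LETTERS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWYZ")


def read_annotation_table(path, validate_cog: bool = False) -> pd.Series:
    """Read an id -> category TSV into a Series indexed by gene id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (id, category)")
    ids, cats = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    series = pd.Series(cats.values, index=ids.values, name="category")
    if validate_cog:
        bad = set(series) - COG_LETTERS
        if bad:
            raise ValueError(f"{path}: categories outside COG vocabulary: {sorted(bad)}")
    return series


def category_distribution(
    table: pd.Series, subset_ids, precision: int = 0
) -> tuple[pd.Series, int]:
    """Percentage of subset genes per category, over annotated genes only.

    Genes absent from the annotation table do not enter the denominator;
    their count is returned separately so the caller can report an
    "unannotated" line.  Percentages are rounded to ``precision`` decimals
    (0 = whole percent, the usual figure convention).

    Returns
    -------
    (percentages, n_unannotated)
    """
    subset = list(subset_ids)
    if not subset:
        raise ValueError("subset is empty")
    if table.index.has_duplicates:
        raise ValueError("annotation table has duplicate ids")
    present = [g for g in subset if g in table.index]
    n_unannotated = len(subset) - len(present)
    if not present:
        return pd.Series(dtype=float, name="percent"), n_unannotated
    counts = table.loc[present].value_counts()
    pct = (100.0 * counts / counts.sum()).round(precision)
    pct.name = "percent"
    pct.index.name = "category"
    return pct.sort_index(), n_unannotated


@dataclass
class HeatmapResult:
    """Trait-gene presence/absence sub-matrix with provenance flags."""

    data: pd.DataFrame
    missing: list[str] = field(default_factory=list)
    conserved: list[str] = field(default_factory=list)


def presence_heatmap(
    matrix: PresenceAbsenceMatrix, gene_ids: list[str]
) -> HeatmapResult:
    """Extract a presence/absence heatmap for the requested genes, in order.

    Genes not found in the matrix yield all-absent rows (with a logged
    warning) rather than an error: a trait gene predicted in none of the
    genomes is itself a finding.  Genes present in every genome are flagged
    ``conserved``.
    """
    if not gene_ids:
        raise ValueError("gene list is empty")
    rows = []
    missing = []
    conserved = []
    for g in gene_ids:
        if g in matrix.data.index:
            row = matrix.data.loc[g]
            if row.all():
                conserved.append(g)
        else:
            row = pd.Series(False, index=matrix.data.columns, name=g)
            missing.append(g)
        rows.append(row.rename(g))
    if missing:
        logger.warning("genes absent from matrix, shown all-absent: %s", missing)
    return HeatmapResult(
        data=pd.DataFrame(rows), missing=missing, conserved=conserved
    )


def read_localization_table(path) -> pd.DataFrame:
    """Read a protein localization/adhesin-score TSV (id, class, score)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = ["protein_id", "localization", "score"][: df.shape[1]]
    return df


def adhesin_crosstab(
    table: pd.DataFrame, threshold: float = 0.7
) -> dict[str, int]:
    """Count predicted adhesins (score strictly > threshold) per localization.

    ``table`` needs columns ``localization`` (one of CYT/ME/PSE/SE) and
    ``score`` in [0, 1].  Returns per-class counts plus ``"total"``.
    """
    loc = table["localization"]
    bad = set(loc) - set(LOCALIZATION_CLASSES)
    if bad:
        raise ValueError(f"unknown localization classes: {sorted(bad)}")
    scores = table["score"].astype(float)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("adhesin scores must lie in [0, 1]")
    hits = table[scores > threshold]
    counts = {c: int((hits["localization"] == c).sum()) for c in LOCALIZATION_CLASSES}
    counts["total"] = int(len(hits))
    return counts


@dataclass
class PPISummary:
    """Score-filtered bipartite bacterium-host interaction network."""

    graph: nx.Graph
    degrees: pd.DataFrame
    top_bacterial: str | None
    top_human: str | None

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_edges() == 0


def read_ppi_table(path) -> pd.DataFrame:
    """Read a PPI edge TSV (bacterial id, human id, score)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["bacterial_id", "human_id", "score"][: df.shape[1]]
    return df


def ppi_summary(edges: pd.DataFrame, min_score: float = 0.9765) -> PPISummary:
    """Filter a PPI edge table and summarize the resulting network.

    Edges with score >= ``min_score`` are kept.  Returns the bipartite graph,
    a per-node degree table, and the most-connected bacterial and human
    proteins (ties broken lexicographically).  An empty post-filter network
    is a valid, explicit result, not an error.
    """
    scores = edges["score"].astype(float)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("interaction scores must lie in [0, 1]")
    pairs = edges[["bacterial_id", "human_id"]]
    if pairs.duplicated().any():
        raise ValueError("duplicate bacterium-human pairs in PPI table")

    kept = edges[scores >= min_score]
    g = nx.Graph()
    for _, row in kept.iterrows():
        g.add_node(row["bacterial_id"], side="bacterial")
        g.add_node(row["human_id"], side="human")
        g.add_edge(row["bacterial_id"], row["human_id"], score=float(row["score"]))

    deg_rows = [
        (node, data["side"], g.degree(node))
        for node, data in sorted(g.nodes(data=True))
    ]
    degrees = pd.DataFrame(deg_rows, columns=["node", "side", "degree"])

    def _top(side: str) -> str | None:
        sub = degrees[degrees["side"] == side]
        if sub.empty:
            return None
        best = sub.sort_values(["degree", "node"], ascending=[False, True])
        return str(best.iloc[0]["node"])

    return PPISummary(
        graph=g,
        degrees=degrees,
        top_bacterial=_top("bacterial"),
        top_human=_top("human"),
    )
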