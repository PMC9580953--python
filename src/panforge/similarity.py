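"""Protein similarity graph construction.

Two routes produce the weighted undirected graph that Markov clustering
partitions into ortholog families:

* :func:`read_similarity_table` imports an all-vs-all search result in the
  12-column tabular dialect (qseqid, sseqid, pident, length, mismatch,
  gapopen, qstart, qend, sstart, send, evalue, bitscore), applying an e-value
  significance cutoff (default 1e-5) and merging reciprocal hits.
* :func:`compute_similarities` is a built-in scorer that makes the pipeline
  self-contained: candidate pairs are screened by shared k-mers and scored by
  global alignment with BLOSUM62 and affine gaps.  It produces raw alignment
  scores, not e-values, and makes no attempt at search statistics.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .simulate import AMINO_ACIDS

__all__ = [
    "ProteinRecord",
    "SimilarityGraph",
    "NoEdgesError",
    "read_similarity_table",
    "compute_similarities",
    "read_genome_fastas",
    "OUTFMT6_COLUMNS",
]

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: cap on -log10(evalue) so that evalue == 0 maps to a finite weight
NEG_LOG_EVALUE_CAP = 200.0

_VALID_RESIDUES = frozenset(AMINO_ACIDS)


class NoEdgesError(ValueError):
    """No similarity edges remain after filtering."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence tagged with its genome of origin."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residues {sorted(bad)} "
                f"(alphabet is the 20 standard amino acids)"
            )


@dataclass
class SimilarityGraph:
    """Weighted undirected protein similarity graph.

    Edge weights are finite and positive; self-loops are excluded at
    construction (MCL regularization adds its own later).  ``cutoff`` records
    the significance threshold applied when the graph was built.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    cutoff: float | None = None

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            return
        if not (math.isfinite(weight) and weight > 0):
            raise ValueError(f"edge weight must be finite and > 0, got {weight}")
        if self.graph.has_edge(u, v):
            if weight > self.graph[u][v]["weight"]:
                self.graph[u][v]["weight"] = weight
        else:
            self.graph.add_edge(u, v, weight=weight)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_similarity_table(
    path,
    score_column: str = "neg_log_evalue",
    cutoff: float = 1e-5,
) -> SimilarityGraph:
    """Build a similarity graph from a 12-column all-vs-all hit table.

    Hits with e-value above ``cutoff`` are dropped; self-hits are dropped;
    reciprocal hits collapse to a single undirected edge whose weight is the
    maximum of the transformed scores.  ``score_column`` selects the weight:
    ``"bitscore"`` uses the raw bit score, ``"neg_log_evalue"`` uses
    -log10(evalue) capped at 200 (the customary monotone, bounded transform).

    Every protein id seen in the file becomes a node, so proteins whose hits
    are all filtered out survive as future singleton clusters.

    Raises
    ------
    ValueError
        On a row with the wrong column count or non-numeric score fields,
        naming the offending line.
    NoEdgesError
        If no edges remain after filtering.
    """
    if score_column not in ("bitscore", "neg_log_evalue"):
        raise ValueError(
            f"score_column must be 'bitscore' or 'neg_log_evalue', got {score_column!r}"
        )
    sg = SimilarityGraph(cutoff=cutoff)
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(row)}"
                )
            qseqid, sseqid = row[0], row[1]
            try:
                evalue = float(row[10])
                bitscore = float(row[11])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric evalue/bitscore field"
                ) from exc
            sg.graph.add_node(qseqid)
            sg.graph.add_node(sseqid)
            if qseqid == sseqid:
                continue
            if evalue > cutoff:
                continue
            if score_column == "bitscore":
                weight = bitscore
            else:
                if evalue <= 0:
                    weight = NEG_LOG_EVALUE_CAP
                else:
                    weight = min(NEG_LOG_EVALUE_CAP, -math.log10(evalue))
            if weight <= 0:
                continue
            sg.add_edge(qseqid, sseqid, weight)
    if sg.n_edges == 0:
        raise NoEdgesError(f"{path}: no similarity edges remain after filtering")
    return sg


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def compute_similarities(
    records: list[ProteinRecord],
    k: int = 5,
    min_score: float = 50.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> SimilarityGraph:
    """All-vs-all similarity graph from a built-in k-mer screen + aligner.

    Candidate pairs must share at least one length-``k`` substring; each
    candidate is then scored by global alignment (BLOSUM62, affine gaps with
    the common open 11 / extend 1 penalties) and kept as an edge when the
    score reaches ``min_score``.  Every record is a node, whether or not any
    edge touches it.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 protein records")
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("protein ids must be unique across the dataset")

    sg = SimilarityGraph(cutoff=min_score)
    for r in records:
        sg.graph.add_node(r.protein_id)

    # inverted k-mer index -> candidate pair set
    index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        seq = rec.sequence
        for pos in range(max(0, len(seq) - k + 1)):
            index.setdefault(seq[pos : pos + k], []).append(i)
    candidates: set[tuple[int, int]] = set()
    for hits in index.values():
        uniq = sorted(set(hits))
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                candidates.add((uniq[a], uniq[b]))

    aligner = _make_aligner(gap_open, gap_extend)
    for i, j in sorted(candidates):
        score = aligner.score(records[i].sequence, records[j].sequence)
        if score >= min_score and score > 0:
            sg.add_edge(records[i].protein_id, records[j].protein_id, float(score))
    return sg


def read_genome_fastas(paths) -> list[ProteinRecord]:
    """Read one multi-FASTA protein file per genome; genome id = file stem."""
    from pathlib import Path

    records = []
    for path in paths:
        path = Path(path)
        genome_id = path.stem
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(
                ProteinRecord(
                    protein_id=rec.id, genome_id=genome_id, sequence=str(rec.seq)
                )
            )
    return records
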