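"""Core / accessory / unique partitioning of a pan-genome.

A gene family is **core** when present in every genome, **unique**
(strain-specific, singleton) when present in exactly one, and **accessory**
(shared) when present in at least two but not all.  The three subsets are
disjoint and exhaust the pan-genome, so their counts always sum to the total
family count.

Percentages of the subsets are reported *truncated* (not rounded) to two
decimals, the convention under which the canonical nine-strain counts
1,268 / 892 / 449 out of 2,609 print as 48.60 / 34.18 / 17.20 — rounding
would give 34.19 and 17.21.

Genome-level summary statistics (size, GC%, CDS) use the arithmetic mean and
the population standard deviation (divisor n).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix

__all__ = [
    "PanGenomePartition",
    "partition",
    "partition_percentages",
    "genome_summary_stats",
    "read_genome_summary",
    "write_partition_report",
]


@dataclass
class PanGenomePartition:
    """Result of classifying gene families into pan-genome subsets.

    ``unique_owner`` maps each unique family to the single genome carrying
    it.  ``degenerate`` flags the one-genome case, where every family is
    simultaneously present-in-all and present-in-exactly-one; such families
    are classified core to keep the subsets disjoint.
    """

    core_ids: tuple[str, ...]
    accessory_ids: tuple[str, ...]
    unique_ids: tuple[str, ...]
    unique_owner: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def n_core(self) -> int:
        return len(self.core_ids)

    @property
    def n_accessory(self) -> int:
        return len(self.accessory_ids)

    @property
    def n_unique(self) -> int:
        return len(self.unique_ids)

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_accessory + self.n_unique

    @property
    def per_genome_unique(self) -> dict[str, int]:
        """Number of strain-specific families per genome."""
        return dict(Counter(self.unique_owner.values()))

    def counts(self) -> dict[str, int]:
        return {
            "core": self.n_core,
            "accessory": self.n_accessory,
            "unique": self.n_unique,
            "total": self.n_total,
        }

    def labels(self) -> pd.Series:
        """Per-family subset label, ordered core, accessory, unique."""
        data = (
            [(f, "core") for f in self.core_ids]
            + [(f, "accessory") for f in self.accessory_ids]
            + [(f, "unique") for f in self.unique_ids]
        )
        idx = pd.Index([f for f, _ in data], name="family")
        return pd.Series([l for _, l in data], index=idx, name="label")


def partition(matrix: PresenceAbsenceMatrix) -> PanGenomePartition:
    """Classify each gene family by its genome presence count.

    With a single genome every family is flagged-degenerate core; otherwise
    core iff present in all genomes, unique iff in exactly one, accessory
    iff in >= 2 and < all.
    """
    counts = matrix.presence_counts()
    G = matrix.n_genomes
    if G == 1:
        return PanGenomePartition(
            core_ids=tuple(matrix.family_ids),
            accessory_ids=(),
            unique_ids=(),
            degenerate=True,
        )
    core = tuple(counts.index[counts == G])
    unique = tuple(counts.index[counts == 1])
    accessory = tuple(counts.index[(counts >= 2) & (counts < G)])
    df = matrix.data
    owner = {fam: df.columns[df.loc[fam].to_numpy().argmax()] for fam in unique}
    return PanGenomePartition(
        core_ids=core,
        accessory_ids=accessory,
        unique_ids=unique,
        unique_owner=owner,
    )


def _truncate2(num: int, den: int) -> float:
    """100*num/den truncated to 2 decimals, computed exactly."""
    return int(Fraction(10000 * num, den)) / 100.0


def partition_percentages(part: PanGenomePartition) -> dict[str, float]:
    """Subset shares as percentages truncated to two decimals."""
    total = part.n_total
    if total == 0:
        raise ValueError("cannot compute percentages of an empty partition")
    return {
        "core": _truncate2(part.n_core, total),
        "accessory": _truncate2(part.n_accessory, total),
        "unique": _truncate2(part.n_unique, total),
    }


def genome_summary_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and population SD of genome size, GC content, and CDS count.

    ``table`` needs columns ``size_mb``, ``gc_percent``, ``cds`` (one row per
    strain).  Returns a DataFrame indexed by those columns with ``mean`` and
    ``sd`` columns; SD uses divisor n (ddof=0).
    """
    if len(table) == 0:
        raise ValueError("genome summary table is empty")
    cols = ["size_mb", "gc_percent", "cds"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"genome summary table missing columns: {missing}")
    if (table["size_mb"] <= 0).any():
        raise ValueError("genome sizes must be > 0")
    gc = table["gc_percent"]
    if ((gc <= 0) | (gc >= 100)).any():
        raise ValueError("GC percent must lie in (0, 100)")
    stats = {
        c: {
            "mean": float(np.mean(table[c])),
            "sd": float(np.std(table[c], ddof=0)),
        }
        for c in cols
    }
    return pd.DataFrame(stats).T[["mean", "sd"]]


def read_genome_summary(path) -> pd.DataFrame:
    """Read a genome-summary CSV with columns strain, size_mb, gc_percent, cds."""
    df = pd.read_csv(path)
    required = {"strain", "size_mb", "gc_percent", "cds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_partition_report(part: PanGenomePartition, path) -> None:
    """Write the partition as TSV: subset, family id, owner genome (uniques)."""
    rows = (
        [("core", f, "") for f in part.core_ids]
        + [("accessory", f, "") for f in part.accessory_ids]
        + [("unique", f, part.unique_owner.get(f, "")) for f in part.unique_ids]
    )
    pd.DataFrame(rows, columns=["subset", "family", "owner_genome"]).to_csv(
        path, sep="\t", index=False
    )
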