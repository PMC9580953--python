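"""Gene-family presence/absence matrix, the pivot of the pan-genome analysis.

Rows are gene families (ortholog clusters), columns are genomes, cells are
boolean incidence.  Every downstream statistic — core/accessory/unique
partitioning, accumulation curves, trait heatmaps — is a function of this
matrix.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PresenceAbsenceMatrix"]


class PresenceAbsenceMatrix:
    """Boolean gene-family x genome incidence table.

    Parameters
    ----------
    data:
        DataFrame with family identifiers as index, genome identifiers as
        columns, and boolean (or 0/1) cells.  Rows that are absent from every
        genome are rejected: a gene family only exists because it was observed
        in at least one genome.

    Raises
    ------
    ValueError
        If family or genome identifiers are not unique, or any row is
        all-false.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.astype(bool).copy()
        if df.index.has_duplicates:
            raise ValueError("family identifiers must be unique")
        if df.columns.has_duplicates:
            raise ValueError("genome identifiers must be unique")
        if len(df.columns) == 0:
            raise ValueError("matrix must have at least one genome column")
        empty = ~df.any(axis=1)
        if empty.any():
            bad = list(df.index[empty][:5])
            raise ValueError(f"all-absent gene family rows are not allowed: {bad}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self._df = df

    @property
    def data(self) -> pd.DataFrame:
        """The underlying boolean DataFrame (a reference, do not mutate)."""
        return self._df

    @property
    def family_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_families(self) -> int:
        return self._df.shape[0]

    @property
    def n_genomes(self) -> int:
        return self._df.shape[1]

    def presence_counts(self) -> pd.Series:
        """Number of genomes each family is present in."""
        return self._df.sum(axis=1)

    def to_tsv(self, path) -> None:
        """Write as TSV: rows = families, columns = genome names, cells 0/1."""
        out = self._df.astype(int)
        out.index.name = "family"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"PresenceAbsenceMatrix({self.n_families} families x "
            f"{self.n_genomes} genomes)"
        )
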