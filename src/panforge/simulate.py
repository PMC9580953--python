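"""Synthetic pan-genome generation with known ground truth.

Real pan-genome studies start from assembled genomes pulled from public
archives.  For testing and method validation this module replaces that step
with a generative model of the same statistical structure the analysis
assumes:

* a fixed set of **core** families present in every genome,
* **accessory** families present in some but not all genomes, with a
  user-chosen frequency spectrum,
* **strain-specific** (unique, singleton) families, Poisson-distributed per
  genome,
* optionally, protein sequences for each family, produced as mutated copies
  of a random seed sequence so that similarity-based clustering can be tested
  against a known family partition.

All randomness flows from a single integer seed through one
`numpy.random.Generator`, so identical specs give byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .matrix import PresenceAbsenceMatrix

__all__ = [
    "SyntheticPanGenomeSpec",
    "ProteinFamilySpec",
    "generate_presence_absence",
    "generate_curve_data",
    "generate_protein_families",
    "write_genome_fastas",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticPanGenomeSpec:
    """Parameters of the synthetic presence/absence model.

    Attributes
    ----------
    n_genomes:
        Number of genomes (strains) to simulate.
    core_size:
        Number of families present in every genome.
    accessory:
        Sequence of ``(frequency, count)`` pairs: ``count`` families each
        present in exactly ``frequency`` genomes, with 2 <= frequency <
        n_genomes.  The member genomes of each family are drawn uniformly
        without replacement.
    unique_rate:
        Poisson mean of the number of strain-specific families per genome.
    seed:
        Seed of the single pseudo-random stream.
    """

    n_genomes: int
    core_size: int
    accessory: tuple[tuple[int, int], ...] = ()
    unique_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.core_size < 0:
            raise ValueError("core_size must be >= 0")
        if self.unique_rate < 0:
            raise ValueError("unique_rate must be >= 0")
        acc = tuple((int(f), int(c)) for f, c in self.accessory)
        for f, c in acc:
            if c < 0:
                raise ValueError("accessory family counts must be >= 0")
            if not (1 < f < self.n_genomes):
                raise ValueError(
                    f"accessory frequency {f} must satisfy 2 <= f < n_genomes "
                    f"(= {self.n_genomes})"
                )
        object.__setattr__(self, "accessory", acc)

    @property
    def expected_pan_size(self) -> float:
        """Expected total family count: core + accessory + n_genomes * lambda."""
        return (
            self.core_size
            + sum(c for _, c in self.accessory)
            + self.n_genomes * self.unique_rate
        )


@dataclass(frozen=True)
class ProteinFamilySpec:
    """Parameters of the synthetic protein-family sequence model.

    Each family is a random seed sequence over the 20 standard amino acids
    plus copies carrying i.i.d. per-site substitutions (no indels).
    """

    family_sizes: tuple[int, ...]
    seed_length: int = 200
    substitution_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.family_sizes)
        if len(sizes) == 0:
            raise ValueError("family_sizes must be non-empty")
        if any(s < 1 for s in sizes):
            raise ValueError("every family must have >= 1 member")
        if self.seed_length <= 0:
            raise ValueError("seed_length must be > 0")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        object.__setattr__(self, "family_sizes", sizes)


def _genome_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"genome{str(i + 1).zfill(width)}" for i in range(n)]


def generate_presence_absence(
    spec: SyntheticPanGenomeSpec,
) -> tuple[PresenceAbsenceMatrix, pd.Series]:
    """Draw a presence/absence matrix with known partition labels.

    Returns
    -------
    matrix:
        PresenceAbsenceMatrix with ``spec.core_size`` all-true rows, the
        requested accessory families, and Poisson-distributed singleton rows.
    truth:
        Series mapping each family id to its true label in
        ``{"core", "accessory", "unique"}``, aligned with the matrix rows.
    """
    rng = np.random.default_rng(spec.seed)
    genomes = _genome_names(spec.n_genomes)

    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] = []

    for i in range(spec.core_size):
        rows.append(np.ones(spec.n_genomes, dtype=bool))
        ids.append(f"CORE{i + 1:05d}")
        labels.append("core")

    acc_idx = 0
    for freq, count in spec.accessory:
        for _ in range(count):
            members = rng.choice(spec.n_genomes, size=freq, replace=False)
            row = np.zeros(spec.n_genomes, dtype=bool)
            row[members] = True
            acc_idx += 1
            rows.append(row)
            ids.append(f"ACC{acc_idx:05d}")
            labels.append("accessory")

    uniq_idx = 0
    for g in range(spec.n_genomes):
        n_novel = rng.poisson(spec.unique_rate)
        for _ in range(int(n_novel)):
            row = np.zeros(spec.n_genomes, dtype=bool)
            row[g] = True
            uniq_idx += 1
            rows.append(row)
            ids.append(f"UNI{uniq_idx:05d}")
            labels.append("unique")

    if rows:
        data = pd.DataFrame(np.vstack(rows), index=ids, columns=genomes)
    else:
        data = pd.DataFrame(
            np.zeros((0, spec.n_genomes), dtype=bool), columns=genomes
        )
    matrix = PresenceAbsenceMatrix(data)
    truth = pd.Series(labels, index=pd.Index(ids, name="family"), name="label")
    return matrix, truth


def generate_curve_data(
    model: str,
    params: dict,
    N_range,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate (N, n) series from one of the two accumulation-curve models.

    Parameters
    ----------
    model:
        ``"heap"`` for the power law ``n = k * N**gamma`` or ``"expdecay"``
        for the offset exponential ``n = k * exp(-x/t) + tg_theta``.
    params:
        Model parameters: ``{"k", "gamma"}`` or ``{"k", "t", "tg_theta"}``.
    N_range:
        Increasing positive integer genome numbers.
    noise_sd:
        Standard deviation of additive Gaussian noise; 0 gives exact model
        values.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    N = np.asarray(list(N_range), dtype=float)
    if N.size == 0:
        raise ValueError("N_range must be non-empty")
    if np.any(N <= 0) or np.any(np.diff(N) <= 0):
        raise ValueError("N_range must be increasing positive integers")

    if model == "heap":
        n = params["k"] * N ** params["gamma"]
    elif model == "expdecay":
        n = params["k"] * np.exp(-N / params["t"]) + params["tg_theta"]
    else:
        raise ValueError(f"unknown model {model!r}; use 'heap' or 'expdecay'")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n = n + rng.normal(0.0, noise_sd, size=N.size)
    return pd.DataFrame({"N": N.astype(int), "n": n})


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at the given rate, uniform over the 19 alternatives."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    for pos in hits:
        # draw from the 19 non-identical residues
        alt = rng.integers(0, 19)
        if alt >= out[pos]:
            alt += 1
        out[pos] = alt
    return out


def generate_protein_families(
    spec: ProteinFamilySpec,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate protein FASTA records with a known family partition.

    Family ``i`` (1-based) consists of ``spec.family_sizes[i-1]`` records; the
    j-th member of every family is assigned to synthetic genome ``j``, so the
    number of genomes equals the largest family size.  Record ids encode both:
    ``<genome>|FAM<i>|<serial>``.

    Returns the records and a truth table with columns
    ``protein_id, family_id, genome_id``.
    """
    rng = np.random.default_rng(spec.seed)
    n_genomes = max(spec.family_sizes)
    genomes = _genome_names(n_genomes)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    records: list[SeqRecord] = []
    truth_rows = []
    serial = 0
    for fam_idx, size in enumerate(spec.family_sizes, start=1):
        seed_seq = rng.integers(0, 20, size=spec.seed_length)
        fam_id = f"FAM{fam_idx:04d}"
        for member in range(size):
            mutated = _mutate(seed_seq, spec.substitution_rate, rng)
            serial += 1
            genome_id = genomes[member]
            pid = f"{genome_id}|{fam_id}|p{serial:05d}"
            seq = alphabet[mutated].tobytes().decode()
            records.append(
                SeqRecord(Seq(seq), id=pid, description=f"{fam_id} member {member + 1}")
            )
            truth_rows.append((pid, fam_id, genome_id))
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "family_id", "genome_id"]
    )
    return records, truth


def write_genome_fastas(records: list[SeqRecord], outdir) -> list[Path]:
    """Write records as multi-FASTA, one file per synthetic genome.

    The genome is taken from the first ``|``-separated field of each record
    id; file names are ``<genome>.faa`` so the genome id round-trips as the
    file stem.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[SeqRecord]] = {}
    for rec in records:
        genome = rec.id.split("|")[0]
        by_genome.setdefault(genome, []).append(rec)
    paths = []
    for genome in sorted(by_genome):
        path = outdir / f"{genome}.faa"
        SeqIO.write(by_genome[genome], str(path), "fasta")
        paths.append(path)
    return paths


def spec_to_dict(spec) -> dict:
    """Serializable view of a spec dataclass (for manifests and configs)."""
    return dataclasses.asdict(spec)
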