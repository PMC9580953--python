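"""Shared fixtures: printed study inputs and deterministic synthetic matrices."""

import numpy as np
import pandas as pd
import pytest

from panforge.matrix import PresenceAbsenceMatrix

# Published genome-summary table for the nine probiotic L. delbrueckii
# strains: size (Mb), GC (%), CDS count.
NINE_STRAIN_SUMMARY = pd.DataFrame(
    {
        "strain": [
            "LJJ", "KLDS1.0207", "DSM20080", "2038", "ATCC11842",
            "TUA4408L", "DSM20074", "CNRZ327", "CIDCA133",
        ],
        "size_mb": [1.89, 1.87, 1.87, 1.87, 1.86, 2.01, 1.95, 2.11, 2.13],
        "gc_percent": [49.50, 49.80, 49.80, 49.70, 49.70, 49.90, 49.60, 49.60, 49.59],
        "cds": [1604, 1607, 1680, 1792, 1683, 1801, 1721, 1525, 1921],
    }
)

# Reported per-strain unique (strain-specific) gene counts; they sum to 449.
UNIQUE_PER_STRAIN = {
    "CIDCA133": 102, "DSM20074": 76, "CNRZ327": 69, "TUA4408L": 53,
    "2038": 47, "ATCC11842": 39, "KLDS1.0207": 32, "LJJ": 16, "DSM20080": 15,
}

# Accessory frequency spectrum summing to the reported 892 shared families.
ACCESSORY_SPECTRUM = {2: 200, 3: 150, 4: 150, 5: 150, 6: 100, 7: 80, 8: 62}


@pytest.fixture
def table1() -> pd.DataFrame:
    return NINE_STRAIN_SUMMARY.copy()


def build_nine_strain_matrix(seed: int = 0) -> PresenceAbsenceMatrix:
    """Deterministic 2,609-family x 9-genome matrix with the reported
    core/accessory/unique subset sizes (1,268 / 892 / 449)."""
    rng = np.random.default_rng(seed)
    genomes = list(NINE_STRAIN_SUMMARY["strain"])
    rows, ids = [], []
    for i in range(1268):
        rows.append(np.ones(9, dtype=bool))
        ids.append(f"CORE{i:04d}")
    acc = 0
    for freq, count in sorted(ACCESSORY_SPECTRUM.items()):
        for _ in range(count):
            row = np.zeros(9, dtype=bool)
            row[rng.choice(9, size=freq, replace=False)] = True
            rows.append(row)
            ids.append(f"ACC{acc:04d}")
            acc += 1
    uni = 0
    for g, n_uni in UNIQUE_PER_STRAIN.items():
        col = genomes.index(g)
        for _ in range(n_uni):
            row = np.zeros(9, dtype=bool)
            row[col] = True
            rows.append(row)
            ids.append(f"UNI{uni:04d}")
            uni += 1
    return PresenceAbsenceMatrix(
        pd.DataFrame(np.vstack(rows), index=ids, columns=genomes)
    )


@pytest.fixture(scope="session")
def nine_strain_matrix() -> PresenceAbsenceMatrix:
    return build_nine_strain_matrix()


def random_matrix(
    n_families: int, n_genomes: int, seed: int, density: float = 0.5
) -> PresenceAbsenceMatrix:
    """Random presence/absence matrix with no all-false rows."""
    rng = np.random.default_rng(seed)
    X = rng.random((n_families, n_genomes)) < density
    empty = ~X.any(axis=1)
    X[empty, rng.integers(0, n_genomes, size=int(empty.sum()))] = True
    return PresenceAbsenceMatrix(
        pd.DataFrame(
            X,
            index=[f"F{i:04d}" for i in range(n_families)],
            columns=[f"g{j}" for j in range(n_genomes)],
        )
    )
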