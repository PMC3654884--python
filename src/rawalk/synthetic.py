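"""Synthetic fixtures: Gaussian-mixture feature tables, random proteins,
and synthetic PSI-BLAST-style PSSM files.

Everything here is a pure function of its arguments and seed, so any
experiment can be regenerated exactly without downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    BLAST_COLUMN_ORDER,
    FeatureTable,
    ProteinRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureSpec:
    """Specification of a labeled Gaussian-mixture benchmark.

    ``separation`` is the distance between class means in units of the
    (unit) within-class standard deviation; 0 gives a class-blind cloud,
    6 a well-separated mixture a reasonable classifier should solve.
    """

    n_per_class: tuple[int, ...] = (50, 50, 50)
    d: int = 8
    separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("every class count must be at least 1")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.d < 1:
            raise ValueError("dimensionality must be at least 1")


def gaussian_mixture_dataset(spec: MixtureSpec) -> FeatureTable:
    """Sample a labeled Gaussian mixture with controllable separation.

    Class c's mean sits at separation * e_c along coordinate axis c; once
    the classes outnumber the dimensions, the remaining means fall back to
    random unit directions (logged).  Within-class noise is isotropic with
    unit SD, so ``separation`` reads directly in within-class SD units.
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.n_per_class)
    means = np.zeros((m, spec.d))
    for c in range(m):
        if c < spec.d:
            means[c, c] = spec.separation
        else:
            direction = rng.normal(size=spec.d)
            direction /= np.linalg.norm(direction)
            means[c] = spec.separation * direction
            logger.info("class %d mean placed on a random direction (m > d)", c)
    ids: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    counter = 0
    for c, n_c in enumerate(spec.n_per_class):
        blocks.append(means[c] + rng.normal(size=(n_c, spec.d)))
        for _ in range(n_c):
            counter += 1
            ids.append(f"s{counter:04d}")
            labels.append(f"c{c + 1}")
    return FeatureTable(sample_ids=ids, X=np.vstack(blocks), labels=labels)


def random_protein_records(
    count: int, length_range: tuple[int, int] = (50, 200), seed: int = 0
) -> list[ProteinRecord]:
    """Uniform-random protein sequences over the 20-letter alphabet."""
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(count):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=L))
        records.append(ProteinRecord(id=f"prot{i + 1:03d}", sequence=seq))
    return records


def write_synthetic_pssm(record: ProteinRecord, seed: int, path: str | Path) -> Path:
    """Write a synthetic PSI-BLAST-style ASCII PSSM for one protein.

    Mimics the real dialect — two header lines, the doubled letters
    header in BLAST's native column order, one row per residue with the
    20 integer log-odds scores followed by a percentages block — so the
    parser is exercised against realistic formatting.  Scores are uniform
    integers in [-10, 10]; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    L = record.length
    scores = rng.integers(-10, 11, size=(L, 20))  # columns in BLAST order
    percents = rng.integers(0, 100, size=(L, 20))
    letters = "   ".join(BLAST_COLUMN_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {letters}    {letters}",
    ]
    for i in range(L):
        row = f"{i + 1:5d} {record.sequence[i]} "
        row += "".join(f"{int(s):4d}" for s in scores[i])
        row += "  "
        row += "".join(f"{int(p):4d}" for p in percents[i])
        row += f"  {rng.uniform(0, 2):5.2f} {rng.uniform(0, 2):9.2f}"
        lines.append(row)
    lines += ["", "                      K         Lambda"]
    path.write_text("\n".join(lines) + "\n")
    return path


def synthetic_protein_corpus(
    count: int,
    length_range: tuple[int, int],
    seed: int,
    pssm_dir: str | Path,
) -> tuple[list[ProteinRecord], dict[str, Path]]:
    """Generate proteins plus one synthetic PSSM file per protein."""
    records = random_protein_records(count, length_range, seed)
    pssm_dir = Path(pssm_dir)
    pssm_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, rec in enumerate(records):
        paths[rec.id] = write_synthetic_pssm(rec, seed + 1000 + i,
                                             pssm_dir / f"{rec.id}.pssm")
    return records, paths
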