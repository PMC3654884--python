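"""Protein descriptors: PSSM column means + pseudo-amino-acid composition.

A protein of length L is represented by a (40 + lambda)-dimensional vector

    F = [ M_bar_1 .. M_bar_20,  p_1 .. p_20, p_21 .. p_{20+lambda} ]

where M_bar_j is the mean PSSM score toward amino-acid type j over the L
positions, p_1..p_20 derive from the amino-acid composition and
p_{20+k} from the k-th sequence-order correlation factor theta_k of the
type-1 pseudo-amino-acid composition (PseAA).  With the default
lambda = 49 the descriptor has 89 entries; sequences with L <= lambda are
excluded, since theta_k needs at least one residue pair at every tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, FeatureTable, ProteinRecord, PSSMMatrix

logger = logging.getLogger(__name__)


def load_property_tables() -> np.ndarray:
    """Load and standardize the three PseAA property tables.

    Returns a 3 x 20 array (hydrophobicity, hydrophilicity, side-chain
    mass), columns in alphabetical amino-acid order, each row standardized
    to mean 0 and unit (population) standard deviation over the 20 amino
    acids.
    """
    with resources.files("rawalk.data").joinpath("pseaa_properties.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df = df.set_index("aa").loc[list(AMINO_ACIDS)]
    raw = df[["hydrophobicity", "hydrophilicity", "side_chain_mass"]].to_numpy().T
    return (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)


@dataclass
class PseAAParams:
    """Parameters of the pseudo-amino-acid composition.

    ``lambda_seq`` is the number of sequence-order correlation tiers
    (default 49) and ``weight`` the factor balancing composition against
    correlation terms (default 0.05).  ``property_tables`` is the 3 x 20
    standardized property matrix; pass your own to swap scales.
    """

    lambda_seq: int = 49
    weight: float = 0.05
    property_tables: np.ndarray = field(default_factory=load_property_tables)

    def __post_init__(self) -> None:
        if self.lambda_seq < 0:
            raise ValueError("lambda_seq must be non-negative")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        self.property_tables = np.asarray(self.property_tables, dtype=float)
        if self.property_tables.shape != (3, 20):
            raise ValueError("property_tables must be 3 x 20")


@dataclass
class Descriptor:
    """The combined descriptor of one protein."""

    protein_id: str
    pssm_means: np.ndarray  # 20
    pseaa: np.ndarray  # 20 + lambda

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.pssm_means, self.pseaa])


def pssm_row_means(pssm: PSSMMatrix) -> np.ndarray:
    """Average the PSSM over positions: entry j = (1/L) sum_i M[i, j]."""
    return pssm.scores.mean(axis=0)


def _indexed(sequence: str) -> np.ndarray:
    idx = np.array([AMINO_ACIDS.index(c) for c in sequence], dtype=int)
    return idx


def correlation_factor(sequence: str, k: int, params: PseAAParams) -> float:
    """Tier-k sequence-order correlation factor theta_k.

    theta_k averages, over all residue pairs (i, i+k), the mean squared
    difference of the three standardized physicochemical properties:

        theta_k = 1/(L-k) * sum_i Theta(R_i, R_{i+k})
        Theta(a, b) = 1/3 * sum_p (prop_p(b) - prop_p(a))^2
    """
    L = len(sequence)
    if not 1 <= k < L:
        raise ValueError(f"tier k={k} requires 1 <= k < L={L}")
    idx = _indexed(sequence)
    props = params.property_tables  # 3 x 20
    diffs = props[:, idx[k:]] - props[:, idx[:-k]]  # 3 x (L-k)
    return float(np.mean(np.sum(diffs**2, axis=0) / 3.0))


def pseaa_vector(sequence: str, params: PseAAParams) -> np.ndarray:
    """Type-1 pseudo-amino-acid composition of a sequence.

    The first 20 entries come from the amino-acid frequencies f_u, the last
    ``lambda_seq`` from the weighted correlation factors; all are normalized
    by sum(f) + w * sum(theta) so the vector sums to 1.  Sequences with
    L <= lambda_seq are rejected (they cannot populate every tier) and must
    be excluded upstream.
    """
    L = len(sequence)
    if L <= params.lambda_seq:
        raise ValueError(
            f"sequence length {L} <= lambda {params.lambda_seq}: "
            "sequence must be excluded"
        )
    idx = _indexed(sequence)
    freqs = np.bincount(idx, minlength=20).astype(float) / L
    thetas = np.array(
        [correlation_factor(sequence, k, params) for k in range(1, params.lambda_seq + 1)]
    )
    denom = freqs.sum() + params.weight * thetas.sum()
    return np.concatenate([freqs, params.weight * thetas]) / denom


def _aligned_pssm(record: ProteinRecord, pssm: PSSMMatrix) -> np.ndarray:
    """Match PSSM rows to the (possibly sanitized) sequence."""
    if pssm.length == record.length:
        return pssm.scores
    original_length = record.length + len(record.removed_positions)
    if pssm.length == original_length and record.removed_positions:
        keep = np.setdiff1d(np.arange(original_length),
                            np.array(record.removed_positions))
        return pssm.scores[keep]
    raise ValueError(
        f"protein {record.id!r}: sequence length {record.length} does not match "
        f"PSSM row count {pssm.length}"
    )


def combined_descriptor(
    record: ProteinRecord, pssm: PSSMMatrix, params: PseAAParams | None = None
) -> Descriptor:
    """Build the combined [PSSM means, PseAA] descriptor for one protein."""
    params = params or PseAAParams()
    scores = _aligned_pssm(record, pssm)
    means = scores.mean(axis=0)
    pseaa = pseaa_vector(record.sequence, params)
    return Descriptor(protein_id=record.id, pssm_means=means, pseaa=pseaa)


def featurize_collection(
    records: Sequence[ProteinRecord],
    pssms: Mapping[str, PSSMMatrix],
    params: PseAAParams | None = None,
) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Featurize a matched collection of proteins and PSSMs.

    Returns a labeled-less :class:`FeatureTable` with one row per
    admissible protein plus an exclusion log of ``(id, reason)`` pairs for
    sequences too short for the requested lambda.  A protein without a PSSM
    is an error, not an exclusion.
    """
    params = params or PseAAParams()
    missing = [r.id for r in records if r.id not in pssms]
    if missing:
        raise KeyError(f"no PSSM found for protein(s): {missing}")

    ids: list[str] = []
    rows: list[np.ndarray] = []
    excluded: list[tuple[str, str]] = []
    for record in records:
        if record.length <= params.lambda_seq:
            excluded.append(
                (record.id,
                 f"length {record.length} <= lambda {params.lambda_seq}")
            )
            continue
        desc = combined_descriptor(record, pssms[record.id], params)
        ids.append(record.id)
        rows.append(desc.combined)
    if excluded:
        logger.info("excluded %d protein(s): %s", len(excluded), excluded)
    if not rows:
        raise ValueError("no admissible proteins after exclusions")
    return FeatureTable(sample_ids=ids, X=np.vstack(rows)), excluded
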