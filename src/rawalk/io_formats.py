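"""Input/output for every external format the tool touches.

Covers multi-record FASTA, PSI-BLAST ASCII position-specific scoring
matrices (PSSMs), delimited numeric feature tables (the UCI-yeast layout:
sample id, numeric attributes, class label), and tab-separated prediction
output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order; residue j
#: of this string is "amino-acid type j" everywhere in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used by PSI-BLAST ASCII PSSM files.
BLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence restricted to the 20-letter amino-acid alphabet.

    ``removed_positions`` records the 0-based positions (in the original,
    unsanitized sequence) that lenient parsing dropped; it lets downstream
    code drop the matching PSSM rows.
    """

    id: str
    sequence: str
    removed_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bad = [c for c in self.sequence if c not in AMINO_ACIDS]
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue(s) {sorted(set(bad))}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSSMMatrix:
    """An L x 20 position-specific scoring matrix for one protein.

    Entry (i, j) is the score of the residue at position i being substituted
    by amino-acid type j, with columns in alphabetical order
    (:data:`AMINO_ACIDS`).  ``residues`` is the residue column of the source
    file, kept for cross-checking against the FASTA sequence.
    """

    protein_id: str
    scores: np.ndarray
    residues: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r} must be L x 20, got {scores.shape}"
            )
        if scores.shape[0] == 0:
            raise ValueError(f"PSSM for {self.protein_id!r} has zero rows")
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"PSSM for {self.protein_id!r} has non-finite entries")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


@dataclass
class FeatureTable:
    """n samples x d numeric features, with optional class labels.

    The universal classifier input: rows are samples, columns are features,
    ``labels[i]`` (when present) is the class of sample i.  ``class_set`` is
    the sorted list of distinct labels and fixes the class order used by
    every downstream state matrix and report.
    """

    sample_ids: list[str]
    X: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {self.X.shape[0]} feature rows"
            )
        if self.X.size == 0:
            raise ValueError("feature matrix is empty")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if self.labels is not None and len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length does not match number of samples")

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    @property
    def d(self) -> int:
        return int(self.X.shape[1])

    @property
    def class_set(self) -> list[str]:
        if self.labels is None:
            return []
        return sorted(set(self.labels))

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            X=self.X[idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )


@dataclass
class PredictionTable:
    """Per-sample predicted class plus the raw per-class walk scores."""

    sample_ids: list[str]
    predicted: list[str]
    class_order: list[str]
    scores: np.ndarray  # m classes x q samples

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        q = len(self.sample_ids)
        if len(self.predicted) != q:
            raise ValueError("predicted length does not match sample ids")
        if self.scores.shape != (len(self.class_order), q):
            raise ValueError(
                f"scores must be {len(self.class_order)} x {q}, got {self.scores.shape}"
            )


def _sanitize(seq: str, record_id: str, strict: bool) -> tuple[str, tuple[int, ...]]:
    seq = seq.upper()
    removed: list[int] = []
    kept: list[str] = []
    for pos, c in enumerate(seq):
        if c in AMINO_ACIDS:
            kept.append(c)
        elif strict:
            raise ValueError(
                f"protein {record_id!r}: illegal residue {c!r} at position {pos + 1}"
            )
        else:
            removed.append(pos)
    if removed:
        logger.warning(
            "protein %r: removed %d non-standard residue(s) at positions %s",
            record_id,
            len(removed),
            [p + 1 for p in removed],
        )
    return "".join(kept), tuple(removed)


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Under ``strict`` parsing, any residue outside the 20-letter alphabet
    raises; under lenient parsing such residues are removed, their positions
    recorded on the record, and the removal logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise ValueError(f"{path}: FASTA entry with empty header")
        seq, removed = _sanitize(str(entry.seq), entry.id, strict)
        if not seq:
            raise ValueError(f"{path}: entry {entry.id!r} has no residues")
        records.append(ProteinRecord(id=entry.id, sequence=seq, removed_positions=removed))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records back out as FASTA (round-trip partner of read_fasta)."""
    out = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(out, str(Path(path)), "fasta")


def read_pssm(path: str | Path) -> PSSMMatrix:
    """Parse a PSI-BLAST ASCII PSSM file into an L x 20 score matrix.

    Only the first 20 numeric columns of each data row (the log-odds block)
    are used; the weighted-percentage block is ignored.  Columns are
    re-mapped from the file's stated order (BLAST's native A R N D ... when
    no letters header is found) to alphabetical order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PSSM file not found: {path}")

    column_order = BLAST_COLUMN_ORDER
    rows: list[list[float]] = []
    residues: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        # Letters header: at least 20 single-letter amino-acid tokens.
        if all(t in AMINO_ACIDS and len(t) == 1 for t in tokens) and len(tokens) >= 20:
            column_order = "".join(tokens[:20])
            continue
        if not tokens[0].isdigit():
            continue  # title / footer lines
        if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
            raise ValueError(f"{path}:{lineno}: malformed PSSM row")
        try:
            scores = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric score ({exc})") from None
        if len(scores) != 20:
            raise ValueError(
                f"{path}:{lineno}: expected 20 scores, found {len(scores)}"
            )
        rows.append(scores)
        residues.append(tokens[1].upper())
    if not rows:
        raise ValueError(f"{path}: no PSSM data rows found")

    raw = np.asarray(rows, dtype=float)
    if sorted(column_order) != sorted(AMINO_ACIDS):
        raise ValueError(f"{path}: unrecognized PSSM column order {column_order!r}")
    remap = [column_order.index(a) for a in AMINO_ACIDS]
    return PSSMMatrix(protein_id=path.stem, scores=raw[:, remap], residues="".join(residues))


def read_feature_table(
    path: str | Path,
    labeled: bool = True,
    delimiter: str | None = None,
) -> FeatureTable:
    """Read a delimited feature table (first column id, last column label).

    The default delimiter is any run of whitespace, which accepts the UCI
    yeast file verbatim; pass ``delimiter=","`` for CSV.  With
    ``labeled=False`` the last column is treated as one more feature.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    sep = r"\s+" if delimiter is None else delimiter
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                     skip_blank_lines=True)
    if df.isna().any().any():
        bad = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: inconsistent column count or missing value at "
            f"row {bad[0] + 1}, column {bad[1] + 1}"
        )
    if df.shape[1] < (3 if labeled else 2):
        raise ValueError(f"{path}: too few columns ({df.shape[1]})")

    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        warnings.warn(f"{path}: duplicate sample ids; suffixing", stacklevel=2)
        seen: dict[str, int] = {}
        unique_ids = []
        for s in ids:
            seen[s] = seen.get(s, 0) + 1
            unique_ids.append(s if seen[s] == 1 else f"{s}_{seen[s]}")
        ids = unique_ids

    feature_block = df.iloc[:, 1:-1] if labeled else df.iloc[:, 1:]
    X = np.empty(feature_block.shape, dtype=float)
    for j in range(feature_block.shape[1]):
        col = feature_block.iloc[:, j]
        try:
            X[:, j] = col.astype(float).to_numpy()
        except ValueError:
            bad_rows = [i for i, v in enumerate(col) if not _is_float(v)]
            raise ValueError(
                f"{path}: non-numeric feature value {col.iloc[bad_rows[0]]!r} at "
                f"row {bad_rows[0] + 1}, column {j + 2}"
            ) from None
    labels = df.iloc[:, -1].tolist() if labeled else None
    return FeatureTable(sample_ids=ids, X=X, labels=labels)


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_feature_table(table: FeatureTable, path: str | Path,
                        delimiter: str = "\t") -> None:
    """Write a feature table in the layout read_feature_table accepts."""
    with open(path, "w") as fh:
        for i, sid in enumerate(table.sample_ids):
            cells = [sid] + [f"{v:.10g}" for v in table.X[i]]
            if table.labels is not None:
                cells.append(table.labels[i])
            fh.write(delimiter.join(cells) + "\n")


def write_predictions(table: PredictionTable, path: str | Path) -> None:
    """Write predictions as TSV: id, predicted class, one score per class."""
    if len(table.sample_ids) == 0:
        raise ValueError("refusing to write an empty prediction table")
    with open(path, "w") as fh:
        header = ["sample_id", "predicted"] + [f"score_{c}" for c in table.class_order]
        fh.write("\t".join(header) + "\n")
        for i, sid in enumerate(table.sample_ids):
            row = [sid, table.predicted[i]] + [
                f"{table.scores[j, i]:.6f}" for j in range(len(table.class_order))
            ]
            fh.write("\t".join(row) + "\n")


def read_predictions(path: str | Path) -> PredictionTable:
    """Read back a prediction TSV written by :func:`write_predictions`."""
    df = pd.read_csv(path, sep="\t")
    class_order = [c[len("score_"):] for c in df.columns if c.startswith("score_")]
    scores = df[[f"score_{c}" for c in class_order]].to_numpy(dtype=float).T
    return PredictionTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        predicted=df["predicted"].astype(str).tolist(),
        class_order=class_order,
        scores=scores,
    )
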