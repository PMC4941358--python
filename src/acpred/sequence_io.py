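"""Reading, validating and writing peptide sequences and tabular results.

Peptides are plain sequences over the 20 standard one-letter amino-acid
codes.  Parsing is tolerant (lowercase and embedded whitespace are
normalised away); validation is strict and is a separate, policy-carrying
step so that callers decide whether an illegal residue aborts a batch or
merely drops the offending record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.  This
#: ordering is canonical throughout the package (feature indices, matrix
#: headers).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Validation policies: ``strict`` raises on an illegal residue, ``skip``
#: drops the record with a warning and continues the batch.
POLICIES = ("strict", "skip")


class FastaFormatError(ValueError):
    """The file is not parseable FASTA (e.g. sequence data before any header)."""


class NoRecordsError(ValueError):
    """The FASTA file contains no records."""


class EmptySequenceError(ValueError):
    """A FASTA record has a header but no residues."""


class InvalidResidueError(ValueError):
    """A residue outside the 20 standard one-letter codes.

    Attributes
    ----------
    peptide_id : str
    residue : str
        The offending character.
    position : int
        1-based position of the residue in the sequence.
    """

    def __init__(self, peptide_id: str, residue: str, position: int):
        self.peptide_id = peptide_id
        self.residue = residue
        self.position = position
        super().__init__(
            f"peptide {peptide_id!r}: illegal residue {residue!r} at position {position}"
        )


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence P = R1 R2 ... RL with a free-text identifier."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Peptides with parallel binary labels (+1 = ACP, -1 = non-ACP).

    The dataset is the union S = S+ ∪ S- of a positive and a negative
    group; ``m_pos`` and ``m_neg`` are the group sizes, ``M`` their total
    and ``K`` the number of groups (always 2).
    """

    peptides: list[Peptide]
    labels: np.ndarray  # int array of +1 / -1, parallel to peptides

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.peptides) != len(self.labels):
            raise ValueError("peptides and labels must have the same length")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +1 or -1")

    @property
    def m_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def m_neg(self) -> int:
        return int(np.sum(self.labels == -1))

    @property
    def M(self) -> int:
        return len(self.peptides)

    @property
    def K(self) -> int:
        return 2

    def positives(self) -> list[Peptide]:
        return [p for p, y in zip(self.peptides, self.labels) if y == 1]

    def negatives(self) -> list[Peptide]:
        return [p for p, y in zip(self.peptides, self.labels) if y == -1]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset([self.peptides[i] for i in idx], self.labels[idx])


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read all records of a FASTA file as :class:`Peptide` objects.

    The full header text after ``>`` becomes the id; sequence lines are
    concatenated, uppercased and stripped of whitespace.  No residue
    validation happens here — see :func:`validate_peptide`.

    Raises
    ------
    NoRecordsError
        The file holds no FASTA records.
    EmptySequenceError
        A record has a header but an empty sequence.
    FastaFormatError
        Sequence data precedes the first ``>`` header.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    try:
        with path.open() as handle:
            for record in SeqIO.parse(handle, "fasta"):
                seq = str(record.seq).upper().replace(" ", "").replace("\t", "")
                if not seq:
                    raise EmptySequenceError(
                        f"record {record.description!r} in {path} has an empty sequence"
                    )
                peptides.append(Peptide(id=record.description, sequence=seq))
    except ValueError as exc:
        if isinstance(exc, (EmptySequenceError,)):
            raise
        # Biopython signals non-FASTA leading content with a ValueError.
        raise FastaFormatError(f"{path}: {exc}") from exc
    if not peptides:
        raise NoRecordsError(f"no FASTA records found in {path}")
    return peptides


def validate_peptide(peptide: Peptide, policy: str = "strict") -> Peptide | None:
    """Check that every residue is one of the 20 standard codes.

    Codes such as B, U, X and Z — and gap/stop characters ``-`` and ``*``
    — are illegal.  Under ``strict`` an :class:`InvalidResidueError` is
    raised; under ``skip`` the function warns and returns ``None`` so the
    caller can drop the record and continue.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    for pos, residue in enumerate(peptide.sequence, start=1):
        if residue not in _ALPHABET_SET:
            if policy == "strict":
                raise InvalidResidueError(peptide.id, residue, pos)
            logger.warning(
                "dropping peptide %r: illegal residue %r at position %d",
                peptide.id, residue, pos,
            )
            return None
    return peptide


def validate_peptides(
    peptides: Iterable[Peptide], policy: str = "strict"
) -> list[Peptide]:
    """Validate a batch; under ``skip`` invalid records are dropped."""
    out = []
    for p in peptides:
        v = validate_peptide(p, policy=policy)
        if v is not None:
            out.append(v)
    return out


def load_labeled(
    pos_path: str | Path, neg_path: str | Path, policy: str = "strict"
) -> LabeledDataset:
    """Load a positive and a negative FASTA file into one labelled dataset.

    Positives come first (label +1), then negatives (label -1).  Duplicate
    ids across the two files trigger a warning but are kept: ids are
    labels, not keys.  Either class being empty after validation is an
    error — every training or selection operation needs both groups.
    """
    pos = validate_peptides(read_fasta(pos_path), policy=policy)
    neg = validate_peptides(read_fasta(neg_path), policy=policy)
    if not pos:
        raise ValueError(f"no valid positive peptides remain from {pos_path}")
    if not neg:
        raise ValueError(f"no valid negative peptides remain from {neg_path}")
    dup = {p.id for p in pos} & {p.id for p in neg}
    if dup:
        warnings.warn(
            f"{len(dup)} duplicate id(s) across positive and negative files "
            f"(e.g. {sorted(dup)[0]!r}); records are kept and disambiguated by order",
            stacklevel=2,
        )
    peptides = pos + neg
    labels = np.concatenate([np.ones(len(pos), int), -np.ones(len(neg), int)])
    return LabeledDataset(peptides, labels)


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as multi-line FASTA (60-column wrap)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def write_table(
    rows: Iterable[Sequence], path: str | Path, columns: Sequence[str]
) -> None:
    """Write rows as a TSV with header, UTF-8, ``\\n`` line endings.

    Row order is preserved; an empty row set yields a header-only file.
    """
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path):
    """Read back a TSV written by :func:`write_table` as a DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")
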