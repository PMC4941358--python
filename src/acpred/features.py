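"""Composition encodings: amino-acid composition and g-gap dipeptide composition.

A peptide P = R1 R2 ... RL is encoded as a fixed-length frequency vector.
The g-gap dipeptide composition counts ordered residue pairs
(R_i, R_{i+g+1}) — pairs separated by g intervening residues — over all
i = 1 .. L-g-1 and normalises by the number of counted pairs, giving a
400-component vector that retains partial sequence-order information
(g = 0 is the ordinary adjacent-dipeptide composition).  The plain
amino-acid composition (AAC) is the 20-component residue-frequency
vector, which discards order entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import ALPHABET, LabeledDataset, Peptide

logger = logging.getLogger(__name__)

AA_TO_RANK = {aa: i for i, aa in enumerate(ALPHABET)}

#: Canonical dipeptide names in index order: AA, AC, AD, ..., YY.
DIPEPTIDE_NAMES = tuple(a + b for a in ALPHABET for b in ALPHABET)

MAX_GAP = 4  # peptides are short; larger gaps leave too few counted pairs

ENCODINGS = ("aac", "ggap")


class PeptideTooShortError(ValueError):
    """The peptide has no counted pair for the requested gap (L - g - 1 < 1)."""

    def __init__(self, peptide: Peptide, g: int):
        self.peptide = peptide
        self.g = g
        super().__init__(
            f"peptide {peptide.id!r} (L={peptide.length}) too short for gap g={g}: "
            f"needs L >= g + 2"
        )


def dipeptide_index(first: str, second: str) -> int:
    """Canonical index u of the ordered dipeptide (first, second).

    u = 20 * rank(first) + rank(second) with residues ranked
    alphabetically (ACDEFGHIKLMNPQRSTVWY); a bijection onto [0, 400).
    """
    try:
        return 20 * AA_TO_RANK[first] + AA_TO_RANK[second]
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length composition vector for one peptide.

    ``values`` sums to 1 whenever the peptide admits at least one counted
    unit; ``omega`` is 20 for AAC and 400 for g-gap mode; ``g`` is None
    for AAC.
    """

    values: np.ndarray
    encoding: str
    g: int | None
    peptide_id: str

    @property
    def omega(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureMatrix:
    """Rows of consistently encoded feature vectors for a dataset.

    ``row_index`` maps each matrix row back to its position in the source
    dataset; ``dropped`` records (dataset position, reason) for peptides
    rejected under the ``skip`` policy.
    """

    X: np.ndarray  # (n, omega)
    ids: list[str]
    labels: np.ndarray  # +1 / -1, parallel to rows
    encoding: str
    g: int | None
    row_index: np.ndarray = field(default=None)  # dataset positions of kept rows
    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.row_index is None:
            self.row_index = np.arange(self.X.shape[0])

    @property
    def omega(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return DIPEPTIDE_NAMES if self.omega == 400 else tuple(ALPHABET)


def ggap_counts(peptide: Peptide, g: int) -> np.ndarray:
    """Raw g-gap dipeptide counts n_u^g; sums to L - g - 1."""
    if not 0 <= g <= MAX_GAP:
        raise ValueError(f"g must be in [0, {MAX_GAP}], got {g}")
    L = peptide.length
    n_pairs = L - g - 1
    if n_pairs < 1:
        raise PeptideTooShortError(peptide, g)
    counts = np.zeros(400)
    seq = peptide.sequence
    for i in range(n_pairs):
        counts[dipeptide_index(seq[i], seq[i + g + 1])] += 1
    return counts


def ggap_composition(peptide: Peptide, g: int) -> FeatureVector:
    """g-gap dipeptide composition d_u^g = n_u^g / (L - g - 1).

    Each component is the frequency of the u-th ordered pair
    (R_i, R_{i+g+1}); components sum to 1.  Peptides with no counted pair
    (L - g - 1 < 1) are a hard error — a zero vector would silently break
    the unit-sum invariant.
    """
    counts = ggap_counts(peptide, g)
    return FeatureVector(
        values=counts / counts.sum(), encoding="ggap", g=g, peptide_id=peptide.id
    )


def aac_composition(peptide: Peptide) -> FeatureVector:
    """Amino-acid composition: normalised residue frequencies f_i (20 components)."""
    if peptide.length < 1:
        raise ValueError(f"peptide {peptide.id!r} is empty")
    counts = np.zeros(20)
    for residue in peptide.sequence:
        try:
            counts[AA_TO_RANK[residue]] += 1
        except KeyError:
            raise ValueError(f"non-standard residue {residue!r}") from None
    return FeatureVector(
        values=counts / peptide.length, encoding="aac", g=None, peptide_id=peptide.id
    )


def encode_peptide(peptide: Peptide, encoding: str, g: int | None = None) -> FeatureVector:
    if encoding == "aac":
        return aac_composition(peptide)
    if encoding == "ggap":
        if g is None:
            raise ValueError("g is required for the ggap encoding")
        return ggap_composition(peptide, g)
    raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")


def encode_dataset(
    dataset: LabeledDataset,
    encoding: str = "ggap",
    g: int | None = 1,
    policy: str = "strict",
) -> FeatureMatrix:
    """Encode every peptide of a labelled dataset; rows follow dataset order.

    Peptides failing the encoding's length precondition are a hard error
    under ``strict`` or dropped (and recorded in ``dropped``) under
    ``skip``.
    """
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown policy {policy!r}")
    rows, ids, labels, kept, dropped = [], [], [], [], []
    for pos, (peptide, label) in enumerate(zip(dataset.peptides, dataset.labels)):
        try:
            vec = encode_peptide(peptide, encoding, g)
        except PeptideTooShortError as exc:
            if policy == "strict":
                raise
            logger.warning("dropping %s", exc)
            dropped.append((pos, str(exc)))
            continue
        rows.append(vec.values)
        ids.append(peptide.id)
        labels.append(label)
        kept.append(pos)
    if not rows:
        raise ValueError("all peptides were dropped during encoding")
    return FeatureMatrix(
        X=np.vstack(rows),
        ids=ids,
        labels=np.asarray(labels, dtype=int),
        encoding=encoding,
        g=g if encoding == "ggap" else None,
        row_index=np.asarray(kept, dtype=int),
        dropped=dropped,
    )


def matrix_to_frame(matrix: FeatureMatrix):
    """Feature matrix as a DataFrame: id column then per-feature columns."""
    import pandas as pd

    df = pd.DataFrame(matrix.X, columns=list(matrix.feature_names))
    df.insert(0, "id", matrix.ids)
    return df
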