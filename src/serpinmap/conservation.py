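"""Alignment-column conservation profiling at structure-mapped positions.

Quantifies the substitution pattern of alignment columns that map onto
structurally interesting residues — e.g. the helix-C position of AAT
occupied by E75, which across the serpin superfamily carries almost
exclusively glutamate or glutamine.  Columns are located through an
ungapped reference sequence (in place of manual indel curation) and
summarised as exact per-column amino-acid relative frequencies; logo
rendering is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Columns with more than this gap fraction are flagged low-coverage.
LOW_COVERAGE_GAP_FRACTION = 0.5


def read_alignment(path: str | Path, format: str | None = None) -> MultipleSeqAlignment:
    """Read a Stockholm or aligned-FASTA alignment.

    The format is inferred from the suffix (.sto/.stk/.stockholm vs
    .fa/.fasta/.afa) unless given.  Ragged inputs raise a ``ValueError``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".sto", ".stk", ".stockholm"):
            format = "stockholm"
        elif suffix in (".fa", ".fasta", ".afa", ".aln"):
            format = "fasta"
        else:
            raise ValueError(f"cannot infer alignment format from {path.name!r}")
    alignment = AlignIO.read(str(path), format)
    lengths = {len(record.seq) for record in alignment}
    if len(lengths) > 1:
        raise ValueError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    return alignment


def map_columns(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    structure_numbering_offset: int = 0,
) -> dict[int, int]:
    """Map residue indices of the reference sequence to alignment columns.

    Returns ``{residue_index: column}`` with 1-based columns; the i-th
    non-gap position of the reference row maps to residue index
    ``i + structure_numbering_offset``.  The offset aligns the row's local
    coordinates with mature structure numbering.
    """
    reference = None
    for record in alignment:
        if record.id == reference_id:
            reference = str(record.seq)
            break
    if reference is None:
        raise KeyError(f"reference sequence {reference_id!r} not in alignment")
    mapping: dict[int, int] = {}
    residue = 0
    for column, letter in enumerate(reference, start=1):
        if letter not in (GAP, "."):
            residue += 1
            mapping[residue + structure_numbering_offset] = column
    return mapping


@dataclass
class AlignmentColumnProfile:
    """Exact per-column amino-acid relative frequencies.

    ``frequencies[c]`` maps each observed state (single-letter amino acid
    or ``'-'`` for gap) to a :class:`fractions.Fraction`, so each column
    sums to exactly 1.  Non-standard letters are counted as gap-equivalent
    and listed in ``nonstandard``.  Columns with > 50% gaps are flagged in
    ``low_coverage``.
    """

    frequencies: dict[int, dict[str, Fraction]]
    n_sequences: int
    nonstandard: dict[int, int]
    low_coverage: set[int]

    def __post_init__(self) -> None:
        for column, freqs in self.frequencies.items():
            if sum(freqs.values()) != 1:
                raise ValueError(f"column {column}: frequencies do not sum to 1")

    def top_states(self, column: int, k: int = 2) -> list[str]:
        """The k most frequent non-gap states of a column."""
        freqs = {
            s: f for s, f in self.frequencies[column].items() if s != GAP
        }
        return sorted(freqs, key=lambda s: (-freqs[s], s))[:k]

    def to_frame(self) -> pd.DataFrame:
        """Wide float table: one row per column, one field per state."""
        states = list(AMINO_ACIDS) + [GAP]
        rows = []
        for column in sorted(self.frequencies):
            freqs = self.frequencies[column]
            row = {"column": column}
            row.update({s: float(freqs.get(s, 0)) for s in states})
            row["low_coverage"] = column in self.low_coverage
            rows.append(row)
        return pd.DataFrame(rows)


def column_frequencies(
    alignment: MultipleSeqAlignment, columns: list[int]
) -> AlignmentColumnProfile:
    """Relative amino-acid frequencies for the requested 1-based columns.

    Counting is case-insensitive; ``-`` and ``.`` are gaps; any other
    non-amino-acid letter is counted as gap-equivalent and reported in the
    profile's ``nonstandard`` tally.
    """
    length = alignment.get_alignment_length()
    n = len(alignment)
    if n == 0:
        raise ValueError("empty alignment")
    frequencies: dict[int, dict[str, Fraction]] = {}
    nonstandard: dict[int, int] = {}
    low_coverage: set[int] = set()
    for column in columns:
        if not 1 <= column <= length:
            raise ValueError(
                f"column {column} outside alignment length {length}"
            )
        counts: dict[str, int] = {}
        odd = 0
        for record in alignment:
            letter = str(record.seq[column - 1]).upper()
            if letter in (".", GAP):
                letter = GAP
            elif letter not in AMINO_ACIDS:
                odd += 1
                letter = GAP
            counts[letter] = counts.get(letter, 0) + 1
        frequencies[column] = {
            s: Fraction(c, n) for s, c in sorted(counts.items())
        }
        if odd:
            nonstandard[column] = odd
        if counts.get(GAP, 0) > n * LOW_COVERAGE_GAP_FRACTION:
            low_coverage.add(column)
    return AlignmentColumnProfile(
        frequencies=frequencies,
        n_sequences=n,
        nonstandard=nonstandard,
        low_coverage=low_coverage,
    )
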