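"""Binary encoding of aligned protein sequences.

Each residue of an aligned protein sequence is mapped to a fixed-width binary
codeword; the concatenated codewords form the initial state of a
one-dimensional two-state cellular automaton.  The built-in code table assigns
an 8-bit word to each of the 20 standard amino acids, derived from the
molecular structure of the side chain (atom counts of C/N/O/S, aromaticity,
covalent bonds), plus dedicated words for alignment gaps ('-') and missing
residues ('?').  For an alignment of P columns the automaton therefore has
M = 8 * P cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "CodeTable",
    "AlignedProteinSet",
    "AmbiguousResidueWarning",
    "STANDARD_AMINO_ACIDS",
    "AMBIGUOUS_RESIDUES",
    "load_code_table",
    "read_aligned_fasta",
    "encode_sequence",
    "decode_state",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: IUPAC one-letter codes with no codeword of their own: ambiguity codes
#: (B, J, Z, X) and the rare residues selenocysteine (U) and pyrrolysine (O).
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")

GAP = "-"
MISSING = "?"

# 8-bit side-chain structure code: one word per standard amino acid plus
# gap and missing-data symbols.
_DEFAULT_ENTRIES = {
    "G": "00000000",
    "A": "00000100",
    "P": "00100110",
    "V": "00010110",
    "M": "00110110",
    "W": "10110110",
    "F": "10000100",
    "I": "00011110",
    "L": "00010111",
    "S": "00100100",
    "C": "01000100",
    "T": "00110100",
    "N": "00101110",
    "Q": "00101111",
    "Y": "10100100",
    "H": "01111110",
    "K": "00110111",
    "R": "01111111",
    "D": "01110100",
    "E": "01110110",
    GAP: "11111111",
    MISSING: "11111110",
}


class AmbiguousResidueWarning(UserWarning):
    """A residue outside the code table was mapped to the missing codeword."""


class CodeTableError(ValueError):
    """Invalid code table (ragged widths, duplicate codewords, bad symbols)."""


class AlignmentError(ValueError):
    """Input records do not form a valid alignment."""


class EncodingError(ValueError):
    """A sequence symbol cannot be resolved under the code table."""


class DecodeError(ValueError):
    """A bit chunk has no corresponding symbol in the code table."""


@dataclass(frozen=True)
class CodeTable:
    """Injective map from residue symbols to fixed-width binary codewords.

    Parameters
    ----------
    entries
        Mapping from single-character symbols to bit strings, all of the
        same length.
    """

    entries: Mapping[str, str]
    width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise CodeTableError("code table is empty")
        widths = {len(code) for code in self.entries.values()}
        if len(widths) != 1:
            raise CodeTableError(f"codewords have mixed widths: {sorted(widths)}")
        (width,) = widths
        if width < 1:
            raise CodeTableError("codeword width must be positive")
        object.__setattr__(self, "width", width)
        for sym, code in self.entries.items():
            if len(sym) != 1:
                raise CodeTableError(f"symbol {sym!r} is not a single character")
            if set(code) - {"0", "1"}:
                raise CodeTableError(f"codeword for {sym!r} is not binary: {code!r}")
        seen: dict[str, str] = {}
        for sym, code in self.entries.items():
            if code in seen:
                raise CodeTableError(
                    f"codeword {code!r} assigned to both {seen[code]!r} and {sym!r}"
                )
            seen[code] = sym

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.entries)

    def codeword(self, symbol: str) -> str:
        return self.entries[symbol]

    def inverse(self) -> dict[str, str]:
        """Codeword -> symbol map (well-defined because the table is injective)."""
        return {code: sym for sym, code in self.entries.items()}

    @classmethod
    def default(cls) -> "CodeTable":
        """The built-in 8-bit molecular-structure code (20 AAs, '-', '?')."""
        return cls(dict(_DEFAULT_ENTRIES))


def load_code_table(source: str | Path | Mapping[str, str] | None = None) -> CodeTable:
    """Load and validate a code table.

    ``source`` may be ``None`` (return the built-in 8-bit table), a mapping of
    symbol -> bit string, or a path to a two-column text file with one
    ``SYMBOL<TAB>BITSTRING`` pair per line ('#' starts a comment).
    """
    if source is None:
        return CodeTable.default()
    if isinstance(source, Mapping):
        return CodeTable(dict(source))
    entries: dict[str, str] = {}
    path = Path(source)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise CodeTableError(f"{path}:{lineno}: expected 'SYMBOL BITSTRING', got {raw!r}")
        sym, code = parts
        if sym in entries:
            raise CodeTableError(f"{path}:{lineno}: duplicate symbol {sym!r}")
        entries[sym.upper() if sym.isalpha() else sym] = code
    return CodeTable(entries)


@dataclass(frozen=True)
class AlignedProteinSet:
    """An ordered set of equal-length (aligned) protein sequences."""

    labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise AlignmentError("labels and sequences differ in count")
        if not self.labels:
            raise AlignmentError("empty alignment")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AlignmentError(f"duplicate labels: {dupes}")
        if any(not l for l in self.labels):
            raise AlignmentError("empty label")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            offenders = [
                f"{l} (len {len(s)})"
                for l, s in zip(self.labels, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise AlignmentError(
                f"sequences are not aligned to a common length: {', '.join(offenders)}"
            )
        if min(lengths) < 1:
            raise AlignmentError("zero-length alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_positions(self) -> int:
        """Number of aligned columns P."""
        return len(self.sequences[0])

    def __len__(self) -> int:
        return self.n_taxa

    def __iter__(self) -> Iterable[tuple[str, str]]:
        return iter(zip(self.labels, self.sequences))

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "AlignedProteinSet":
        labels, seqs = [], []
        for label, seq in records:
            labels.append(label)
            seqs.append(seq.upper())
        return cls(tuple(labels), tuple(seqs))

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for label, seq in self:
                fh.write(f">{label}\n{seq}\n")


def read_aligned_fasta(path: str | Path) -> AlignedProteinSet:
    """Read an aligned FASTA file into an :class:`AlignedProteinSet`.

    Record order is preserved and residues are uppercased.  Raises
    :class:`AlignmentError` for ragged records, duplicate identifiers or an
    empty/short file (at least two records are required).
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least two records, found {len(records)}")
    return AlignedProteinSet.from_records(records)


def encode_sequence(seq: str, table: CodeTable | None = None) -> np.ndarray:
    """Encode a residue string as a binary automaton state.

    Returns a 1-D ``uint8`` array of length ``M = table.width * len(seq)``,
    the per-symbol codewords concatenated in sequence order.  Residues without
    a codeword of their own (B, J, O, U, X, Z) fall back to the
    missing-information codeword, with an :class:`AmbiguousResidueWarning`;
    anything else unresolvable raises :class:`EncodingError`.
    """
    table = table or CodeTable.default()
    if not seq:
        raise EncodingError("empty sequence")
    seq = seq.upper()
    bits = np.empty(table.width * len(seq), dtype=np.uint8)
    for pos, sym in enumerate(seq):
        code = table.entries.get(sym)
        if code is None:
            if sym in AMBIGUOUS_RESIDUES and MISSING in table.entries:
                warnings.warn(
                    f"residue {sym!r} at position {pos + 1} has no codeword; "
                    f"using the missing-information code",
                    AmbiguousResidueWarning,
                    stacklevel=2,
                )
                code = table.entries[MISSING]
            else:
                raise EncodingError(
                    f"symbol {sym!r} at position {pos + 1} cannot be encoded"
                )
        start = pos * table.width
        bits[start : start + table.width] = [int(b) for b in code]
    return bits


def decode_state(state: np.ndarray, table: CodeTable | None = None) -> str:
    """Inverse of :func:`encode_sequence` on valid encodings."""
    table = table or CodeTable.default()
    state = np.asarray(state, dtype=np.uint8)
    if state.ndim != 1 or state.size == 0:
        raise DecodeError("state must be a non-empty 1-D bit vector")
    if state.size % table.width:
        raise DecodeError(
            f"state length {state.size} is not a multiple of width {table.width}"
        )
    inv = table.inverse()
    chars = []
    for idx in range(state.size // table.width):
        chunk = "".join(str(b) for b in state[idx * table.width : (idx + 1) * table.width])
        sym = inv.get(chunk)
        if sym is None:
            raise DecodeError(f"chunk {idx} ({chunk!r}) is not a known codeword")
        chars.append(sym)
    return "".join(chars)
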