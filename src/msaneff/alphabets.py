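"""Residue alphabets, integer encoding of alignments, and MSA validation.

This module owns *character* semantics: which symbols a protein, DNA or RNA
alignment may contain, how non-standard residues are treated, and how an
alignment is turned into the integer matrix the NEFF computation consumes.
Format semantics (headers, blocks, A3M insertion states) live in
:mod:`msaneff.io`; by the time sequences reach :func:`encode_msa` they are
plain column-aligned rows.

Character policy
----------------
All comparisons happen after uppercasing.  Both ``-`` and ``.`` are gaps and
share a single gap code.  Non-standard residues (protein ``B J O U X Z``;
nucleotide IUPAC ambiguity codes plus ``X``) are either given their own codes
(``as_standard``, the default — two ``X`` residues in the same column then
count as a match) or collapsed onto the gap code (``as_gap``).  Any other
character, including ``*``, is rejected with the offending record and column.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import EncodingError

if TYPE_CHECKING:  # pragma: no cover
    from .io import Msa, MsaFormat

GAP_SYMBOLS = ("-", ".")

_PROTEIN_STANDARD = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_NON_STANDARD = "BJOUXZ"
_DNA_STANDARD = "ACGT"
_RNA_STANDARD = "ACGU"
# IUPAC nucleotide ambiguity letters, plus X as a generic unknown.
_NUC_NON_STANDARD = "NRYSWKMBDHVX"


@dataclass(frozen=True)
class Alphabet:
    """A biological sequence alphabet.

    ``standard_symbols``, ``non_standard_symbols`` and the gap symbols are
    pairwise disjoint; every uppercase character accepted by :func:`encode_msa`
    belongs to exactly one of the three sets.
    """

    name: str
    standard_symbols: str
    non_standard_symbols: str
    gap_symbols: tuple[str, ...] = GAP_SYMBOLS

    def __post_init__(self) -> None:
        std, non, gap = (
            set(self.standard_symbols),
            set(self.non_standard_symbols),
            set(self.gap_symbols),
        )
        if std & non or std & gap or non & gap:
            raise ValueError("alphabet symbol sets must be pairwise disjoint")

    @property
    def allowed(self) -> frozenset[str]:
        """Every permitted uppercase character, gaps included."""
        return frozenset(self.standard_symbols) | frozenset(
            self.non_standard_symbols
        ) | frozenset(self.gap_symbols)

    @classmethod
    def protein(cls) -> "Alphabet":
        return cls("protein", _PROTEIN_STANDARD, _PROTEIN_NON_STANDARD)

    @classmethod
    def dna(cls) -> "Alphabet":
        return cls("dna", _DNA_STANDARD, _NUC_NON_STANDARD)

    @classmethod
    def rna(cls) -> "Alphabet":
        return cls("rna", _RNA_STANDARD, _NUC_NON_STANDARD)

    @classmethod
    def from_name(cls, name: str) -> "Alphabet":
        try:
            return {"protein": cls.protein, "dna": cls.dna, "rna": cls.rna}[
                name.lower()
            ]()
        except KeyError:
            raise ValueError(
                f"unknown alphabet {name!r}; expected protein, dna, or rna"
            ) from None


class NonStandardPolicy(enum.Enum):
    """How non-standard residues are encoded.

    ``AS_STANDARD`` gives each its own distinct code; ``AS_GAP`` maps all of
    them onto the gap code.
    """

    AS_STANDARD = "as_standard"
    AS_GAP = "as_gap"

    @classmethod
    def coerce(cls, value) -> "NonStandardPolicy":
        if isinstance(value, cls):
            return value
        key = str(value).lower()
        if key in ("standard", "as_standard"):
            return cls.AS_STANDARD
        if key in ("gap", "as_gap"):
            return cls.AS_GAP
        raise ValueError(f"unknown non-standard residue policy {value!r}")


GAP_CODE = 0


@dataclass
class EncodedMsa:
    """Integer-matrix view of a column-aligned MSA.

    ``matrix`` is N rows x L columns of codes; ``gap_code`` is the single
    reserved gap value.  ``column_map`` maps current columns back to 0-based
    columns of the original alignment and stays strictly increasing through
    preprocessing.  ``columns_removed`` records (query-gap, gappy) column
    counts once preprocessing has run.
    """

    matrix: np.ndarray
    gap_code: int
    symbol_map: dict[str, int]
    column_map: list[int]
    query_row: int = 0
    columns_removed: tuple[int, int] = (0, 0)

    @property
    def n_rows(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.matrix.shape[1])


def build_symbol_map(
    alphabet: Alphabet, policy: NonStandardPolicy
) -> dict[str, int]:
    """Deterministic character→code map for an alphabet under a policy."""
    mapping: dict[str, int] = {g: GAP_CODE for g in alphabet.gap_symbols}
    code = GAP_CODE + 1
    for ch in alphabet.standard_symbols:
        mapping[ch] = code
        code += 1
    for ch in alphabet.non_standard_symbols:
        if policy is NonStandardPolicy.AS_GAP:
            mapping[ch] = GAP_CODE
        else:
            mapping[ch] = code
            code += 1
    return mapping


def encode_msa(
    msa: "Msa",
    alphabet: Alphabet | None = None,
    policy: NonStandardPolicy = NonStandardPolicy.AS_STANDARD,
) -> EncodedMsa:
    """Encode a column-aligned MSA into an :class:`EncodedMsa`.

    Rows are uppercased before mapping; ``.`` and ``-`` both become the gap
    code.  A character outside the alphabet raises :class:`EncodingError`
    naming the character, record id, and 1-based column.
    """
    if alphabet is None:
        alphabet = Alphabet.protein()
    elif isinstance(alphabet, str):
        alphabet = Alphabet.from_name(alphabet)
    policy = NonStandardPolicy.coerce(policy)
    records = msa.records
    if not records:
        raise EncodingError("alignment has no records")
    length = len(records[0].seq)
    if length == 0:
        raise EncodingError("alignment has zero columns")
    for rec in records:
        if len(rec.seq) != length:
            raise EncodingError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {length};"
                " alignment must be column-aligned before encoding"
            )

    mapping = build_symbol_map(alphabet, policy)
    # 256-entry lookup over raw bytes; -1 marks a rejected character.
    table = np.full(256, -1, dtype=np.int16)
    for ch, code in mapping.items():
        table[ord(ch)] = code
        table[ord(ch.lower())] = code

    matrix = np.empty((len(records), length), dtype=np.int16)
    for i, rec in enumerate(records):
        raw = np.frombuffer(rec.seq.encode("ascii", "replace"), dtype=np.uint8)
        row = table[raw]
        bad = np.nonzero(row < 0)[0]
        if bad.size:
            col = int(bad[0])
            raise EncodingError(
                f"character {rec.seq[col]!r} in record {rec.id!r} at column "
                f"{col + 1} is not a {alphabet.name} residue or gap"
            )
        matrix[i] = row

    return EncodedMsa(
        matrix=matrix,
        gap_code=GAP_CODE,
        symbol_map=dict(mapping),
        column_map=list(range(length)),
        query_row=msa.query_index,
    )


def decode_msa(encoded: EncodedMsa) -> list[str]:
    """Inverse of :func:`encode_msa` up to the encoding's normalizations.

    Gaps come back as ``-``; symbols that the policy remapped to the gap code
    are irrecoverable and also decode to ``-``.
    """
    inverse: dict[int, str] = {encoded.gap_code: "-"}
    for ch, code in encoded.symbol_map.items():
        if code != encoded.gap_code:
            inverse[code] = ch
    return [
        "".join(inverse[int(c)] for c in row) for row in encoded.matrix
    ]


@dataclass
class Issue:
    severity: str  # "error" | "warning"
    message: str
    line: int | None = None


@dataclass
class ValidationReport:
    """Outcome of validating one MSA file against a format and alphabet."""

    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def summary(self) -> str:
        if self.ok and not self.issues:
            return "OK"
        lines = []
        for issue in self.issues:
            where = f" (line {issue.line})" if issue.line is not None else ""
            lines.append(f"{issue.severity.upper()}{where}: {issue.message}")
        return "\n".join(lines)


def validate_msa(source, format, alphabet: Alphabet | None = None) -> ValidationReport:
    """Validate an MSA file or text for format conformance and characters.

    Collects *every* violation found: malformed structure for the declared
    format, unequal aligned lengths, characters outside the alphabet's
    permitted set, and empty alignments, each with a 1-based line number
    where locatable.  The input is never modified.  An unreadable source
    raises ``OSError`` rather than returning a report.
    """
    from .io import MsaFormat, parse_for_validation, read_text

    alphabet = alphabet or Alphabet.protein()
    fmt = MsaFormat.coerce(format)
    text = read_text(source)
    parsed = parse_for_validation(text, fmt)

    report = ValidationReport(
        issues=[Issue(sev, msg, line) for sev, msg, line in parsed.issues]
    )
    allowed = alphabet.allowed
    for line_no, rec_id, chunk in parsed.chunks:
        for pos, ch in enumerate(chunk):
            if ch.upper() not in allowed:
                report.issues.append(
                    Issue(
                        "error",
                        f"character {ch!r} in record {rec_id!r} is not a "
                        f"{alphabet.name} residue or gap (column {pos + 1} of this line)",
                        line_no,
                    )
                )
    return report
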