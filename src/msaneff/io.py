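"""Reading, writing, converting and merging MSAs across seven formats.

Supported formats: aligned FASTA, A2M, A3M, Stockholm 1.0, Clustal, PFAM
(one ``id<whitespace>sequence`` line per record, i.e. a header-less Stockholm
body), and ALN (bare aligned rows, one per line, no ids — the minimal dialect
used by DeepMSA-style pipelines).

A2M/A3M carry alignment-state semantics in letter case: uppercase letters and
``-`` are match columns, lowercase letters are insertions relative to the
query.  A2M pads insertion columns with ``.`` so raw rows stay equal length;
A3M omits the padding so raw rows may differ in length.
:func:`resolve_insertions` converts either into a plain column-aligned view,
by removing insertions (the match-column view NEFF consumes) or expanding
them into full gap-padded columns.

Conventions: the query is the first record unless ``query_index`` says
otherwise; ``.`` and ``-`` are interchangeable gaps everywhere except inside
A2M/A3M state semantics; written FASTA wraps at 60 columns.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence, TextIO, Union

from .errors import MergeError, MsaParseError, UnrecognizedFormatError

logger = logging.getLogger("msaneff")

Source = Union[str, os.PathLike, TextIO]


class MsaFormat(enum.Enum):
    FASTA = "fasta"
    A2M = "a2m"
    A3M = "a3m"
    STO = "sto"
    ALN = "aln"
    CLUSTAL = "clustal"
    PFAM = "pfam"

    @classmethod
    def coerce(cls, value) -> "MsaFormat":
        if isinstance(value, cls):
            return value
        key = str(value).lower()
        aliases = {"stockholm": "sto", "fa": "fasta", "clu": "clustal"}
        key = aliases.get(key, key)
        try:
            return cls(key)
        except ValueError:
            names = ", ".join(f.value for f in cls)
            raise ValueError(f"unknown MSA format {value!r}; expected one of {names}") from None


#: Formats whose on-disk rows are guaranteed column-aligned.
COLUMN_ALIGNED_FORMATS = frozenset(
    {MsaFormat.FASTA, MsaFormat.STO, MsaFormat.ALN, MsaFormat.CLUSTAL, MsaFormat.PFAM}
)


@dataclass
class MsaRecord:
    """One aligned sequence row: id, optional description, sequence string."""

    id: str
    seq: str
    description: str = ""

    def normalized_seq(self) -> str:
        """Uppercased sequence with ``.`` gaps rewritten as ``-``."""
        return self.seq.upper().replace(".", "-")


@dataclass
class Msa:
    """An ordered multiple sequence alignment plus format metadata.

    ``annotations`` holds pass-through annotation lines (Stockholm
    ``#=GF/#=GC/#=GS/#=GR``).  For A3M sources the raw rows may differ in
    length until :func:`resolve_insertions` has run.
    """

    records: list[MsaRecord]
    source_format: MsaFormat = MsaFormat.FASTA
    annotations: list[str] = field(default_factory=list)
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("an Msa needs at least one record")
        if not 0 <= self.query_index < len(self.records):
            raise ValueError("query_index out of range")

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def query(self) -> MsaRecord:
        return self.records[self.query_index]

    def is_aligned(self) -> bool:
        length = len(self.records[0].seq)
        return all(len(r.seq) == length for r in self.records)

    @property
    def n_cols(self) -> int:
        if not self.is_aligned():
            raise ValueError(
                "alignment rows differ in raw length (unresolved a3m?); "
                "call resolve_insertions first"
            )
        return len(self.records[0].seq)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]


def read_text(source: Source) -> str:
    """Return the text behind a path, raw string, or open file object."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, os.PathLike):
        with open(source, "r", encoding="utf-8") as handle:
            return handle.read()
    if isinstance(source, str):
        if "\n" in source or source == "":
            return source
        if os.path.exists(source):
            with open(source, "r", encoding="utf-8") as handle:
                return handle.read()
        # Single-line string that is not an existing path: treat as raw text
        # unless it looks like a file name.
        looks_like_path = os.sep in source or source.lower().endswith(
            (".fasta", ".fa", ".a2m", ".a3m", ".sto", ".aln", ".clustal", ".pfam", ".txt")
        )
        if looks_like_path and not any(ch in source for ch in (">", " ")):
            raise FileNotFoundError(source)
        return source
    raise TypeError(f"unsupported source type {type(source).__name__}")


class ParsedMsa(NamedTuple):
    """Parser output shared by the reader and the validator."""

    records: list[MsaRecord]
    annotations: list[str]
    issues: list[tuple[str, str, int | None]]  # (severity, message, line)
    chunks: list[tuple[int, str, str]]  # (line_no, record_id, sequence chunk)


def _match_length(seq: str) -> int:
    """Number of match-state columns of an A2M/A3M row (uppercase + '-')."""
    return sum(1 for ch in seq if ch == "-" or ch.isupper())


def _check_equal_lengths(
    records: list[MsaRecord],
    first_lines: dict[int, int],
    issues: list,
    length_of=len,
    what: str = "length",
) -> None:
    if not records:
        return
    expected = length_of(records[0].seq)
    for idx, rec in enumerate(records[1:], start=1):
        got = length_of(rec.seq)
        if got != expected:
            issues.append(
                (
                    "error",
                    f"record {rec.id!r} has unequal {what} {got}, expected {expected}",
                    first_lines.get(idx),
                )
            )


def _parse_fasta_like(text: str, fmt: MsaFormat) -> ParsedMsa:
    records: list[MsaRecord] = []
    issues: list[tuple[str, str, int | None]] = []
    chunks: list[tuple[int, str, str]] = []
    first_lines: dict[int, int] = {}
    parts: list[str] = []

    def flush() -> None:
        if records:
            records[-1].seq = "".join(parts)

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = []
            header = line[1:].strip()
            if not header:
                issues.append(("error", "empty FASTA header", line_no))
                rec_id, desc = f"seq_{len(records) + 1}", ""
            else:
                bits = header.split(None, 1)
                rec_id = bits[0]
                desc = bits[1] if len(bits) > 1 else ""
            records.append(MsaRecord(rec_id, "", desc))
        else:
            if not records:
                issues.append(
                    ("error", "sequence data before the first '>' header", line_no)
                )
                continue
            chunk = "".join(line.split())
            if not parts:
                first_lines[len(records) - 1] = line_no
            parts.append(chunk)
            chunks.append((line_no, records[-1].id, chunk))
    flush()

    if not records:
        issues.append(("error", "empty alignment: no records found", None))
    for idx, rec in enumerate(records):
        if not rec.seq:
            issues.append(("error", f"record {rec.id!r} has an empty sequence", None))
    if records and all(r.seq for r in records):
        if fmt is MsaFormat.A3M:
            _check_equal_lengths(
                records, first_lines, issues, length_of=_match_length,
                what="match-column count",
            )
        else:
            _check_equal_lengths(records, first_lines, issues)
    return ParsedMsa(records, [], issues, chunks)


def _parse_stockholm(text: str) -> ParsedMsa:
    records: list[MsaRecord] = []
    annotations: list[str] = []
    issues: list[tuple[str, str, int | None]] = []
    chunks: list[tuple[int, str, str]] = []
    order: dict[str, int] = {}
    first_lines: dict[int, int] = {}
    lines = text.splitlines()
    terminated = False
    saw_header = False

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        if not saw_header:
            if line.startswith("# STOCKHOLM"):
                saw_header = True
                continue
            issues.append(
                ("error", "missing '# STOCKHOLM 1.0' header line", line_no)
            )
            saw_header = True  # keep parsing to report more
        if line.startswith("#="):
            annotations.append(line)
            continue
        if line.startswith("#"):
            continue  # plain comment
        if line.strip() == "//":
            terminated = True
            break
        bits = line.split()
        if len(bits) != 2:
            issues.append(
                ("error", f"expected 'id sequence' line, got {line.strip()!r}", line_no)
            )
            continue
        rec_id, chunk = bits
        if rec_id not in order:
            order[rec_id] = len(records)
            records.append(MsaRecord(rec_id, chunk))
            first_lines[order[rec_id]] = line_no
        else:
            records[order[rec_id]].seq += chunk
        chunks.append((line_no, rec_id, chunk))

    if not terminated:
        issues.append(("error", "missing '//' terminator", None))
    if not records:
        issues.append(("error", "empty alignment: no sequence lines found", None))
    else:
        _check_equal_lengths(records, first_lines, issues)
    return ParsedMsa(records, annotations, issues, chunks)


_CLUSTAL_CONSERVATION = frozenset("*:. ")


def _parse_clustal(text: str) -> ParsedMsa:
    records: list[MsaRecord] = []
    issues: list[tuple[str, str, int | None]] = []
    chunks: list[tuple[int, str, str]] = []
    order: dict[str, int] = {}
    first_lines: dict[int, int] = {}
    lines = text.splitlines()
    saw_header = False

    for line_no, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if not saw_header:
            if raw.lstrip().upper().startswith("CLUSTAL"):
                saw_header = True
                continue
            issues.append(("error", "missing CLUSTAL header line", line_no))
            saw_header = True
        if raw[:1].isspace():
            # conservation line (or stray indentation): ignore
            continue
        bits = raw.split()
        if len(bits) >= 3 and bits[-1].isdigit():
            bits = bits[:-1]  # trailing cumulative residue count
        if len(bits) != 2:
            issues.append(
                ("error", f"expected 'id sequence' line, got {raw.strip()!r}", line_no)
            )
            continue
        rec_id, chunk = bits
        if rec_id not in order:
            order[rec_id] = len(records)
            records.append(MsaRecord(rec_id, chunk))
            first_lines[order[rec_id]] = line_no
        else:
            records[order[rec_id]].seq += chunk
        chunks.append((line_no, rec_id, chunk))

    if not records:
        issues.append(("error", "empty alignment: no sequence lines found", None))
    else:
        _check_equal_lengths(records, first_lines, issues)
    return ParsedMsa(records, [], issues, chunks)


def _parse_pfam(text: str) -> ParsedMsa:
    records: list[MsaRecord] = []
    annotations: list[str] = []
    issues: list[tuple[str, str, int | None]] = []
    chunks: list[tuple[int, str, str]] = []
    first_lines: dict[int, int] = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#="):
            annotations.append(line)
            continue
        if line.startswith("#") or line == "//":
            continue
        bits = line.split()
        if len(bits) != 2:
            issues.append(
                ("error", f"expected 'id sequence' line, got {line!r}", line_no)
            )
            continue
        rec_id, seq = bits
        records.append(MsaRecord(rec_id, seq))
        first_lines[len(records) - 1] = line_no
        chunks.append((line_no, rec_id, seq))

    if not records:
        issues.append(("error", "empty alignment: no records found", None))
    else:
        _check_equal_lengths(records, first_lines, issues)
    return ParsedMsa(records, annotations, issues, chunks)


def _parse_aln(text: str) -> ParsedMsa:
    records: list[MsaRecord] = []
    issues: list[tuple[str, str, int | None]] = []
    chunks: list[tuple[int, str, str]] = []
    first_lines: dict[int, int] = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if len(line.split()) != 1:
            issues.append(
                ("error", f"expected one bare aligned row per line, got {line!r}", line_no)
            )
            continue
        rec_id = f"seq_{len(records) + 1}"
        records.append(MsaRecord(rec_id, line))
        first_lines[len(records) - 1] = line_no
        chunks.append((line_no, rec_id, line))

    if not records:
        issues.append(("error", "empty alignment: no rows found", None))
    else:
        _check_equal_lengths(records, first_lines, issues)
    return ParsedMsa(records, [], issues, chunks)


_PARSERS = {
    MsaFormat.FASTA: lambda t: _parse_fasta_like(t, MsaFormat.FASTA),
    MsaFormat.A2M: lambda t: _parse_fasta_like(t, MsaFormat.A2M),
    MsaFormat.A3M: lambda t: _parse_fasta_like(t, MsaFormat.A3M),
    MsaFormat.STO: _parse_stockholm,
    MsaFormat.CLUSTAL: _parse_clustal,
    MsaFormat.PFAM: _parse_pfam,
    MsaFormat.ALN: _parse_aln,
}


def parse_for_validation(text: str, fmt: MsaFormat) -> ParsedMsa:
    """Run the format parser in issue-collecting mode (used by the validator)."""
    return _PARSERS[MsaFormat.coerce(fmt)](text)


def read_msa(source: Source, format) -> Msa:
    """Parse an MSA from a path, text, or file object.

    Record order follows file order.  Raises :class:`MsaParseError` on the
    first structural violation, with a line number where locatable.
    """
    fmt = MsaFormat.coerce(format)
    parsed = _PARSERS[fmt](read_text(source))
    for severity, message, line in parsed.issues:
        if severity == "error":
            raise MsaParseError(message, line)
    return Msa(
        records=parsed.records,
        source_format=fmt,
        annotations=parsed.annotations,
    )


def detect_format(source: Source) -> MsaFormat:
    """Guess the format of an MSA from structural cues.

    Deterministic rules: a Stockholm magic line wins; then a Clustal header
    word; ``>`` headers are FASTA when all rows are uppercase and equal
    length, A2M when rows are equal raw length but carry lowercase or ``.``,
    A3M otherwise; headerless two-column lines are PFAM and bare rows ALN.
    """
    text = read_text(source)
    stripped = [ln for ln in text.splitlines() if ln.strip()]
    if not stripped:
        raise UnrecognizedFormatError("empty input")
    first = stripped[0]
    if first.startswith("# STOCKHOLM"):
        return MsaFormat.STO
    if first.lstrip().upper().startswith("CLUSTAL"):
        return MsaFormat.CLUSTAL
    if first.lstrip().startswith(">"):
        parsed = _parse_fasta_like(text, MsaFormat.A3M)
        seqs = [r.seq for r in parsed.records if r.seq]
        if not seqs:
            raise UnrecognizedFormatError("FASTA-like input with no sequences")
        plain = all(
            s == s.upper() and "." not in s for s in seqs
        ) and len({len(s) for s in seqs}) == 1
        if plain:
            return MsaFormat.FASTA
        if len({len(s) for s in seqs}) == 1:
            return MsaFormat.A2M
        return MsaFormat.A3M
    fields = {len(ln.split()) for ln in stripped if not ln.startswith("#")}
    if fields == {1}:
        return MsaFormat.ALN
    if fields == {2}:
        return MsaFormat.PFAM
    raise UnrecognizedFormatError(
        "no structural cue matched; pass the format explicitly (--in-format)"
    )


def resolve_insertions(msa: Msa, mode: str = "remove") -> Msa:
    """Turn an A2M/A3M alignment into a plain column-aligned one.

    ``remove`` deletes all lowercase (insertion) residues and ``.``
    placeholders, leaving only match columns.  ``expand`` turns every
    insertion run into full columns: the inserting row contributes its
    residues (uppercased) and all other rows contribute ``-``; runs between
    the same pair of match columns are left-aligned and gap-padded to the
    longest run.
    """
    if msa.source_format not in (MsaFormat.A2M, MsaFormat.A3M):
        raise ValueError("resolve_insertions applies to a2m/a3m alignments only")
    if mode not in ("remove", "expand"):
        raise ValueError(f"unknown insertion mode {mode!r}")

    match_counts = {_match_length(r.seq) for r in msa.records}
    if len(match_counts) != 1:
        raise MsaParseError(
            f"inconsistent a2m/a3m: match-column counts differ across rows "
            f"({sorted(match_counts)})"
        )
    n_match = match_counts.pop()

    if mode == "remove":
        new_records = [
            MsaRecord(
                r.id,
                "".join(ch for ch in r.seq if ch == "-" or ch.isupper()),
                r.description,
            )
            for r in msa.records
        ]
    else:
        # insertions[row][p] = residues inserted before match column p
        per_row: list[list[str]] = []
        for rec in msa.records:
            runs: list[str] = [""] * (n_match + 1)
            pos = 0
            buf: list[str] = []
            for ch in rec.seq:
                if ch == "." :
                    continue
                if ch.islower():
                    buf.append(ch.upper())
                else:  # match column: uppercase residue or '-'
                    runs[pos] = "".join(buf)
                    buf = []
                    pos += 1
            runs[n_match] = "".join(buf)
            per_row.append(runs)
        widths = [
            max(len(per_row[i][p]) for i in range(len(per_row)))
            for p in range(n_match + 1)
        ]
        new_records = []
        for rec, runs in zip(msa.records, per_row):
            match_chars = [ch for ch in rec.seq if ch == "-" or ch.isupper()]
            out: list[str] = []
            for p in range(n_match):
                out.append(runs[p].ljust(widths[p], "-"))
                out.append(match_chars[p])
            out.append(runs[n_match].ljust(widths[n_match], "-"))
            new_records.append(MsaRecord(rec.id, "".join(out), rec.description))

    return Msa(
        records=new_records,
        source_format=MsaFormat.FASTA,
        annotations=list(msa.annotations),
        query_index=msa.query_index,
    )


def _wrap(seq: str, width: int) -> Iterable[str]:
    for start in range(0, len(seq), width):
        yield seq[start : start + width]


def write_msa(msa: Msa, format, sink: Source, width: int = 60) -> None:
    """Write an MSA in the given format to a path or file object.

    Lossy targets log a warning naming what is dropped: ALN drops ids and
    descriptions; every non-Stockholm target drops annotation lines.
    """
    fmt = MsaFormat.coerce(format)
    if fmt in COLUMN_ALIGNED_FORMATS and not msa.is_aligned():
        raise ValueError(
            f"rows differ in length; resolve insertions before writing {fmt.value}"
        )
    if msa.annotations and fmt is not MsaFormat.STO:
        logger.warning(
            "writing %s drops %d annotation line(s)", fmt.value, len(msa.annotations)
        )

    lines: list[str] = []
    if fmt in (MsaFormat.FASTA, MsaFormat.A2M, MsaFormat.A3M):
        for rec in msa.records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            lines.append(header)
            if fmt is MsaFormat.A3M:
                lines.append(rec.seq)  # rows may differ in raw length
            else:
                lines.extend(_wrap(rec.seq, width))
    elif fmt is MsaFormat.STO:
        lines.append("# STOCKHOLM 1.0")
        pad = max(len(r.id) for r in msa.records)
        pad = max(pad, max((len(a.split(None, 1)[0]) for a in msa.annotations), default=0))
        for rec in msa.records:
            lines.append(f"{rec.id.ljust(pad)} {rec.seq}")
        lines.extend(msa.annotations)
        lines.append("//")
    elif fmt is MsaFormat.CLUSTAL:
        lines.append("CLUSTAL multiple sequence alignment")
        lines.append("")
        pad = max(len(r.id) for r in msa.records) + 3
        length = msa.n_cols
        for start in range(0, length, width):
            for rec in msa.records:
                lines.append(f"{rec.id.ljust(pad)}{rec.seq[start : start + width]}")
            lines.append("")
    elif fmt is MsaFormat.PFAM:
        pad = max(len(r.id) for r in msa.records)
        for rec in msa.records:
            lines.append(f"{rec.id.ljust(pad)} {rec.seq}")
    elif fmt is MsaFormat.ALN:
        logger.warning("writing aln drops record ids and descriptions")
        lines.extend(rec.seq for rec in msa.records)

    payload = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(payload)
    else:
        with open(sink, "w", encoding="utf-8") as handle:
            handle.write(payload)


def convert(
    in_path: Source,
    in_format,
    out_path: Source,
    out_format,
    insertion_mode: str = "remove",
    width: int = 60,
) -> Msa:
    """Read ``in_path``, optionally resolve A2M/A3M insertions, write ``out_path``.

    Output is byte-deterministic for a fixed input and options.  Returns the
    Msa that was written (handy for chaining and tests).
    """
    in_fmt = MsaFormat.coerce(in_format) if in_format else detect_format(in_path)
    out_fmt = MsaFormat.coerce(out_format)
    msa = read_msa(in_path, in_fmt)
    if in_fmt in (MsaFormat.A2M, MsaFormat.A3M) and out_fmt in COLUMN_ALIGNED_FORMATS:
        msa = resolve_insertions(msa, insertion_mode)
    write_msa(msa, out_fmt, out_path, width=width)
    return msa


def merge_msas(msas: Sequence[Msa], require_same_query: bool = True) -> Msa:
    """Concatenate alignments in order and drop duplicate sequences.

    A record is a duplicate iff its gap-normalized, uppercased sequence
    string equals that of an earlier record (ids are ignored); the first
    occurrence wins.  All inputs must be column-aligned with one common
    length; by default each must carry the same query sequence (first MSA's
    query becomes the merged query).
    """
    if not msas:
        raise MergeError("nothing to merge")
    for k, msa in enumerate(msas):
        if not msa.is_aligned():
            raise MergeError(f"input #{k + 1} is not column-aligned; resolve insertions first")
    length = msas[0].n_cols
    for k, msa in enumerate(msas[1:], start=2):
        if msa.n_cols != length:
            raise MergeError(
                f"alignment lengths differ: input #1 has {length} columns, "
                f"input #{k} has {msa.n_cols}"
            )
    ref_query = msas[0].query.normalized_seq()
    if require_same_query:
        for k, msa in enumerate(msas[1:], start=2):
            if msa.query.normalized_seq() != ref_query:
                raise MergeError(
                    f"query sequences differ between input #1 and input #{k}; "
                    "pass require_same_query=False to merge anyway"
                )

    seen: dict[str, int] = {}
    merged: list[MsaRecord] = []
    query_pos = 0
    n_duplicates = 0
    for k, msa in enumerate(msas):
        for i, rec in enumerate(msa.records):
            key = rec.normalized_seq()
            if key in seen:
                n_duplicates += 1
                if k == 0 and i == msa.query_index:
                    query_pos = seen[key]
                continue
            seen[key] = len(merged)
            if k == 0 and i == msa.query_index:
                query_pos = len(merged)
            merged.append(MsaRecord(rec.id, rec.seq, rec.description))
    if n_duplicates:
        logger.info("merge removed %d duplicate sequence(s)", n_duplicates)

    annotations: list[str] = []
    for msa in msas:
        annotations.extend(msa.annotations)
    return Msa(
        records=merged,
        source_format=msas[0].source_format,
        annotations=annotations,
        query_index=query_pos,
    )
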