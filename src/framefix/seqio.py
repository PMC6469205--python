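"""Readers and writers for the formats the toolkit exchanges.

Supported formats
-----------------
* FASTA (nucleotide or protein; multi-record, wrapped or unwrapped)
* the tool-native pairwise alignment TSV carrying a frame-shift transcript
* PAF (minimap2-style, 12 mandatory columns, extra tags kept verbatim)
* a 4-column taxonomy table (taxon_id, parent_id, rank, name)

All coordinates are 0-based half-open on the forward strand; minus-strand
alignments keep forward-strand query coordinates plus a strand flag.
Any reader transparently accepts gzip-compressed input (``.gz`` suffix).

Alignment transcripts use a six-letter alphabet::

    =  codon match        (3 query bases, 1 subject residue)
    X  codon mismatch     (3 query bases, 1 subject residue)
    /  frame decrease     (2 query bases, 1 subject residue, one event)
    \\  frame increase     (4 query bases, 1 subject residue, one event)
    D  gap in subject     (3 query bases, 0 residues)
    I  gap in query       (0 query bases, 1 residue)

so a transcript fully determines how many bases and residues an alignment
consumes; every row is audited against its coordinates on read and write.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: query bases / subject residues consumed per transcript symbol
QUERY_CONSUMPTION = {"=": 3, "X": 3, "/": 2, "\\": 4, "D": 3, "I": 0}
SUBJECT_CONSUMPTION = {"=": 1, "X": 1, "/": 1, "\\": 1, "D": 0, "I": 1}
FRAMESHIFT_SYMBOLS = frozenset("/\\")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True)
class NucleotideRecord:
    """A DNA sequence over {A, C, G, T, N}, upper-cased."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 amino acids plus X and ``*``."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRow:
    """One local DNA-vs-protein alignment with a frame-shift transcript.

    ``qstart``/``qend`` are forward-strand query coordinates regardless of
    ``strand``; ``sstart``/``send`` count protein residues.
    """

    qid: str
    sid: str
    qstart: int
    qend: int
    strand: str
    sstart: int
    send: int
    raw_score: int
    bit_score: float
    pident: float
    transcript: str

    def n_frameshifts(self) -> int:
        return sum(self.transcript.count(c) for c in FRAMESHIFT_SYMBOLS)

    def validate(self) -> None:
        if not self.qid or not self.sid:
            raise ValidationError("empty qid or sid")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.qend <= self.qstart:
            raise ValidationError(
                f"{self.qid} vs {self.sid}: qend ({self.qend}) must exceed qstart ({self.qstart})"
            )
        if self.send <= self.sstart:
            raise ValidationError(
                f"{self.qid} vs {self.sid}: send ({self.send}) must exceed sstart ({self.sstart})"
            )
        if not 0.0 <= self.pident <= 100.0:
            raise ValidationError(f"pident {self.pident} outside [0, 100]")
        bad = set(self.transcript) - set(QUERY_CONSUMPTION)
        if bad:
            raise ValidationError(f"unknown transcript symbols {sorted(bad)}")
        qlen = sum(QUERY_CONSUMPTION[c] for c in self.transcript)
        slen = sum(SUBJECT_CONSUMPTION[c] for c in self.transcript)
        if qlen != self.qend - self.qstart:
            raise ValidationError(
                f"{self.qid} vs {self.sid}: transcript consumes {qlen} query bases "
                f"but coordinates span {self.qend - self.qstart}"
            )
        if slen != self.send - self.sstart:
            raise ValidationError(
                f"{self.qid} vs {self.sid}: transcript consumes {slen} residues "
                f"but coordinates span {self.send - self.sstart}"
            )


@dataclass
class PafRow:
    """One minimap2-style PAF line (12 mandatory columns plus opaque tags)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_matches: int
    block_len: int
    mapq: int
    tags: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for label, lo, hi, length in (
            ("query", self.qstart, self.qend, self.qlen),
            ("target", self.tstart, self.tend, self.tlen),
        ):
            if not (0 <= lo < hi <= length):
                raise ValidationError(
                    f"{self.qname}: {label} interval [{lo}, {hi}) invalid for length {length}"
                )
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")


def _open_text(path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, kind: Literal["nucleotide", "protein"]) -> list[NucleotideRecord | ProteinRecord]:
    """Parse a FASTA file, normalising case and checking the alphabet.

    Nucleotide sequences are upper-cased and U is mapped to T; IUPAC
    ambiguity codes other than N are rejected rather than silently mapped.
    Errors name the offending line number.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"unknown kind {kind!r}")
    alphabet = NUCLEOTIDE_ALPHABET if kind == "nucleotide" else PROTEIN_ALPHABET
    cls = NucleotideRecord if kind == "nucleotide" else ProteinRecord

    records: list = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        records.append(cls(header, "".join(chunks)))

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                if header in seen:
                    raise ParseError(f"line {lineno}: duplicate record id {header!r}")
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence data before any header")
                seq = line.upper()
                if kind == "nucleotide":
                    seq = seq.replace("U", "T")
                bad = set(seq) - alphabet
                if bad:
                    raise ParseError(
                        f"line {lineno}: illegal {kind} character(s) {sorted(bad)}"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(records: Iterable[NucleotideRecord | ProteinRecord], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
            if not rec.seq:
                fh.write("\n")


# ---------------------------------------------------------------------------
# alignment TSV

_ALN_COLUMNS = (
    "qid sid qstart qend strand sstart send raw_score bit_score pident transcript".split()
)


def write_alignment_tsv(rows: Iterable[AlignmentRow], path) -> None:
    """Write rows to the tool-native TSV; every row is validated first."""
    with _open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(_ALN_COLUMNS) + "\n")
        for i, row in enumerate(rows):
            try:
                row.validate()
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            fh.write(
                "\t".join(
                    [
                        row.qid,
                        row.sid,
                        str(row.qstart),
                        str(row.qend),
                        row.strand,
                        str(row.sstart),
                        str(row.send),
                        str(row.raw_score),
                        f"{row.bit_score:.6g}",
                        f"{row.pident:.6g}",
                        row.transcript,
                    ]
                )
                + "\n"
            )


def read_alignment_tsv(path) -> list[AlignmentRow]:
    rows: list[AlignmentRow] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_ALN_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(_ALN_COLUMNS)} columns, got {len(parts)}"
                )
            try:
                row = AlignmentRow(
                    qid=parts[0],
                    sid=parts[1],
                    qstart=int(parts[2]),
                    qend=int(parts[3]),
                    strand=parts[4],
                    sstart=int(parts[5]),
                    send=int(parts[6]),
                    raw_score=int(parts[7]),
                    bit_score=float(parts[8]),
                    pident=float(parts[9]),
                    transcript=parts[10],
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            try:
                row.validate()
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# PAF


def read_paf(path) -> list[PafRow]:
    """Parse a PAF file; columns beyond the 12th are kept as opaque strings."""
    rows: list[PafRow] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"line {lineno}: PAF needs >= 12 columns, got {len(parts)}")
            try:
                row = PafRow(
                    qname=parts[0],
                    qlen=int(parts[1]),
                    qstart=int(parts[2]),
                    qend=int(parts[3]),
                    strand=parts[4],
                    tname=parts[5],
                    tlen=int(parts[6]),
                    tstart=int(parts[7]),
                    tend=int(parts[8]),
                    n_matches=int(parts[9]),
                    block_len=int(parts[10]),
                    mapq=int(parts[11]),
                    tags=parts[12:],
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            try:
                row.validate()
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            rows.append(row)
    return rows


def write_paf(rows: Iterable[PafRow], path) -> None:
    with _open_text(path, "wt") as fh:
        for row in rows:
            fields = [
                row.qname, str(row.qlen), str(row.qstart), str(row.qend), row.strand,
                row.tname, str(row.tlen), str(row.tstart), str(row.tend),
                str(row.n_matches), str(row.block_len), str(row.mapq), *row.tags,
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# taxonomy table


def read_taxonomy_tsv(path) -> list[tuple[str, str, str, str]]:
    """Read a 4-column taxonomy table: taxon_id, parent_id, rank, name.

    The root is the row whose parent_id equals its own id (or is empty).
    Tree invariants (single root, no cycles) are checked by
    :class:`framefix.taxbin.Taxonomy`, not here.
    """
    rows: list[tuple[str, str, str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], parts[2], parts[3]))
    return rows


def write_taxonomy_tsv(rows: Iterable[Sequence[str]], path) -> None:
    with _open_text(path, "wt") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")
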