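"""Parser for the COSMIC dialect of HGVS-style variant descriptions.

COSMIC exports describe each mutation twice: at the protein level
("p.N511Ifs*13", "p.Q689*", "p.L34=") and at the coding-DNA level
("c.1532del", "c.2165A>G").  Real exports are dirty — prefixes vary in
case, stop gains appear as "*" or legacy "X", frameshifts appear with and
without the "fs*N" stop offset, and unparseable strings must survive as
``unknown`` rather than being dropped.  This module is a pure parsing
layer with no file I/O.

Not covered (deliberately): alleles in trans, mosaic syntax, protein
extension ("ext") variants, and validation of nucleotide changes against
a transcript sequence.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "ProteinKind",
    "CdnaKind",
    "ProteinChange",
    "CdnaChange",
    "MalformedInputError",
    "parse_protein_change",
    "parse_cdna_change",
    "format_protein_change",
    "format_cdna_change",
    "predicted_stop_residue",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"


class MalformedInputError(ValueError):
    """Raised for inputs the parser cannot accept at all (e.g. empty)."""


class ProteinKind(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    UNKNOWN = "unknown"


class CdnaKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"
    INTRONIC_OR_UTR = "intronic_or_utr"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ProteinChange:
    """A typed amino-acid-level change.

    ``position`` is the 1-based index of the first affected residue.
    ``alt_residue`` is "*" for stop gains, "=" for synonymous changes, a
    one-letter amino acid for missense (and optionally the first residue
    of the shifted frame for frameshifts), or empty.  ``fs_stop_offset``
    is the N of "fs*N": translation continues N codons in the new frame
    before terminating, counting the substituted residue as codon 1.

    ``raw`` preserves the input spelling and is excluded from equality so
    that semantically identical records (e.g. "N511fs*13" vs
    "p.N511Ifs*13" after formatting) compare by content.
    """

    raw: str = field(compare=False)
    kind: ProteinKind
    position: int | None = None
    ref_residue: str = ""
    alt_residue: str = ""
    fs_stop_offset: int | None = None

    def __post_init__(self) -> None:
        if self.position is not None and self.position < 1:
            raise ValueError(f"residue position must be >= 1, got {self.position}")
        if (self.fs_stop_offset is not None) and self.kind is not ProteinKind.FRAMESHIFT:
            raise ValueError("fs_stop_offset is only meaningful for frameshifts")
        if self.kind is ProteinKind.NONSENSE and self.alt_residue != "*":
            raise ValueError("nonsense changes must carry alt_residue '*'")
        if self.kind is ProteinKind.SYNONYMOUS and self.alt_residue != "=":
            raise ValueError("synonymous changes must carry alt_residue '='")


@dataclass(frozen=True)
class CdnaChange:
    """A typed coding-DNA-level change.

    ``start``/``end`` are 1-based coding-nucleotide indices (``end ==
    start`` for single-base events).  Intronic positions ("123+5",
    "124-2") carry the signed ``intron_offset``; UTR positions ("*45",
    "-12") are classed ``intronic_or_utr`` without an offset.
    """

    raw: str = field(compare=False)
    kind: CdnaKind
    start: int | None = None
    end: int | None = None
    ref_base: str = ""
    alt_base: str = ""
    intron_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.intron_offset is not None and self.kind is not CdnaKind.INTRONIC_OR_UTR:
            raise ValueError("intron_offset implies an intronic/UTR change")


# --- protein-level grammar -------------------------------------------------

_P_PREFIX = re.compile(r"^p\.", re.IGNORECASE)
# "N511Ifs*13", "N511fs", "N511LFS*13" — the shifted-frame residue is optional
_P_FRAMESHIFT = re.compile(
    r"^([A-Z])(\d+)([A-Z]?)fs(?:\*(\d+))?$", re.IGNORECASE
)
_P_SYNONYMOUS = re.compile(r"^([A-Z])(\d+)=$")
# stop gain: "*" or legacy COSMIC "X"
_P_NONSENSE = re.compile(r"^([A-Z])(\d+)(\*|X)$")
_P_MISSENSE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_P_DEL = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?del$", re.IGNORECASE)
_P_DUP = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?dup$", re.IGNORECASE)
_P_INS = re.compile(r"^([A-Z])(\d+)_([A-Z])(\d+)ins([A-Z]+)$")


def parse_protein_change(s: str) -> ProteinChange:
    """Parse a COSMIC-style amino-acid change string.

    The leading "p." prefix is optional and case-insensitive.  Strings the
    grammar does not recognise (including "?" / "p.?") come back with
    ``kind=unknown`` and the raw text preserved — never a silent drop.
    An empty string raises :class:`MalformedInputError`.
    """
    if s is None or not str(s).strip():
        raise MalformedInputError("empty amino-acid change string")
    raw = str(s).strip()
    body = _P_PREFIX.sub("", raw)

    m = _P_FRAMESHIFT.match(body)
    if m:
        ref, pos, alt, off = m.groups()
        return ProteinChange(
            raw=raw,
            kind=ProteinKind.FRAMESHIFT,
            position=int(pos),
            ref_residue=ref.upper(),
            alt_residue=alt.upper(),
            fs_stop_offset=int(off) if off else None,
        )
    m = _P_SYNONYMOUS.match(body)
    if m:
        return ProteinChange(
            raw=raw, kind=ProteinKind.SYNONYMOUS, position=int(m.group(2)),
            ref_residue=m.group(1), alt_residue="=",
        )
    m = _P_NONSENSE.match(body)
    if m:
        return ProteinChange(
            raw=raw, kind=ProteinKind.NONSENSE, position=int(m.group(2)),
            ref_residue=m.group(1), alt_residue="*",
        )
    m = _P_MISSENSE.match(body)
    if m:
        ref, pos, alt = m.groups()
        if ref == alt:  # identity substitution is synonymous
            return ProteinChange(
                raw=raw, kind=ProteinKind.SYNONYMOUS, position=int(pos),
                ref_residue=ref, alt_residue="=",
            )
        return ProteinChange(
            raw=raw, kind=ProteinKind.MISSENSE, position=int(pos),
            ref_residue=ref, alt_residue=alt,
        )
    m = _P_DEL.match(body)
    if m:
        return ProteinChange(
            raw=raw, kind=ProteinKind.INFRAME_DELETION, position=int(m.group(2)),
            ref_residue=m.group(1).upper(),
        )
    m = _P_DUP.match(body)
    if m:
        return ProteinChange(
            raw=raw, kind=ProteinKind.INFRAME_INSERTION, position=int(m.group(2)),
            ref_residue=m.group(1).upper(),
        )
    m = _P_INS.match(body)
    if m:
        return ProteinChange(
            raw=raw, kind=ProteinKind.INFRAME_INSERTION, position=int(m.group(2)),
            ref_residue=m.group(1),
        )
    return ProteinChange(raw=raw, kind=ProteinKind.UNKNOWN)


def format_protein_change(p: ProteinChange) -> str:
    """Render the canonical "p."-prefixed spelling of a parsed change.

    Round-trip contract: ``parse_protein_change(format_protein_change(p))``
    equals ``p`` on every field except ``raw``.
    """
    if p.kind is ProteinKind.UNKNOWN or p.position is None:
        return "p.?"
    stem = f"p.{p.ref_residue}{p.position}"
    if p.kind is ProteinKind.MISSENSE:
        return f"{stem}{p.alt_residue}"
    if p.kind is ProteinKind.NONSENSE:
        return f"{stem}*"
    if p.kind is ProteinKind.SYNONYMOUS:
        return f"{stem}="
    if p.kind is ProteinKind.FRAMESHIFT:
        out = f"{stem}{p.alt_residue}fs"
        if p.fs_stop_offset is not None:
            out += f"*{p.fs_stop_offset}"
        return out
    if p.kind is ProteinKind.INFRAME_DELETION:
        return f"{stem}del"
    return f"{stem}dup"  # inframe insertion / duplication


def predicted_stop_residue(p: ProteinChange) -> int:
    """Residue index of the premature stop created by a frameshift.

    HGVS counts the substituted residue as codon 1 of the shifted frame,
    so "N511Ifs*13" terminates at residue 511 + 13 - 1 = 523.
    """
    if p.kind is not ProteinKind.FRAMESHIFT:
        raise ValueError(f"not a frameshift: {p.raw!r}")
    if p.fs_stop_offset is None:
        raise ValueError(f"frameshift without a stop offset: {p.raw!r}")
    assert p.position is not None
    return p.position + p.fs_stop_offset - 1


# --- cDNA-level grammar ----------------------------------------------------

_C_PREFIX = re.compile(r"^c\.", re.IGNORECASE)
# intron offset: "123+5G>A", "124-2del" (ASCII or unicode minus)
_C_INTRON = re.compile(r"^(\d+)([+−-]\d+)")
# UTR positions: "*45A>G" (3'UTR), "-12C>T" (5'UTR)
_C_UTR = re.compile(r"^([*−-])(\d+)")
_C_SUB = re.compile(r"^(\d+)([ACGTN])>([ACGTN])$", re.IGNORECASE)
_C_SPAN = {
    CdnaKind.DELETION: re.compile(r"^(\d+)(?:_(\d+))?del([ACGTN]*)$", re.IGNORECASE),
    CdnaKind.DUPLICATION: re.compile(r"^(\d+)(?:_(\d+))?dup([ACGTN]*)$", re.IGNORECASE),
    CdnaKind.DELINS: re.compile(r"^(\d+)(?:_(\d+))?delins([ACGTN]+)$", re.IGNORECASE),
    CdnaKind.INSERTION: re.compile(r"^(\d+)_(\d+)ins([ACGTN]+)$", re.IGNORECASE),
}


def parse_cdna_change(s: str) -> CdnaChange:
    """Parse a COSMIC-style coding-DNA change string ("c." optional).

    Intronic and UTR positions are typed ``intronic_or_utr`` so the
    ingest layer can exclude them from ORF analyses.  Empty input raises
    :class:`MalformedInputError`; unrecognised syntax yields ``unknown``.
    """
    if s is None or not str(s).strip():
        raise MalformedInputError("empty cDNA change string")
    raw = str(s).strip()
    body = _C_PREFIX.sub("", raw)

    m = _C_INTRON.match(body)
    if m:
        off = int(m.group(2).replace("−", "-"))
        return CdnaChange(
            raw=raw, kind=CdnaKind.INTRONIC_OR_UTR,
            start=int(m.group(1)), end=int(m.group(1)), intron_offset=off,
        )
    m = _C_UTR.match(body)
    if m:
        return CdnaChange(
            raw=raw, kind=CdnaKind.INTRONIC_OR_UTR,
            start=int(m.group(2)), end=int(m.group(2)),
        )
    m = _C_SUB.match(body)
    if m:
        pos = int(m.group(1))
        return CdnaChange(
            raw=raw, kind=CdnaKind.SUBSTITUTION, start=pos, end=pos,
            ref_base=m.group(2).upper(), alt_base=m.group(3).upper(),
        )
    # order matters: delins before del
    for kind in (CdnaKind.DELINS, CdnaKind.DELETION, CdnaKind.DUPLICATION,
                 CdnaKind.INSERTION):
        m = _C_SPAN[kind].match(body)
        if not m:
            continue
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        bases = (m.group(3) or "").upper()
        if kind is CdnaKind.DELETION:
            return CdnaChange(raw=raw, kind=kind, start=start, end=end, ref_base=bases)
        if kind in (CdnaKind.DELINS, CdnaKind.INSERTION):
            return CdnaChange(raw=raw, kind=kind, start=start, end=end, alt_base=bases)
        return CdnaChange(raw=raw, kind=kind, start=start, end=end)
    return CdnaChange(raw=raw, kind=CdnaKind.UNKNOWN)


def format_cdna_change(c: CdnaChange) -> str:
    """Canonical "c."-prefixed spelling; inverse of :func:`parse_cdna_change`
    up to the ``raw`` field."""
    if c.kind is CdnaKind.UNKNOWN or c.start is None:
        return "c.?"
    if c.kind is CdnaKind.INTRONIC_OR_UTR:
        if c.intron_offset is not None:
            return f"c.{c.start}{c.intron_offset:+d}"
        return f"c.*{c.start}"
    span = f"{c.start}" if c.end in (None, c.start) else f"{c.start}_{c.end}"
    if c.kind is CdnaKind.SUBSTITUTION:
        return f"c.{span}{c.ref_base}>{c.alt_base}"
    if c.kind is CdnaKind.DELETION:
        return f"c.{span}del{c.ref_base}"
    if c.kind is CdnaKind.DUPLICATION:
        return f"c.{span}dup"
    if c.kind is CdnaKind.INSERTION:
        return f"c.{span}ins{c.alt_base}"
    return f"c.{span}delins{c.alt_base}"
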