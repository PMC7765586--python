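"""Consensus-threshold conservation classification from a protein MSA.

A residue of the designated human reference sequence is called conserved
("identity" class) when, in its alignment column, the modal non-gap
residue (i) reaches a consensus fraction theta of all aligned sequences
and (ii) equals the reference residue itself.  With the default
theta = 0.98 and alignments of <= 27 sequences this forces unanimity
(0.98 x 27 = 26.46, so 26/27 does not qualify), which is the intended
stringency: the threshold tolerates only rare deviations in deep
alignments while demanding identity in small ones.

Gaps count in the denominator — a heavily gapped column cannot reach
consensus — and ``X``/ambiguous residues mismatch everything.  Both
choices are switchable where noted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "ConservationProfile",
    "read_alignment",
    "column_to_ref_map",
    "consensus_profile",
    "count_conserved",
    "REFERENCE_LENGTHS",
]

GAP_CHARS = frozenset("-.")
AMBIGUOUS = frozenset("XBZJUO*")

# ungapped human reference lengths the published residue totals rest on;
# the profile builder warns when a supplied alignment disagrees
REFERENCE_LENGTHS = {"MRE11": 708, "RAD50": 1312, "NBN": 754}


@dataclass(frozen=True)
class Alignment:
    """A protein multiple sequence alignment (equal-length gapped rows)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        if self.rows:
            ncol = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise ValueError(f"ragged alignment row: {sid!r}")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id not in alignment: {seq_id!r}") from None


@dataclass(frozen=True)
class ConservationProfile:
    """Per-reference-residue conservation flags.

    ``conserved[i]`` refers to reference residue ``i+1``.  ``modal_residue``
    and ``modal_fraction`` describe each residue's alignment column (the
    fraction is over all sequences, gaps included).
    """

    gene: str
    ref_id: str
    conserved: tuple[bool, ...]
    ref_sequence: str = ""
    modal_residue: tuple[str, ...] = ()
    modal_fraction: tuple[float, ...] = ()
    theta: float = 0.98

    def __post_init__(self) -> None:
        if self.ref_sequence and len(self.ref_sequence) != len(self.conserved):
            raise ValueError("flag vector length != ungapped reference length")

    @property
    def n_residues(self) -> int:
        return len(self.conserved)

    def is_conserved(self, position: int) -> bool:
        """1-based residue lookup."""
        if not 1 <= position <= self.n_residues:
            raise IndexError(f"residue {position} outside 1..{self.n_residues}")
        return self.conserved[position - 1]


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal protein alignment.

    Ragged FASTA input (sequences of unequal length) raises a format
    error naming the offending record.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        # biopython rejects ragged fasta before we can; recover ids for the report
        if format == "fasta":
            from Bio import SeqIO
            seqs = list(SeqIO.parse(str(path), "fasta"))
            if seqs:
                lengths = {len(s.seq) for s in seqs}
                if len(lengths) > 1:
                    ref_len = len(seqs[0].seq)
                    bad = [s.id for s in seqs if len(s.seq) != ref_len]
                    raise ValueError(
                        f"ragged alignment row(s): {bad}") from exc
        raise
    return Alignment(ids=tuple(rec.id for rec in msa),
                     rows=tuple(str(rec.seq).upper() for rec in msa))


def column_to_ref_map(a: Alignment, ref_id: str
                      ) -> tuple[dict[int, int], dict[int, int]]:
    """Bidirectional map between 0-based alignment columns and 1-based
    reference residue positions, defined only at non-gap reference
    columns.  COSMIC positions are human coordinates; this is how they
    land on alignment columns."""
    ref_row = a.row(ref_id)
    col_to_res: dict[int, int] = {}
    res_to_col: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(ref_row):
        if ch in GAP_CHARS:
            continue
        residue += 1
        col_to_res[col] = residue
        res_to_col[residue] = col
    if residue == 0:
        logger.warning("reference row %r is all gaps; empty coordinate map",
                       ref_id)
    return col_to_res, res_to_col


def consensus_profile(a: Alignment, ref_id: str, theta: float = 0.98,
                      gene: str = "", count_gaps_in_denominator: bool = True,
                      ) -> ConservationProfile:
    """Classify each reference residue as conserved or not.

    A residue is conserved iff the modal non-gap, non-ambiguous residue of
    its column reaches ``theta`` of the sequence count *and* equals the
    reference residue.  Ties for the mode resolve to not-conserved unless
    the reference residue itself attains the threshold.
    """
    if not 0 < theta <= 1:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    ref_row = a.row(ref_id)  # raises KeyError for unknown ids
    col_to_res, _ = column_to_ref_map(a, ref_id)

    flags: list[bool] = []
    modal_res: list[str] = []
    modal_frac: list[float] = []
    ref_seq: list[str] = []
    for col, _residue in sorted(col_to_res.items(), key=lambda kv: kv[1]):
        column = [row[col] for row in a.rows]
        counts: dict[str, int] = {}
        for ch in column:
            if ch in GAP_CHARS or ch in AMBIGUOUS:
                continue
            counts[ch] = counts.get(ch, 0) + 1
        denom = a.n_seqs if count_gaps_in_denominator else max(
            sum(counts.values()), 1)
        ref_ch = ref_row[col]
        ref_count = counts.get(ref_ch, 0)
        # mode == reference and threshold met; a tied mode only qualifies
        # through the reference residue itself
        max_count = max(counts.values(), default=0)
        conserved = (ref_count == max_count
                     and ref_count >= theta * denom - 1e-9
                     and ref_count > 0)
        flags.append(conserved)
        if counts:
            top = max(counts, key=lambda k: (counts[k], k == ref_ch))
            modal_res.append(top)
            modal_frac.append(counts[top] / denom)
        else:
            modal_res.append("")
            modal_frac.append(0.0)
        ref_seq.append(ref_ch)

    gene = gene or ref_id
    expected = REFERENCE_LENGTHS.get(gene.upper())
    if expected is not None and expected != len(flags):
        logger.warning(
            "%s: ungapped reference length %d differs from the configured "
            "%d; published residue totals will not reproduce",
            gene, len(flags), expected)
    return ConservationProfile(
        gene=gene, ref_id=ref_id, conserved=tuple(flags),
        ref_sequence="".join(ref_seq), modal_residue=tuple(modal_res),
        modal_fraction=tuple(modal_frac), theta=theta)


def count_conserved(profile: ConservationProfile
                    ) -> tuple[int, int, float]:
    """(n_conserved, n_non_conserved, percent conserved to one decimal)."""
    n_cons = sum(profile.conserved)
    n_non = profile.n_residues - n_cons
    total = n_cons + n_non
    percent = round(100.0 * n_cons / total, 1) if total else 0.0
    return n_cons, n_non, percent


def profile_from_flags(gene: str, flags: Sequence[bool],
                       theta: float = 0.98) -> ConservationProfile:
    """Build a profile directly from known flags (simulator ground truth,
    or the published conserved/non-conserved totals)."""
    return ConservationProfile(gene=gene, ref_id=gene,
                               conserved=tuple(bool(f) for f in flags),
                               theta=theta)


def profile_to_frame(profile: ConservationProfile):
    """Per-residue TSV-ready table: index, reference residue, flag, modal
    residue, modal fraction."""
    import pandas as pd

    n = profile.n_residues
    return pd.DataFrame({
        "residue": np.arange(1, n + 1),
        "ref_residue": list(profile.ref_sequence) if profile.ref_sequence
        else [""] * n,
        "conserved": list(profile.conserved),
        "modal_residue": list(profile.modal_residue) or [""] * n,
        "modal_fraction": list(profile.modal_fraction) or [float("nan")] * n,
    })
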