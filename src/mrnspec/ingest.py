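"""Reading, normalising and filtering COSMIC-style mutation export tables.

COSMIC exports one row per reported mutation observation: sample ID, gene,
cDNA change, amino-acid change, primary site, zygosity, sample source and
PubMed ID.  The same biological observation is frequently deposited by
more than one study, so ingest deduplicates on a (gene, sample, change)
key before any counting.  Intronic and UTR changes are excluded from ORF
analyses; synonymous changes are retained, since they can affect mRNA
stability.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hgvs import (
    CdnaChange,
    CdnaKind,
    ProteinChange,
    ProteinKind,
    format_cdna_change,
    format_protein_change,
    parse_cdna_change,
    parse_protein_change,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "TableSchema",
    "SchemaError",
    "DEFAULT_SCHEMA",
    "COSMIC_SCHEMA",
    "read_mutation_table",
    "records_from_frame",
    "deduplicate",
    "filter_orf",
    "write_records",
    "read_schema_config",
]

ORIGIN_VALUES = ("primary_tumour", "cell_line", "unknown")
ZYGOSITY_VALUES = ("heterozygous", "homozygous", "unknown")

# substring markers used to normalise COSMIC "Sample source" free text
_CELL_LINE_MARKERS = ("cell-line", "cell line", "cellline", "cultured")
_PRIMARY_MARKERS = ("fresh", "surgery", "frozen", "tumour", "tumor", "biopsy",
                    "primary")


class SchemaError(ValueError):
    """Input table header does not satisfy the column mapping."""


@dataclass(frozen=True)
class MutationRecord:
    """One deduplicated somatic mutation observation."""

    gene: str
    sample_id: str
    protein_change: ProteinChange
    cdna_change: CdnaChange | None = None
    tissue: str = "unknown"
    origin: str = "unknown"
    zygosity: str = "unknown"
    pubmed_id: str | None = None

    def __post_init__(self) -> None:
        if not self.gene or not self.sample_id:
            raise ValueError("gene and sample_id must be non-empty")
        if self.origin not in ORIGIN_VALUES:
            raise ValueError(f"bad origin {self.origin!r}")
        if self.zygosity not in ZYGOSITY_VALUES:
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def dedup_key(self) -> tuple[str, str, str]:
        """Distinct cDNA events at one codon are distinct alleles, so the
        cDNA spelling is the preferred third key component."""
        if self.cdna_change is not None:
            return (self.gene, self.sample_id, self.cdna_change.raw)
        return (self.gene, self.sample_id, self.protein_change.raw)


@dataclass(frozen=True)
class TableSchema:
    """Mapping from canonical field names to input-file header names.

    ``gene``, ``sample_id`` and at least one of ``protein_change`` /
    ``cdna_change`` are required; the remaining fields are optional and
    default to absent.
    """

    columns: Mapping[str, str] = field(default_factory=dict)

    REQUIRED = ("gene", "sample_id")
    KNOWN = ("gene", "sample_id", "protein_change", "cdna_change", "tissue",
             "zygosity", "sample_source", "pubmed_id")

    def __post_init__(self) -> None:
        for name in self.REQUIRED:
            if name not in self.columns:
                raise SchemaError(f"schema missing required mapping: {name}")
        if not ({"protein_change", "cdna_change"} & set(self.columns)):
            raise SchemaError(
                "schema must map at least one of protein_change/cdna_change")
        unknown = set(self.columns) - set(self.KNOWN)
        if unknown:
            raise SchemaError(f"unrecognised schema fields: {sorted(unknown)}")

    def get(self, name: str) -> str | None:
        return self.columns.get(name)


DEFAULT_SCHEMA = TableSchema({
    "gene": "gene",
    "sample_id": "sample_id",
    "protein_change": "aa_change",
    "cdna_change": "cdna_change",
    "tissue": "primary_site",
    "zygosity": "zygosity",
    "sample_source": "sample_source",
    "pubmed_id": "pubmed_id",
})

# header names of a COSMIC "complete mutation data" export saved as TSV
COSMIC_SCHEMA = TableSchema({
    "gene": "Gene name",
    "sample_id": "Sample name",
    "protein_change": "AA Mutation",
    "cdna_change": "CDS Mutation",
    "tissue": "Primary site",
    "zygosity": "Zygosity",
    "sample_source": "Sample source",
    "pubmed_id": "Pubmed_PMID",
})


def read_schema_config(path: str | Path) -> TableSchema:
    """Read a plain-text ``field: column`` mapping into a TableSchema."""
    columns: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        columns[key.strip()] = value.strip()
    return TableSchema(columns)


def _normalise_origin(source: str) -> str:
    s = source.strip().lower()
    if not s or s in ("ns", "na", "unknown"):
        return "unknown"
    if any(m in s for m in _CELL_LINE_MARKERS):
        return "cell_line"
    if any(m in s for m in _PRIMARY_MARKERS):
        return "primary_tumour"
    return "unknown"


def _normalise_zygosity(z: str) -> str:
    s = z.strip().lower()
    if s.startswith("het"):
        return "heterozygous"
    if s.startswith("hom"):
        return "homozygous"
    return "unknown"


def _cell(row: pd.Series, col: str | None) -> str:
    if col is None:
        return ""
    v = row[col]
    return "" if pd.isna(v) else str(v).strip()


def records_from_frame(df: pd.DataFrame,
                       schema: TableSchema = DEFAULT_SCHEMA,
                       ) -> list[MutationRecord]:
    """Build records from an in-memory table (shared by file and simulator
    paths).  Rows with unparseable change strings are retained with
    ``kind=unknown``; a parse-outcome tally is logged."""
    required = [schema.columns[f] for f in
                ("gene", "sample_id", "protein_change", "cdna_change")
                if f in schema.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"input table missing column(s): {missing}")
    # optional fields whose mapped column is absent simply default
    schema = TableSchema({f: c for f, c in schema.columns.items()
                          if c in df.columns})

    records: list[MutationRecord] = []
    outcomes: Counter[str] = Counter()
    for _, row in df.iterrows():
        aa_raw = _cell(row, schema.get("protein_change"))
        cdna_raw = _cell(row, schema.get("cdna_change"))
        protein = (parse_protein_change(aa_raw) if aa_raw
                   else ProteinChange(raw="", kind=ProteinKind.UNKNOWN))
        cdna = parse_cdna_change(cdna_raw) if cdna_raw else None
        outcomes[protein.kind.value] += 1
        tissue = _cell(row, schema.get("tissue")) or "unknown"
        records.append(MutationRecord(
            gene=_cell(row, schema.get("gene")),
            sample_id=_cell(row, schema.get("sample_id")),
            protein_change=protein,
            cdna_change=cdna,
            tissue=tissue,
            origin=_normalise_origin(_cell(row, schema.get("sample_source"))),
            zygosity=_normalise_zygosity(_cell(row, schema.get("zygosity"))),
            pubmed_id=_cell(row, schema.get("pubmed_id")) or None,
        ))
    logger.info("ingested %d rows; parse outcomes: %s",
                len(records), dict(outcomes))
    return records


def read_mutation_table(path: str | Path,
                        schema: TableSchema = DEFAULT_SCHEMA,
                        ) -> list[MutationRecord]:
    """Read a TSV mutation export into typed records.

    Raises :class:`SchemaError` when a mapped column is missing or the
    header contains duplicated names.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = [c for c, n in Counter(header).items() if n > 1]
    if dupes:
        raise SchemaError(f"duplicated header column(s): {dupes}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return records_from_frame(df, schema)


def deduplicate(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep the first record per (gene, sample, change) key.

    Emulates the manual removal of observations deposited independently by
    multiple studies; recurrence across *different* samples is preserved.
    Idempotent, and commutes with :func:`filter_orf`.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[MutationRecord] = []
    for rec in records:
        key = rec.dedup_key
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    if len(out) < len(records):
        logger.info("deduplicate: removed %d of %d rows",
                    len(records) - len(out), len(records))
    return out


def _is_orf(rec: MutationRecord) -> bool:
    cdna_intronic = (rec.cdna_change is not None
                     and rec.cdna_change.kind is CdnaKind.INTRONIC_OR_UTR)
    if cdna_intronic:
        return False
    return True


def filter_orf(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Drop intronic and 5'/3' UTR changes; keep everything in the ORF,
    including synonymous changes."""
    out = [r for r in records if _is_orf(r)]
    if len(out) < len(records):
        logger.info("filter_orf: removed %d intronic/UTR rows",
                    len(records) - len(out))
    return out


RECORD_COLUMNS = ("gene", "sample_id", "aa_change", "aa_kind", "position",
                  "cdna_change", "cdna_kind", "primary_site", "origin",
                  "zygosity", "pubmed_id")


def write_records(records: Iterable[MutationRecord],
                  path: str | Path) -> pd.DataFrame:
    """Write normalised records to a canonical TSV (fixed column order)."""
    rows = []
    for r in records:
        rows.append({
            "gene": r.gene,
            "sample_id": r.sample_id,
            "aa_change": (format_protein_change(r.protein_change)
                          if r.protein_change.kind is not ProteinKind.UNKNOWN
                          else r.protein_change.raw),
            "aa_kind": r.protein_change.kind.value,
            "position": r.protein_change.position,
            "cdna_change": (format_cdna_change(r.cdna_change)
                            if r.cdna_change is not None else ""),
            "cdna_kind": (r.cdna_change.kind.value
                          if r.cdna_change is not None else ""),
            "primary_site": r.tissue,
            "origin": r.origin,
            "zygosity": r.zygosity,
            "pubmed_id": r.pubmed_id or "",
        })
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df
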