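"""Synthetic alignments and COSMIC-like mutation tables with known ground
truth.

Every pipeline stage is testable without downloads: the generator plants
conserved alignment columns, places mutations with a controllable
conserved-vs-non-conserved odds ratio, injects recurrence hotspots and
duplicate reports, and returns the per-row truth alongside the table.

Defaults mirror the study conditions the pipeline targets: 27 aligned
sequences (the MRE11 alignment depth), a 0.98 consensus threshold
regime, ~15% conserved residues, an off-consensus substitution
probability of 0.3 per sequence per non-conserved column, and a few
hundred mutation observations per gene.  The substitution model is
deliberately plain — one uniform replacement process, no rate
heterogeneity or indels — which is sufficient to exercise the consensus
classifier's decision boundary.

In non-conserved columns the per-sequence substitution indicators are
drawn conditioned on at least one substitution occurring, so a planted
non-conserved column can never be unanimous: the returned truth flags
are exact by construction whenever ``theta * n_seqs > n_seqs - 1``
(e.g. theta = 0.98 with 27 sequences).

cDNA strings for simulated rows are position-consistent fabrications
(a frameshift at residue p is written ``c.{3p-2}del``) so the
deduplication key is exercised; they are not validated against any
transcript.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import Alignment, profile_from_flags
from .enrichment import chi_square_gof, expected_counts, observed_counts
from .hgvs import AA1
from .ingest import DEFAULT_SCHEMA, filter_orf, records_from_frame

__all__ = [
    "SimulationConfig",
    "simulate_alignment",
    "simulate_mutation_table",
    "null_calibration",
    "write_fasta",
]

KINDS = ("missense", "nonsense", "frameshift", "synonymous", "intronic")

# primary-site weights loosely following the reported tissue spread
# (large intestine most represented, then liver/lung/breast/prostate/skin)
DEFAULT_TISSUES = {
    "large_intestine": 0.30, "liver": 0.10, "lung": 0.12, "breast": 0.12,
    "prostate": 0.08, "skin": 0.08, "endometrium": 0.08, "stomach": 0.06,
    "unknown": 0.06,
}
# zygosity is mostly unreported in real exports
DEFAULT_ZYGOSITY = {"unknown": 0.80, "heterozygous": 0.18, "homozygous": 0.02}

_SOURCE_TEXT = {"cell_line": "cell-line",
                "primary_tumour": "fresh/surgery - NOS",
                "unknown": "NS"}
_ZYG_TEXT = {"heterozygous": "het", "homozygous": "hom", "unknown": "u"}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one simulated gene; ``seed`` fixes all output bit-for-bit."""

    seed: int = 0
    gene: str = "GENE1"
    n_seqs: int = 27
    ref_length: int = 708
    conserved_fraction: float = 0.15
    substitution_prob: float = 0.3
    n_mutations: int = 300
    enrichment_odds: float = 1.0
    kind_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {"missense": 0.6, "nonsense": 0.1,
                                 "frameshift": 0.1, "synonymous": 0.1,
                                 "intronic": 0.1})
    hotspot_spec: tuple[tuple[int, int], ...] = ()
    tissue_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES))
    zygosity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZYGOSITY))
    cell_line_fraction: float = 0.2
    duplicate_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.conserved_fraction <= 1:
            raise ValueError("conserved_fraction must be in [0, 1]")
        if not 0 < self.substitution_prob <= 1:
            raise ValueError("substitution_prob must be in (0, 1]")
        if self.enrichment_odds < 0:
            raise ValueError("enrichment_odds must be >= 0")
        total = sum(self.kind_probabilities.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"kind probabilities sum to {total}, not 1")
        if any(k not in KINDS for k in self.kind_probabilities):
            raise ValueError("unknown mutation kind in kind_probabilities")
        for pos, n in self.hotspot_spec:
            if not 1 <= pos <= self.ref_length:
                raise ValueError(f"hotspot position {pos} outside reference")
            if n < 1:
                raise ValueError("hotspot sample count must be >= 1")


def _ref_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA1), size=length))


def simulate_alignment(cfg: SimulationConfig
                       ) -> tuple[Alignment, np.ndarray]:
    """Generate a gapless protein MSA with planted conserved columns.

    Returns the alignment and the boolean truth flags (length
    ``ref_length``).  Conserved columns are identical across all
    sequences; in every non-conserved column each non-reference sequence
    substitutes with probability ``substitution_prob`` (conditioned on at
    least one substitution; see module docstring).
    """
    rng = np.random.default_rng(cfg.seed)
    L, n = cfg.ref_length, cfg.n_seqs
    ref = _ref_protein(rng, L)
    n_cons = int(round(cfg.conserved_fraction * L))
    flags = np.zeros(L, dtype=bool)
    flags[rng.choice(L, size=n_cons, replace=False)] = True

    others = np.tile(np.frombuffer(ref.encode(), dtype="S1"), (n - 1, 1))
    aa = np.frombuffer(AA1.encode(), dtype="S1")
    for col in np.nonzero(~flags)[0]:
        while True:
            mutate = rng.random(n - 1) < cfg.substitution_prob
            if mutate.any():
                break
        for i in np.nonzero(mutate)[0]:
            choices = aa[aa != others[i, col]]
            others[i, col] = rng.choice(choices)

    ids = (f"{cfg.gene}_HUMAN",) + tuple(
        f"{cfg.gene}_sp{i:02d}" for i in range(1, n))
    rows = (ref,) + tuple(row.tobytes().decode() for row in others)
    return Alignment(ids=ids, rows=rows), flags


def write_fasta(a: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(a.ids, a.rows):
            fh.write(f">{sid}\n{row}\n")


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float],
                     size: int) -> np.ndarray:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return rng.choice(keys, size=size, p=p / p.sum())


def simulate_mutation_table(cfg: SimulationConfig,
                            truth_flags: np.ndarray | Sequence[bool],
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a COSMIC-like mutation table plus per-row ground truth.

    Background mutation positions are drawn with relative weight
    ``enrichment_odds`` on conserved residues and 1 on non-conserved
    residues; hotspot rows (one fixed frameshift allele per hotspot,
    distinct synthetic sample IDs) are appended afterwards.  Change
    strings are rendered in the COSMIC dialect the parser accepts.
    """
    flags = np.asarray(truth_flags, dtype=bool)
    if len(flags) != cfg.ref_length:
        raise ValueError("truth_flags length != ref_length")
    rng = np.random.default_rng(cfg.seed)
    ref = _ref_protein(rng, cfg.ref_length)
    M = cfg.n_mutations

    weights = np.where(flags, cfg.enrichment_odds, 1.0)
    if weights.sum() == 0:
        raise ValueError("degenerate placement weights")
    positions = rng.choice(cfg.ref_length, size=M,
                           p=weights / weights.sum()) + 1
    kind_names = list(cfg.kind_probabilities)
    kinds = _weighted_choice(rng, cfg.kind_probabilities, M)
    del kind_names
    tissues = _weighted_choice(rng, cfg.tissue_weights, M)
    zygosities = _weighted_choice(rng, cfg.zygosity_weights, M)
    origin_draw = rng.random(M)
    origins = np.where(origin_draw < cfg.cell_line_fraction, "cell_line",
                       "primary_tumour")

    rows, truth = [], []

    def render(kind: str, pos: int) -> tuple[str, str]:
        r = ref[pos - 1]
        if kind == "missense":
            alt = rng.choice([a for a in AA1 if a != r])
            base = rng.choice(["A", "C", "G", "T"])
            alt_b = rng.choice([b for b in "ACGT" if b != base])
            return f"p.{r}{pos}{alt}", f"c.{3 * pos - 2}{base}>{alt_b}"
        if kind == "nonsense":
            return f"p.{r}{pos}*", f"c.{3 * pos - 2}C>T"
        if kind == "frameshift":
            off = int(rng.integers(1, 31))
            alt = rng.choice([a for a in AA1 if a != r])
            return f"p.{r}{pos}{alt}fs*{off}", f"c.{3 * pos - 2}del"
        if kind == "synonymous":
            return f"p.{r}{pos}=", f"c.{3 * pos}G>A"
        # intronic: offset notation flags the row for ORF exclusion
        off = int(rng.integers(1, 50))
        return "p.?", f"c.{3 * pos - 2}+{off}G>A"

    for i in range(M):
        kind, pos = str(kinds[i]), int(positions[i])
        aa, cdna = render(kind, pos)
        rows.append({
            "gene": cfg.gene, "sample_id": f"S{i:06d}", "aa_change": aa,
            "cdna_change": cdna, "primary_site": str(tissues[i]),
            "zygosity": _ZYG_TEXT[str(zygosities[i])],
            "sample_source": _SOURCE_TEXT[str(origins[i])],
            "pubmed_id": str(int(rng.integers(10_000_000, 40_000_000))),
        })
        truth.append({
            "sample_id": f"S{i:06d}", "kind": kind, "position": pos,
            "conserved": bool(flags[pos - 1]), "tissue": str(tissues[i]),
            "origin": str(origins[i]), "zygosity": str(zygosities[i]),
            "is_hotspot": False, "is_duplicate": False,
        })

    for pos, n_samples in cfg.hotspot_spec:
        r = ref[pos - 1]
        alt = rng.choice([a for a in AA1 if a != r])
        off = int(rng.integers(1, 31))
        aa, cdna = f"p.{r}{pos}{alt}fs*{off}", f"c.{3 * pos - 2}del"
        for j in range(n_samples):
            sid = f"H{pos}_{j:03d}"
            rows.append({
                "gene": cfg.gene, "sample_id": sid, "aa_change": aa,
                "cdna_change": cdna, "primary_site": "large_intestine",
                "zygosity": "u", "sample_source": "fresh/surgery - NOS",
                "pubmed_id": str(int(rng.integers(10_000_000, 40_000_000))),
            })
            truth.append({
                "sample_id": sid, "kind": "frameshift", "position": pos,
                "conserved": bool(flags[pos - 1]),
                "tissue": "large_intestine", "origin": "primary_tumour",
                "zygosity": "unknown", "is_hotspot": True,
                "is_duplicate": False,
            })

    if cfg.duplicate_fraction > 0 and rows:
        n_dup = int(round(cfg.duplicate_fraction * len(rows)))
        for idx in rng.choice(len(rows), size=n_dup, replace=False):
            dup = dict(rows[idx])
            dup["pubmed_id"] = str(int(rng.integers(10_000_000, 40_000_000)))
            rows.append(dup)
            t = dict(truth[idx])
            t["is_duplicate"] = True
            truth.append(t)

    table = pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA.columns.values()))
    return table, pd.DataFrame(truth)


def null_calibration(cfg: SimulationConfig, n_reps: int = 2000,
                     alpha: float = 0.05) -> float:
    """Fraction of replicates rejecting at ``alpha`` under the null.

    Requires ``enrichment_odds == 1`` (uniform placement).  Each
    replicate reseeds with ``seed + r``, runs the full pipeline —
    simulate table, ingest, ORF filter, observed/expected counts,
    chi-square — and tests p < alpha.  The exact (unrounded) statistic
    is used.
    """
    if cfg.enrichment_odds != 1.0:
        raise ValueError("null calibration requires enrichment_odds = 1")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    hits = 0
    for r in range(n_reps):
        cfg_r = dataclasses.replace(cfg, seed=cfg.seed + r)
        rng = np.random.default_rng(cfg_r.seed)
        L = cfg_r.ref_length
        n_cons = int(round(cfg_r.conserved_fraction * L))
        flags = np.zeros(L, dtype=bool)
        flags[rng.choice(L, size=n_cons, replace=False)] = True
        table, _ = simulate_mutation_table(cfg_r, flags)
        records = filter_orf(records_from_frame(table))
        profile = profile_from_flags(cfg_r.gene, flags)
        o_cons, o_non, _rej = observed_counts(records, profile)
        o_total = o_cons + o_non
        if o_total == 0:
            continue
        expected = expected_counts(o_total, n_cons, L, "exact_proportion")
        if expected[0] <= 0 or expected[1] <= 0:
            continue
        _, _, _, p = chi_square_gof((o_cons, o_non), expected,
                                    sum_decimals=None)
        if p < alpha:
            hits += 1
    return hits / n_reps
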