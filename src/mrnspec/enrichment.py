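"""Chi-square goodness-of-fit test for enrichment of mutations in
evolutionarily conserved residues.

Residues are partitioned into conserved ("identity") and non-conserved
classes; observed mutation counts in each class are compared with the
counts expected if mutations fell uniformly per residue.  With two
classes and a fixed total the statistic has one degree of freedom, and
the upper-tail probability has the closed form ``p = erfc(sqrt(x / 2))``.

Published tables of this construction round each chi-square component to
two decimals and derive p from the rounded sum; ``chi_square_gof``
reproduces that convention by default (``sum_decimals=2``) and computes
the exact statistic with ``sum_decimals=None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .conservation import ConservationProfile
from .hgvs import ProteinKind
from .ingest import MutationRecord

__all__ = [
    "EnrichmentResult",
    "observed_counts",
    "expected_counts",
    "chi_square_gof",
    "enrichment_report",
    "POINT_MUTATION_KINDS",
]

# "point mutations": single-residue ORF changes.  Frameshifts and in-frame
# indels alter runs of residues, so the class membership of their start
# position is not well defined; the selection is configurable.
POINT_MUTATION_KINDS = (ProteinKind.MISSENSE, ProteinKind.NONSENSE,
                        ProteinKind.SYNONYMOUS)


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene's enrichment test: the published-table row shape."""

    gene: str
    n_conserved: int
    n_non_conserved: int
    observed: tuple[int, int]
    expected: tuple[float, float]
    components: tuple[float, float]
    chi_square_sum: float
    df: int
    p_value: float
    expected_mode: str
    n_rejects: int = 0
    testable: bool = True


def observed_counts(records: Sequence[MutationRecord],
                    profile: ConservationProfile,
                    kinds_included: Iterable[ProteinKind] = POINT_MUTATION_KINDS,
                    ) -> tuple[int, int, list[MutationRecord]]:
    """Count mutations at conserved vs non-conserved residues.

    Each counted record lands in exactly one class via its residue's
    flag.  Records at positions without a profile entry go to the
    returned rejects list.
    """
    kinds = set(kinds_included)
    o_cons = o_non = 0
    rejects: list[MutationRecord] = []
    for r in records:
        if r.protein_change.kind not in kinds:
            continue
        pos = r.protein_change.position
        if pos is None or not 1 <= pos <= profile.n_residues:
            rejects.append(r)
            continue
        if profile.conserved[pos - 1]:
            o_cons += 1
        else:
            o_non += 1
    return o_cons, o_non, rejects


def expected_counts(o_total: int, n_cons: int, n_total: int,
                    mode: str = "exact_proportion",
                    ) -> tuple[float, float]:
    """Expected class counts under uniform per-residue mutation placement.

    ``exact_proportion``: E_cons = O_total * n_cons / n_total.
    ``rounded_percent``: the conserved fraction is first rounded to one
    decimal of percent (16.0%, 10.4%, 5.0%), matching how published
    tables of this analysis derive their expected column; E_cons =
    O_total * round1(percent) / 100.  E_non = O_total - E_cons either way.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if o_total < 0:
        raise ValueError("o_total must be non-negative")
    if not 0 <= n_cons <= n_total:
        raise ValueError("n_cons must lie in [0, n_total]")
    if mode == "exact_proportion":
        e_cons = o_total * n_cons / n_total
    elif mode == "rounded_percent":
        e_cons = o_total * round(100.0 * n_cons / n_total, 1) / 100.0
    else:
        raise ValueError(f"unknown expected mode: {mode!r}")
    return e_cons, o_total - e_cons


def chi_square_gof(observed: Sequence[float], expected: Sequence[float],
                   sum_decimals: int | None = 2,
                   ) -> tuple[tuple[float, float], float, int, float]:
    """Two-class goodness of fit with df = 1.

    Returns ``(components, chi_square_sum, df, p_value)`` where
    component_i = (O_i - E_i)^2 / E_i and p is the df = 1 upper tail
    ``erfc(sqrt(sum / 2))``.  ``sum_decimals`` rounds the statistic
    before the tail evaluation (published-table convention); pass
    ``None`` for the exact statistic.
    """
    if len(observed) != 2 or len(expected) != 2:
        raise ValueError("exactly two classes expected")
    if any(e <= 0 for e in expected):
        raise ValueError("expected counts must be positive")
    components = tuple((o - e) ** 2 / e for o, e in zip(observed, expected))
    total = sum(components)
    if sum_decimals is not None:
        total = round(total, sum_decimals)
    p = math.erfc(math.sqrt(total / 2.0))
    return components, total, 1, p  # type: ignore[return-value]


def enrichment_report(records: Sequence[MutationRecord],
                      profile: ConservationProfile,
                      kinds_included: Iterable[ProteinKind] = POINT_MUTATION_KINDS,
                      modes: Sequence[str] = ("exact_proportion",
                                              "rounded_percent"),
                      sum_decimals: int | None = 2,
                      ) -> list[EnrichmentResult]:
    """Wire observed -> expected -> chi-square and emit one result per
    expected mode.  A gene with no countable mutations is flagged
    not-testable rather than given a p-value."""
    o_cons, o_non, rejects = observed_counts(records, profile, kinds_included)
    n_cons = sum(profile.conserved)
    n_non = profile.n_residues - n_cons
    o_total = o_cons + o_non

    results = []
    for mode in modes:
        if o_total == 0 or n_cons == 0 or n_non == 0:
            results.append(EnrichmentResult(
                gene=profile.gene, n_conserved=n_cons, n_non_conserved=n_non,
                observed=(o_cons, o_non), expected=(float("nan"), float("nan")),
                components=(float("nan"), float("nan")),
                chi_square_sum=float("nan"), df=1, p_value=float("nan"),
                expected_mode=mode, n_rejects=len(rejects), testable=False))
            continue
        expected = expected_counts(o_total, n_cons, profile.n_residues, mode)
        comps, total, df, p = chi_square_gof((o_cons, o_non), expected,
                                             sum_decimals)
        results.append(EnrichmentResult(
            gene=profile.gene, n_conserved=n_cons, n_non_conserved=n_non,
            observed=(o_cons, o_non), expected=expected, components=comps,
            chi_square_sum=total, df=df, p_value=p, expected_mode=mode,
            n_rejects=len(rejects)))
    return results


def report_to_frame(results: Sequence[EnrichmentResult]):
    """Results as a TSV-ready table mirroring the published column order.

    Note: three unadjusted p-values are reported, matching the original
    three-gene analysis; no multiple-testing correction is applied.
    """
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "gene": r.gene, "mode": r.expected_mode,
            "n_conserved": r.n_conserved, "n_non_conserved": r.n_non_conserved,
            "observed_conserved": r.observed[0],
            "observed_non_conserved": r.observed[1],
            "expected_conserved": round(r.expected[0], 2),
            "expected_non_conserved": round(r.expected[1], 2),
            "chi_component_conserved": round(r.components[0], 2),
            "chi_component_non_conserved": round(r.components[1], 2),
            "chi_square_sum": r.chi_square_sum, "df": r.df,
            "p_value": r.p_value, "testable": r.testable,
            "n_rejects": r.n_rejects,
        })
    return pd.DataFrame(rows)
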