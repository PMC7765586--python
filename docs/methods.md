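# Methods

## Problem and scope

`mrnspec` analyses somatic mutation reports for the genes of the MRN DNA
double-strand-break sensor complex (MRE11, RAD50, NBS1/NBN) and its
partner CtIP/RBBP8, as exported from COSMIC-style catalogues. The
pipeline has four stages:

1. **Ingest** — parse each row's protein-level and cDNA-level HGVS
   change strings, normalise tissue/zygosity/origin fields, collapse
   reports of the same observation deposited by independent studies, and
   exclude intronic and 5'/3' UTR changes from ORF analyses (synonymous
   changes are retained, since they can affect mRNA stability).
2. **Spectrum** — counts by mutation class and by tissue (optionally
   split into primary-tumour vs cell-line origin), per-residue positional
   histograms over domain maps, recurrence hotspot calls, zygosity
   tables, and N-half/C-half summaries of truncating mutations.
3. **Conservation** — classify each residue of the human reference
   sequence as evolutionarily conserved or not, from a protein multiple
   sequence alignment, by a consensus-frequency threshold.
4. **Enrichment** — a two-class chi-square goodness-of-fit test of
   whether point mutations are over-represented in conserved residues.

Alignment computation (e.g. MAFFT) is out of scope: alignments are
consumed, not produced. No network access is used anywhere.

## Mutation parsing

The parser targets the COSMIC dialect of HGVS rather than the full
standard: missense (`E185Q`), nonsense (`Q689*`, legacy `Q689X`),
synonymous (`L34=`, and identity substitutions like `A1A`), frameshift
(`N511Ifs*13`; bare `fs` without a stop offset is accepted because real
exports contain both spellings), and in-frame del/dup/ins. Prefixes are
case-insensitive and optional; `p.?` and unrecognised syntax map to an
explicit `unknown` class so no row is silently dropped. A frameshift's
predicted stop residue is `position + offset − 1`, counting the
substituted residue as codon 1 of the shifted frame.

Deduplication keys on `(gene, sample_id, cDNA string)`, falling back to
the protein string when no cDNA annotation exists, first occurrence
winning. The cDNA spelling is preferred because distinct nucleotide
events (e.g. `c.2165del` vs `c.2164_2165del`) can produce annotations at
the same codon yet are different alleles. The original curation was a
manual visual inspection with unstated criteria; this key-based rule is
a reproducible stand-in for it.

Sample origin is derived from the free-text sample-source field:
cell-line markers map to `cell_line`, explicit tumour/surgery/biopsy
markers to `primary_tumour`, anything else to `unknown`. Tissue labels
pass through verbatim (no ontology mapping); zygosity strings normalise
by prefix (`het`/`hom`), with everything else `unknown`.

## Hotspot calling

A hotspot is a residue position mutated in at least `min_recurrence`
**distinct samples** (rows never inflate a call; counting samples rather
than studies is a documented choice). Hotspots are keyed by residue, not
allele, because a single codon often carries several alleles (a
recurrent frameshift plus sporadic missense and alternative frameshifts);
every distinct change string at the position is reported. The default
threshold is 5 distinct samples: well-replicated recurrences qualify,
isolated repeats do not. It is a parameter and CLI flag, not a constant.

Positions beyond the configured protein length go to a rejects report
rather than failing the run, since real exports contain
annotation-version drift. Domain intervals (for positional aggregates
and lollipop exports) ship in a versioned YAML config; the intervals are
approximate boundaries assembled from the structural literature and
carry no statistical weight. The reference lengths in that config
(MRE11 708, RAD50 1312, NBN 754) are load-bearing: the conservation
profile warns when a supplied alignment's ungapped reference length
disagrees, because the published residue totals depend on them.

## Conservation classification

For each alignment column containing a non-gap reference residue, the
column's modal residue and frequency are computed over **all** sequences
(gaps count in the denominator, so a heavily gapped column cannot reach
consensus; switchable via `count_gaps_in_denominator`). A reference
residue is conserved iff the modal residue frequency reaches
`theta * n_seqs` **and** the modal residue equals the reference residue —
a column unanimously conserved around a non-human residue is not a
conserved human residue (this is the "identity" reading of the class).
Ties for the mode resolve to not-conserved unless the reference residue
itself attains the threshold. `X`/ambiguous residues mismatch
everything and can never be the mode.

The default `theta = 0.98` is deliberately stringent: with alignments of
27 or fewer sequences it forces unanimity (0.98 × 27 = 26.46, so 26/27
fails), while in deeper alignments it tolerates rare deviant sequences.
Conservation percentages are reported to one decimal; with the published
residue totals this gives 16.0% (113/708), 10.4% (136/1312) and 5.0%
(38/754). The NBN value is sometimes quoted as 5.3%, which 38/754 does
not produce; the package reports the computed 5.0% and surfaces the
discrepancy instead of matching the quote.

## Enrichment test

Let `n_cons` of `n_total` residues be conserved and `O_total` point
mutations be observed, `O_cons` of them at conserved residues. Under
uniform per-residue placement, `E_cons = O_total · n_cons / n_total` and
`E_non = O_total − E_cons`. The statistic is
`χ² = Σ (O − E)² / E` over the two classes with df = 1 (the totals are
constrained), no continuity correction, and the upper tail has the
closed form `p = erfc(√(χ²/2))`.

Two expected-count modes are always reported side by side:

* `exact_proportion` (default) — the formula above;
* `rounded_percent` — the conserved fraction is first rounded to one
  decimal of percent (16.0, 10.4, 5.0) before multiplying. This exists
  solely to reproduce published tables of this construction digit for
  digit (their expected columns equal `O_total × {0.160, 0.104, 0.050}`).

Similarly, `chi_square_gof` rounds the statistic to two decimals before
the tail evaluation by default (`sum_decimals=2`), because published
tables derive p from the two-decimal statistic (2.05 → 0.152206);
`sum_decimals=None` gives the exact statistic and p. The default
`kinds_included` is missense + nonsense + synonymous — the
single-residue ORF classes — since the class membership of a frameshift
or indel spanning many residues is not well defined; the selection is a
config flag and this default is an interpretation of "point mutations".
Three unadjusted p-values are reported for the three genes, with no
multiple-testing correction, and this is noted in the report.

## Synthetic data generator

The generator exists so every stage is testable with known ground truth
and no downloads. It emulates (a) the alignment structure: `n_seqs`
gapless protein sequences of length `L` with a planted conserved-column
set of fraction `f`, where non-conserved columns substitute each
non-reference sequence independently with probability `s`; and (b) the
mutation-table structure: `M` rows with positions drawn with relative
weight `rho` on conserved residues (the enrichment odds ratio), mutation
classes drawn from `kind_probabilities`, COSMIC-dialect change strings,
tissue/zygosity/origin fields drawn from weight tables, optional
injected hotspots (one fixed frameshift allele, distinct synthetic
sample IDs) and optional duplicate rows for dedup testing.

Defaults mirror the targeted study conditions: 27 sequences (the MRE11
alignment depth), L = 708 (the MRE11 ORF), f = 0.15 (near the observed
conservation range), s = 0.3, M = 300 observations (the per-gene order
of magnitude), ρ = 1, mutation-class weights 0.6/0.1/0.1/0.1/0.1 for
missense/nonsense/frameshift/synonymous/intronic, tissue weights with
the large intestine most represented, zygosity 80% unknown / 18%
heterozygous / 2% homozygous, and a 20% cell-line fraction.

One deliberate deviation from a plain Bernoulli model: in non-conserved
columns the substitution indicators are drawn conditioned on at least
one substitution occurring. Unconditionally, a non-conserved column is
unanimous with probability `(1−s)^(n−1)` (~9×10⁻⁵ at s = 0.3, n = 27),
which would make the planted labels occasionally wrong; conditioning
makes the returned truth flags exact by construction whenever
`theta · n > n − 1`. All draws come from one seeded generator per
operation; replicate `r` of the calibration loop reseeds with
`seed + r`, so every output is bit-reproducible.

What the generator does **not** emulate: trinucleotide mutational
signatures, phylogenetic correlation between sequences, alignment gaps
and indels, tissue-specific mutation spectra, and the biological
consistency of fabricated cDNA strings (a frameshift at residue p is
written `c.{3p−2}del` only so the dedup key is exercised). Passing tests
therefore demonstrate the pipeline's arithmetic and classification
logic, not robustness to real-data artefacts like annotation drift
across COSMIC versions.

## Operating characteristics (computed, not asserted from literature)

* **Type-I error**: with ρ = 1, M = 300, f = 0.15, the full-pipeline
  rejection fraction at α = 0.05 over 2000 replicates is checked to lie
  in [0.03, 0.07] (chi-square asymptotics at these counts).
* **Power**: with ρ = 3, f = 0.15 and ~300 countable mutations, the
  rejection fraction at α = 0.05 exceeds 0.90 (direct simulation).
* **Parameter recovery**: planted conserved flags are recovered exactly
  at n = 27, θ = 0.98, s = 0.3, L = 1000, and the empirical placement
  odds ratio at M = 10⁴ is within 10% of ρ = 3.

Problem sizes in the test-suite (2000 calibration replicates, 10⁴-row
placement tables, 10³-row hotspot tables) were chosen as the smallest
sizes at which these statistical bands are comfortably stable.

## Numerical and degenerate-input conventions

* Percentages are rounded half-even to one decimal (Python `round`).
* The consensus comparison `count ≥ theta · n` uses a 10⁻⁹ slack to
  absorb float noise at exact thresholds (e.g. θ = 1).
* A gene with zero countable mutations, or a profile with an empty
  class, yields a result flagged `testable=False` with no p-value.
* `expected_counts` requires `n_total > 0`; `chi_square_gof` requires
  strictly positive expected counts; hotspot calling requires
  `min_recurrence ≥ 2`.
* The truncation-position midpoint residue (position = L/2) is assigned
  to the N-terminal half.
* An all-gap reference row produces an empty coordinate map with a
  warning rather than an error.

## Known limitations

* The observed counts of the published three-gene table (52/219, 81/463,
  30/339) depend on the authors' manually curated COSMIC v91 extract and
  cannot be re-derived here; the package treats them as printed inputs
  and instead verifies its counting logic against brute-force oracles on
  synthetic tables.
* Only the identity/consensus classification is implemented; similarity
  shading and consensus logos are out of scope, as are alternative
  enrichment tests (Fisher's exact, permutation) — natural future work.
* Tissue over-representation is tabulated but not tested statistically.
* The hotspot spelling variance in the literature (`N511fs*13`,
  `N511Ifs*13`, `N511LFS*13`) is handled by keying hotspots on
  (position, kind, cDNA change) rather than guessing an authoritative
  spelling; known inconsistent pairings in source material (an `R555K`
  paired with `c.1652G>A`, which maps to residue 551) are preserved
  as-is, not corrected.
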