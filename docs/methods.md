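# Methods

## Scope and model

`cypminer` covers the post-assembly, post-gene-calling portion of a P450
mining study: given candidate proteins and a labelled panel of known P450s,
it produces dereplicated candidates, screen and filter verdicts with
reasons, CYP names, and per-site statistics. Read QC, assembly, binning,
gene calling, multiple alignment and tree building are out of scope; the
gene caller is honoured only through its completeness flags.

The classification model is the standard CYP nomenclature convention:
family membership above 40% sequence identity, subfamily membership above
55%, a new family below 40% to every named P450. Both comparisons are
strict (identity exactly at a cut-off falls to the lower category), read
literally from the convention's wording; both are configurable
(`nomenclature.Thresholds`).

## Alignment and identity

All stages share one aligner (Biopython's `PairwiseAligner`) and one
parameter set (`pairwise.AlignParams`): BLOSUM62, affine gaps with the
BLAST convention cost(k) = open + k·extend, defaults open = 10,
extend = 1 (first gapped residue costs 11). Two modes are used:

* **local** (Smith–Waterman) for the blastp-style reference screen, with a
  Karlin–Altschul E-value E = K·m·n·e^(−λS) using the standard gapped
  BLOSUM62 constants λ = 0.267, K = 0.041 and a search space of query
  residues × total panel residues. These constants are configurable; they
  approximate the filtering behaviour of a database-search tool's defaults.
* **semi-global** (terminal gaps free) for every identity used in
  filtering and nomenclature, because CYP naming compares near-full-length
  proteins and should not penalize length variation.

Semi-global percent identity is

    100 · matches / max(aligned_columns, min(len_a, len_b))

where aligned columns run from the first to the last aligned residue pair
(internal gap columns counted, terminal overhangs not), matches require
equal residues and exclude X (unknown residue never counts as identical).
The shorter-sequence floor in the denominator is essential: with free end
gaps, the optimal alignment of two *unrelated* proteins is typically a tiny
perfect-match overlap (often 1–3 residues), which without the floor would
read as 100% identity. With the floor, unrelated 400-residue proteins score
~5–10%, while any comparison in which the shorter sequence is fully aligned
— the nomenclature use case — is unaffected. This is the shorter-sequence
convention of greedy clustering tools.

Among co-optimal alignments Biopython's traceback is deterministic but
order-sensitive, so `global_align` canonicalizes argument order
(lexicographic) and mirrors the result; identity and coverages are then
exactly symmetric. Degenerate inputs: empty sequences are errors; if the
optimum is the zero-overlap alignment the result reports identity 0 with no
spans; a local alignment with no positive-scoring cell is reported as "no
hit" (score 0, undefined identity).

## Dereplication

Greedy longest-first clustering at 100% identity. A 100%-identity local
alignment can contain no gap column (any gap would lower identity below
100), so the maximal such alignment is the longest common substring, which
is computed directly (vectorized dynamic programme; X matches nothing). A
record joins the first seed whose overlap covers ≥ 80% of the record's own
length — the "80% of *their* sequence" member-relative convention of the
clustering tools this mirrors. An exact prefix therefore always merges,
regardless of how short it is relative to the seed; the seed-relative
denominator is available via `relative_to="seed"` for the stricter reading.
Ties in seed order (equal length) are broken by record id.

## Filter cascade

Order: completeness → microbial identity → heme motif; the first failing
stage is the recorded rejection reason, so the reports partition the input
and the per-stage counts form the run's funnel. Completeness trusts an
explicit gene-caller flag (`"00"` = both codons seen) and otherwise falls
back to sequence evidence (initial Met plus a stop marker seen at ingest).
The microbial filter requires best semi-global identity ≥ 20% (inclusive)
to a microbial panel entry with both coverages ≥ 50%; the coverage floor is
adopted for symmetry with the screen and is configurable. The motif scanner
reports *every* window matching F(x)ₙG/A(x)ₘCxG for n ∈ 2..5, m ∈ 3..6
anywhere in the sequence (no positional restriction; positions are reported
so users can impose one), plus near-misses in which only the axial cysteine
differs — a substitution observed in nature (e.g. Cys→Tyr) and worth
surfacing rather than silently dropping. Records with > 10% X are flagged
but kept. Where a manual curation step would sit in a real study, this
package applies only the stated objective criteria; counts on real data
will accordingly differ from any manually curated inventory.

## Nomenclature and the registry

Queries are classified sequentially in deterministic order (descending
length, then id) against the panel plus all previously classified queries,
so mutually similar novel sequences share their newly founded group. Best
hits maximize identity, with ties broken by query coverage then
lexicographic target id (logged). The registry allocates names
CYP⟨family⟩⟨letters⟩⟨allele⟩: next allele within a known subfamily, next
free letter (A…Z, AA, AB, …) within a family, next free family number from
a private base (default 9001) for new families — committee-assigned numbers
are never imitated. Allocated names are unique across a run and across
registry save/reload (JSON).

Near a threshold, chained classification makes group co-membership depend
on processing order. Rather than hiding this, any query whose best identity
falls within 3 points of a cut-off (configurable) is flagged and listed in
a warning and in the run summary.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure the analysis assumes:
references 380–480 aa starting with Met and carrying exactly one canonical
motif in their C-terminal third; families mutually < 35% identical;
subfamilies within a family at 43–52%; query categories with identity bands
62–90% (known subfamily), 43–52% (new subfamily), 28–35% (new family),
each ≥ 3 points clear of the 40/55 cut-offs so category recovery is
well-posed (an adversarial preset generates near-threshold cases instead,
to exercise the order-dependence warning). New-family queries are made as
remote homologs of a reference rather than unrelated random sequences: a
genuine novel P450 still resembles the superfamily enough to survive an
alignment screen, whereas pure noise would vanish at the E-value filter —
that role is played by the motif-free random decoys. Truncated queries
(start or heme region removed, flagged partial) test the completeness
filter; exact copies and ≥ 80%-length exact prefixes test dereplication.

Identity control works by binary search on the number of substituted
positions (substitutions only outside protected spans — the motif and the
initial Met — plus occasional short indels), measuring each candidate with
the package's own semi-global aligner; the independent brute-force Gotoh
oracle in the test suite re-verifies the realized identities to within 0.5
points. Residue composition is uniform over the 20 canonical amino acids —
deliberately simple and documented, not phylogenetically realistic: no
substitution-model structure, no compositional bias, no shared domain
architecture beyond the motif. Passing the recovery tests therefore shows
the *decision logic* is correct under controlled identities; it does not
show that thresholds or E-value constants are well calibrated for real
metagenomic data.

All randomness flows from a single integer seed through one numpy
Generator; a fixed seed yields byte-identical FASTA/TSV output across
platforms.

## Defaults and problem sizes

The default synthetic preset — 4 families × 2 subfamilies (8 references)
and 42 queries (12 known-subfamily, 8 new-subfamily, 6 new-family,
6 decoys, 4 incomplete, 6 duplicates) — is the package's standard
benchmark: large enough that every stage and every rejection reason is
exercised several times, small enough that a full pipeline run takes
seconds. Unit tests that re-align full sequences with the pure-Python
oracle use a scaled-down preset (3 × 2 families, 120–160 aa references),
where the oracle's O(n·m) dynamic programme stays cheap.

## Statistics

The per-site diversity percentage is 100 · n_families / n_P450s, rounded
half-up to one decimal (the printed precision of the source tables; the raw
ratio is also stored). Dominance ties are preserved, never broken
arbitrarily. Overall family/subfamily totals count distinct groups across
sites, not sums of per-site counts. Shannon diversity uses the natural log
(base configurable) with zero coverages contributing nothing; relative
abundances are coverages divided by their sum, with all-zero input an
error.

## Known limitations

* The screen is alignment-only against a labelled panel; profile-HMM
  search is deliberately not reimplemented, so sensitivity to very remote
  homologs is bounded by the panel's breadth.
* Identity-threshold classification is order-dependent near the cut-offs;
  the package surfaces this rather than resolving it (no MSA or
  tree-based reconciliation).
* E-values use fixed Karlin–Altschul constants rather than
  sequence-composition-adjusted statistics.
* The synthetic generator does not simulate reads, assembly artefacts, or
  realistic residue composition (see above).
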