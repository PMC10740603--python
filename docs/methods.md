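# Methods

## The problem and the model

Universal eukaryotic 18S primers co-amplify host rRNA when the template is
animal tissue; for snail hosts the host fraction can dominate the library.
The remedy modelled here is a *blocking primer*: an oligo ending in a
3' C3 spacer, so polymerase cannot extend it, that anneals to the host
template across the reverse-primer binding site and its host-specific
flank. During annealing it competes with the reverse primer on host
molecules only; blocked host templates yield no product, and the sequencing
budget shifts to the microeukaryote community.

Everything in this package is combinatorial sequence analysis: primer
binding is modelled as IUPAC set-subset matching with a mismatch budget,
never as annealing thermodynamics, and a "blocked" call is a binary
full-length match, not an elongation-arrest efficiency. These are the
standard desk approximations for primer design; wet-lab ratio and
temperature optimization are out of scope.

## Matching rule

A primer symbol covers a target symbol iff the target's base set is a
subset of the primer's. This is asymmetric on purpose: a degenerate primer
position (`Y`, `S`, …) matches any base it encodes, but an `N` in a
low-quality reference matches only a primer `N` — an ambiguous reference
base should not be credited as a primer match. Sites are searched on both
strands (coordinates always reported on the sense strand); the scan is
vectorized over 4-bit base masks and is exactly equivalent to the naive
all-positions scan, which the test suite keeps as an independent oracle.

The default mismatch allowance for amplicon extraction is **1 per primer**
(separately for forward and reverse, both configurable): known host snail
sequences differ from the universal reverse primer at one position, and the
working database must retain them. Amplicon extraction keeps one amplicon
per reference — the best forward site (fewest mismatches, then leftmost),
then the best compatible reverse site giving a product in the configured
length window (default 200–600 nt, generous bounds around the ~380-nt 18S
V4 product).

## Terminal block and entropy

The design region is the last *W* = 40 nt of each amplicon: the 18-nt
reverse-primer site plus its 22-nt host-specific flank. Rows are
right-anchored at the amplicon 3' terminus — a positional alignment
justified by the shared primer anchor — rather than re-aligned with an MSA
heuristic; a user-supplied pre-aligned FASTA of the region is also
accepted. Per column and per set (host vs non-target), Shannon entropy
`H = −Σ f·log2 f` is computed over {A, C, G, T, other}; the logarithm base
is configurable (bits by default, the oligotyping convention), gap symbols
are excluded from the frequencies, and an all-gap column is reported as
missing rather than zero. Rare ambiguity codes are pooled into one "other"
class. ΔH = H(non-target) − H(host) highlights columns that are conserved
in the host yet variable in the community — the blocker's discriminative
positions.

## Candidate enumeration and constraints

Candidates are **host-consensus windows**: one oligo designed for the whole
host clade, not per-sequence oligos. The consensus takes the majority
concrete base per column (ties broken to the lexicographically smallest
base and flagged); conservation is the majority base's frequency among
non-gap symbols. Because the blocker anneals to the same strand as the
reverse primer, the candidate oligo is the *reverse complement* of the
consensus window, and its 5' prefix then overlaps the reverse primer's 3'
suffix — the published snail blocker shows exactly this geometry, with one
host-specific mismatch inside the 10-bp overlap.

Enumerated geometry: length 24–32 nt (target ~28) × overlap 8–12 bp
(target ~10) with the reverse-primer site. Filters, each recorded with a
reason in a near-miss diagnostics table when it rejects a candidate:

- no gap in the consensus window;
- mean host conservation ≥ 0.90 over the non-primer-site columns (the
  primer-site columns are constrained by the assay, not by host
  conservation);
- melting temperature inside the acceptance window. The default window is
  the amplification pair's Tm span padded by ±3 °C (`tm_reference:
  pair_range`): a blocking oligo must stay annealed wherever the
  amplification primers do, and a point reference would be arbitrary for a
  pair whose own Tm values differ by >10 °C. Point references (pair mean,
  forward, reverse) remain selectable. Tm defaults to the SantaLucia-1998
  unified nearest-neighbor model at 50 mM Na⁺ and 0.25 µM oligo (via
  Biopython); the Wallace rule `2(A+T) + 4(G+C)` is kept for transparency
  and as a closed-form oracle. Degenerate oligos are averaged over their
  concrete expansions (expansion capped at 64);
- off-target blocked fraction ≤ 1% (the acceptance bar for collateral
  blocking of the community).

Ranking: `score = host_blocked − λ·off_target_blocked` with λ = 10 — the
penalty is deliberately lopsided because collateral blocking biases the
community profile, the one thing the method must not do. Ties break by
distance of Tm from the pair midpoint, then larger overlap, then sequence
(all deterministic).

Block calls: an amplicon is blocked when the blocker matches it full-length
with ≤ `k_block` mismatches (default 0, i.e. the strictest call; the
criterion the published analysis used is unstated, so the knob is exposed)
on the reverse-complement strand; a `both_strands` flag adds the written
orientation for safety audits. Specificity reports give blocked fractions
per set and a per-clade breakdown of blocked non-targets at a configurable
lineage depth. Read-partition summaries (host/microeukaryote/other
proportions per sample) use the sample (n−1) standard deviation, suited to
the small sample counts typical of such tables.

## Synthetic data: what it emulates and what it does not

The generator draws one ancestor uniformly over ACGT (default 1800 nt, the
scale of an SSU gene) and embeds one concrete expansion of each primer site
at fixed offsets (default insert 342 nt → 380-nt amplicon). Host records
diverge at 0.005/site outside protected regions (primer sites, and the
terminal 40 nt when the conservation switch is on — snail 18S V4 termini
are effectively clade-conserved); each host record also carries the
host-specific mismatch at reverse-primer position 14 (the suffix position
implied by the published blocker/reverse alignment), injected at rate 1.0
by default. Non-targets diverge at 0.15/site everywhere except the primer
sites (protected by default, since a primer-matched working database is the
method's input); decoys are unrelated random sequences. Substitutions are
i.i.d. uniform over the three alternative bases (Jukes–Cantor-like); no
indels, so the gap-padding path is exercised only by short amplicons.
Identical configs (including seed) produce byte-identical FASTA.

What passing tests on these data show: the pipeline recovers a planted,
discriminative design and calls specificity correctly when host/non-target
structure is as modelled. What they do not show: robustness to real-world
taxonomic misannotation, chimeric or truncated reference entries, rRNA
secondary-structure-constrained evolution, intragenomic polymorphism, or
length variation in the terminal region — on real references the entropy
profile and conservation filter must absorb that noise, and results should
be sanity-checked against the per-clade off-target breakdown.

Default study conditions for the end-to-end recovery check: 100 host and
100 non-target records, conserved host terminus, divergences as above,
`k_block = 0`, evaluated over 20 seeds. At these sizes the whole 20-seed
sweep runs in well under a minute on one core.

## Numerical and design choices

- Coordinates are 0-based half-open internally and 1-based inclusive in
  human-readable tables.
- A record carrying the host clade is host even when it also carries an
  excluded clade (Heterobranchia ⊂ Metazoa); clade matching is exact
  whole-rank, case-insensitive, never substring.
- Suffix–prefix overlap between reverse primer and blocker is measured with
  the reverse primer as the degenerate side and ≤1 mismatch by default,
  reproducing the published pair's 10-bp overlap including the snail
  mismatch.
- All tie-breaks (consensus base, candidate ranking, site selection) are
  deterministic and documented, so identical inputs give byte-identical
  outputs.
- Every emitted candidate is re-checked by an independent validator
  (`validate_candidate`), which recomputes length, overlap, fractions and
  Tm from scratch.

## Known limitations

No secondary-structure (hairpin/dimer) screening; no clamp/PNA chemistry or
annealing kinetics; no multi-amplicon-per-reference mode; no MSA of the
terminal region (positional anchoring assumes primer-anchored termini); the
Wallace rule systematically overestimates Tm for long AT-rich oligos
relative to the nearest-neighbor model (the published 28-mer blocker reads
72 °C by Wallace vs ≈55 °C nearest-neighbor), so cross-model comparisons
should use one model consistently.
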