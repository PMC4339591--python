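# Methods

`cnmskit` identifies **conserved non-coding microsatellites (CNMS)** in
the 5' upstream regulatory regions (URRs) of protein-coding genes and
turns them into PCR-typable markers. A CNMS is defined by three
simultaneous conditions on an upstream window (default 1000 bp ending
immediately 5' of the translation start codon, ATG):

1. a perfect microsatellite (SSR) tract;
2. the tract intersects a match of a known regulatory-element /
   transcription-factor-binding-site signal consensus (e.g.
   GAGA8HVBKN3 = (GA)8, RAV1AAT = CAACA);
3. the composite SSR + signal interval lies inside a non-coding segment
   conserved in the upstream region of at least one orthologous or
   paralogous gene of a comparator species (within-species paralogs
   count).

The biological rationale is that repeat-length variation inside a
conserved cis-element is both easy to genotype (fragment-length
polymorphism) and likely to be functional (it perturbs a binding site
that purifying selection has retained across species).

## Coordinate frames

Sequences are stored 5'→3' on the strand read toward the ATG; the last
base of the stored string is adjacent to the A of ATG. Two frames are
used: 1-based string positions (GFF3-compatible) and the ATG-relative
upstream frame, where position 1 is the base nearest the ATG. The
conversion `(i, j) → (L − j + 1, L − i + 1)` is a self-inverse
reflection; tests verify the involution for many window lengths.
Upstream windows may be shorter than the configured width (e.g. when
truncated by a neighbouring gene); all operations use the actual length.

## SSR mining

`find_ssrs` reports every maximal perfect tandem run of a primitive
1–6 nt unit. A period-`k` run is a maximal stretch satisfying
`seq[j] == seq[j−k]` with N never matching; the tract is trimmed to
whole unit copies, and the unit is phased to its earliest occurrence, so
a run such as `GAGAGAG` yields one locus, (GA)3 at positions 1–6, not
two phase-shifted variants. Non-primitive units (GAGA, …) are skipped;
the same physical run is therefore reported exactly once, with the
smallest unit.

Thresholds are a per-unit-size minimum repeat count
(`{1:10, 2:6, 3:4, 4:3, 5:3, 6:3}`) **and** an independent tract floor
of 12 bp. These defaults deliberately admit short reference motifs such
as (TTCT)3, (ATGGT)3 and (AAG)4 that stricter mining defaults would
miss; both knobs are exposed. Tracts ≥ 20 bp are hypervariable
**class I**, 12–19 bp **class II** — the conventional boundary for
hypervariable SSR markers; shorter tracts are kept internally as
`sub12` but excluded from marker calling, as are mononucleotide runs.
Compound/interrupted repeats are not modelled: the marker use-case rests
on perfect runs.

Correctness is anchored to an independent brute-force oracle
(enumeration over every start and unit size) on an exhaustive sweep of
all strings up to 10 nt over {A,C} and 8 nt over {A,C,G}, and on seeded
random strings up to 500 nt including N.

## Signal scanning

Element libraries are TSVs of (name, IUPAC consensus, source); repeat
notation like `(GA)8` is expanded on parse. Matching is
exact-degenerate: a consensus letter matches exactly the base set it
denotes, with no mismatch allowance, mirroring the semantics of
PLACE-style signal sequences. A sequence N matches only a consensus N,
so masked regions cannot spawn hits. Both strands are scanned (minus
hits are reported in plus coordinates) and all overlapping occurrences
are kept — marker calling only needs existence-of-overlap, so duplicate
hits are harmless and make the scanner trivially checkable against a
per-position comparison oracle. Position-weight-matrix scoring and
over-representation statistics are out of scope.

The package ships a five-element reference library (GAGA8HVBKN3,
CTRMCAMV35S, RAV1AAT, S1FBOXSORPS1L21, CANBNNAPA); real surveys supply
their own, typically hundreds of elements.

## Conserved non-coding blocks

Conservation is established by an **ungapped seed-and-extend**
comparison of the target upstream sequence with each comparator
ortholog. Parameters: seed length `seed_k = 8`, minimum block length
`min_len = 20` bp, minimum identity `min_identity = 0.70`. These
defaults follow common conserved-non-coding-sequence practice and are
config-exposed; no claim is made that they reproduce any particular
published catalogue.

A reported block is a maximal segment on a shared-seed diagonal that
starts and ends on a match, has overall identity ≥ the threshold, is at
least `min_len` long, and contains ≥ `seed_k` consecutive matches. This
is the fixed point of "extend from the seed while running identity
stays above threshold, then trim trailing mismatches", stated
declaratively so that an exhaustive enumeration oracle is well defined;
the implementation finds the same set with prefix-sum searches.
Overlapping blocks on one diagonal are resolved deterministically:
longer first, then higher identity, then smaller target start.

Two numerical notes. Identity comparisons carry a 1e−9 tolerance so
that exact-fraction thresholds (e.g. 14/20 at 0.70) are not lost to
floating-point rounding. And parameter monotonicity is asymmetric:
raising `min_len` can only remove blocks (tested as a subset property),
but raising `min_identity` can *split* one merged block into two — a
stricter threshold may report more, shorter blocks — so the tests
assert per-block threshold compliance rather than set shrinkage.

Support rule: a species supports a locus only if one of its blocks
**fully contains** the composite interval. Containment rather than
overlap is required because the claim being made is that the element
itself is conserved, not merely nearby sequence. Gapped alignment is
deliberately not modelled: the question "is this locus inside a
conserved segment" does not need indel handling, and ungapped blocks
keep the oracle exact. Orthologs with indels in the conserved region
will be under-detected; that is a stated limitation.

## Marker calling and summaries

One marker is emitted per (SSR, element) pair where at least one hit of
that element intersects the tract by ≥ 1 bp (the weakest faithful
overlap reading; configurable) and the composite has non-empty support.
Multiple hits of one element collapse into the marker with a hit count.
Marker ids are serials assigned in (gene, position) order so reruns are
bit-identical. Every emitted marker re-verifies its three defining
predicates directly from the raw inputs in the test suite.

Positional distributions bin each marker by the midpoint of its
composite interval into 100-bp ATG-relative intervals; the midpoint is
symmetric under strand conventions, unlike the start. Physical marker
density is span/markers in kb to one decimal. Percentages and cM
spacings round half-up (1 and 2 decimals respectively); intermarker
spacing is map length divided by marker count (not count − 1), the
convention under which a summary table's total row equals total length
over total markers.

## Primer design

One primer pair per locus from the flanks of the composite interval,
under hard constraints: product 100–300 bp, primer 18–24 nt, GC 40–60%,
Tm 50–62 °C, 3'-end self-complementarity ≤ 4 nt (longest 3' suffix
whose reverse complement occurs in the primer — a cheap dimer/hairpin
proxy; full thermodynamics out of scope), and template uniqueness of
each annealing site. Tm uses the two-regime convention: Wallace rule
2(A+T) + 4(G+C) below 14 nt, else 64.9 + 41(nG + nC − 16.4)/L.
Printed annealing temperatures in real marker tables come from
bench-side optimisation and are not modelled.

Neither primer may overlap the locus, which yields the property the
markers exist for: expanding the repeat by k units grows the amplicon
by exactly k × unit-size bp (asserted as a test). Among qualifying
pairs the product size closest to the midpoint of the allowed range
wins, with deterministic tie-breaks (smaller product, leftmost forward
primer, shorter primers).

## Marker statistics

Allele frequencies are computed over non-missing fragment-size calls.
PIC uses the Botstein definition,
`1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`, the quantity standard marker-survey
software reports; it is bounded above by expected heterozygosity, with
equality only for monomorphic markers (property-tested). Polymorphism
flags support an optional group contrast (e.g. two market classes of
germplasm): a marker can separate groups while being monomorphic within
each. Haplotypes across the markers of one gene are ordered allele
tuples per individual, valid only for inbred (homozygous) lines;
heterozygous calls are rejected rather than phased.

## Synthetic data: what it does and does not show

`simulate_upstream_set` generates the full input bundle with a truth
table. Backgrounds are i.i.d. nucleotides at GC 0.38 (AT-rich, as plant
promoter regions are); planted composites are exact in the target and
copied into supporting comparator orthologs with i.i.d. point
substitutions at rate 0.05 — safely below 1 − min_identity so planted
blocks stay detectable — never inside the signal core or the segment
edges, so containment survives. Decoys mirror the three predicate
clauses: SSR without element, element without SSR, and composite
without conservation. Each gene is re-drawn (bounded, from the same
seeded stream) until its realised neighbourhood matches its truth
record exactly, so recovery/specificity tests compare against
ground truth rather than probability.

Default study conditions: 12 genes per bundle (4 true composites, 3
decoys, 5 plain), 3 comparator species, 1000-bp windows; the acceptance
benchmark runs 20 such bundles. These sizes exercise every code path
while keeping the whole suite fast; they are three orders of magnitude
below a genome-scale survey, so passing them demonstrates correctness
of the predicate logic, not discovery power on real genomes. Real
promoter evolution (indels, repeat slippage, segmental turnover) is
explicitly not emulated: backgrounds are uncorrelated, conservation is
ungapped, and repeat counts do not mutate. Consequently the 100%
recovery / 0% decoy result is a statement about the pipeline's
soundness and completeness under its own model, not about sensitivity
on diverged genomes.

## Known limitations

* Ungapped conservation misses orthologs whose conserved elements are
  separated by indels.
* Exact-degenerate matching cannot rank partial signal matches; a PWM
  layer would be needed for that.
* Compound and interrupted SSRs are not called.
* Primer screening is combinatorial, not thermodynamic.
* Genome-scale catalogue counts depend on the input genomes and element
  library and are outside what the synthetic bed can certify.
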