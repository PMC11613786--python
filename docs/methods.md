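# Methods

## Coordinates and data model

All in-memory coordinates are 0-based half-open; segment tables and
nomenclature strings use 1-based inclusive coordinates and are converted at
the I/O boundary (the conversion round-trips exactly). A *breakpoint* lives
on the boundary between two bases; its `side` says which flank the
derivative retains: `LEFT` (H) keeps the sequence before the boundary,
`RIGHT` (T) the sequence after it. With the two breakpoints of a junction
sorted by coordinate this yields the four orientation classes HT
(reference-like, deletion-type), TH (tandem-duplication-type) and HH/TT
(the two inversion types). The fixed BEDPE strand mapping is HT→(+,+),
HH→(+,−), TT→(−,+), TH→(−,−); VCF breakends use the standard bracket ALT
encoding and are paired by MATEID. Coordinate sorting can reverse the
derivative order of a junction's endpoints; the `swapped` flag preserves
that order, which matters for insertion orientation (microhomology is
invariant under the reading direction, an inverted templated insert is
not).

A derivative chromosome is a `DerivativeWalk`: an ordered list of oriented
reference intervals, linear or circular. Consecutive steps are joined
either by reference adjacency (abutting coordinates, same orientation) or
by exactly one novel adjacency. Walk equality in tests is up to
normalization (merging reference-adjacent runs), reflection, and — for
rings — rotation, because those readings describe the same molecule.

## Derivative reconstruction

The manual practice of following junction-spanning read evidence is
formalized as graph search. The reference region is partitioned into atoms
at every segment boundary; each atom carries its derivative copy count
(0 for a loss, 1 for retained or inverted material, `cn − 1` for a gain
with total copy number `cn`; from dosage classes: DEL/TELDEL→0, NML/INV→1,
DUP→2). Junction endpoints must coincide with atom boundaries within a
configurable tolerance (default 0, since curated breakpoints are exact;
non-zero tolerance snaps caller-imprecise endpoints and reports the
nearest boundaries on failure).

`assemble_walk` enumerates, by depth-first search, every walk that visits
each atom exactly its copy count and uses each novel edge exactly once,
ending at a chromosome end (linear) or closing on its first step (ring;
the closing join may be the last novel edge or a reference adjacency).
Tie-breaking is deterministic — novel edges before reference continuation,
lower coordinates first — and results are deduplicated up to reflection
and rotation. All consistent walks are returned; more than one marks the
evidence as ambiguous, which is reported rather than resolved by guessing.
The search is capped by a state budget (default 500,000 states) and raises
a structured error naming the violated constraint class when no walk
exists.

Unresolved junction partners terminate a branch into an explicit *gap
step* carrying the known anchor coordinate; traversal resumes through the
paired half-junction and the gap index is reported on the walk. A
gap-opening endpoint is the one junction endpoint allowed off the atom
boundaries.

**Breakpoint counting convention.** Each DEL/DUP/INV row contributes its
two boundaries; boundaries shared by abutting rows are deduplicated, and a
chromosome terminus touched only by deletion-type rows is not counted (a
lost telomeric end is not a junction endpoint, whereas a duplication
reaching the terminus still is). Under this convention the packaged cases
report 12, 8 and 26 breakpoints. Other conventions exist — in particular,
counts that include inversion-internal breakpoints visible only in the
derivative description, not as copy-number rows — so the function takes
the segment table as its explicit unit of evidence.

**Template switches.** The number of novel adjacencies in a walk is
reported as a lower bound on template switches under a replicative model;
a junction inventory can exceed the minimal switch count when independent
evidence (e.g. an unresolved partner) splits one event into two recorded
junctions.

## Nomenclature

The grammar covers the constructs used in derivative descriptions of
intrachromosomal CGRs: `::` and `;` separators, `a_b`, `inv`, `del`,
`delins[...]`, `ins` (bracketed or single-range), `pter`/`qter`,
uncertainty ranges `(lo_hi)` and the unresolved token `?`. Uncertain
positions resolve to the interval midpoint for walk construction (the
range is retained on the AST node) — a convention of this package, chosen
because the midpoint minimizes the maximum coordinate error. Cytoband
`der(...)` strings are stored verbatim, not parsed: band arithmetic would
require an external ideogram table.

Lenient parsing repairs exactly two defect classes, each recorded as a
diagnostic instead of an error: a stray `inv:` separator (read as `inv;`)
and an insertion target whose second coordinate carries one surplus digit
(an insertion target must name two adjacent bases). One packaged case
string exercises both.

**Ring convention.** A parsed derivative whose walk retains neither the
first nor the last reference base is circular: two broken ends without
telomeres are taken to be rescued by ring formation. This matches the ring
case (both termini deleted → circular, 4 junctions counting the closing
join) while leaving derivatives that retain either terminus linear. The
emitter writes rings as `pter_qterdelins[...]`, which re-parses as
circular under the same convention; a hypothetical linear derivative that
lost both telomeres is not representable and triggers a warning.

Emission is canonical: prefix/suffix reference runs become the deletion
target, interior steps the replacement list; a pure insertion uses the
`ins` form, a duplication spanning the join is rewritten as an insertion
of the re-copied piece. `parse(emit(w))` equals `w` after normalization
for every walk the simulator produces (checked on 200 random walks
including rings and gaps).

## Junction signatures

With derivative-oriented sequences — `flank_a` ending at breakpoint 1,
`ref_beyond_a` the reference continuation past it, `flank_b` starting at
breakpoint 2, `ref_beyond_b` the reference run-up to it — microhomology is
`k_left + k_right`: the common suffix of (`flank_a`, `ref_beyond_b`) plus
the common prefix of (`flank_b`, `ref_beyond_a`). This equals the number
of breakpoint placements consistent with the junction, minus one, which is
what the brute-force oracle in the tests enumerates. `N` bases never
match and truncate the comparison with a warning. The default flank window
is 150 nt, comfortably above the largest homology the package models
(79 nt).

Inserted bases are located by exact 20-nt anchors of both flanks inside
the junction-spanning sequence (the reverse-complemented reading is tried
before failing). Classification as TEMPLATED requires at least 10
*matched* bases (query length minus edit distance) at ≥90% identity,
directly or reverse-complemented, inside ±2,000 nt of either breakpoint;
an inverted templated hit adds a `short_inversion` flag and a
homopolymer/short-tandem-repeat insert a `simple_repeat` flag. Requiring
matched bases rather than query length keeps the false-positive rate on
random ≥10 nt inserts below 1% (measured over 1,000 trials). When both an
insert and flanking homology could describe a join, the insert takes
precedence as the category; microhomology is still computed on the
insert-excised flanks and both are reported, with `blunt` meaning neither.
A `flank_similarity` flag marks junctions whose two reference flanks align
at ≥80% identity over 50 nt — a reporting category, not a mechanism.

**Mechanism heuristics** (rule order, first hit wins): a circular walk
with lost terminal ends → ring rescue (named for the recombination-driven
ring mechanism; the rule keys on topology only, since repeat annotation is
out of scope); ≥3 copy-number gains with ≥50% of classified junctions
showing 1–100 nt microhomology or a templated insert → chromoanasynthesis;
≤2 junctions, all blunt or ≤2 nt microhomology → simple end joining; else
unclassified. Evidence strings list each fired rule.

## Parental-origin phasing

Sites pass the filter with QUAL strictly greater than 40 in all three
samples (the conventional genotype-quality cut for this analysis).
Diploid logic annotates the parent of the child's ALT allele when it is
unambiguous (one parent carries the ALT, the other can supply the REF).
Per segment:

* **deletions** tally the single remaining allele's parent from the
  apparent-homozygous child genotype — the rearranged homolog is the
  *other* parent's;
* **diploid/duplicated segments** average per-site paternal support; with
  `use_allelic_depth` each site contributes the child's allele-dosage
  fraction for the informative allele, which sits at 2/3 for the carrier
  parent of a CN=3 duplication and at 1/2 in diploid segments. At the
  genotype level a duplication is invisible, so allelic depth is the
  duplication signal and is used whenever the child VCF carries AD.

The test statistic is a Welch (unequal-variance) two-sided *t*-test on
per-segment paternal-support values, affected (paternal fraction for
gains, maternal fraction for deletions) versus diploid controls, requiring
at least two segments per group. Per-segment fractions are the test unit
because sites within a segment share one phase block and are not
independent. The call is PATERNAL/MATERNAL when p < α (α = 0.05, one test
per case, no multiplicity correction) *and* the group difference exceeds
`min_effect = 0.05`: the smallest real dosage effect is 1/6, so a
statistically significant sub-percent shift is biologically meaningless;
the guard keeps copy-neutral controls INCONCLUSIVE instead of producing
spurious calls at the type-I rate.

## Copy number from depth

Bins are normalized by the genome-median depth (ratio 1.0 at CN=2),
grouped greedily while each bin stays within 0.25 of the running segment
mean, short segments (<3 bins) are absorbed into the closer-mean
neighbour, and CN is `round(2·ratio)` half-up. Defaults suit ≥30×
coverage with bins a few of which span the smallest event; there is no GC
correction — synthetic references are GC-neutral, and on real data a GC
bias would need correcting upstream. Noise-free profiles are recovered
exactly; under Poisson noise at 30× with 1 kb bins, boundaries land within
one bin in ≥95% of seeded runs.

## Simulator

The simulator emits everything the pipeline consumes, deterministic in the
seed, with truth files alongside. Microhomology is planted by mutating the
reference flanks *before* splicing, so both copies genuinely share the
bases and a placement-enumeration oracle agrees; the base adjacent to each
planted run is forced to mismatch so the homology is exactly the requested
length, and the plant is re-verified from the final reference (guarding
against collisions between nearby junctions). Templated inserts are copied
from 300 nt upstream of the first breakpoint (inside the ±2 kb search
window), nontemplated inserts are random sequence re-drawn if it resembles
either window. Unresolved steps splice 500 `N`s. Junction-spanning
sequences are sliced from the derivative itself (±150 nt).

Trio genotypes: half the informative sites carry a paternal ALT, half
maternal; allelic depths are binomial at the true dosage over
Poisson-distributed coverage (30× diploid, 45× in gains); roughly 10% of
sites draw QUAL below the filter to exercise it. Depth profiles are
Poisson read counts at `coverage · cn/2`.

The three named scenarios mirror the structure of the packaged cases at
toy scale — 100–150 kb references rather than the 45 Mb chromosome, which
keeps every test's simulation in seconds while preserving the structural
features under test (junction counts, homology range 0–79 nt, insert
range 4–40 nt, gains, ring topology, one unresolved partner). Phasing
recovery uses 6 affected + 6 control segments at 200 informative sites
per segment, the sampling depth at which the per-segment standard error
(≈0.007 with allelic depths) is far below the 1/6 dosage effect.

## Known limitations

* Intrachromosomal derivatives only; translocation walks across contigs
  are not modeled.
* Ambiguous evidence yields multiple walks by design; the caller must
  choose, as the underlying data would require.
* Repeat-family annotation (and hence sequence-level repeat-mediated
  mechanism evidence) is out of scope; the ring rule is topological.
* The synthetic references are uniform-random: no GC structure, no
  segmental duplications, no satellite arrays. Passing tests therefore
  validate the algorithms' correctness on clean evidence, not robustness
  to alignment artifacts in low-complexity regions, where real acrocentric
  short-arm data are hardest.
* Genotype-level phasing cannot detect duplication origin without allelic
  depth; deletion origin is detectable either way.
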