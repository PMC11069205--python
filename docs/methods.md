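# Methods

## The problem and the model

`aluscan` reconstructs, as testable software, the analysis of two structural
variants in the *EYS* gene: a heterozygous AluYa5 insertion in coding exon 43
and a recurrent ~56.4 kb deletion of exons 32–33. The underlying biology is
target-primed reverse transcription (TPRT): an Alu element integrates as

```
reference:  ... L  [TSD]              R ...
mutant:     ... L  [TSD] [body][A-tail][TSD copy]  R ...
```

so the inserted tract carries the element body, a homopolymer tail (poly-A
on the element strand, poly-T on the opposite strand) and a duplicated copy
of the short reference tract (TSD) immediately 5' of the integration site.
*EYS* is transcribed from the minus strand, so reports can be mirrored onto
the transcript strand (`reporting_strand="minus"`), where the EYS TSD reads
`AACATTGTATCCTTC` and the tail is poly-T.

## Coordinates and fixtures

All public coordinates are 1-based inclusive (HGVS convention); 0-based
half-open arithmetic is internal, and BED input is converted at the
boundary. The study fixture (`synthetic.eys_fixture`) consists of **two
compact loci** rather than one: the insertion site (g.64430524) and the
deletion (g.64764235–64820592) are ~334 kb apart, and nothing in the
analysis couples them on one sequence, so a ~2 kb insertion locus and a
~58.4 kb deletion locus keep every simulation desk-scale. Each locus embeds
the known junction context (`...ATTA|GAAGGATACAATGTT|TATG...` for the
insertion, i.e. the plus-strand TSD ending at g.64430524) inside 1 kb of
seeded-random flank, regenerated until no diagnostic k-mer occurs by chance.

The element body is a bundled **synthetic** 282 bp AluYa5-like consensus
(`data/synthetic_sine_consensus.fasta`) that begins with the canonical Alu
5' bases `GGCCGGGCGCGGTGG`; its companions are a ~18%-diverged AluYb8-like
decoy and an unrelated L1-like fragment, giving the classifier meaningful
competition. It is not the Genbank Alu sequence, so the printed "39 aberrant
amino acids" consequence of the real insert is *not* asserted anywhere; the
coding-consequence routine is instead checked against a direct three-frame
translation oracle. Likewise the fixture insert totals 353 bp
(282 + 56 + 15) as the component lengths dictate, and the HGVS renderer
prints whatever length it is given.

## Decomposition (TSD → tail → body)

1. **TSD**: the longest exact string that is a suffix of both the insert and
   the left reference flank (3' placement of the copy) or a prefix of both
   the insert and the right flank (5' placement); the longer placement wins,
   ties go 3'. Bounds: 5–50 bp (TPRT TSDs are typically 5–20 bp; the EYS one
   is 15). Matching is exact — mismatch tolerance adds ambiguity with no
   benefit at these lengths.

   *Tail-maximal convention.* When the base adjacent to the TSD on the
   insert side is part of the homopolymer tail, the boundary between TSD and
   tail is genuinely ambiguous: at the EYS locus the reference base 5' of
   the TSD is `A` and the insert base 5' of the TSD copy is the tail's `A`,
   so the maximal shared string is 16 bp. Ambiguous homopolymer bases are
   therefore reassigned to the tail (never shrinking the TSD below its
   minimum), which yields the conventional 15 bp TSD / 56 bp tail partition.
2. **Tail**: searched at the insert end adjacent to the detected TSD first
   (the far end as fallback, which is where the tail of a minus-orientation
   element sits). A tail is the longest window anchored at that end whose
   majority base (A or T) makes up ≥ 0.9 of the window and matches both
   endpoint bases; minimum 10 bp. The purity threshold tolerates sequencing
   error while finding a pure 56-mer exactly; the closed-form window
   definition is monotone and has a trivial brute-force oracle.
3. **Body**: the remainder, aligned (global, free end gaps, +1/−1/−2)
   against each library consensus and its reverse complement. Identity is
   matches over alignment columns with the column count floored at the
   shorter sequence length — without the floor, a 10 bp perfect core inside
   an unrelated 600 bp consensus would score 1.0; with it, a truncated
   element aligned exactly within a longer consensus still does. Default
   acceptance identity 0.8.

**Identifiability.** The partition is only well-defined when the flanks and
body do not extend it by coincidence: the decomposition round-trip property
(100 random specs, exact recovery of all three lengths) therefore draws
specs whose reference base before the TSD, insert base after the insertion
point, TSD first base and body terminal bases avoid the ambiguous
coincidences (e.g. the body's last 8 bases exclude the tail base — also true
of the bundled consensus, whose 282 bp body excludes the A-tail by
definition). On real data such coincidences shift a boundary by a base or
two; they cannot be resolved by any algorithm, only by convention.

## Long-read calling

Signatures come only from explicit I/D alignment operations ≥ 30 bp
(separating SVs from indel noise at nanopore error rates); alignment itself
is out of scope and the simulator emits truthful operation lists. Same-kind
signatures within 50 bp merge by single linkage; the call takes the integer
median position and length, support = cluster size, CI = max deviation from
the median, and clusters under 3 reads are dropped. Insert consensus:
medoid by summed edit distance (edlib), then per-column majority polish with
strict-majority gap deletion and strict-majority insertion of bases missing
from the medoid — both rules needed because equal-cost indel placements
correlate across reads inside homopolymers. On error-free reads every
breakpoint equals the construction coordinate with CI 0; with 5% random
substitutions the polished consensus lands within edit distance ~2 of truth.

## Probe design and screening

A characterized insertion has two informative mutant junctions on the plus
strand — reference→body and tail→TSD-copy (the insert-end→reference junction
duplicates reference sequence and is useless) — plus the wild-type site.
Default probes are centered k-mers (k = 23), with a homopolymer-adjacent
side capped at 8 bases; the published EYS probe set used hand-chosen
per-side widths (15+8, 8+14 — a 22-mer — and 19+4), so the designer accepts
explicit per-side splits (`EYS_JUNCTION_SPLITS`) and reproduces those six
sequences verbatim, 22-mers included. Specificity is exact substring
matching of each probe and its reverse complement against the mutant allele,
wild-type allele and background sequences.

Screening mirrors `grep -c` semantics: a read counts once per probe class it
contains; reads matching both classes are conflicts and count for neither.
VAF = mut/(mut+wt). Because two mutant junctions are probed against one
wild-type site, a heterozygote's expected VAF is ~2/3 rather than 1/2; the
default genotype thresholds (min 10 informative reads, min 3 mutant reads,
het at VAF ≥ 0.2, hom at ≥ 0.8) account for this and are fully
configurable — the original screen reported no thresholds since it observed
zero carriers. A single nucleotide of sequencing error defeats a probe;
this sensitivity limit is inherent to exact matching and shared with the
grep pipeline the module reproduces.

## Soft-clip evidence

Clips shorter than 8 bp are ignored; boundaries within 10 bp of the locus
group by (position, side); fully soft-clipped reads have no anchor and are
excluded. The clipped consensus is per-column majority anchored at the
junction side; agreement with the expected insert end requires ≥ 90%
identity over the shorter length. The clipped percentage is reported
rounded to the nearest integer (76/449 → 17%). Coverage drop uses fixed
windows — mean M-op depth over ±25 bp of the junction versus two 100 bp
windows 200 bp away — to make a qualitative statement reproducible.

## Pedigree phase and STR sharing

Phase is inferred by exhaustive enumeration of haplotype-content assignments
(each haplotype a subset of the two variants) consistent with the genotypes
and Mendelian transmission; the result is `cis`/`trans` only when every
consistent assignment agrees, `unknown` otherwise, with a conflict flag when
no assignment exists. De novo events and intragenic recombination are not
modelled. Enumeration is exponential in pedigree size but exact and
instantaneous at family scale; the test oracle is an independently coded
flat enumeration.

STR sharing is identity-by-state: a marker is shared when one allele value
occurs in every carrier's genotype; the reported interval is the maximal run
of consecutive shared markers containing the marker nearest the anchor
(default: the deletion midpoint), with bp length the span between the run's
first and last markers, plus extended intervals over family subsets. No IBD
probability model is attempted. The eight default marker positions
(D6S1573…D6S1681, spanning ~12.6 Mb of chr6 around *EYS*) are synthetic
placeholders chosen once for realistic spacing; the published interval sizes
are figure-derived and are never used as test values.

## Synthetic data: what it does and does not emulate

The simulator draws reads uniformly from the two haplotypes of a genotype,
computes truthful alignment operations against the wild-type reference
(I for spanning reads, S for junction-partial reads, D across the deletion),
injects substitution-only errors, and writes FASTQ with constant "I"
qualities (no stage uses base quality). Long mode draws lengths uniformly
in [½·L, 1½·L]. It does not emulate nanopore error profiles (indel-heavy,
homopolymer-biased), mapping ambiguity, chimeras, coverage biases, or
adaptive-sampling enrichment; passing tests therefore demonstrate the
correctness of the algorithms under their stated models, not robustness to
every artifact of real sequencing. Cohort and read simulations are
deterministic per seed, with per-sample seeds derived from the cohort seed.

## Problem sizes

Default test and acceptance runs use ~200 simulated long reads (depth 10,
3 kb reads) for the 58 kb deletion locus, depth 30 × 1 kb reads for the 2 kb
insertion locus, a 327-sample depth-5 cohort for the non-carrier screen and
depth-30 cohorts for carrier recovery, 100 random specs for the
decomposition round trip, and nuclear pedigrees up to 6 members for the
phase oracle. These sizes were chosen so the entire suite runs in seconds
while every statistic is computed from non-trivial data.
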