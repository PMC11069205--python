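# aluscan

Mobile-element insertions (MEIs) are a recurrent blind spot of short-read
diagnostic sequencing: an Alu retrotransposon landing in a coding exon breaks
read alignment at the junctions, so standard pipelines often call nothing at
all. `aluscan` is a toolkit for the complete workflow around one such
scenario in the *EYS* gene — a major gene of autosomal recessive retinitis
pigmentosa — where a heterozygous AluYa5 insertion in coding exon 43
(chr6(GRCh37):g.64430524_64430525ins) occurs in compound heterozygosity with
a recurrent ~56.4 kb deletion of exons 32–33
(g.64764235_64820592del). It is written for genome diagnosticians and
method developers who want each step of that analysis as a tested, reusable
program rather than a one-off shell pipeline.

## What it does

* **Insertion decomposition** (`aluscan.mei`): partitions an insertion call
  into the anatomy created by target-primed reverse transcription — a
  target-site duplication (TSD) `s` that is simultaneously a suffix of the
  reference flank and of the insert, a poly-A/T tail detected as the maximal
  end-anchored window with base purity ≥ 0.9, and the element body, which is
  classified against a consensus library by free-end-gap alignment
  (match +1, mismatch −1, gap −2; identity = matches / columns). Reports an
  HGVS-like description and an optional coding consequence (aberrant residues
  before the first premature stop).
* **Long-read SV calling** (`aluscan.lrs`): per-read I/D signatures from
  explicit alignment operations, single-linkage clustering within a window
  (call = median breakpoint/length, CI = max deviation), medoid +
  majority-vote consensus of inserted sequences, and RepeatMasker-style BED
  annotation of breakpoint context.
* **Probe design and cohort screening** (`aluscan.probes`,
  `aluscan.screen`): allele-diagnostic junction k-mers for both mutant
  junctions and the wild-type site (plus reverse complements), exact
  substring specificity checking, grep-equivalent pattern emission, and
  streaming FASTQ/SAM screening with VAF = mut/(mut+wt) and threshold-based
  genotype calls.
* **Soft-clip evidence** (`aluscan.softclip`): clip clustering at a locus,
  clipped-base majority consensus vs the expected insert ends, clipped-read
  percentage and junction coverage drop.
* **Segregation and linkage** (`aluscan.linkage`): cis/trans phase of two
  variants by exhaustive enumeration of pedigree-consistent haplotype
  assignments, recessive-segregation checking, and identity-by-state STR
  haplotype sharing across carrier families for founder assessment.
* **Synthetic data** (`aluscan.synthetic`): rebuilds the study alleles from
  their printed junction context (TSD `AACATTGTATCCTTC` on the transcript
  strand, 282 bp AluYa5-like body, 56 bp tail) and simulates long/short
  reads, screening cohorts and STR family tables, so the whole pipeline runs
  and is tested without any external data.

## Worked example

```python
from aluscan import synthetic, mei, lrs

fx = synthetic.eys_fixture()
pair = synthetic.build_alleles(fx.insertion_locus, fx.insertion)

reads = synthetic.simulate_reads(pair, "ref/mut", depth=30, read_len=1000,
                                 mode="long", seed=7)
calls = lrs.cluster_signatures(lrs.collect_signatures(reads))
call = next(c for c in calls if c.kind == "INS")
print(f"INS at g.{call.insert_after}, length {call.length}, support {call.support}")

a = fx.insertion.insert_after - fx.insertion_locus.ref_offset + 1
icall = mei.InsertionCall(call.insert_after, call.consensus_insert,
                          pair.wt[:a], pair.wt[a:])
report = mei.decompose_insertion(icall, synthetic.load_consensus_library(),
                                 reporting_strand="minus")
print(f"body {report.body_len} bp ({report.family}, identity {report.body_identity:.2f}), "
      f"poly-{report.tail_base} {report.tail_len} bp, TSD {report.tsd_len} bp "
      f"({report.tsd_sequence})")
```

prints

```
INS at g.64430524, length 353, support 15
body 282 bp (AluYa5_synthetic, identity 1.00), poly-T 56 bp, TSD 15 bp (AACATTGTATCCTTC)
```

i.e. fifteen simulated long reads support an insertion after g.64430524 whose
consensus decomposes, on the transcript strand, into a full-length
AluYa5-like body, a 56 bp poly-T tail and the 15 bp duplication of exon 43
sequence. Probe design on the same allele emits the screening command

```
zgrep -c "GAAGGATACAATGTTGGCCGGGC\|GCCCGGCCAACATTGTATCCTTC\|AAAAAAAAGAAGGATACAATGT\|ACATTGTATCCTTCTTTTTTTT" *fastq.gz
```

The same stages are available as a CLI: `aluscan simulate | characterize |
design-probes | screen | softclip | linkage` (see `aluscan --help`).

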