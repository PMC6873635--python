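# mlstkit

Multi-locus sequence typing (MLST) from short sequencing reads, without
whole-genome assembly.

MLST types a bacterial isolate by the allele variants it carries at a small
set of housekeeping loci (typically seven); each unique combination of
allele numbers defines a sequence type (ST).  Given an isolate's FASTQ
read set, a per-locus allele FASTA database and an ST profile table (the
PubMLST file conventions), `mlstkit`:

1. **recruits** reads per locus by their *perfect-match fraction* — the
   longest exact run of the read (either strand) found in any known allele,
   divided by read length — into four nested tiers (all mapped / ≥ 30 % /
   ≥ 60 % / ≥ 90 %);
2. **assembles** each tier at multiple k-mer sizes (k = 11, 15, 21, 33, 35)
   with an internal de Bruijn assembler, no read error correction, plus a
   greedy-overlap backup assembler;
3. **calls** each locus by exact full-length comparison of contigs against
   the reference: an allele number, a novel allele (`New?`, with the
   reconstructed sequence written to `new_alleles/`), or `low coverage`;
4. **assigns** the ST from the profile table (`ST`, `new`, or `ND`);
5. **evaluates** typing performance with three benchmark metrics —
   percentage of no-output, capability to identify correct alleles
   (predictions vs. truth on the full database), and capability to identify
   new alleles (predictions against a leave-correct-allele-out database).

A fully seeded synthetic-data module generates allele databases, profile
tables, isolate genomes (alleles embedded in k-mer-disjoint background) and
paired-end read sets, so everything is testable offline.  See
`docs/methods.md` for the model, parameter rationale and limitations.

Intended users: bioinformaticians typing bacterial isolates from WGS runs,
and method developers who need a transparent, dependency-light MLST caller
whose every step is property-testable.

## Worked example

Generate a three-sample synthetic benchmark, type it, and score it:

```bash
mlstkit simulate --out-dir demo --n-samples 3 --seed 42
mlstkit batch --reads-dir demo/reads --db-dir demo/db \
              --profile demo/profiles.tsv --out-dir demo/out
```

which prints the report table (also written to `demo/out/report.tsv`):

```text
sample	abcZ	adk	aroE	fumC	gdh	pdhC	pgm	ST
sample000	7	1	2	2	1	8	5	14
sample001	4	2	4	3	7	7	4	19
sample002	8	1	4	3	6	9	1	11
```

Each locus column holds the called allele number (`New?` would mark a
putative novel allele, `low coverage` an unresolvable locus); the ST column
is the profile-table lookup of the seven-allele combination.  Here all
three samples reproduce their simulated truth (`demo/truth.tsv`).

Scoring against the truth — including the leave-correct-allele-out re-run
that measures new-allele detection:

```bash
mlstkit evaluate --reads-dir demo/reads --db-dir demo/db \
                 --profile demo/profiles.tsv --truth demo/truth.tsv \
                 --out-dir demo/eval
```

```text
alleles	pct_no_output	0.0%
alleles	capability_correct	100.0%
alleles	capability_new	100.0%
st	pct_no_output	0.0%
st	capability_correct	100.0%
st	capability_new	100.0%
```

`capability_correct` is the fraction of locus calls equal to the true
allele number; `capability_new` is the fraction flagged `New?` when each
sample's true alleles were removed from the reference before calling.

The same functionality is available as a library (`mlstkit.call_sample`,
`mlstkit.run_benchmark`, `mlstkit.simulate.make_benchmark`, ...).

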