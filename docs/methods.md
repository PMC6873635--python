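# Methods

`mlstkit` assigns multi-locus sequence types (MLST) to bacterial isolates
directly from short-read data, using a hybrid of read mapping and assembly:
instead of assembling the whole genome and querying it, it assembles only
the reads that belong to each typing locus.  This note documents the model,
its parameters, the numerical choices, and what the synthetic benchmark
does and does not demonstrate.

## Pipeline model

For each sample the FASTQ files are merged into a single read collection;
pairing information is deliberately ignored (locus-scale assembly gains
nothing from insert-size constraints at typical MLST locus lengths of
400–600 bp).

**Read recruitment.**  For every locus, each read is scored by its
*perfect-match fraction*: the length of the longest substring of the read
— on either strand — that occurs exactly in any known allele of the locus,
divided by the read length.  Scoring only the longest mismatch-free run
makes the score insensitive to non-matching read ends, the same effect
soft clipping has in local alignment, without a scoring aligner: the
computation is a suffix-automaton traversal and is exactly verifiable
against a brute-force longest-common-substring enumeration.  Reads whose
run reaches the seed length (default 20 bp) form the base tier ("all
mapped"); nested sub-tiers keep reads matching at least 30 %, 60 % and
90 % of their length (thresholds inclusive).  The stringent tiers exist
because reads straddling a locus boundary carry flanking genomic sequence,
and assembling them freely can produce chimeric contigs; demanding that
most of the read match the reference suppresses such border reads.

**Targeted assembly.**  Each tier is assembled independently at k = 11,
15, 21, 33 and 35 with an edge-centric de Bruijn graph.  No read error
correction is performed; the only noise filter is the minimum k-mer
multiplicity `min_count` (default 2, relaxed to 1 for tiers with fewer
than 50 reads, where every observation matters and chimera risk is low).
Unitigs — maximal non-branching paths — are reported once each on the
lexicographically smaller strand.  Short dead-end side branches ("tips",
length < 2k and mean multiplicity below `min_tip_count` = 3) are pruned;
isolated short paths are kept, since they may be a weak locus's only
signal.  Bubbles are never popped: a bubble is genuine evidence of mixed
or divergent sequence and must surface as non-matching contigs rather
than be averaged away.  A greedy maximal-exact-overlap merger (minimum
overlap 25 bp) acts as a backup assembler when the graph yields nothing
from a non-empty read set.

**Allele calling.**  Tiers are evaluated most-stringent-first (0.90 →
0.60 → 0.30 → all), and within a tier largest k first; the loop stops at
the first decisive exact match.  Because the tier filters admit reads
overhanging the locus by up to (1 − threshold) of their length, assembled
unitigs routinely carry a few bases of genomic flank whose coverage is
comparable to the allele's own terminal k-mers — no coverage rule can trim
them.  Contigs are therefore compared to the reference by *infix
alignment* (edlib, both strands): each allele is aligned inside the
contig and the spanned substring excised as a candidate.

* A candidate at edit distance 0 means the allele occurs verbatim, full
  length, inside the contig — the same criterion a nucleotide-BLAST
  perfect match expresses — and yields an **exact** call (the excised
  candidate is re-verified by string equality).  If two distinct alleles
  are contained verbatim the call is ambiguous and not made.
* If no tier yields an exact match, candidates at small positive distance
  (at most 35 % of the anchor allele's length) and at least half the
  locus's shortest allele length are ranked by edit distance to their
  closest reference allele, then tier stringency, then k, then length,
  then lexicographically, and the best becomes the **novel-allele**
  sequence (`New?` in reports).  Distance-first ranking matters: under
  leave-one-out the stringent tiers fragment at the divergent positions,
  and the full-length reconstruction (distance = the true divergence)
  must beat those fragments (distance ≈ missing length).
* When the aligned region's boundaries are ambiguous (a substitution at
  the very end of an allele can be scored equally as an end indel), a
  same-length window with equal or better substitution-only distance is
  preferred, keeping the excised sequence in register with the reference.
* No recruited reads, or no contig anywhere, is reported as
  **low coverage**; **no output** is reserved for internal faults, which
  are contained per locus.

**ST assignment.**  All-exact calls whose allele tuple appears in the
profile table give the known ST; a fully resolved sample with an unseen
tuple or any novel allele is a novel combination (`new`); any unresolved
locus makes the sample incomplete (`ND`).

## Benchmark metrics

Three fractions are computed over predictions against a known truth:
percentage of no-output (blank or low-coverage labels over all labels);
capability to identify correct alleles (labels equal to the true allele
number, predictions against the full database; blanks are misses and stay
in the denominator); and capability to identify new alleles (labels
flagging novelty when predictions were made against a reference lacking
each sample's true alleles; naming any remaining allele is a miss).  The
same fractions are computed at ST level, where a hit needs the whole
combination.  Starred labels emitted by mapping-based tools
(``allele*`` = closest allele with ≥ 1 mismatch) are scored under two
stringencies: *high* reads the star as a new-allele flag, *low* ignores
it.  Low-coverage labels assert no allele and flag no novelty, so they
count as blanks for all three metrics.

## Synthetic data

The generator emulates one isolate's WGS experiment at desk scale:

| parameter | default | rationale |
| --- | --- | --- |
| loci | 7 (abcZ, adk, aroE, fumC, gdh, pdhC, pgm) | classic seven-gene scheme |
| alleles per locus | 10 | founder + 1–5-SNP derivatives: realistic within-locus similarity |
| allele length | 400–600 bp | typical MLST locus size |
| background genome | 20 kb | ~40× the targeted sequence; enough flank and off-target mass to exercise recruitment specificity at desk scale |
| coverage | 30× | comfortably above the ~20× where locus ends stay covered |
| read length / insert | 100 bp, 300 ± 30 | common short-read geometry |
| error rate | 0 (substitutions only when > 0) | benchmark conditions are error-free; substitution-only errors exercise exactly the multiplicity filter, the pipeline's only error handling |

The background is rejection-sampled to share no seed-length k-mer (either
strand) with any allele, so off-target recruitment is zero by construction
and specificity tests are airtight.  Allele insertion points keep a 1 kb
margin from the ends of the linear background and 200 bp from each other:
fragments are sampled wholly inside the sequence, so a locus flush against
an end would see artificially collapsing coverage that no chromosomal
locus exhibits.  Alleles are embedded in random orientation and positions
are recorded.

What passing these benchmarks does **not** show: robustness to real error
profiles (quality-dependent, indel-bearing), coverage bias, contamination,
paralogous loci sharing k-mers with the scheme, or within-sample mixtures.
The leave-one-out protocol also guarantees a close relative (1–5 SNPs) of
every removed allele remains in the database; novel-allele excision
anchors on the closest remaining allele and will degrade as that distance
grows.

## Problem sizes and numerical choices

The shipped test suite and the reproduction script use 50-sample
benchmarks (350 locus calls) for the recovery experiments and 60 mutant
samples (50 single-SNP, 10 with a 3 bp deletion; indels placed ≥ 20 bp
from the allele ends, where excision boundaries are well defined) —
sizes chosen so the whole suite re-runs in minutes on one CPU while every
fraction retains a 1/350-level resolution.  All randomness flows from
explicit integer seeds through `numpy.random.Generator`; derived
per-sample seeds stay below 2³¹.  Ties are broken deterministically
everywhere (forward orientation, lowest allele id, lexicographic
sequences), recruitment sets are sorted by read id, and k-mer counting is
order-independent, so results are byte-identical across read input order
and worker counts.

## Known limitations

* Exact calling requires the allele to be reconstructed verbatim; a
  single uncorrected sequencing-error k-mer surviving `min_count` inside
  a low-coverage locus can break a unitig and demote an exact call to
  low coverage or a fragment-based novel call.
* Novel alleles with no reference within ~35 % edit distance are not
  excised and are reported, at best, as untrimmed contigs or low
  coverage.
* The greedy backup assembler is quadratic in read count; it only runs
  when the de Bruijn graph fails, which at sane coverages means tiny
  read sets.
* PubMLST download is stubbed; databases must be provided as files or
  generated synthetically.
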