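"""Synthetic MLST data: allele databases, genomes, and simulated read sets.

Everything the pipeline consumes can be generated here, fully seeded, so the
whole package is testable without network access.  The generator emulates a
bacterial isolate's sequencing experiment at desk scale:

* a scheme of housekeeping loci whose alleles are single-nucleotide variants
  of a founder sequence (realistic within-locus similarity);
* a profile table of random allele combinations with unique STs;
* a sample genome — random background with the chosen allele embedded per
  locus at a random position and orientation, the background
  rejection-sampled to share no seed-length k-mer with any allele so that
  read recruitment has zero off-target signal by construction;
* paired-end reads with uniform start positions, a fixed-insert model and
  independent per-base substitution errors (no simulated indels: the
  assembler performs no read correction, so the multiplicity filter is the
  only error handling, and substitution-only errors exercise exactly that).

What this does *not* emulate: platform-specific quality profiles, coverage
bias, contamination, or within-sample mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .db import Allele, AlleleDatabase, Locus, ProfileTable, write_allele_fasta, write_profile_table
from .dna import revcomp
from .recruit import Read

__all__ = [
    "SimulationConfig",
    "Sample",
    "Benchmark",
    "generate_allele_db",
    "build_sample_genome",
    "simulate_reads",
    "mutate_allele",
    "make_benchmark",
    "make_mutant_benchmark",
    "write_benchmark",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))

#: locus names of a classic seven-gene scheme; extra loci get generic names
_SCHEME_NAMES = ("abcZ", "adk", "aroE", "fumC", "gdh", "pdhC", "pgm")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the benchmark conditions used throughout the test suite:
    seven 400-600 bp loci, 30-fold coverage of error-free 100 bp paired
    reads on a 20 kb background genome.
    """

    n_loci: int = 7
    alleles_per_locus: int = 10
    allele_length_range: tuple[int, int] = (400, 600)
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0
    insert_size: int = 300
    insert_sd: float = 30.0
    background_length: int = 20_000
    seed_length: int = 20
    n_profiles: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("need >= 1 locus and >= 2 alleles per locus")


@dataclass(frozen=True)
class Sample:
    """One synthetic isolate: reads plus its ground truth."""

    sample_id: str
    reads1: tuple[Read, ...]
    reads2: tuple[Read, ...]
    true_alleles: Mapping[str, int]
    true_st: int
    #: for mutant samples: locus -> engineered novel sequence
    mutated: Mapping[str, str] | None = None


@dataclass(frozen=True)
class Benchmark:
    db: AlleleDatabase
    profiles: ProfileTable
    samples: tuple[Sample, ...]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _locus_names(n: int) -> list[str]:
    if n <= len(_SCHEME_NAMES):
        return list(_SCHEME_NAMES[:n])
    return list(_SCHEME_NAMES) + [f"locus{i}" for i in range(len(_SCHEME_NAMES) + 1, n + 1)]


def _snp_variant(rng: np.random.Generator, seq: str, n_snps: int) -> str:
    positions = rng.choice(len(seq), size=n_snps, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def generate_allele_db(config: SimulationConfig) -> tuple[AlleleDatabase, ProfileTable]:
    """Generate a scheme: per locus a founder allele plus 1-5-SNP derivatives,
    and a profile table of unique random allele combinations."""
    rng = np.random.default_rng(config.seed)
    names = _locus_names(config.n_loci)
    loci: dict[str, Locus] = {}
    lo, hi = config.allele_length_range
    for name in names:
        length = int(rng.integers(lo, hi + 1))
        founder = _random_dna(rng, length)
        seqs = [founder]
        seen = {founder}
        while len(seqs) < config.alleles_per_locus:
            variant = _snp_variant(rng, founder, int(rng.integers(1, 6)))
            if variant not in seen:
                seen.add(variant)
                seqs.append(variant)
        loci[name] = Locus(
            name, [Allele(name, i + 1, s) for i, s in enumerate(seqs)]
        )
    rows: dict[tuple[int, ...], int] = {}
    st = 1
    while len(rows) < config.n_profiles:
        key = tuple(int(rng.integers(1, config.alleles_per_locus + 1)) for _ in names)
        if key not in rows:
            rows[key] = st
            st += 1
    db = AlleleDatabase(loci=loci, schema=names)
    return db, ProfileTable(schema=names, rows=rows)


def _background(
    rng: np.random.Generator, length: int, forbidden: set[str], k: int
) -> str:
    """Random DNA sharing no k-mer (either strand handled by caller) with
    the forbidden set; offending windows are resampled."""
    seq = _random_dna(rng, length)
    for _ in range(60):
        bad = [
            i for i in range(len(seq) - k + 1) if seq[i : i + k] in forbidden
        ]
        if not bad:
            return seq
        chars = list(seq)
        for i in bad:
            for j in range(i, i + k):
                chars[j] = str(_BASES[rng.integers(0, 4)])
        seq = "".join(chars)
    raise RuntimeError("could not sample background free of allele k-mers")


def _assemble_genome(
    rng: np.random.Generator,
    seq_by_locus: Mapping[str, str],
    background_length: int,
    seed_length: int,
    forbidden: set[str],
) -> tuple[str, dict[str, tuple[int, int, str]]]:
    names = list(seq_by_locus)
    if background_length <= 0:
        # degenerate layout: alleles joined by 1 kb random spacers
        background_length = 1000 * (len(names) + 1)
        cuts = [1000 * (i + 1) for i in range(len(names))]
    else:
        # keep loci away from the (linear) genome ends, where fragment
        # sampling cannot reach full depth, and apart from each other;
        # a chromosomal locus always has flanking sequence on both sides
        margin, gap = 1000, 200
        span = background_length - 2 * margin - (len(names) - 1) * gap
        if span < len(names):
            raise ValueError(
                "background too short to embed all loci with end margins"
            )
        offsets = sorted(
            int(c) for c in rng.choice(span, size=len(names), replace=False)
        )
        cuts = [margin + off + i * gap for i, off in enumerate(offsets)]
    bg = _background(rng, background_length, forbidden, seed_length)
    pieces: list[str] = []
    positions: dict[str, tuple[int, int, str]] = {}
    prev = 0
    offset = 0
    for name, cut in zip(names, cuts):
        pieces.append(bg[prev:cut])
        offset += cut - prev
        seq = seq_by_locus[name]
        strand = "+" if rng.random() < 0.5 else "-"
        embedded = seq if strand == "+" else revcomp(seq)
        pieces.append(embedded)
        positions[name] = (offset, offset + len(seq), strand)
        offset += len(seq)
        prev = cut
    pieces.append(bg[prev:])
    return "".join(pieces), positions


def build_sample_genome(
    db: AlleleDatabase,
    chosen: Mapping[str, int],
    background_length: int = 20_000,
    seed: int = 0,
    seed_length: int = 20,
) -> tuple[str, dict[str, tuple[int, int, str]]]:
    """Embed the chosen alleles into a random background genome.

    Each allele is inserted at a random non-overlapping position in random
    orientation.  The background is guaranteed to share no ``seed_length``-mer
    with any allele of the database (both strands), so off-target read
    recruitment is impossible by construction.  Returns the genome and the
    recorded (start, end, strand) of each locus.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for name, allele_id in chosen.items():
        allele = db.locus(name).get(allele_id)
        if allele is None:
            raise ValueError(f"no allele {name}_{allele_id} in database")
        seqs[name] = allele.sequence
    forbidden: set[str] = set()
    for locus in db.loci.values():
        forbidden |= locus.kmer_set(seed_length)
    return _assemble_genome(rng, seqs, background_length, seed_length, forbidden)


def simulate_reads(
    genome: str, config: SimulationConfig, seed: int = 0
) -> tuple[list[Read], list[Read]]:
    """Paired-end reads at the configured coverage (insert ~ N(size, sd)).

    Mate 1 is the fragment's leading strand, mate 2 the reverse complement
    of its trailing end.  Substitution errors are drawn independently per
    base at ``error_rate``; qualities are constant placeholders.  Byte-level
    deterministic for a fixed seed.
    """
    rl = config.read_length
    if rl >= len(genome):
        raise ValueError("read_length must be smaller than the genome")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(config.coverage * len(genome) / (2 * rl)))
    reads1: list[Read] = []
    reads2: list[Read] = []
    qual = "I" * rl
    for i in range(n_pairs):
        insert = int(round(rng.normal(config.insert_size, config.insert_sd)))
        insert = max(rl, min(insert, len(genome)))
        start = int(rng.integers(0, len(genome) - insert + 1))
        fragment = genome[start : start + insert]
        r1 = fragment[:rl]
        r2 = revcomp(fragment[-rl:])
        if config.error_rate > 0:
            r1 = _add_errors(rng, r1, config.error_rate)
            r2 = _add_errors(rng, r2, config.error_rate)
        reads1.append(Read(f"sim_{i}/1", r1, qual))
        reads2.append(Read(f"sim_{i}/2", r2, qual))
    return reads1, reads2


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if not n_err:
        return seq
    chars = list(seq)
    for p in rng.choice(len(seq), size=n_err, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def mutate_allele(
    allele: Allele | str,
    n_snps: int = 0,
    indel: tuple[int, int, str] | None = None,
    seed: int = 0,
    avoid: Sequence[str] = (),
) -> str:
    """Engineer a novel allele: apply SNPs and/or one indel to a sequence.

    ``indel`` is ``(position, length, "ins"|"del")``.  The result is
    guaranteed to differ from the input and from every sequence in
    ``avoid`` (SNP positions are resampled on collision); an unavoidable
    collision raises.
    """
    seq = allele if isinstance(allele, str) else allele.sequence
    rng = np.random.default_rng(seed)
    taboo = set(avoid) | {seq}
    for _ in range(100):
        out = seq
        if indel is not None:
            pos, length, kind = indel
            if not (0 <= pos <= len(out)):
                raise ValueError(f"indel position {pos} outside sequence")
            if kind == "del":
                if pos + length > len(out):
                    raise ValueError("deletion runs off the sequence end")
                out = out[:pos] + out[pos + length :]
            elif kind == "ins":
                out = out[:pos] + _random_dna(rng, length) + out[pos:]
            else:
                raise ValueError("indel type must be 'ins' or 'del'")
        if n_snps:
            out = _snp_variant(rng, out, n_snps)
        if out not in taboo:
            return out
        if n_snps == 0 and indel is not None and indel[2] == "del":
            raise RuntimeError("deletion collides with an existing sequence")
    raise RuntimeError("could not generate a collision-free mutant")


def _derive_seed(seed: int, *salt: int) -> int:
    """Mix a base seed with salt integers; stays below 2**31."""
    h = seed & 0x7FFFFFFF
    for s in salt:
        h = (h * 1_000_003 + s + 12_345) % 2_147_483_647
    return h


def make_benchmark(
    config: SimulationConfig, n_samples: int, seed: int | None = None
) -> Benchmark:
    """A full synthetic benchmark: database, profiles, and typed samples.

    Each sample's truth is a row of the profile table; reads are simulated
    from a genome embedding exactly those alleles.
    """
    seed = config.seed if seed is None else seed
    db, profiles = generate_allele_db(replace(config, seed=_derive_seed(seed, 1)))
    rows = sorted(profiles.rows.items(), key=lambda kv: kv[1])
    rng = np.random.default_rng(_derive_seed(seed, 2))
    samples: list[Sample] = []
    for i in range(n_samples):
        key, st = rows[int(rng.integers(0, len(rows)))]
        chosen = dict(zip(profiles.schema, key))
        genome, _ = build_sample_genome(
            db,
            chosen,
            background_length=config.background_length,
            seed=_derive_seed(seed, 3, i),
            seed_length=config.seed_length,
        )
        r1, r2 = simulate_reads(genome, config, seed=_derive_seed(seed, 4, i))
        samples.append(
            Sample(f"sample{i:03d}", tuple(r1), tuple(r2), chosen, st)
        )
    return Benchmark(db=db, profiles=profiles, samples=tuple(samples))


def make_mutant_benchmark(
    config: SimulationConfig,
    n_snp_samples: int,
    n_indel_samples: int = 0,
    indel_length: int = 3,
    seed: int | None = None,
) -> Benchmark:
    """Samples each carrying one engineered novel allele at a random locus.

    SNP mutants differ from their parent allele by one substitution; indel
    mutants carry one deletion of ``indel_length`` bases placed away from
    the allele ends.  The mutated sequence is recorded per sample so novel
    calls can be compared to it exactly.
    """
    seed = config.seed if seed is None else seed
    db, profiles = generate_allele_db(replace(config, seed=_derive_seed(seed, 1)))
    rows = sorted(profiles.rows.items(), key=lambda kv: kv[1])
    rng = np.random.default_rng(_derive_seed(seed, 5))
    samples: list[Sample] = []
    forbidden: set[str] = set()
    for locus in db.loci.values():
        forbidden |= locus.kmer_set(config.seed_length)
    total = n_snp_samples + n_indel_samples
    for i in range(total):
        key, st = rows[int(rng.integers(0, len(rows)))]
        chosen = dict(zip(profiles.schema, key))
        target = profiles.schema[int(rng.integers(0, len(profiles.schema)))]
        locus = db.locus(target)
        parent = locus.get(chosen[target])
        assert parent is not None
        existing = [a.sequence for a in locus.alleles]
        mseed = _derive_seed(seed, 6, i)
        if i < n_snp_samples:
            mutant = mutate_allele(parent, n_snps=1, seed=mseed, avoid=existing)
        else:
            pos = int(rng.integers(20, len(parent.sequence) - 20 - indel_length))
            mutant = mutate_allele(
                parent, indel=(pos, indel_length, "del"), seed=mseed, avoid=existing
            )
        seqs = {n: db.locus(n).get(a).sequence for n, a in chosen.items()}
        seqs[target] = mutant
        genome, _ = _assemble_genome(
            np.random.default_rng(_derive_seed(seed, 7, i)),
            seqs,
            config.background_length,
            config.seed_length,
            forbidden,
        )
        r1, r2 = simulate_reads(genome, config, seed=_derive_seed(seed, 8, i))
        samples.append(
            Sample(
                f"mutant{i:03d}", tuple(r1), tuple(r2), chosen, st,
                mutated={target: mutant},
            )
        )
    return Benchmark(db=db, profiles=profiles, samples=tuple(samples))


def write_fastq(reads: Sequence[Read], path: str | Path, compress: bool | None = None) -> Path:
    """Write reads as FASTQ; gzip when the path ends in .gz (or compress=True)."""
    import gzip as _gzip

    path = Path(path)
    use_gz = compress if compress is not None else str(path).endswith(".gz")
    opener = _gzip.open if use_gz else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")
    return path


def write_benchmark(
    benchmark: Benchmark, out_dir: str | Path, compress: bool = True
) -> dict[str, Path]:
    """Materialize a benchmark on disk in the pipeline's input conventions.

    Layout: ``db/<locus>.fasta``, ``profiles.tsv``, ``reads/<sample>_{1,2}.fastq[.gz]``
    and ``truth.tsv`` (columns ``sample``, one per locus, ``ST``).
    """
    out_dir = Path(out_dir)
    db_dir = out_dir / "db"
    reads_dir = out_dir / "reads"
    db_dir.mkdir(parents=True, exist_ok=True)
    reads_dir.mkdir(parents=True, exist_ok=True)
    for name in benchmark.db.schema:
        write_allele_fasta(benchmark.db.loci[name], db_dir / f"{name}.fasta")
    profile_path = out_dir / "profiles.tsv"
    write_profile_table(benchmark.profiles, profile_path)
    ext = ".fastq.gz" if compress else ".fastq"
    for sample in benchmark.samples:
        write_fastq(sample.reads1, reads_dir / f"{sample.sample_id}_1{ext}")
        write_fastq(sample.reads2, reads_dir / f"{sample.sample_id}_2{ext}")
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample\t" + "\t".join(benchmark.db.schema) + "\tST\n")
        for sample in benchmark.samples:
            cells = [str(sample.true_alleles[n]) for n in benchmark.db.schema]
            fh.write(sample.sample_id + "\t" + "\t".join(cells) + f"\t{sample.true_st}\n")
    return {
        "db_dir": db_dir,
        "profile_path": profile_path,
        "reads_dir": reads_dir,
        "truth_path": truth_path,
    }
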