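"""Read recruitment: select reads per locus by perfect-match fraction.

Input FASTQ files are merged into one read collection, pairing deliberately
ignored.  For each locus, a read's *match fraction* is the length of the
longest substring of the read (on either strand) that occurs exactly in any
reference allele of the locus, divided by the read length.  Reads whose
longest exact run reaches the seed length (default 20 bp) form the base tier
("all mapped reads"); three nested sub-tiers keep reads matching at least
30, 60 and 90 % of their length.  Assembling the stringent tiers first keeps
border reads — which run off the locus into flanking genome — from seeding
chimeric contigs.

Exact-substring search replaces a local aligner: because only the longest
mismatch-free run is scored, non-matching read ends are ignored exactly as
soft clipping would ignore them.  The matcher is a suffix automaton built
over each locus's alleles, so fractions are exact (verifiable against a
brute-force longest-common-substring oracle), with a seed k-mer prefilter
for speed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .db import AlleleDatabase, Locus
from .dna import revcomp

__all__ = [
    "Read",
    "ReadSet",
    "RecruitedRead",
    "RecruitmentTiers",
    "FastqError",
    "TIER_THRESHOLDS",
    "merge_fastq",
    "perfect_match_fraction",
    "recruit",
    "recruit_all",
    "LocusMatcher",
]

#: perfect-match-fraction thresholds defining the four tiers (inclusive)
TIER_THRESHOLDS: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9)

ReadSet = list  # a ReadSet is simply a list of Read


class FastqError(ValueError):
    """Raised for malformed FASTQ input."""


@dataclass(frozen=True)
class Read:
    """A sequencing read.  Quality scores are carried but never interpreted."""

    read_id: str
    sequence: str
    quality: str | None = None


@dataclass(frozen=True)
class RecruitedRead:
    """A read recruited to a locus, with its best perfect-match evidence."""

    read: Read
    match_fraction: float
    orientation: str  # "forward" | "reverse"
    best_allele_id: int


@dataclass
class RecruitmentTiers:
    """The four nested tier sets of recruited reads for one locus."""

    tiers: dict[float, list[RecruitedRead]] = field(default_factory=dict)

    def ids(self, threshold: float) -> set[str]:
        return {rr.read.read_id for rr in self.tiers[threshold]}

    def reads(self, threshold: float) -> list[Read]:
        return [rr.read for rr in self.tiers[threshold]]


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def merge_fastq(paths: Sequence[str | Path]) -> list[Read]:
    """Merge FASTQ(.gz) files into one read list, disregarding pairing.

    Both mates of a pair become independent reads; mate suffixes (``/1``,
    space-delimited tags) are retained in the read id but never interpreted.
    """
    reads: list[Read] = []
    for path in paths:
        path = Path(path)
        with _open_text(path) as fh:
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    reads.append(Read(title, seq.upper(), qual))
            except ValueError as exc:
                raise FastqError(
                    f"{path}: malformed FASTQ near record {len(reads) + 1}: {exc}"
                ) from None
    return reads


class _SuffixAutomaton:
    """Suffix automaton supporting longest-exact-match queries.

    Built once per locus over the alleles joined with ``#`` separators, so a
    query substring can never span two alleles.  ``longest_match`` runs in
    O(|query|) and returns the length and end position (in the query) of the
    longest query substring occurring in the text.
    """

    __slots__ = ("next", "link", "length")

    def __init__(self, text: str) -> None:
        self.next: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        last = 0
        for ch in text:
            last = self._extend(last, ch)

    def _extend(self, last: int, ch: str) -> int:
        nxt, link, length = self.next, self.link, self.length
        cur = len(nxt)
        nxt.append({})
        length.append(length[last] + 1)
        link.append(-1)
        p = last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(nxt)
                nxt.append(dict(nxt[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and nxt[p].get(ch) == q:
                    nxt[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        return cur

    def longest_match(self, query: str) -> tuple[int, int]:
        """(length, end index in query) of the longest matching substring."""
        nxt, link, length = self.next, self.link, self.length
        v = 0
        run = 0
        best = 0
        best_end = -1
        for i, ch in enumerate(query):
            while v != 0 and ch not in nxt[v]:
                v = link[v]
                run = length[v]
            if ch in nxt[v]:
                v = nxt[v][ch]
                run += 1
            else:
                run = 0
            if run > best:
                best = run
                best_end = i
        return best, best_end


class LocusMatcher:
    """Reusable exact matcher for one locus (automaton + seed k-mer index)."""

    def __init__(self, locus: Locus, seed_length: int = 20) -> None:
        if seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        self.locus = locus
        self.seed_length = seed_length
        self._automaton = _SuffixAutomaton("#".join(a.sequence for a in locus.alleles))
        self._seed_kmers = locus.kmer_set(seed_length)

    def shares_seed(self, read_kmers: set[str]) -> bool:
        return not read_kmers.isdisjoint(self._seed_kmers)

    def best_match(self, sequence: str) -> tuple[int, str, int]:
        """(run length, orientation, best allele id) for a read sequence.

        Ties between orientations break toward forward; the reported allele
        is the lowest-numbered one containing the winning substring.
        """
        fwd_len, fwd_end = self._automaton.longest_match(sequence)
        rc = revcomp(sequence)
        rev_len, rev_end = self._automaton.longest_match(rc)
        if fwd_len >= rev_len:
            run, orientation = fwd_len, "forward"
            sub = sequence[fwd_end - fwd_len + 1 : fwd_end + 1] if fwd_len else ""
        else:
            run, orientation = rev_len, "reverse"
            sub = rc[rev_end - rev_len + 1 : rev_end + 1]
        best_id = 0
        if run:
            for allele in self.locus.alleles:  # ascending id: lowest wins ties
                if sub in allele.sequence:
                    best_id = allele.allele_id
                    break
        return run, orientation, best_id


def perfect_match_fraction(read: Read, locus: Locus) -> tuple[float, str, int]:
    """Longest exact-match run of ``read`` against a locus, as a fraction.

    Returns ``(fraction, orientation, best_allele_id)`` where fraction is the
    length of the longest substring of the read occurring exactly in any
    allele (either strand) divided by the read length.  Fraction 0 when no
    single base matches; orientation ties break toward forward.
    """
    if not locus.alleles:
        raise ValueError(f"locus {locus.name} has no alleles")
    matcher = LocusMatcher(locus, seed_length=1)
    run, orientation, best_id = matcher.best_match(read.sequence)
    return run / len(read.sequence), orientation, best_id


def _recruit_with_matcher(
    reads: Iterable[Read],
    matcher: LocusMatcher,
    read_kmer_cache: dict[Read, set[str]] | None = None,
) -> RecruitmentTiers:
    seed = matcher.seed_length
    recruited: list[RecruitedRead] = []
    for read in reads:
        seq = read.sequence
        if len(seq) < seed:
            continue
        if read_kmer_cache is not None:
            rk = read_kmer_cache.get(read)
            if rk is None:
                rk = {seq[i : i + seed] for i in range(len(seq) - seed + 1)}
                read_kmer_cache[read] = rk
        else:
            rk = {seq[i : i + seed] for i in range(len(seq) - seed + 1)}
        # a perfect run >= seed exists iff read and locus share a seed k-mer
        if not matcher.shares_seed(rk):
            continue
        run, orientation, best_id = matcher.best_match(seq)
        if run < seed:
            continue
        recruited.append(
            RecruitedRead(read, run / len(seq), orientation, best_id)
        )
    recruited.sort(key=lambda rr: (rr.read.read_id, rr.read.sequence))
    tiers = {
        t: [rr for rr in recruited if rr.match_fraction >= t] for t in TIER_THRESHOLDS
    }
    return RecruitmentTiers(tiers=tiers)


def recruit(reads: Iterable[Read], locus: Locus, seed_length: int = 20) -> RecruitmentTiers:
    """Build the four nested tier sets of reads recruited to a locus.

    Tier 0.0 holds every read whose longest exact-match run is at least
    ``seed_length``; tiers 0.3/0.6/0.9 additionally require the run to cover
    that fraction of the read length (thresholds inclusive).  Reads shorter
    than ``seed_length`` are never recruited.  Output is independent of read
    input order.
    """
    return _recruit_with_matcher(reads, LocusMatcher(locus, seed_length))


def recruit_all(
    reads: Iterable[Read], database: AlleleDatabase, seed_length: int = 20
) -> dict[str, RecruitmentTiers]:
    """Recruit one read set against every locus, sharing per-read k-mer sets."""
    reads = list(reads)
    cache: dict[Read, set[str]] = {}
    out: dict[str, RecruitmentTiers] = {}
    for name in database.schema:
        matcher = LocusMatcher(database.loci[name], seed_length)
        out[name] = _recruit_with_matcher(reads, matcher, read_kmer_cache=cache)
    return out
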