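"""Per-locus allele calling: the recruit -> assemble -> match loop.

For each locus the recruited tiers are processed from most stringent to
least (0.90, 0.60, 0.30, all-mapped), and within a tier the multi-k
assemblies are evaluated largest k first.  The loop stops as soon as a
contig yields a perfect full-length match to exactly one reference allele
(status ``exact``).  If no tier produces an exact match but a sufficiently
long contig exists, the locus is flagged as carrying a putative novel allele
(status ``new``) and the reconstructed sequence is reported; if no reads are
recruited or no contig is produced anywhere, the locus is ``low_coverage``.
``no_output`` is reserved for internal pipeline faults.

Candidate extraction
--------------------
Assembled unitigs routinely carry a few bases of flanking genome beyond the
locus boundaries, because the tier filters admit reads that overhang the
locus by up to (1 - threshold) of their length.  A raw unitig is therefore
compared to the reference by *infix alignment*: each reference allele is
aligned inside the contig (edlib, both contig strands) and the contig
substring spanning the alignment is excised as a candidate.  A candidate at
edit distance zero is the allele occurring verbatim inside the contig — the
exact-containment criterion a nucleotide BLAST perfect match expresses.  A
candidate at small positive distance is the locus sequence excised at the
boundaries of its closest known allele: the reported novel-allele sequence.
Because the trim anchors on a reference, reported sequences carry no flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .assembly import DEFAULT_KS, Contig, assemble_multi_k, build_dbg, extract_unitigs, greedy_fallback
from .db import DatabaseError, Locus
from .dna import revcomp
from .recruit import TIER_THRESHOLDS, Read, RecruitmentTiers, recruit

__all__ = [
    "AlleleCall",
    "CallParams",
    "match_contig",
    "call_locus",
    "call_recruited",
    "write_new_alleles",
]

logger = logging.getLogger(__name__)


@dataclass
class CallParams:
    """Tunables of the calling loop (defaults mirror the pipeline contract)."""

    seed_length: int = 20
    ks: tuple[int, ...] = DEFAULT_KS
    min_count: int = 2
    #: below this many reads in a tier, min_count drops to 1
    small_set_size: int = 50
    tiers: tuple[float, ...] = TIER_THRESHOLDS
    #: a novel candidate must reach this fraction of the locus's shortest allele
    min_new_frac: float = 0.5
    #: a novel candidate's edit distance to its closest reference allele must
    #: not exceed this fraction of the allele length (guards against junk)
    max_new_dist_frac: float = 0.35
    min_tip_count: int = 3
    min_overlap: int = 25


@dataclass(frozen=True)
class AlleleCall:
    """Outcome of calling one locus on one sample."""

    locus_name: str
    status: str  # "exact" | "new" | "low_coverage" | "no_output"
    allele_id: int | None = None
    novel_sequence: str | None = None
    tier_used: float | None = None
    k_used: int | None = None

    def __post_init__(self) -> None:
        if self.status == "exact" and self.allele_id is None:
            raise ValueError("exact call requires allele_id")
        if self.status == "new" and not self.novel_sequence:
            raise ValueError("new call requires novel_sequence")
        if self.status in ("low_coverage", "no_output") and (
            self.allele_id is not None or self.novel_sequence is not None
        ):
            raise ValueError(f"{self.status} call must carry no allele")

    def label(self) -> str:
        """Report-cell vocabulary: allele number, ``New?`` or ``low coverage``."""
        if self.status == "exact":
            return str(self.allele_id)
        if self.status == "new":
            return "New?"
        if self.status == "low_coverage":
            return "low coverage"
        return ""


def match_contig(contig: Contig | str, locus: Locus) -> int | None:
    """Exact full-length match of a contig against the reference alleles.

    Returns the allele id iff the contig sequence (or its reverse
    complement) is string-equal to exactly one allele.  Contigs shorter,
    longer or different from every allele return ``None``.  Equality with
    two or more alleles is only possible in an invalid database holding
    duplicate sequences and raises.
    """
    seq = contig if isinstance(contig, str) else contig.sequence
    rc = revcomp(seq)
    hits = [a.allele_id for a in locus.alleles if a.sequence == seq or a.sequence == rc]
    if not hits:
        return None
    if len(hits) > 1:
        raise DatabaseError(
            f"contig matches alleles {hits} of locus {locus.name}: "
            "database contains duplicate sequences"
        )
    return hits[0]


@dataclass(frozen=True)
class _Candidate:
    """A reference-trimmed contig excerpt, with its anchor evidence."""

    sequence: str
    distance: int
    anchor_id: int
    tier: float
    k: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _excise(contig_seq: str, allele_seq: str) -> tuple[int, str] | None:
    """Best infix alignment of an allele inside one strand of a contig.

    Returns ``(edit distance, excised contig substring)`` or ``None`` when
    edlib finds no alignment.  When a same-length window achieves the same
    (or better) substitution-only distance near the aligned region, that
    window is preferred: end-of-allele substitutions are then reported as
    substitutions rather than as boundary indels, keeping the excised
    sequence in register with the reference.
    """
    res = edlib.align(allele_seq, contig_seq, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    if start is None:
        start = 0
    cand = contig_seq[start : end + 1]
    la = len(allele_seq)
    best = (dist, cand)
    for s in range(max(0, start - 2), min(len(contig_seq) - la, start + 2) + 1):
        window = contig_seq[s : s + la]
        hd = _hamming(window, allele_seq)
        if hd <= best[0]:
            if hd < best[0] or len(best[1]) != la:
                best = (hd, window)
    return best


def _contig_candidates(
    contig: Contig, locus: Locus, tier: float, k: int
) -> list[_Candidate]:
    """Per-allele best trim of one contig (forward strand preferred on ties)."""
    out: list[_Candidate] = []
    for allele in locus.alleles:
        best: tuple[int, str] | None = None
        for strand_seq in (contig.sequence, revcomp(contig.sequence)):
            hit = _excise(strand_seq, allele.sequence)
            if hit is not None and (best is None or hit[0] < best[0]):
                best = hit
        if best is not None:
            out.append(_Candidate(best[1], best[0], allele.allele_id, tier, k))
    return out


def _evaluate_contigs(
    contigs: Sequence[Contig],
    locus: Locus,
    tier: float,
    k: int,
    params: CallParams,
    novel_pool: list[_Candidate],
) -> AlleleCall | None:
    """Check one tier/k contig set for an exact call; bank novel candidates."""
    min_len = locus.min_allele_length()
    exact: dict[int, _Candidate] = {}
    for contig in contigs:
        for cand in _contig_candidates(contig, locus, tier, k):
            if cand.distance == 0:
                exact.setdefault(cand.anchor_id, cand)
            else:
                allele = locus.get(cand.anchor_id)
                assert allele is not None
                if (
                    len(cand.sequence) >= params.min_new_frac * min_len
                    and cand.distance <= params.max_new_dist_frac * len(allele.sequence)
                ):
                    novel_pool.append(cand)
    if len(exact) == 1:
        (allele_id, cand), = exact.items()
        assert match_contig(cand.sequence, locus) == allele_id
        return AlleleCall(
            locus.name, "exact", allele_id=allele_id, tier_used=tier, k_used=k
        )
    if len(exact) > 1:
        logger.warning(
            "locus %s: contigs contain %d distinct reference alleles verbatim "
            "(tier %.2f, k=%d); no exact call made",
            locus.name, len(exact), tier, k,
        )
    return None


def call_recruited(
    tiers: RecruitmentTiers, locus: Locus, params: CallParams | None = None
) -> AlleleCall:
    """Run the tier/k calling loop on already-recruited reads."""
    params = params or CallParams()
    tier_order = sorted(params.tiers, reverse=True)
    novel_pool: list[_Candidate] = []
    produced_any = False
    ks_desc = sorted(params.ks, reverse=True)
    min_k = min(params.ks)

    for tier in tier_order:
        reads = tiers.reads(tier)
        if not reads:
            continue
        min_count = params.min_count if len(reads) >= params.small_set_size else 1
        for k in ks_desc:
            contigs = extract_unitigs(
                build_dbg(reads, k, min_count),
                min_tip_count=params.min_tip_count,
            )
            contigs = [c for c in contigs if len(c) >= min_k]
            if not contigs:
                continue
            produced_any = True
            hit = _evaluate_contigs(contigs, locus, tier, k, params, novel_pool)
            if hit is not None:
                return hit

    if not produced_any and tiers.reads(0.0):
        # backup assembler: the graph produced nothing from a non-empty set
        contigs = [c for c in greedy_fallback(tiers.reads(0.0), params.min_overlap)
                   if len(c) >= min_k]
        if contigs:
            hit = _evaluate_contigs(contigs, locus, 0.0, 0, params, novel_pool)
            if hit is not None:
                return hit

    if novel_pool:
        # closest to a known allele first (full-length reconstructions beat
        # fragments), then most stringent tier, largest k, longest, lexicographic
        novel_pool.sort(
            key=lambda c: (c.distance, -c.tier, -c.k, -len(c.sequence), c.sequence)
        )
        chosen = novel_pool[0]
        if match_contig(chosen.sequence, locus) is None:
            return AlleleCall(
                locus.name,
                "new",
                novel_sequence=chosen.sequence,
                tier_used=chosen.tier,
                k_used=chosen.k or None,
            )
    return AlleleCall(locus.name, "low_coverage")


def call_locus(
    reads: Iterable[Read], locus: Locus, params: CallParams | None = None
) -> AlleleCall:
    """Recruit reads to a locus and call its allele.

    Deterministic for fixed inputs and parameters; independent of read
    input order.
    """
    params = params or CallParams()
    tiers = recruit(reads, locus, params.seed_length)
    return call_recruited(tiers, locus, params)


def write_new_alleles(
    calls: Iterable[AlleleCall], out_dir: str | Path, sample_id: str = "sample"
) -> list[Path]:
    """Write one FASTA per novel-allele call into ``<out_dir>/new_alleles/``."""
    calls = [c for c in calls if c.status == "new"]
    written: list[Path] = []
    if not calls:
        return written
    target = Path(out_dir) / "new_alleles"
    target.mkdir(parents=True, exist_ok=True)
    for call in calls:
        name = f"{sample_id}_{call.locus_name}_new"
        path = target / f"{name}.fasta"
        with open(path, "w") as fh:
            fh.write(f">{name}\n{call.novel_sequence}\n")
        written.append(path)
    return written
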