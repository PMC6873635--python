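"""Targeted assembly of recruited reads.

Each tier of recruited reads is assembled into contigs with a multi-k
de Bruijn graph.  No read error correction is performed: the only
error-handling mechanism is the minimum k-mer multiplicity filter
(``min_count``), which drops edges seen fewer times than the cutoff —
singleton k-mers from sequencing errors or border chimeras rarely recur.
Assemblies at the different k values (default 11, 15, 21, 33, 35) are
independent; the caller consumes them largest-k-first, since larger k
resolves more repeat structure.

A greedy maximal-exact-overlap merger serves as a backup assembler for read
sets on which the de Bruijn graph yields nothing (tiny or very uneven sets).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dna import canonical, revcomp
from .recruit import Read

__all__ = [
    "DeBruijnGraph",
    "Contig",
    "DEFAULT_KS",
    "build_dbg",
    "extract_unitigs",
    "assemble_multi_k",
    "greedy_fallback",
]

DEFAULT_KS: tuple[int, ...] = (11, 15, 21, 33, 35)


@dataclass(frozen=True)
class Contig:
    """An assembled sequence with its provenance."""

    sequence: str
    k_used: int
    tier_used: float | None = None
    mean_edge_coverage: float = 0.0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DeBruijnGraph:
    """Edge-centric de Bruijn graph: edges are k-mers with multiplicities.

    Both strands are represented explicitly (each read also contributes the
    k-mers of its reverse complement), so every unitig appears as a pair of
    mirror paths; extraction deduplicates to the canonical strand.
    """

    k: int
    edges: dict[str, int] = field(default_factory=dict)

    def out_edges(self, node: str) -> list[str]:
        return [node + b for b in "ACGT" if node + b in self.edges]

    def in_edges(self, node: str) -> list[str]:
        return [b + node for b in "ACGT" if b + node in self.edges]


def _sequences(reads: Iterable[Read | str]) -> list[str]:
    return [r if isinstance(r, str) else r.sequence for r in reads]


def build_dbg(reads: Iterable[Read | str], k: int, min_count: int = 1) -> DeBruijnGraph:
    """Count k-mers over both strands of every read; keep edges >= min_count.

    ``k`` must be odd (no k-mer is then its own reverse complement) and at
    most 127; assembly k values below 11 are rarely useful but accepted.
    Reads shorter than k contribute nothing; an all-short read set yields an
    empty graph.
    """
    if k % 2 == 0 or not (3 <= k <= 127):
        raise ValueError(f"k must be odd and within [3, 127], got {k}")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[str] = Counter()
    for seq in _sequences(reads):
        if len(seq) < k:
            continue
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                counts[s[i : i + k]] += 1
    edges = {kmer: c for kmer, c in counts.items() if c >= min_count}
    return DeBruijnGraph(k=k, edges=edges)


def _compact(graph: DeBruijnGraph) -> list[tuple[str, list[str]]]:
    """Maximal non-branching paths as (sequence, [k-mers]) pairs, both strands."""
    k = graph.k
    edges = graph.edges
    out_deg: Counter[str] = Counter()
    in_deg: Counter[str] = Counter()
    for kmer in edges:
        out_deg[kmer[:-1]] += 1
        in_deg[kmer[1:]] += 1

    def linear_through(node: str) -> bool:
        return out_deg[node] == 1 and in_deg[node] == 1

    visited: set[str] = set()
    paths: list[tuple[str, list[str]]] = []

    def walk(start: str) -> None:
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            node = cur[1:]
            if not linear_through(node):
                break
            nxt = graph.out_edges(node)[0]
            if nxt in visited:
                break  # closes a cycle
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = chain[0] + "".join(e[-1] for e in chain[1:])
        paths.append((seq, chain))

    # anchor walks at junctions first, then sweep up pure cycles
    for kmer in sorted(edges):
        if kmer in visited:
            continue
        if not linear_through(kmer[:-1]):
            walk(kmer)
    for kmer in sorted(edges):
        if kmer not in visited:
            walk(kmer)
    return paths


def extract_unitigs(
    graph: DeBruijnGraph,
    remove_tips: bool = True,
    min_tip_count: int = 3,
) -> list[Contig]:
    """Compact the graph into unitigs, reported once on the canonical strand.

    A *tip* — a unitig dead-ended on exactly one side, shorter than 2k and
    with mean edge multiplicity below ``min_tip_count`` — is removed before
    the final compaction: such stubs arise from rare chimeric or erroneous
    k-mers branching off a well-supported path.  Isolated short paths are
    kept (they may be the only signal at a poorly covered locus).  Bubbles
    are deliberately left intact: a bubble is genuine evidence of mixed or
    novel alleles and must surface as non-matching contigs.
    """
    paths = _compact(graph)
    if remove_tips and paths:
        out_deg: Counter[str] = Counter()
        in_deg: Counter[str] = Counter()
        for kmer in graph.edges:
            out_deg[kmer[:-1]] += 1
            in_deg[kmer[1:]] += 1
        doomed: set[str] = set()
        for seq, chain in paths:
            if len(seq) >= 2 * graph.k:
                continue
            start_dead = in_deg[chain[0][:-1]] == 0
            end_dead = out_deg[chain[-1][1:]] == 0
            if start_dead == end_dead:  # isolated (both) or internal (neither)
                continue
            mean_cov = sum(graph.edges[e] for e in chain) / len(chain)
            if mean_cov < min_tip_count:
                doomed.update(chain)
                doomed.update(revcomp(e) for e in chain)
        if doomed:
            pruned = DeBruijnGraph(
                k=graph.k,
                edges={e: c for e, c in graph.edges.items() if e not in doomed},
            )
            paths = _compact(pruned)
            graph = pruned

    best: dict[str, Contig] = {}
    for seq, chain in paths:
        mean_cov = sum(graph.edges[e] for e in chain) / len(chain)
        canon = canonical(seq)
        if canon not in best:
            best[canon] = Contig(canon, k_used=graph.k, mean_edge_coverage=mean_cov)
    return sorted(best.values(), key=lambda c: (-len(c.sequence), c.sequence))


def assemble_multi_k(
    reads: Iterable[Read | str],
    ks: Sequence[int] = DEFAULT_KS,
    min_count: int = 1,
    remove_tips: bool = True,
    min_tip_count: int = 3,
) -> dict[int, list[Contig]]:
    """Independent single-k assemblies for every k (no iterative composition)."""
    reads = list(reads)
    return {
        k: extract_unitigs(
            build_dbg(reads, k, min_count),
            remove_tips=remove_tips,
            min_tip_count=min_tip_count,
        )
        for k in ks
    }


def _longest_overlap(a: str, b: str, min_overlap: int) -> int:
    """Length of the longest suffix of ``a`` equal to a prefix of ``b``."""
    limit = min(len(a), len(b)) - 1
    for olen in range(limit, min_overlap - 1, -1):
        if a[-olen:] == b[:olen]:
            return olen
    return 0


def greedy_fallback(reads: Iterable[Read | str], min_overlap: int = 25) -> list[Contig]:
    """Greedy maximal-exact-overlap merging of reads, both orientations.

    Backup assembler for read sets where the de Bruijn graph produced no
    usable contig.  Repeatedly merges the pair with the longest suffix-prefix
    overlap (>= ``min_overlap``), ties broken lexicographically, until no
    merge remains; reads contained in another read (either strand) are
    absorbed.  Fully deterministic.
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    seqs = sorted({canonical(s) for s in _sequences(reads) if s})

    def drop_contained(items: list[str]) -> list[str]:
        items = sorted(set(items), key=lambda s: (-len(s), s))
        kept: list[str] = []
        for s in items:
            rc = revcomp(s)
            if any(s in t or rc in t for t in kept):
                continue
            kept.append(s)
        return kept

    seqs = drop_contained(seqs)
    while len(seqs) > 1:
        best: tuple[int, str, str] | None = None  # (-overlap, merged, ...) ordering
        best_key = None
        for i, x in enumerate(seqs):
            for j, y in enumerate(seqs):
                if i == j:
                    continue
                for sx in (x, revcomp(x)):
                    for sy in (y, revcomp(y)):
                        olen = _longest_overlap(sx, sy, min_overlap)
                        if olen:
                            key = (-olen, sx, sy)
                            if best_key is None or key < best_key:
                                best_key = key
                                best = (olen, sx, sy)
                                best_pair = (x, y)
        if best is None:
            break
        olen, sx, sy = best
        merged = sx + sy[olen:]
        seqs = [s for s in seqs if s not in best_pair]
        seqs.append(canonical(merged))
        seqs = drop_contained(seqs)
        seqs.sort()
    return [
        Contig(canonical(s), k_used=0, mean_edge_coverage=0.0)
        for s in sorted(seqs, key=lambda s: (-len(s), s))
    ]
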