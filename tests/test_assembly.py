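"""De Bruijn assembly, unitig extraction and the greedy-overlap fallback."""

from __future__ import annotations

import networkx as nx
import pytest

from mlstkit.assembly import (
    DEFAULT_KS,
    assemble_multi_k,
    build_dbg,
    extract_unitigs,
    greedy_fallback,
)
from mlstkit.dna import canonical, revcomp
from .conftest import random_dna


def tiling_reads(seq, read_len, step):
    """Uniform tiling that always includes a read flush with each end."""
    reads = [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    if reads[-1] != seq[-read_len:]:
        reads.append(seq[-read_len:])
    return reads


def networkx_unitigs(graph):
    """Independent oracle: maximal non-branching paths via an explicit
    networkx digraph over (k-1)-mer nodes."""
    g = nx.MultiDiGraph()
    for kmer in graph.edges:
        g.add_edge(kmer[:-1], kmer[1:], kmer=kmer)

    def linear(node):
        return g.in_degree(node) == 1 and g.out_degree(node) == 1

    seqs = set()
    visited = set()
    for u, v, data in sorted(g.edges(data=True), key=lambda e: e[2]["kmer"]):
        kmer = data["kmer"]
        if kmer in visited or linear(u):
            continue
        seq = kmer
        visited.add(kmer)
        cur = v
        while linear(cur):
            (_, nxt, d2), = g.out_edges(cur, data=True)
            if d2["kmer"] in visited:
                break
            seq += d2["kmer"][-1]
            visited.add(d2["kmer"])
            cur = nxt
        seqs.add(canonical(seq))
    for u, v, data in sorted(g.edges(data=True), key=lambda e: e[2]["kmer"]):
        # pure cycles: anchor at smallest unvisited edge
        kmer = data["kmer"]
        if kmer in visited:
            continue
        seq = kmer
        visited.add(kmer)
        cur = v
        while True:
            (_, nxt, d2), = g.out_edges(cur, data=True)
            if d2["kmer"] in visited:
                break
            seq += d2["kmer"][-1]
            visited.add(d2["kmer"])
            cur = nxt
        seqs.add(canonical(seq))
    return seqs


class TestBuildDbg:
    def test_single_read_enumeration(self):
        # ACGTACGT is its own reverse complement: the forward and RC k-mer
        # sets coincide, so each of the 4 edges is counted twice
        g = build_dbg(["ACGTACGT"], k=5, min_count=1)
        fwd = {"ACGTA", "CGTAC", "GTACG", "TACGT"}
        assert fwd == {revcomp(k) for k in fwd}
        assert set(g.edges) == fwd
        assert all(c == 2 for c in g.edges.values())
        # a non-palindromic read contributes both strands once each
        g2 = build_dbg(["ACGTAAGCT"], k=5, min_count=1)
        assert set(g2.edges) == {"ACGTA", "CGTAA", "GTAAG", "TAAGC", "AAGCT"} | {
            revcomp(k) for k in ("ACGTA", "CGTAA", "GTAAG", "TAAGC", "AAGCT")
        }
        assert all(c == 1 for c in g2.edges.values())

    def test_min_count_filters_rare_kmers(self):
        g = build_dbg(["ACGTACGTACG", "ACGTACGTACG", "TTGACCTGATC"], k=11, min_count=2)
        assert "TTGACCTGATC" not in g.edges
        assert "ACGTACGTACG" in g.edges

    def test_empty_or_short_reads_yield_empty_graph(self):
        assert build_dbg([], k=21).edges == {}
        assert build_dbg(["ACGT"], k=21).edges == {}

    def test_even_or_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            build_dbg(["ACGTACGT"], k=4)
        with pytest.raises(ValueError):
            build_dbg(["ACGTACGT"], k=129)


class TestExtractUnitigs:
    def test_single_path_graph_yields_the_source_sequence(self, rng):
        seq = random_dna(rng, 300)
        reads = tiling_reads(seq, 60, 10)
        contigs = extract_unitigs(build_dbg(reads, k=21, min_count=1))
        assert canonical(seq) in {c.sequence for c in contigs}

    def test_snp_pair_produces_bubble_not_chimera(self, rng):
        seq = random_dna(rng, 200)
        variant = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
        reads = tiling_reads(seq, 50, 7) + tiling_reads(variant, 50, 7)
        contigs = extract_unitigs(build_dbg(reads, k=21, min_count=1))
        assert len(contigs) >= 2  # the SNP forks the graph

    def test_empty_graph_yields_no_contigs(self):
        assert extract_unitigs(build_dbg([], k=21)) == []

    def test_matches_networkx_enumeration_on_small_read_sets(self, rng):
        for trial in range(20):
            n_reads = int(rng.integers(1, 11))
            reads = [random_dna(rng, int(rng.integers(21, 60))) for _ in range(n_reads)]
            if rng.random() < 0.5:  # overlapping reads from one template
                template = random_dna(rng, 150)
                reads = tiling_reads(template, 40, 15)[:10]
            g = build_dbg(reads, k=21, min_count=1)
            ours = {c.sequence for c in extract_unitigs(g, remove_tips=False)}
            assert ours == networkx_unitigs(g)

    def test_strand_invariance(self, rng):
        seq = random_dna(rng, 250)
        reads = tiling_reads(seq, 50, 9)
        flipped = [revcomp(r) for r in reads]
        a = {c.sequence for c in extract_unitigs(build_dbg(reads, 21))}
        b = {c.sequence for c in extract_unitigs(build_dbg(flipped, 21))}
        assert a == b

    def test_low_coverage_tip_removed_but_isolated_path_kept(self, rng):
        seq = random_dna(rng, 200)
        # well-supported backbone + a single chimeric read branching off
        reads = tiling_reads(seq, 60, 6) * 3
        chimera = seq[80:110] + random_dna(rng, 12)
        g = build_dbg(reads + [chimera], k=21, min_count=1)
        contigs = extract_unitigs(g, remove_tips=True, min_tip_count=3)
        assert canonical(seq) in {c.sequence for c in contigs}
        assert all(len(c.sequence) >= 100 for c in contigs)
        # an isolated short path is not a tip
        lone = extract_unitigs(build_dbg(["ACGTACGTACGTACGTACGTACGTA"[:25]], 21))
        assert len(lone) == 1


class TestAssembleMultiK:
    def test_largest_k_reconstructs_the_allele(self, rng):
        allele = random_dna(rng, 450)
        reads = tiling_reads(allele, 100, 2)
        by_k = assemble_multi_k(reads, ks=DEFAULT_KS, min_count=1)
        assert canonical(allele) in {c.sequence for c in by_k[35]}

    def test_reads_shorter_than_k_leave_that_k_empty(self, rng):
        allele = random_dna(rng, 200)
        reads = tiling_reads(allele, 30, 3)
        by_k = assemble_multi_k(reads, ks=(21, 35), min_count=1)
        assert by_k[35] == []
        assert by_k[21] != []

    def test_empty_reads_all_k_empty(self):
        by_k = assemble_multi_k([], ks=DEFAULT_KS)
        assert all(v == [] for v in by_k.values())


class TestGreedyFallback:
    def test_exact_min_overlap_pair_merges(self, rng):
        a = random_dna(rng, 60)
        b = a[-25:] + random_dna(rng, 40)
        contigs = greedy_fallback([a, b], min_overlap=25)
        assert len(contigs) == 1
        assert contigs[0].sequence == canonical(a + b[25:])

    def test_tiling_reads_reassemble_the_allele(self, rng):
        allele = random_dna(rng, 300)
        reads = tiling_reads(allele, 60, 20)  # overlap 40 >= min_overlap
        contigs = greedy_fallback(reads, min_overlap=25)
        assert [c.sequence for c in contigs] == [canonical(allele)]

    def test_non_overlapping_reads_come_back_deduplicated(self, rng):
        a = random_dna(rng, 50)
        b = random_dna(rng, 50)
        contigs = greedy_fallback([a, a, b], min_overlap=25)
        assert {c.sequence for c in contigs} == {canonical(a), canonical(b)}

    def test_merges_across_orientations(self, rng):
        a = random_dna(rng, 60)
        b = revcomp(a[-30:] + random_dna(rng, 30))
        contigs = greedy_fallback([a, b], min_overlap=25)
        assert len(contigs) == 1
        assert len(contigs[0].sequence) == 90


class TestPerfectReconstruction:
    def test_most_alleles_reconstruct_at_some_k(self, rng):
        """Error-free tiling coverage of random alleles: some k yields the
        allele exactly (up to reverse complement) nearly always."""
        wins = 0
        trials = 30
        for _ in range(trials):
            allele = random_dna(rng, int(rng.integers(400, 601)))
            reads = tiling_reads(allele, 100, 4)  # ~25x tiling
            by_k = assemble_multi_k(reads, min_count=1)
            if any(
                canonical(allele) in {c.sequence for c in contigs}
                for contigs in by_k.values()
            ):
                wins += 1
        assert wins >= trials - 1
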