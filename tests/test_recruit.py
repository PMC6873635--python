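"""Read merging and perfect-match-fraction recruitment."""

from __future__ import annotations

import gzip

import numpy as np
import pytest

from mlstkit.db import Allele, Locus
from mlstkit.dna import revcomp
from mlstkit.recruit import (
    FastqError,
    Read,
    merge_fastq,
    perfect_match_fraction,
    recruit,
)
from .conftest import random_dna


def brute_force_longest_run(read_seq: str, locus: Locus) -> int:
    """Independent oracle: longest substring of the read (either strand)
    occurring in any allele, by direct substring enumeration."""
    best = 0
    for query in (read_seq, revcomp(read_seq)):
        for length in range(len(query), best, -1):
            found = False
            for i in range(len(query) - length + 1):
                sub = query[i : i + length]
                if any(sub in a.sequence for a in locus.alleles):
                    found = True
                    break
            if found:
                best = max(best, length)
                break
    return best


def fastq_text(reads):
    return "".join(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n" for r in reads)


class TestMergeFastq:
    def test_paired_files_contribute_both_mates(self, tmp_path):
        r1 = [Read(f"r{i}/1", "ACGTACGTACGT") for i in range(5)]
        r2 = [Read(f"r{i}/2", "TTTTACGTACGT") for i in range(5)]
        p1 = tmp_path / "s_1.fastq"
        p2 = tmp_path / "s_2.fastq"
        p1.write_text(fastq_text(r1))
        p2.write_text(fastq_text(r2))
        merged = merge_fastq([p1, p2])
        assert len(merged) == 10
        assert {r.read_id for r in merged} == {r.read_id for r in r1 + r2}

    def test_empty_file_yields_empty_read_set(self, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        assert merge_fastq([p]) == []

    def test_gzipped_and_plain_inputs_are_equivalent(self, tmp_path):
        reads = [Read(f"r{i}", "ACGTACGTAC") for i in range(4)]
        plain = tmp_path / "a.fastq"
        plain.write_text(fastq_text(reads))
        gz = tmp_path / "a.fastq.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(fastq_text(reads))
        assert merge_fastq([plain, gz]) == merge_fastq([plain, plain])

    def test_malformed_record_raises_with_context(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(FastqError, match="bad.fastq"):
            merge_fastq([p])


class TestPerfectMatchFraction:
    def test_read_equal_to_allele_substring_scores_one(self, adk_locus):
        read = Read("r", adk_locus.alleles[0].sequence[5:35])
        frac, orientation, best_id = perfect_match_fraction(read, adk_locus)
        assert frac == 1.0
        assert orientation == "forward"
        assert best_id == 1

    def test_partial_copy_scores_the_copied_fraction(self, rng, adk_locus):
        # first 30 bases copy allele 1, last 20 are unrelated random bases
        while True:
            tail = random_dna(rng, 20)
            read = Read("r", adk_locus.alleles[0].sequence[:30] + tail)
            if brute_force_longest_run(read.sequence, adk_locus) == 30:
                break
        frac, _, _ = perfect_match_fraction(read, adk_locus)
        assert frac == pytest.approx(30 / 50)

    def test_reverse_complement_segment_scores_reverse(self, adk_locus):
        seg = adk_locus.alleles[0].sequence[10:40]
        read = Read("r", revcomp(seg))
        frac, orientation, _ = perfect_match_fraction(read, adk_locus)
        assert frac == 1.0
        assert orientation == "reverse"

    def test_matches_brute_force_on_random_reads(self, rng, adk_locus):
        for _ in range(50):
            if rng.random() < 0.5:
                start = int(rng.integers(0, 30))
                seq = adk_locus.alleles[0].sequence[start : start + 25] + random_dna(rng, 15)
            else:
                seq = random_dna(rng, 40)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            frac, _, _ = perfect_match_fraction(Read("r", seq), adk_locus)
            assert frac * len(seq) == pytest.approx(
                brute_force_longest_run(seq, adk_locus)
            )


class TestRecruit:
    def _tiling_reads(self, seq, read_len=30, step=5):
        return [
            Read(f"t{i}", seq[i : i + read_len])
            for i in range(0, len(seq) - read_len + 1, step)
        ]

    def test_error_free_interior_reads_fill_all_tiers(self, adk_locus):
        reads = self._tiling_reads(adk_locus.alleles[0].sequence)
        tiers = recruit(reads, adk_locus, seed_length=20)
        all_ids = {r.read_id for r in reads}
        assert tiers.ids(0.0) == all_ids
        assert tiers.ids(0.9) == all_ids  # interior reads have fraction 1.0

    def test_unrelated_reads_leave_all_tiers_empty(self, rng, adk_locus):
        while True:
            reads = [Read(f"u{i}", random_dna(rng, 50)) for i in range(20)]
            if all(
                brute_force_longest_run(r.sequence, adk_locus) < 20 for r in reads
            ):
                break
        tiers = recruit(reads, adk_locus, seed_length=20)
        assert all(not tiers.tiers[t] for t in (0.0, 0.3, 0.6, 0.9))

    def test_thresholds_are_inclusive(self, rng, adk_locus):
        # read of length 50 whose longest run is exactly 30 -> fraction 0.60
        while True:
            tail = random_dna(rng, 20)
            seq = adk_locus.alleles[0].sequence[:30] + tail
            if brute_force_longest_run(seq, adk_locus) == 30:
                break
        tiers = recruit([Read("edge", seq)], adk_locus, seed_length=20)
        assert tiers.ids(0.0) == tiers.ids(0.3) == tiers.ids(0.6) == {"edge"}
        assert tiers.ids(0.9) == set()

    def test_tier_nesting(self, rng, adk_locus):
        reads = [
            Read(f"m{i}", adk_locus.alleles[0].sequence[j : j + 20] + random_dna(rng, int(rng.integers(0, 30))))
            for i, j in enumerate(rng.integers(0, 30, size=30))
        ]
        tiers = recruit(reads, adk_locus, seed_length=20)
        assert tiers.ids(0.9) <= tiers.ids(0.6) <= tiers.ids(0.3) <= tiers.ids(0.0)

    def test_strand_symmetric_membership(self, rng, adk_locus):
        reads = self._tiling_reads(adk_locus.alleles[1].sequence)
        flipped = [Read(r.read_id, revcomp(r.sequence)) for r in reads]
        t1 = recruit(reads, adk_locus, seed_length=20)
        t2 = recruit(flipped, adk_locus, seed_length=20)
        for t in (0.0, 0.3, 0.6, 0.9):
            assert t1.ids(t) == t2.ids(t)

    def test_membership_is_input_order_independent(self, rng, adk_locus):
        reads = self._tiling_reads(adk_locus.alleles[0].sequence)
        shuffled = list(reads)
        np.random.default_rng(3).shuffle(shuffled)
        t1 = recruit(reads, adk_locus, seed_length=20)
        t2 = recruit(shuffled, adk_locus, seed_length=20)
        assert t1.tiers == t2.tiers

    def test_reads_shorter_than_seed_never_recruited(self, adk_locus):
        short = Read("s", adk_locus.alleles[0].sequence[:10])
        tiers = recruit([short], adk_locus, seed_length=20)
        assert not tiers.tiers[0.0]
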