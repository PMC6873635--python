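"""Shared fixtures: hand-built toy databases and a small synthetic benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from mlstkit.db import Allele, AlleleDatabase, Locus, ProfileTable
from mlstkit.simulate import SimulationConfig, make_benchmark


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)


@pytest.fixture
def adk_locus() -> Locus:
    """Three hand-written alleles of one locus (allele 2 = allele 1 + 1 SNP)."""
    def flip(base: str) -> str:
        return "A" if base != "A" else "G"

    a1 = "ATGGCTGACTTAGCCGTAATCGGCACTGATTACCGGAAACCTAGGACAGT"
    a2 = a1[:20] + flip(a1[20]) + a1[21:]
    a3 = a1[:10] + flip(a1[10]) + a1[11:30] + flip(a1[30]) + a1[31:]
    return Locus("adk", [Allele("adk", i + 1, s) for i, s in enumerate((a1, a2, a3))])


@pytest.fixture
def toy_db(rng) -> AlleleDatabase:
    """Seven-locus toy database with 3 random-derived alleles per locus."""
    names = [f"locus{i}" for i in range(1, 8)]
    loci = {}
    for name in names:
        founder = random_dna(rng, 60)
        variants = [founder]
        for _ in range(2):
            while True:
                pos = int(rng.integers(0, len(founder)))
                base = "ACGT"[int(rng.integers(0, 4))]
                v = founder[:pos] + base + founder[pos + 1 :]
                if v not in variants:
                    variants.append(v)
                    break
        loci[name] = Locus(name, [Allele(name, i + 1, s) for i, s in enumerate(variants)])
    return AlleleDatabase(loci=loci, schema=names)


@pytest.fixture
def toy_profiles(toy_db) -> ProfileTable:
    rows = {
        (1, 1, 1, 1, 1, 1, 1): 1,
        (2, 1, 1, 1, 1, 1, 1): 2,
        (1, 2, 1, 1, 1, 1, 1): 3,
        (3, 3, 3, 3, 3, 3, 3): 4,
    }
    return ProfileTable(schema=list(toy_db.schema), rows=rows)


@pytest.fixture(scope="session")
def small_benchmark():
    """Six error-free synthetic samples at the default study conditions."""
    return make_benchmark(SimulationConfig(), n_samples=6, seed=11)
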