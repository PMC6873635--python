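"""Allele reference databases and ST profile tables (PubMLST file conventions).

An MLST scheme consists of a small set of housekeeping loci.  For each locus a
FASTA file holds every known allele, with headers of the form
``>locus_number`` (e.g. ``>adk_3``).  A tab-separated profile table maps each
observed combination of allele numbers to a sequence type (ST).  This module
loads, validates and manipulates those two artefacts; everything downstream
queries the in-memory :class:`AlleleDatabase` / :class:`ProfileTable`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from Bio import SeqIO

from .dna import VALID_BASES, revcomp

__all__ = [
    "Allele",
    "Locus",
    "AlleleDatabase",
    "ProfileTable",
    "DatabaseError",
    "ProfileError",
    "Finding",
    "load_allele_fasta",
    "load_database",
    "load_profile_table",
    "write_allele_fasta",
    "write_profile_table",
    "remove_alleles",
    "validate_db",
    "fetch_pubmlst",
]

#: profile-table columns that are metadata rather than loci (PubMLST dialect)
_NON_LOCUS_COLUMNS = {"clonal_complex", "species", "cc", "lineage", "mlst_clade"}


class DatabaseError(ValueError):
    """Raised for malformed allele FASTA files or inconsistent databases."""


class ProfileError(ValueError):
    """Raised for malformed or self-contradictory profile tables."""


@dataclass(frozen=True)
class Allele:
    """One reference allele: a numbered sequence variant of a locus."""

    locus_name: str
    allele_id: int
    sequence: str

    def __post_init__(self) -> None:
        if self.allele_id < 1:
            raise DatabaseError(f"allele id must be positive, got {self.allele_id}")
        if not self.sequence:
            raise DatabaseError(f"empty sequence for {self.locus_name}_{self.allele_id}")


@dataclass
class Locus:
    """A named locus together with its known alleles, ordered by allele id."""

    name: str
    alleles: list[Allele] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a.locus_name != self.name:
                raise DatabaseError(
                    f"allele {a.locus_name}_{a.allele_id} placed in locus {self.name}"
                )
        self.alleles = sorted(self.alleles, key=lambda a: a.allele_id)
        ids = [a.allele_id for a in self.alleles]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatabaseError(f"duplicate allele id(s) {dup} in locus {self.name}")

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    def get(self, allele_id: int) -> Allele | None:
        for a in self.alleles:
            if a.allele_id == allele_id:
                return a
        return None

    def min_allele_length(self) -> int:
        return min(len(a.sequence) for a in self.alleles)

    def kmer_set(self, k: int) -> set[str]:
        """All k-mers over both strands of every allele (recruitment seed index)."""
        kmers: set[str] = set()
        for a in self.alleles:
            for s in (a.sequence, revcomp(a.sequence)):
                kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
        return kmers


@dataclass
class AlleleDatabase:
    """All loci of a scheme, plus the schema (profile-table column order)."""

    loci: dict[str, Locus]
    schema: list[str]

    def __post_init__(self) -> None:
        if sorted(self.schema) != sorted(self.loci):
            raise DatabaseError(
                f"schema {self.schema} does not match loci {sorted(self.loci)}"
            )

    def locus(self, name: str) -> Locus:
        try:
            return self.loci[name]
        except KeyError:
            raise DatabaseError(f"unknown locus {name!r}") from None


@dataclass
class ProfileTable:
    """Injective mapping from allele-number tuples to ST identifiers."""

    schema: list[str]
    rows: dict[tuple[int, ...], int]

    def lookup(self, alleles: Mapping[str, int]) -> int | None:
        key = tuple(alleles[name] for name in self.schema)
        return self.rows.get(key)


class Finding(NamedTuple):
    """One database-validation observation (never an exception)."""

    locus: str
    kind: str
    detail: str


def _parse_header(token: str) -> tuple[str, int]:
    """Split a PubMLST FASTA id into (locus, allele number).

    The allele number is the integer after the *last* underscore, so locus
    names containing underscores stay parseable.
    """
    stem, sep, num = token.rpartition("_")
    if not sep or not num.isdigit():
        raise DatabaseError(
            f"header {token!r} does not follow the locus_number convention"
        )
    return stem, int(num)


def load_allele_fasta(
    path: str | Path,
    locus_name: str | None = None,
    on_ambiguous: str = "error",
) -> Locus:
    """Load one locus's allele FASTA.

    Parameters
    ----------
    path:
        FASTA file, headers ``>locus_number``.
    locus_name:
        Name of the locus; defaults to the filename stem.  Records whose
        header names a different locus are rejected.
    on_ambiguous:
        ``"error"`` (default) rejects records containing non-ACGT characters;
        ``"drop"`` silently skips them.  Exact matching downstream is
        undefined on ambiguity codes, so they never enter a database.
    """
    path = Path(path)
    if on_ambiguous not in ("error", "drop"):
        raise ValueError("on_ambiguous must be 'error' or 'drop'")
    name = locus_name if locus_name is not None else path.stem
    alleles: list[Allele] = []
    seen_ids: set[int] = set()
    for i, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        try:
            rec_locus, allele_id = _parse_header(record.id)
        except DatabaseError as exc:
            raise DatabaseError(f"{path}, record {i}: {exc}") from None
        if rec_locus != name:
            raise DatabaseError(
                f"{path}, record {i}: header names locus {rec_locus!r}, "
                f"expected {name!r}"
            )
        seq = str(record.seq).upper()
        if not seq:
            raise DatabaseError(f"{path}, record {i}: empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            if on_ambiguous == "drop":
                continue
            raise DatabaseError(
                f"{path}, record {i}: non-ACGT character(s) {sorted(bad)} "
                f"in {name}_{allele_id}"
            )
        if allele_id in seen_ids:
            raise DatabaseError(f"{path}: duplicate allele id {name}_{allele_id}")
        seen_ids.add(allele_id)
        alleles.append(Allele(name, allele_id, seq))
    if not alleles:
        raise DatabaseError(f"{path}: no alleles")
    return Locus(name=name, alleles=alleles)


def load_database(
    db_dir: str | Path,
    schema: Iterable[str] | None = None,
    on_ambiguous: str = "error",
) -> AlleleDatabase:
    """Load every locus FASTA in a directory (filename stem = locus name).

    ``schema`` fixes the locus order (typically from the profile table); by
    default loci are ordered alphabetically.
    """
    db_dir = Path(db_dir)
    paths = {p.stem: p for ext in ("*.fasta", "*.fa", "*.tfa") for p in db_dir.glob(ext)}
    if not paths:
        raise DatabaseError(f"no allele FASTA files found in {db_dir}")
    if schema is None:
        names = sorted(paths)
    else:
        names = list(schema)
        missing = [n for n in names if n not in paths]
        if missing:
            raise DatabaseError(f"missing allele FASTA file(s) for loci {missing} in {db_dir}")
    loci = {n: load_allele_fasta(paths[n], n, on_ambiguous=on_ambiguous) for n in names}
    return AlleleDatabase(loci=loci, schema=names)


def load_profile_table(path: str | Path) -> ProfileTable:
    """Parse a PubMLST profile TSV (``ST<TAB>locus1...locusL[<TAB>extras]``).

    Columns named like known metadata (clonal_complex, species, ...) and
    everything after the first such column are ignored.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ProfileError(f"{path}: empty profile table")
    header = lines[0].split("\t")
    if header[0].upper() != "ST":
        raise ProfileError(f"{path}: first column must be ST, got {header[0]!r}")
    schema: list[str] = []
    for col in header[1:]:
        if col.strip().lower() in _NON_LOCUS_COLUMNS:
            break
        schema.append(col.strip())
    if not schema:
        raise ProfileError(f"{path}: no locus columns found")
    rows: dict[tuple[int, ...], int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) < 1 + len(schema):
            raise ProfileError(f"{path}, line {lineno}: expected {1 + len(schema)} columns")
        try:
            st = int(cells[0])
            key = tuple(int(c) for c in cells[1 : 1 + len(schema)])
        except ValueError:
            raise ProfileError(f"{path}, line {lineno}: non-integer cell") from None
        if key in rows and rows[key] != st:
            raise ProfileError(
                f"{path}, line {lineno}: allele combination {key} maps to both "
                f"ST {rows[key]} and ST {st}"
            )
        rows[key] = st
    return ProfileTable(schema=schema, rows=rows)


def write_allele_fasta(locus: Locus, path: str | Path) -> None:
    """Write a locus back to PubMLST-convention FASTA (round-trips with load)."""
    with open(path, "w") as fh:
        for a in locus.alleles:
            fh.write(f">{a.locus_name}_{a.allele_id}\n{a.sequence}\n")


def write_profile_table(table: ProfileTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ST\t" + "\t".join(table.schema) + "\n")
        for key, st in sorted(table.rows.items(), key=lambda kv: kv[1]):
            fh.write(str(st) + "\t" + "\t".join(str(i) for i in key) + "\n")


def remove_alleles(db: AlleleDatabase, assignments: Mapping[str, int]) -> AlleleDatabase:
    """Return a copy of ``db`` lacking the named alleles (leave-one-out protocol).

    Used to measure new-allele detection: each sample's true alleles are
    removed from the reference before re-calling, so a correct caller must
    flag every locus as novel.  The input database is unchanged.
    """
    new_loci: dict[str, Locus] = {}
    for name, locus in db.loci.items():
        if name in assignments:
            target = assignments[name]
            if locus.get(target) is None:
                raise DatabaseError(f"cannot remove {name}_{target}: no such allele")
            kept = [a for a in locus.alleles if a.allele_id != target]
            if not kept:
                raise DatabaseError(f"removing {name}_{target} would empty locus {name}")
            new_loci[name] = Locus(name=name, alleles=kept)
        else:
            new_loci[name] = copy.deepcopy(locus)
    unknown = set(assignments) - set(db.loci)
    if unknown:
        raise DatabaseError(f"assignments name unknown loci {sorted(unknown)}")
    return AlleleDatabase(loci=new_loci, schema=list(db.schema))


def validate_db(db: AlleleDatabase) -> list[Finding]:
    """Report (never raise) duplicate sequences, non-ACGT characters, empty loci."""
    findings: list[Finding] = []
    for name, locus in db.loci.items():
        if not locus.alleles:
            findings.append(Finding(name, "empty_locus", "locus has no alleles"))
            continue
        by_seq: dict[str, list[int]] = {}
        for a in locus.alleles:
            by_seq.setdefault(a.sequence, []).append(a.allele_id)
            bad = set(a.sequence) - VALID_BASES
            if bad:
                findings.append(
                    Finding(name, "non_acgt", f"allele {a.allele_id} contains {sorted(bad)}")
                )
        for seq, ids in by_seq.items():
            if len(ids) > 1:
                findings.append(
                    Finding(name, "duplicate_sequence", f"alleles {ids} share one sequence")
                )
    return findings


def fetch_pubmlst(scheme: str, out_dir: str | Path):  # pragma: no cover - stub
    """Stub for fetching a scheme from PubMLST (https://pubmlst.org).

    The live service exposes per-locus allele FASTAs at
    ``https://rest.pubmlst.org/db/<database>/loci/<locus>/alleles_fasta`` and
    profile tables at ``.../schemes/<id>/profiles_csv``.  Network access is
    deliberately out of scope; generate data with :mod:`mlstkit.simulate` or
    download files manually.
    """
    raise NotImplementedError("PubMLST download is not implemented; see docstring")
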