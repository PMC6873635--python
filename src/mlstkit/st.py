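"""Sequence-type assignment: combine per-locus allele calls via the profile table.

An ST is a numeric identifier for one unique combination of allele numbers
across the scheme's loci, so a known ST requires an exact call at *every*
locus and the resulting tuple to exist in the profile table.  A sample whose
loci all resolve (exactly or as novel alleles) but whose combination is
absent — or which carries any novel allele — is a novel combination; any
unresolved locus makes the assignment incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .calling import AlleleCall
from .db import ProfileTable

__all__ = ["STCall", "assign_st"]


@dataclass(frozen=True)
class STCall:
    """ST-level outcome for one sample."""

    sample_id: str
    locus_calls: Mapping[str, AlleleCall]
    st_status: str  # "known" | "novel_combination" | "incomplete"
    st_id: int | None = None

    def label(self) -> str:
        """Report vocabulary: ST number, ``new`` or ``ND``."""
        if self.st_status == "known":
            return str(self.st_id)
        if self.st_status == "novel_combination":
            return "new"
        return "ND"


def assign_st(
    calls: Mapping[str, AlleleCall],
    profiles: ProfileTable,
    sample_id: str = "",
) -> STCall:
    """Assign an ST from per-locus calls.

    Every schema locus must be present in ``calls``.  All-exact calls whose
    allele tuple exists in the table give a known ST; fully resolved samples
    with an unseen tuple or any novel allele are a novel combination; any
    low-coverage or no-output locus makes the sample incomplete.
    """
    missing = [name for name in profiles.schema if name not in calls]
    if missing:
        raise ValueError(f"calls missing schema locus/loci {missing}")
    statuses = {name: calls[name].status for name in profiles.schema}
    if any(s in ("low_coverage", "no_output") for s in statuses.values()):
        return STCall(sample_id, dict(calls), "incomplete")
    if all(s == "exact" for s in statuses.values()):
        st = profiles.lookup({n: calls[n].allele_id for n in profiles.schema})
        if st is not None:
            return STCall(sample_id, dict(calls), "known", st_id=st)
    return STCall(sample_id, dict(calls), "novel_combination")
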