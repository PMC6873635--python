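"""Benchmark metrics for typing tools.

Three performance measures are computed over a set of predictions against an
experimentally established truth:

* **Percentage of no-output** — the fraction of labels for which a tool
  reports nothing usable (a blank, NA, or a low-coverage message).
* **Capability to identify correct alleles** — the fraction of labels equal
  to the true allele number, with predictions made against the full
  reference database.  Blanks count as misses.
* **Capability to identify new alleles** — the fraction of labels flagging a
  novel allele when predictions were made against a reference from which
  each sample's true alleles had been removed (leave-correct-allele-out).
  Labels naming any remaining reference allele count as misses.

The same three fractions are also computed at ST level, where a hit requires
the whole seven-allele combination to be right.

Starred labels
--------------
Mapping-based tools emit ``allele*`` to mean "closest allele, with at least
one mismatch" — often a novel allele.  Two interpretations are supported:
under **high** stringency a star is read as a new-allele flag (a starred
correct id therefore misses the correct allele, and a starred id on a
reduced database hits as new); under **low** stringency the star is ignored
(the bare id is the prediction, so it can hit the correct allele but never
flags novelty).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .db import ProfileTable

__all__ = [
    "TruthRecord",
    "PredictionRecord",
    "MetricsSummary",
    "pct_no_output",
    "capability_correct",
    "capability_new",
    "st_metrics",
]

#: labels that convey no allele call at all
_BLANK = {"", "na", "nd", "-", "low coverage", "low_coverage", "no output", "no_output"}


@dataclass(frozen=True)
class TruthRecord:
    """Experimentally assigned alleles and ST for one sample."""

    sample_id: str
    true_alleles: Mapping[str, int]
    true_st: int


@dataclass(frozen=True)
class PredictionRecord:
    """One tool's per-locus labels (and optional ST label) for one sample.

    Labels are free text in the tools' output vocabulary: an allele number
    (``"5"``), a starred number (``"5*"``), a new-allele flag (``"New?"``),
    a low-coverage message, or blank.
    """

    sample_id: str
    labels: Mapping[str, str]
    st_label: str | None = None


@dataclass(frozen=True)
class MetricsSummary:
    """The three benchmark fractions plus their denominator."""

    pct_no_output: float
    capability_correct: float
    capability_new: float
    n_labels: int


def _is_blank(label: str) -> bool:
    return label.strip().lower() in _BLANK


def _is_new_flag(label: str, stringency: str) -> bool:
    label = label.strip()
    if label.lower() in ("new?", "new"):
        return True
    if label.endswith("*"):
        return stringency == "high"
    return False


def _parse_allele(label: str, stringency: str) -> int | None:
    """The allele number a label asserts, or None if it asserts none."""
    label = label.strip()
    if label.endswith("*"):
        if stringency == "high":
            return None  # the star is read as "novel", not as the bare id
        label = label[:-1]
    try:
        return int(label)
    except ValueError:
        return None


def _check_stringency(stringency: str) -> None:
    if stringency not in ("high", "low"):
        raise ValueError("stringency must be 'high' or 'low'")


def _paired(
    preds: Sequence[PredictionRecord], truth: Sequence[TruthRecord]
) -> list[tuple[PredictionRecord, TruthRecord]]:
    by_id = {t.sample_id: t for t in truth}
    missing = [p.sample_id for p in preds if p.sample_id not in by_id]
    if missing:
        raise ValueError(f"no truth record for sample(s) {missing}")
    return [(p, by_id[p.sample_id]) for p in preds]


def pct_no_output(preds: Sequence[PredictionRecord]) -> float:
    """Fraction of per-locus labels that are blank (or low-coverage/NA)."""
    labels = [lab for p in preds for lab in p.labels.values()]
    if not labels:
        raise ValueError("no predictions supplied")
    return sum(_is_blank(lab) for lab in labels) / len(labels)


def capability_correct(
    preds: Sequence[PredictionRecord],
    truth: Sequence[TruthRecord],
    stringency: str = "high",
) -> float:
    """Fraction of labels equal to the true allele id (blanks are misses)."""
    _check_stringency(stringency)
    hits = total = 0
    for pred, tr in _paired(preds, truth):
        for locus, true_id in tr.true_alleles.items():
            label = pred.labels.get(locus, "")
            total += 1
            if _parse_allele(label, stringency) == true_id:
                hits += 1
    if not total:
        raise ValueError("no labels to score")
    return hits / total


def capability_new(
    preds: Sequence[PredictionRecord],
    truth: Sequence[TruthRecord],
    stringency: str = "high",
) -> float:
    """Fraction of labels flagging a novel allele on the reduced reference.

    ``preds`` must have been produced against a database from which each
    sample's true alleles were removed; any label naming a remaining
    reference allele (or blank) is a miss.
    """
    _check_stringency(stringency)
    hits = total = 0
    for pred, tr in _paired(preds, truth):
        for locus in tr.true_alleles:
            label = pred.labels.get(locus, "")
            total += 1
            if _is_new_flag(label, stringency):
                hits += 1
    if not total:
        raise ValueError("no labels to score")
    return hits / total


def st_metrics(
    preds: Sequence[PredictionRecord],
    truth: Sequence[TruthRecord],
    profiles: ProfileTable | None = None,
    stringency: str = "high",
    reduced_preds: Sequence[PredictionRecord] | None = None,
) -> MetricsSummary:
    """The three fractions over per-sample ST labels.

    ``preds`` carries full-database ST labels (scored for correctness);
    ``reduced_preds``, when given, carries leave-one-out ST labels (scored
    for novelty).  ``profiles`` is accepted for interface symmetry; the ST
    labels themselves are what is scored.
    """
    _check_stringency(stringency)
    del profiles
    pairs = _paired(preds, truth)
    if not pairs:
        raise ValueError("no predictions supplied")
    labels = [(p.st_label or "") for p, _ in pairs]
    blank = sum(_is_blank(lab) for lab in labels)
    correct = sum(
        _parse_allele(lab, stringency) == tr.true_st
        for lab, (_, tr) in zip(labels, pairs)
    )
    if reduced_preds is not None:
        red_labels = [(p.st_label or "") for p, _ in _paired(reduced_preds, truth)]
    else:
        red_labels = labels
    new = sum(_is_new_flag(lab, stringency) for lab in red_labels)
    n = len(labels)
    return MetricsSummary(
        pct_no_output=blank / n,
        capability_correct=correct / n,
        capability_new=new / len(red_labels),
        n_labels=n,
    )
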