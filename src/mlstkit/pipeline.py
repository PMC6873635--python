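"""Per-sample pipeline orchestration and benchmark evaluation.

``run_sample`` executes the whole chain for one isolate: merge its FASTQ
files, recruit reads per locus, call every locus independently (optionally
in parallel worker processes — results are identical for any worker count),
assign the ST, and write the report row plus any novel-allele FASTAs.
``run_benchmark`` additionally re-calls every sample against a per-sample
reduced database (leave-correct-allele-out) and scores the three benchmark
metrics at allele and ST level.
"""

from __future__ import annotations

import logging
import re
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .calling import AlleleCall, CallParams, call_recruited, write_new_alleles
from .db import (
    AlleleDatabase,
    DatabaseError,
    ProfileTable,
    load_database,
    load_profile_table,
    remove_alleles,
)
from .metrics import MetricsSummary, PredictionRecord, TruthRecord, capability_correct, capability_new, pct_no_output, st_metrics
from .recruit import Read, RecruitmentTiers, merge_fastq, recruit_all
from .st import STCall, assign_st

__all__ = [
    "RunConfig",
    "BenchmarkResult",
    "call_sample",
    "run_sample",
    "run_batch",
    "run_benchmark",
    "discover_samples",
    "load_truth",
]

logger = logging.getLogger(__name__)

_MATE_SUFFIX = re.compile(r"(_R?[12])$")


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run."""

    reads_dir: Path
    db_dir: Path
    profile_path: Path
    out_dir: Path
    workers: int = 1
    params: CallParams = field(default_factory=CallParams)

    def __post_init__(self) -> None:
        self.reads_dir = Path(self.reads_dir)
        self.db_dir = Path(self.db_dir)
        self.profile_path = Path(self.profile_path)
        self.out_dir = Path(self.out_dir)
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass(frozen=True)
class BenchmarkResult:
    """Benchmark metrics plus the per-sample predictions they were scored on."""

    allele_metrics: MetricsSummary
    st_summary: MetricsSummary
    full_predictions: tuple[PredictionRecord, ...]
    reduced_predictions: tuple[PredictionRecord, ...]


def _call_one(args: tuple[RecruitmentTiers, object, CallParams]) -> AlleleCall:
    """Call one recruited locus; a fault becomes a no_output call, never a crash."""
    tiers, locus, params = args
    try:
        return call_recruited(tiers, locus, params)
    except Exception:
        logger.exception("locus %s failed", locus.name)
        return AlleleCall(locus.name, "no_output")


def call_sample(
    reads: Sequence[Read],
    db: AlleleDatabase,
    profiles: ProfileTable,
    params: CallParams | None = None,
    workers: int = 1,
    sample_id: str = "sample",
) -> STCall:
    """Call every locus of one read set and assign the ST.

    Loci are processed independently; a fault in one locus yields a
    ``no_output`` call for that locus only and the run continues.  Results
    are deterministic and identical for any ``workers`` value.
    """
    params = params or CallParams()
    tiers_by_locus = recruit_all(reads, db, params.seed_length)
    jobs = [(tiers_by_locus[name], db.loci[name], params) for name in db.schema]
    calls: dict[str, AlleleCall] = {}
    if workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_call_one, jobs))
    else:
        results = [_call_one(job) for job in jobs]
    for name, call in zip(db.schema, results):
        calls[name] = call
    return assign_st(calls, profiles, sample_id=sample_id)


def discover_samples(reads_dir: str | Path) -> dict[str, list[Path]]:
    """Group FASTQ files in a directory by sample id.

    Files ``<sample>_1.fastq[.gz]`` / ``<sample>_2.fastq[.gz]`` (also
    ``_R1``/``_R2``) pair up; any other ``<sample>.fastq[.gz]`` stands
    alone.
    """
    reads_dir = Path(reads_dir)
    groups: dict[str, list[Path]] = {}
    for path in sorted(reads_dir.iterdir()):
        name = path.name
        if name.endswith(".gz"):
            name = name[:-3]
        if not (name.endswith(".fastq") or name.endswith(".fq")):
            continue
        stem = name.rsplit(".", 1)[0]
        stem = _MATE_SUFFIX.sub("", stem)
        groups.setdefault(stem, []).append(path)
    return groups


def _load_inputs(config: RunConfig) -> tuple[AlleleDatabase, ProfileTable]:
    profiles = load_profile_table(config.profile_path)
    try:
        db = load_database(config.db_dir, schema=profiles.schema)
    except DatabaseError as exc:
        raise DatabaseError(f"cannot load allele database: {exc}") from None
    return db, profiles


def _report_row(st_call: STCall, schema: Sequence[str]) -> dict[str, str]:
    row = {"sample": st_call.sample_id}
    for name in schema:
        row[name] = st_call.locus_calls[name].label()
    row["ST"] = st_call.label()
    return row


def run_sample(config: RunConfig, sample_id: str) -> tuple[STCall, dict[str, str]]:
    """Run the pipeline on one sample resolved from ``reads_dir`` by id."""
    db, profiles = _load_inputs(config)
    groups = discover_samples(config.reads_dir)
    if sample_id not in groups:
        raise FileNotFoundError(f"no FASTQ files for sample {sample_id!r} in {config.reads_dir}")
    reads = merge_fastq(groups[sample_id])
    st_call = call_sample(
        reads, db, profiles, config.params, workers=config.workers, sample_id=sample_id
    )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    write_new_alleles(st_call.locus_calls.values(), config.out_dir, sample_id=sample_id)
    for name in db.schema:
        call = st_call.locus_calls[name]
        logger.info(
            "sample=%s locus=%s status=%s tier=%s k=%s",
            sample_id, name, call.status, call.tier_used, call.k_used,
        )
    return st_call, _report_row(st_call, db.schema)


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Run every sample in ``reads_dir``; write ``report.tsv`` to ``out_dir``."""
    db, profiles = _load_inputs(config)
    rows = []
    for sample_id in sorted(discover_samples(config.reads_dir)):
        _, row = run_sample(config, sample_id)
        rows.append(row)
    report = pd.DataFrame(rows, columns=["sample", *db.schema, "ST"])
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(config.out_dir / "report.tsv", sep="\t", index=False)
    return report


def load_truth(path: str | Path, schema: Sequence[str]) -> list[TruthRecord]:
    """Read a truth TSV (``sample``, one column per locus, ``ST``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample", *schema, "ST") if c not in frame.columns]
    if missing:
        raise ValueError(f"truth table missing column(s) {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            TruthRecord(
                sample_id=row["sample"],
                true_alleles={n: int(row[n]) for n in schema},
                true_st=int(row["ST"]),
            )
        )
    return records


def _prediction(st_call: STCall, schema: Sequence[str]) -> PredictionRecord:
    return PredictionRecord(
        sample_id=st_call.sample_id,
        labels={n: st_call.locus_calls[n].label() for n in schema},
        st_label=st_call.label(),
    )


def run_benchmark(
    config: RunConfig,
    truth_path: str | Path,
    stringency: str = "high",
) -> BenchmarkResult:
    """Score the pipeline against a truth table.

    Every sample is called twice: against the full reference database
    (capability to identify correct alleles/STs) and against a per-sample
    database from which its true alleles were removed (capability to
    identify new alleles/STs).  Unknown sample ids in the truth table raise.
    """
    db, profiles = _load_inputs(config)
    truth = load_truth(truth_path, db.schema)
    groups = discover_samples(config.reads_dir)
    unknown = [t.sample_id for t in truth if t.sample_id not in groups]
    if unknown:
        raise ValueError(f"truth table names unknown sample(s) {unknown}")
    full_preds: list[PredictionRecord] = []
    reduced_preds: list[PredictionRecord] = []
    for record in truth:
        reads = merge_fastq(groups[record.sample_id])
        st_full = call_sample(
            reads, db, profiles, config.params,
            workers=config.workers, sample_id=record.sample_id,
        )
        full_preds.append(_prediction(st_full, db.schema))
        reduced_db = remove_alleles(db, record.true_alleles)
        st_reduced = call_sample(
            reads, reduced_db, profiles, config.params,
            workers=config.workers, sample_id=record.sample_id,
        )
        reduced_preds.append(_prediction(st_reduced, db.schema))
    allele_metrics = MetricsSummary(
        pct_no_output=pct_no_output(full_preds),
        capability_correct=capability_correct(full_preds, truth, stringency),
        capability_new=capability_new(reduced_preds, truth, stringency),
        n_labels=len(truth) * len(db.schema),
    )
    st_summary = st_metrics(
        full_preds, truth, profiles, stringency, reduced_preds=reduced_preds
    )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    for name, preds in (("full", full_preds), ("reduced", reduced_preds)):
        frame = pd.DataFrame(
            [{"sample": p.sample_id, **p.labels, "ST": p.st_label} for p in preds],
            columns=["sample", *db.schema, "ST"],
        )
        frame.to_csv(config.out_dir / f"predictions_{name}.tsv", sep="\t", index=False)
    return BenchmarkResult(
        allele_metrics=allele_metrics,
        st_summary=st_summary,
        full_predictions=tuple(full_preds),
        reduced_predictions=tuple(reduced_preds),
    )
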