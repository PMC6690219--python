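"""Benchmark scoring: truth matching, precision/recall/F-score, full runs.

A call counts as a true positive when its position lies within a tolerance
window (default +/-100 bp) of a planted insertion, matched one-to-one in
order of increasing distance.  ``run_benchmark`` reproduces the simulation
protocol end to end: plant insertions into a genome, simulate paired-end
reads at each requested coverage, run the calling pipeline, and score the
calls against the truth table.
"""

from __future__ import annotations

import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import InsertionCall
from .simulate import (
    ReadSimParams,
    TruthRecord,
    insert_tdna,
    random_genome,
    random_tdna,
    simulate_reads,
)


@dataclass(frozen=True)
class BenchmarkResult:
    """Confusion counts and derived scores for one call set vs one truth set."""

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f_score: float
    n_truth_complete: int = 0
    n_truth_truncated: int = 0
    tp_complete: int = 0
    tp_truncated: int = 0


def match_calls(
    calls: Sequence[InsertionCall],
    truth: Sequence[TruthRecord],
    tol: int = 100,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one matching by increasing |call - truth| distance.

    Returns ``(tp, fp, fn, pairs)`` where pairs holds (call index, truth
    index) for every match.  Unmatched calls are false positives, unmatched
    truth records false negatives.
    """
    candidates = []
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truth):
            if call.chr != t.chr:
                continue
            dist = abs(call.position - t.position)
            if dist <= tol:
                candidates.append((dist, ci, ti))
    candidates.sort()
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _dist, ci, ti in candidates:
        if ci in used_calls or ti in used_truth:
            continue
        used_calls.add(ci)
        used_truth.add(ti)
        pairs.append((ci, ti))
    tp = len(pairs)
    return tp, len(calls) - tp, len(truth) - tp, pairs


def score(tp: int, fp: int, fn: int, **per_class) -> BenchmarkResult:
    """Precision, recall and F-score from confusion counts.

    An undefined ratio (zero denominator) is reported as ``None`` and
    treated as zero in the harmonic mean.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    p = precision or 0.0
    r = recall or 0.0
    f_score = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return BenchmarkResult(tp, fp, fn, precision, recall, f_score, **per_class)


def evaluate_calls(
    calls: Sequence[InsertionCall],
    truth: Sequence[TruthRecord],
    tol: int = 100,
) -> BenchmarkResult:
    """Match then score, with per-class (complete vs truncated) counts."""
    tp, fp, fn, pairs = match_calls(calls, truth, tol)
    matched_truth = {ti for _ci, ti in pairs}
    n_complete = sum(1 for t in truth if not t.truncated)
    n_truncated = len(truth) - n_complete
    tp_complete = sum(1 for ti in matched_truth if not truth[ti].truncated)
    return score(
        tp,
        fp,
        fn,
        n_truth_complete=n_complete,
        n_truth_truncated=n_truncated,
        tp_complete=tp_complete,
        tp_truncated=tp - tp_complete,
    )


def run_benchmark(
    coverages: Sequence[float],
    seed: int,
    genome_length: int = 10_000_000,
    n_insertions: int = 100,
    tdna_length: int = 6743,
    min_gap: int = 2000,
    read_length: int = 150,
    fragment_mean: float = 500.0,
    fragment_sd: float = 50.0,
    base_error_rate: float = 0.01,
    tol: int = 100,
    workdir: str | Path | None = None,
    keep_intermediates: bool = False,
    estimate_zygosity: bool = False,
    aligner=None,
    min_support: int = 3,
) -> pd.DataFrame:
    """Simulate, call, and score at each coverage; returns one row per coverage.

    One genome + insertion set is drawn per seed and shared across
    coverages, so rows differ only in sequencing depth.  Zygosity
    estimation is skipped by default: the F-score does not use it and the
    all-read ICF remap dominates the runtime.
    """
    from .formats import ReferenceSequence, write_fasta, write_truth_table
    from .pipeline import PipelineConfig, run_call_pipeline

    own_workdir = workdir is None
    workdir = Path(tempfile.mkdtemp(prefix="tdnaseeker-bench-")) if own_workdir else Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    try:
        rng = np.random.default_rng([seed, 0])
        genome = random_genome(genome_length, rng)
        tdna = random_tdna(rng, tdna_length)
        mutated, truth = insert_tdna(genome, tdna, n_insertions, rng, min_gap=min_gap)

        genome_fa = workdir / "genome.fa"
        tdna_fa = workdir / "tdna.fa"
        write_fasta(genome, genome_fa)
        write_fasta([ReferenceSequence(tdna.id, tdna.sequence)], tdna_fa)
        write_truth_table(truth, workdir / "truth.tsv")

        rows = []
        for i, coverage in enumerate(coverages):
            covdir = workdir / f"cov{coverage:g}"
            covdir.mkdir(exist_ok=True)
            params = ReadSimParams(
                coverage=coverage,
                read_length=read_length,
                fragment_mean=fragment_mean,
                fragment_sd=fragment_sd,
                base_error_rate=base_error_rate,
                seed=int(np.random.SeedSequence([seed, 1, i]).generate_state(1)[0] % 2**31),
            )
            fq1, fq2 = covdir / "sim_1.fq", covdir / "sim_2.fq"
            simulate_reads(mutated, params, fq1, fq2)
            config = PipelineConfig(
                fastq1=fq1,
                fastq2=fq2,
                tdna_fasta=tdna_fa,
                genome_fasta=genome_fa,
                out_dir=covdir / "out",
                min_support=min_support,
                estimate_zygosity=estimate_zygosity,
                aligner=aligner,
            )
            calls, _stats = run_call_pipeline(config)
            result = evaluate_calls(calls, truth, tol)
            rows.append(
                {
                    "coverage": coverage,
                    "n_truth": len(truth),
                    "n_calls": len(calls),
                    "tp": result.tp,
                    "fp": result.fp,
                    "fn": result.fn,
                    "precision": result.precision,
                    "recall": result.recall,
                    "f_score": result.f_score,
                }
            )
            if not keep_intermediates:
                shutil.rmtree(covdir, ignore_errors=True)
        return pd.DataFrame(rows)
    finally:
        if own_workdir and not keep_intermediates:
            shutil.rmtree(workdir, ignore_errors=True)
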