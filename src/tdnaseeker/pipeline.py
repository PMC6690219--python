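"""The five-stage calling pipeline.

1. map all paired-end reads to the T-DNA construct;
2. extract the stage-1 informative candidates (IR1);
3. realign the candidates to the host genome;
4. classify (IR2), cluster, and call insertions;
5. remap all reads to the +/-500 bp flanks of each call to estimate the
   insertion frequency, then annotate against gene models.

Every intermediate is written to the output directory in a standard format
(SAM/TSV/FASTA) so any stage can be replayed in isolation, and each stage
alternatively accepts a pre-computed SAM file so the core logic runs
without an aligner binary.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate as _annotate
from . import caller as _caller
from . import informative as _informative
from . import zygosity as _zygosity
from .aligner import BwaMem
from .formats import (
    read_fasta,
    read_gff3,
    read_sam,
    write_call_table,
    write_fasta,
    write_fastq,
)

logger = logging.getLogger("tdnaseeker")


class ConfigurationError(ValueError):
    """The pipeline configuration is unusable; raised before any work."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one calling run.

    Either the FASTQ pair plus an available aligner, or pre-computed SAM
    paths (``tdna_sam``/``genome_sam``), must be supplied.
    """

    tdna_fasta: str | Path
    genome_fasta: str | Path
    out_dir: str | Path
    fastq1: str | Path | None = None
    fastq2: str | Path | None = None
    gff3: str | Path | None = None
    tdna_sam: str | Path | None = None
    genome_sam: str | Path | None = None
    min_support: int = 3
    win_clr: int = 5
    win_dir: int = 500
    min_clip: int = 20
    clip_tol: int = 5
    flank: int = 500
    min_mapq: int = 30
    span_overhang: int = 5
    workers: int = 1
    estimate_zygosity: bool = True
    feature_types: tuple[str, ...] = ("gene",)
    aligner: BwaMem | None = None

    def validate(self) -> None:
        for name in ("min_support", "win_clr", "win_dir", "min_clip", "flank",
                     "span_overhang", "workers"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.clip_tol < 0 or self.min_mapq < 0:
            raise ConfigurationError("clip_tol and min_mapq must be non-negative")
        for name in ("tdna_fasta", "genome_fasta"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise ConfigurationError(f"{name} missing: {path}")
        have_fastq = self.fastq1 is not None and self.fastq2 is not None
        if have_fastq:
            for path in (self.fastq1, self.fastq2):
                if not Path(path).exists():
                    raise ConfigurationError(f"FASTQ file missing: {path}")
        if self.tdna_sam is None:
            if not have_fastq:
                raise ConfigurationError(
                    "either a FASTQ pair or a pre-computed T-DNA SAM is required"
                )
            if not self._aligner().available():
                raise ConfigurationError(
                    "no aligner binary available and no pre-computed SAM supplied"
                )
        if self.estimate_zygosity and not have_fastq:
            raise ConfigurationError("zygosity estimation needs the FASTQ pair")
        if self.gff3 is not None and not Path(self.gff3).exists():
            raise ConfigurationError(f"GFF3 file missing: {self.gff3}")

    def _aligner(self) -> BwaMem:
        return self.aligner if self.aligner is not None else BwaMem()


def run_call_pipeline(config: PipelineConfig):
    """Run the full pipeline; returns ``(calls, stats)``.

    ``stats`` records read counts at every stage (reads mapped to the
    T-DNA, IR1, IR2, clusters, calls), mirroring the log output.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aligner = config._aligner()
    stats: dict[str, int] = {}

    tdna_seqs = read_fasta(config.tdna_fasta)
    if len(tdna_seqs) != 1:
        raise ConfigurationError("the T-DNA FASTA must contain exactly one sequence")
    tdna_length = len(tdna_seqs[0])

    # stage 1: map everything to the T-DNA construct
    t0 = time.perf_counter()
    if config.tdna_sam is not None:
        tdna_sam = Path(config.tdna_sam)
    else:
        tdna_sam = out / "tdna.sam"
        try:
            aligner.map_paired(config.tdna_fasta, config.fastq1, config.fastq2, tdna_sam)
        except Exception as exc:
            raise PipelineError(f"stage 'map-to-tdna' failed: {exc}") from exc
    logger.info("stage map-to-tdna done in %.1fs", time.perf_counter() - t0)

    # stage 2: IR1 extraction
    t0 = time.perf_counter()
    n_mapped = 0

    def _counting(records):
        nonlocal n_mapped
        for rec in records:
            if rec.is_mapped:
                n_mapped += 1
            yield rec

    try:
        candidates = _informative.extract_ir1(
            _counting(read_sam(tdna_sam)), config.min_clip, config.workers
        )
    except Exception as exc:
        raise PipelineError(f"stage 'extract-ir1' failed: {exc}") from exc
    stats["reads_mapped_to_tdna"] = n_mapped
    stats["n_ir1"] = len(candidates)
    logger.info(
        "stage extract-ir1 done in %.1fs: %d reads mapped to T-DNA, %d candidates",
        time.perf_counter() - t0, n_mapped, len(candidates),
    )

    # stage 3: realign candidates to the host genome
    t0 = time.perf_counter()
    by_tag = {cand.tag: cand for cand in candidates}
    if config.genome_sam is not None:
        genome_records = list(read_sam(config.genome_sam))
    elif candidates:
        ir1_fq = out / "ir1.fq"
        write_fastq(((c.tag, c.sequence) for c in candidates), ir1_fq)
        genome_sam = out / "genome.sam"
        try:
            aligner.map_single(config.genome_fasta, ir1_fq, genome_sam)
        except Exception as exc:
            raise PipelineError(f"stage 'map-to-genome' failed: {exc}") from exc
        genome_records = list(read_sam(genome_sam))
    else:
        genome_records = []
    logger.info("stage map-to-genome done in %.1fs", time.perf_counter() - t0)

    # stage 4: classify IR2, cluster, call
    t0 = time.perf_counter()
    informative_reads = []
    for rec in genome_records:
        if not rec.is_mapped:
            continue
        cand = by_tag.get(rec.query_name)
        if cand is None:
            continue
        if cand.role == _informative.CLR and not _informative.check_clip_consistency(
            cand.tdna_record.cigar, rec.cigar, config.clip_tol
        ):
            continue
        ir = _informative.classify_ir2(
            cand.tdna_record, rec, tdna_length, read_type=cand.role
        )
        if ir is not None:
            ir.query_name = cand.query_name
            informative_reads.append(ir)
    stats["n_ir2"] = len(informative_reads)
    _informative.write_ir_table(informative_reads, out / "ir.tsv")

    calls = _caller.call_insertions(
        informative_reads,
        tdna_length,
        min_support=config.min_support,
        win_clr=config.win_clr,
        win_dir=config.win_dir,
    )
    stats["n_calls"] = len(calls)
    write_call_table(calls, out / "calls.raw.tsv")
    logger.info(
        "stage cluster-and-call done in %.1fs: %d IR2, %d calls",
        time.perf_counter() - t0, len(informative_reads), len(calls),
    )

    # stage 5: zygosity + annotation
    if config.estimate_zygosity and calls:
        t0 = time.perf_counter()
        try:
            genome = read_fasta(config.genome_fasta)
            icf = _zygosity.build_icf(genome, calls, config.flank)
            icf_fa = out / "icf.fa"
            write_fasta(_zygosity.icf_fasta_records(icf), icf_fa)
            icf_sam = out / "icf.sam"
            aligner.map_paired(icf_fa, config.fastq1, config.fastq2, icf_sam)
            _zygosity.assign_frequencies(
                calls, read_sam(icf_sam), config.min_mapq, config.span_overhang
            )
        except Exception as exc:
            raise PipelineError(f"stage 'zygosity' failed: {exc}") from exc
        logger.info("stage zygosity done in %.1fs", time.perf_counter() - t0)

    if config.gff3 is not None:
        try:
            features = read_gff3(config.gff3, config.feature_types)
            _annotate.annotate_calls(calls, features)
        except Exception as exc:
            raise PipelineError(f"stage 'annotation' failed: {exc}") from exc

    write_call_table(calls, out / "calls.tsv")
    logger.info("pipeline finished: %d calls", len(calls))
    return calls, stats
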