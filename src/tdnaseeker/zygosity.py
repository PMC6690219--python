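"""Insertion-frequency (zygosity) estimation.

For every call, the reference-allele sequence +/-500 bp around the
insertion point is extracted into an Insertion Candidate FASTA (ICF).  All
reads are remapped to the ICF records; a read with mapping quality >= 30
whose aligned interval spans the insertion point by at least 5 bp on both
sides testifies for the reference allele.  The insertion frequency is

    freq = N_clr / (N_clr + N_span)

where ``N_clr`` is the soft-clip support counted by the caller and
``N_span`` the junction-spanning count — about 0.5 for a heterozygous and
about 1 for a homozygous insertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .caller import InsertionCall
from .formats import AlignmentRecord, ReferenceSequence

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
LOW_FREQUENCY = "low_frequency"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ICFRecord:
    """Reference-allele flanking sequence for one call.

    ``junction_offset`` is the 1-based position of the insertion point
    within the record (the last base before the insertion); it equals the
    flank size except near contig edges, where the flank is truncated.
    """

    chr: str
    position: int
    sequence: str
    junction_offset: int

    @property
    def name(self) -> str:
        return f"{self.chr}:{self.position}"


def build_icf(
    genome: Mapping[str, str] | Sequence[ReferenceSequence],
    calls: Iterable[InsertionCall],
    flank: int = 500,
) -> list[ICFRecord]:
    """One ICF record per call, flanks clipped at contig boundaries."""
    if not isinstance(genome, Mapping):
        genome = {s.id: s.sequence for s in genome}
    records = []
    for call in calls:
        if call.chr not in genome:
            raise ValueError(f"call on unknown chromosome {call.chr!r}")
        seq = genome[call.chr]
        if not 1 <= call.position <= len(seq):
            raise ValueError(
                f"call position {call.chr}:{call.position} outside the contig"
            )
        lo = max(call.position - flank + 1, 1)
        hi = min(call.position + flank, len(seq))
        records.append(
            ICFRecord(
                chr=call.chr,
                position=call.position,
                sequence=seq[lo - 1 : hi],
                junction_offset=call.position - lo + 1,
            )
        )
    return records


def icf_fasta_records(icf: Iterable[ICFRecord]) -> list[ReferenceSequence]:
    """ICF records as FASTA entries named ``chr:position|offset``."""
    return [
        ReferenceSequence(f"{r.name}|{r.junction_offset}", r.sequence) for r in icf
    ]


def parse_icf_name(name: str) -> tuple[str, int, int]:
    """Inverse of :func:`icf_fasta_records` naming -> (chr, position, offset)."""
    locus, _, offset = name.rpartition("|")
    chrom, _, pos = locus.rpartition(":")
    return chrom, int(pos), int(offset)


def count_spanning(
    alignments: Iterable[AlignmentRecord],
    junction_offset: int,
    min_mapq: int = 30,
    min_overhang: int = 5,
) -> int:
    """Count reads whose alignment spans the junction on both sides.

    A read counts when it is a mapped primary alignment with
    ``mapq >= min_mapq`` whose aligned reference interval covers
    ``[junction_offset - min_overhang + 1, junction_offset + min_overhang]``.
    """
    lo = junction_offset - min_overhang + 1
    hi = junction_offset + min_overhang
    n = 0
    for rec in alignments:
        if not rec.is_mapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapq < min_mapq:
            continue
        if rec.position <= lo and rec.reference_end >= hi:
            n += 1
    return n


def insertion_frequency(n_clr: int, n_span: int) -> float | None:
    """``n_clr / (n_clr + n_span)``; ``None`` when there is no evidence."""
    if n_clr < 0 or n_span < 0:
        raise ValueError("read counts must be non-negative")
    total = n_clr + n_span
    if total == 0:
        return None
    return n_clr / total


def label_zygosity(
    freq: float | None,
    homozygous_min: float = 0.8,
    heterozygous_min: float = 0.3,
) -> str:
    """Coarse zygosity label from the insertion frequency."""
    if freq is None:
        return UNDETERMINED
    if freq >= homozygous_min:
        return HOMOZYGOUS
    if freq >= heterozygous_min:
        return HETEROZYGOUS
    return LOW_FREQUENCY


def assign_frequencies(
    calls: Sequence[InsertionCall],
    icf_alignments: Iterable[AlignmentRecord],
    min_mapq: int = 30,
    min_overhang: int = 5,
) -> None:
    """Fill ``call.freq`` in place from an ICF remapping stream.

    ``N_clr`` is taken from the caller's cluster (not recounted on the
    ICF); frequencies are reported rounded to two decimals.
    """
    span_counts: dict[tuple[str, int], int] = {}
    offsets: dict[str, tuple[str, int, int]] = {}
    for rec in icf_alignments:
        if not rec.is_mapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapq < min_mapq:
            continue
        info = offsets.get(rec.reference_name)
        if info is None:
            info = parse_icf_name(rec.reference_name)
            offsets[rec.reference_name] = info
        chrom, pos, offset = info
        lo = offset - min_overhang + 1
        hi = offset + min_overhang
        if rec.position <= lo and rec.reference_end >= hi:
            key = (chrom, pos)
            span_counts[key] = span_counts.get(key, 0) + 1
    for call in calls:
        n_span = span_counts.get((call.chr, call.position), 0)
        freq = insertion_frequency(call.n_clr, n_span)
        call.freq = None if freq is None else round(freq, 2)
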