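"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tdnaseeker.formats import AlignmentRecord, parse_cigar
from tdnaseeker.informative import CLR, DIR, InformativeRead


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_record(
    query_name="r1",
    is_mapped=True,
    is_reverse=False,
    is_first_in_pair=True,
    reference_name="chr1",
    position=1,
    mapq=60,
    cigar="150M",
    sequence="",
    **kwargs,
) -> AlignmentRecord:
    """Build an alignment record by hand for classifier tests."""
    return AlignmentRecord(
        query_name=query_name,
        is_mapped=is_mapped,
        is_reverse=is_reverse,
        is_first_in_pair=is_first_in_pair,
        reference_name=reference_name if is_mapped else None,
        position=position if is_mapped else 0,
        mapq=mapq,
        cigar=parse_cigar(cigar if is_mapped else "*"),
        sequence=sequence or "A" * 150,
        **kwargs,
    )


def make_informative(
    bp,
    read_type=CLR,
    chrom="chr1",
    border="start",
    tdna_pos=1,
    orientation="forward",
    scenario=None,
    name=None,
) -> InformativeRead:
    if read_type == DIR:
        border, tdna_pos, orientation = "unknown", None, "unknown"
        scenario = scenario or "C"
    else:
        scenario = scenario or ("A" if orientation == "forward" else "D")
    return InformativeRead(
        query_name=name or f"r{bp}",
        chr=chrom,
        bp=bp,
        read_type=read_type,
        scenario=scenario,
        tdna_border=border,
        tdna_pos=tdna_pos,
        orientation=orientation,
        cigar1=parse_cigar("60S90M"),
        cigar2=parse_cigar("90M60S"),
    )


def write_sam(path, ref_lengths, rows):
    """Write a minimal SAM file from (qname, flag, rname, pos, mapq, cigar, seq)."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in ref_lengths.items():
            handle.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, rname, pos, mapq, cigar, seq in rows:
            handle.write(
                f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*\n"
            )
    return path
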