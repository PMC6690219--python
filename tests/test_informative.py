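"""Stage-1 filtering, clip consistency, and the six-scenario classifier."""

from __future__ import annotations

import pytest

from tdnaseeker.formats import parse_cigar, read_sam
from tdnaseeker.informative import (
    CLR,
    DIR,
    check_clip_consistency,
    classify_ir2,
    extract_ir1,
    read_ir_table,
    split_tag,
    write_ir_table,
)

from conftest import make_record, write_sam

L_T = 6743


@pytest.mark.parametrize(
    "cigar1, cigar2, expected",
    [
        ("60S90M", "62M88S", True),  # |60 - 62| = 2
        ("60S90M", "90M60S", False),  # |60 - 90| = 30
        ("55S95M", "60M90S", True),  # difference exactly at the 5 bp tolerance
    ],
)
def test_clip_consistency_rule(cigar1, cigar2, expected):
    assert check_clip_consistency(parse_cigar(cigar1), parse_cigar(cigar2)) is expected


def test_scenario_a_forward_insertion_right_clip():
    """Genome match ending in a clip whose bases map to the T-DNA start."""
    tdna = make_record(reference_name="tdna", position=1, cigar="90S60M")
    genome = make_record(reference_name="chr1", position=4911, cigar="90M60S")
    ir = classify_ir2(tdna, genome, L_T, read_type=CLR)
    assert (ir.scenario, ir.read_type) == ("A", CLR)
    assert ir.bp == 5000
    assert (ir.tdna_border, ir.tdna_pos) == ("start", 1)
    assert ir.orientation == "forward"


def test_scenario_d_reverse_insertion_right_clip():
    """Same genome geometry, clip matching the reverse-complemented donor end."""
    tdna = make_record(
        reference_name="tdna", position=6684, cigar="60M90S", is_reverse=True
    )
    genome = make_record(reference_name="chr1", position=4911, cigar="90M60S")
    ir = classify_ir2(tdna, genome, L_T, read_type=CLR)
    assert ir.scenario == "D"
    assert ir.orientation == "reverse"
    assert (ir.tdna_border, ir.tdna_pos) == ("end", 6743)
    assert ir.bp == 5000


def test_scenario_b_and_e_left_clip_mirrors():
    tdna_fwd = make_record(reference_name="tdna", position=6684, cigar="60M90S")
    genome = make_record(reference_name="chr1", position=5001, cigar="60S90M")
    ir = classify_ir2(tdna_fwd, genome, L_T, read_type=CLR)
    assert (ir.scenario, ir.orientation) == ("B", "forward")
    assert ir.bp == 5000
    assert (ir.tdna_border, ir.tdna_pos) == ("end", 6743)

    tdna_rev = make_record(
        reference_name="tdna", position=1, cigar="90S60M", is_reverse=True
    )
    ir = classify_ir2(tdna_rev, genome, L_T, read_type=CLR)
    assert (ir.scenario, ir.orientation) == ("E", "reverse")
    assert (ir.tdna_border, ir.tdna_pos) == ("start", 1)


def test_scenario_c_discordant_forward_mate():
    """Mate mapped forward ending at 4,980; its pair maps only to the T-DNA."""
    tdna_mate = make_record(reference_name="tdna", position=100, cigar="150M")
    genome = make_record(reference_name="chr1", position=4831, cigar="150M")
    ir = classify_ir2(tdna_mate, genome, L_T, read_type=DIR)
    assert (ir.scenario, ir.read_type) == ("C", DIR)
    assert ir.bp == 4980
    assert ir.orientation == "unknown"
    assert ir.tdna_border == "unknown" and ir.tdna_pos is None


def test_scenario_f_discordant_reverse_mate():
    tdna_mate = make_record(reference_name="tdna", position=100, cigar="150M")
    genome = make_record(
        reference_name="chr1", position=5021, cigar="150M", is_reverse=True
    )
    ir = classify_ir2(tdna_mate, genome, L_T, read_type=DIR)
    assert ir.scenario == "F"
    assert ir.bp == 5020


def test_classifier_null_cases():
    tdna = make_record(reference_name="tdna", position=1, cigar="90S60M")
    unmapped = make_record(is_mapped=False)
    assert classify_ir2(tdna, unmapped, L_T, read_type=CLR) is None
    # genome explains the whole read: no junction evidence
    full = make_record(reference_name="chr1", position=100, cigar="150M")
    assert classify_ir2(tdna, full, L_T, read_type=CLR) is None
    assert classify_ir2(tdna, None, L_T, read_type=CLR) is None


def _tdna_sam(tmp_path, rows):
    return write_sam(tmp_path / "tdna.sam", {"tdna": L_T}, rows)


def test_extract_ir1_filters_uninformative_pairs(tmp_path):
    seq = "A" * 150
    sam = _tdna_sam(
        tmp_path,
        [
            # pair p1: both fully matched to the T-DNA -> no junction evidence
            ("p1", 99, "tdna", 100, 60, "150M", seq),
            ("p1", 147, "tdna", 400, 60, "150M", seq),
            # pair p2: read1 soft-clipped (CLR candidate); mate also mapped
            ("p2", 99, "tdna", 1, 60, "60S90M", seq),
            ("p2", 147, "tdna", 300, 60, "150M", seq),
            # pair p3: read1 mapped, read2 unmapped -> read2 is a DIR candidate
            ("p3", 73, "tdna", 500, 60, "150M", seq),
            ("p3", 133, "*", 0, 0, "*", "C" * 150),
            # pair p4: clip below the 20 bp threshold -> uninformative
            ("p4", 99, "tdna", 1, 60, "10S140M", seq),
            ("p4", 147, "tdna", 200, 60, "150M", seq),
        ],
    )
    candidates = extract_ir1(read_sam(sam), min_clip=20)
    roles = {(c.query_name, c.role) for c in candidates}
    assert roles == {("p2", CLR), ("p3", DIR)}
    clr = next(c for c in candidates if c.role == CLR)
    assert clr.tdna_record.position == 1 and str(clr.tdna_record.cigar) == "60S90M"
    dirc = next(c for c in candidates if c.role == DIR)
    assert dirc.sequence == "C" * 150  # the unmapped mate's bases
    assert dirc.tdna_record.position == 500  # the T-DNA-mapped mate


def test_extract_ir1_clr_candidate_with_unmapped_mate_yields_both(tmp_path):
    seq = "A" * 150
    sam = _tdna_sam(
        tmp_path,
        [
            ("p1", 99, "tdna", 1, 60, "60S90M", seq),
            ("p1", 133, "*", 0, 0, "*", seq),
        ],
    )
    candidates = extract_ir1(read_sam(sam))
    assert {(c.query_name, c.role, c.mate_index) for c in candidates} == {
        ("p1", CLR, 1),
        ("p1", DIR, 2),
    }


def test_extract_ir1_skips_double_clipped_reads(tmp_path):
    """A read clipped on both ends spans the whole insert: no single junction."""
    seq = "A" * 150
    sam = _tdna_sam(
        tmp_path,
        [
            ("p1", 99, "tdna", 1, 60, "50S50M50S", seq),
            ("p1", 147, "tdna", 1, 60, "150M", seq),
        ],
    )
    assert extract_ir1(read_sam(sam)) == []


def test_extract_ir1_rejects_multi_reference_stream(tmp_path):
    sam = write_sam(
        tmp_path / "multi.sam",
        {"tdna": L_T, "chr1": 10_000},
        [
            ("p1", 99, "tdna", 1, 60, "150M", "A" * 150),
            ("p1", 147, "chr1", 1, 60, "150M", "A" * 150),
        ],
    )
    with pytest.raises(ValueError, match="multiple references"):
        extract_ir1(read_sam(sam))


def test_extract_ir1_parallel_equals_sequential(tmp_path):
    seq = "A" * 150
    rows = []
    for i in range(40):
        rows.append((f"p{i}", 99, "tdna", 1, 60, "60S90M", seq))
        rows.append((f"p{i}", 133, "*", 0, 0, "*", seq))
    sam = _tdna_sam(tmp_path, rows)
    sequential = extract_ir1(read_sam(sam), workers=1)
    parallel = extract_ir1(read_sam(sam), workers=4)
    assert sorted(c.tag for c in sequential) == sorted(c.tag for c in parallel)


def test_tag_round_trip():
    assert split_tag("read:7__C1") == ("read:7", CLR, 1)
    assert split_tag("read__with__underscores__D2") == (
        "read__with__underscores",
        DIR,
        2,
    )


def test_ir_table_round_trip(tmp_path):
    tdna = make_record(reference_name="tdna", position=1, cigar="90S60M")
    genome = make_record(reference_name="chr1", position=4911, cigar="90M60S")
    reads = [
        classify_ir2(tdna, genome, L_T, read_type=CLR),
        classify_ir2(tdna, make_record(reference_name="chr1", position=4831,
                                       cigar="150M"), L_T, read_type=DIR),
    ]
    path = tmp_path / "ir.tsv"
    write_ir_table(reads, path)
    assert read_ir_table(path) == reads
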