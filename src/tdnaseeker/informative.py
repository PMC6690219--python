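"""Two-stage evidence extraction: IR1 against the T-DNA, IR2 on the genome.

Stage 1 maps all reads to the donor construct only and keeps two kinds of
informative candidates:

* CLR (soft-clipped read) candidates — reads mapped to the T-DNA with a
  soft clip of at least ``min_clip`` bases; the clipped part is the
  host-genome side of an insertion junction.
* DIR (discordant read) candidates — pairs where exactly one mate maps to
  the T-DNA; the other mate is host-genome sequence near the insertion.

Stage 2 realigns the candidates to the host genome and classifies each
mapped read into one of six junction scenarios: A/B (soft-clipped, forward
insertion), D/E (soft-clipped, reverse insertion), C/F (discordant; the
orientation stays unknown).  Every informative read is summarised as the
sextuple (chr, bp, read_type, tdna_border, tdna_pos, orientation).
"""

from __future__ import annotations

from dataclasses import dataclass
from multiprocessing import Pool
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .formats import AlignmentRecord, CigarProfile, parse_cigar

CLR = "CLR"
DIR = "DIR"


@dataclass
class InformativeRead:
    """One unit of junction evidence (the clustering sextuple + provenance).

    ``bp`` is normalised so that both sides of a junction report the same
    genome coordinate: the last matched base before a right clip, or
    (first matched base - 1) for a left clip; discordant mates report their
    innermost mapped base analogously.
    """

    query_name: str
    chr: str
    bp: int
    read_type: str  # CLR | DIR
    scenario: str  # A..F
    tdna_border: str  # start | end | unknown
    tdna_pos: int | None
    orientation: str  # forward | reverse | unknown
    cigar1: CigarProfile  # vs T-DNA (for DIR: the T-DNA-mapped mate's)
    cigar2: CigarProfile  # vs genome


@dataclass
class Ir1Candidate:
    """A stage-1 survivor queued for realignment to the host genome."""

    query_name: str
    mate_index: int  # 1 or 2
    role: str  # CLR | DIR
    sequence: str  # original (as-sequenced) orientation
    tdna_record: AlignmentRecord  # own T-DNA alignment (CLR) or the mate's (DIR)

    @property
    def tag(self) -> str:
        """Unique FASTQ name for the realignment run."""
        return f"{self.query_name}__{self.role[0]}{self.mate_index}"


def split_tag(tagged_name: str) -> tuple[str, str, int]:
    """Inverse of :attr:`Ir1Candidate.tag` -> (query_name, role, mate_index)."""
    name, _, suffix = tagged_name.rpartition("__")
    role = CLR if suffix[0] == "C" else DIR
    return name, role, int(suffix[1])


def iter_pairs(
    records: Iterable[AlignmentRecord],
) -> Iterator[tuple[AlignmentRecord, AlignmentRecord | None]]:
    """Group primary records into mate pairs by query name (order-tolerant)."""
    pending: dict[str, AlignmentRecord] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = rec
        else:
            yield (mate, rec) if mate.is_first_in_pair else (rec, mate)
    for rec in pending.values():
        yield rec, None


def _pair_candidates(
    pair: tuple[AlignmentRecord, AlignmentRecord | None], min_clip: int
) -> list[Ir1Candidate]:
    r1, r2 = pair
    mates = [(1, r1), (2, r2)]
    out: list[Ir1Candidate] = []
    for idx, rec in mates:
        if rec is None or not rec.is_mapped:
            continue
        clips = (rec.cigar.left_clip, rec.cigar.right_clip)
        # one dominant clip: reads clipped on both ends span the whole
        # insert and carry no usable single junction
        if max(clips) >= min_clip and min(clips) < min_clip:
            out.append(
                Ir1Candidate(rec.query_name, idx, CLR, rec.oriented_sequence, rec)
            )
    mapped = [(idx, rec) for idx, rec in mates if rec is not None and rec.is_mapped]
    unmapped = [(idx, rec) for idx, rec in mates if rec is not None and not rec.is_mapped]
    if len(mapped) == 1 and len(unmapped) == 1:
        uidx, urec = unmapped[0]
        if urec.sequence:
            out.append(
                Ir1Candidate(
                    urec.query_name, uidx, DIR, urec.oriented_sequence, mapped[0][1]
                )
            )
    return out


def _batch_candidates(args) -> list[Ir1Candidate]:
    pairs, min_clip = args
    out: list[Ir1Candidate] = []
    for pair in pairs:
        out.extend(_pair_candidates(pair, min_clip))
    return out


def extract_ir1(
    records: Iterable[AlignmentRecord],
    min_clip: int = 20,
    workers: int = 1,
) -> list[Ir1Candidate]:
    """Filter a T-DNA-only alignment stream down to informative candidates.

    The input must come from an alignment against the donor construct alone;
    multiple reference names raise ``ValueError``.  With ``workers > 1`` the
    pair stream is partitioned into batches and filtered in parallel; the
    output is identical to the sequential result.
    """
    pairs: list[tuple[AlignmentRecord, AlignmentRecord | None]] = []
    refs: set[str] = set()
    for pair in iter_pairs(records):
        for rec in pair:
            if rec is not None and rec.is_mapped:
                refs.add(rec.reference_name)
        pairs.append(pair)
    if len(refs) > 1:
        raise ValueError(
            f"stage-1 alignments span multiple references {sorted(refs)}; "
            "expected the T-DNA construct only"
        )
    if workers > 1 and pairs:
        batch = max(1, (len(pairs) + workers - 1) // workers)
        chunks = [(pairs[i : i + batch], min_clip) for i in range(0, len(pairs), batch)]
        with Pool(workers) as pool:
            results = pool.map(_batch_candidates, chunks)
        return [cand for chunk in results for cand in chunk]
    return _batch_candidates((pairs, min_clip))


def check_clip_consistency(
    cigar1: CigarProfile, cigar2: CigarProfile, tol: int = 5
) -> bool:
    """Soft-clipped bases on the T-DNA must reappear as genome matches.

    Accepts iff ``|cigar1.total_clip - cigar2.total_match| <= tol`` (both
    profiles from the same read; CIGAR1 vs the T-DNA, CIGAR2 vs the genome).
    """
    return abs(cigar1.total_clip - cigar2.total_match) <= tol


def classify_ir2(
    tdna_record: AlignmentRecord,
    genome_record: AlignmentRecord | None,
    tdna_length: int,
    read_type: str | None = None,
) -> InformativeRead | None:
    """Assign a junction scenario to one realigned candidate.

    Scenario letters follow a fixed geometric convention: for soft-clipped
    reads, A/B are the right-/left-clipped faces of a forward insertion and
    D/E their reverse-orientation analogues; discordant mates are C when the
    genome mate maps on the forward strand (junction downstream) and F on
    the reverse strand (junction upstream).  The T-DNA border a read
    testifies about is the construct endpoint adjacent to the junction:
    right-clip+forward and left-clip+reverse expose the segment start,
    the other two combinations its end.

    Returns ``None`` when the geometry matches no scenario (including an
    unmapped genome record).
    """
    if genome_record is None or not genome_record.is_mapped:
        return None
    if read_type is None:
        # a CLR candidate is, by construction, clipped against the T-DNA
        read_type = CLR if tdna_record.cigar.total_clip > 0 else DIR
    c2 = genome_record.cigar

    if read_type == DIR:
        if genome_record.is_reverse:
            scenario = "F"
            bp = genome_record.position - 1
        else:
            scenario = "C"
            bp = genome_record.reference_end
        return InformativeRead(
            query_name=genome_record.query_name,
            chr=genome_record.reference_name,
            bp=max(bp, 1),
            read_type=DIR,
            scenario=scenario,
            tdna_border="unknown",
            tdna_pos=None,
            orientation="unknown",
            cigar1=tdna_record.cigar,
            cigar2=c2,
        )

    left, right = c2.left_clip, c2.right_clip
    if left == 0 and right == 0:
        return None  # fully explained by the genome: no junction here
    side = "right" if right >= left else "left"
    forward = tdna_record.is_reverse == genome_record.is_reverse
    a1 = tdna_record.position
    b1 = tdna_record.reference_end
    if side == "right":
        bp = genome_record.reference_end
        scenario = "A" if forward else "D"
    else:
        bp = genome_record.position - 1
        scenario = "B" if forward else "E"
    border = "start" if (side == "right") == forward else "end"
    tdna_pos = a1 if border == "start" else b1
    return InformativeRead(
        query_name=genome_record.query_name,
        chr=genome_record.reference_name,
        bp=max(bp, 1),
        read_type=CLR,
        scenario=scenario,
        tdna_border=border,
        tdna_pos=min(max(tdna_pos, 1), tdna_length),
        orientation="forward" if forward else "reverse",
        cigar1=tdna_record.cigar,
        cigar2=c2,
    )


IR_TABLE_COLUMNS = (
    "query_name",
    "chr",
    "bp",
    "read_type",
    "scenario",
    "tdna_border",
    "tdna_pos",
    "orientation",
    "cigar1",
    "cigar2",
)


def write_ir_table(reads: Sequence[InformativeRead], path: str | Path) -> None:
    """Write the intermediate informative-read table (debug/replay aid)."""
    with open(path, "w") as handle:
        handle.write("\t".join(IR_TABLE_COLUMNS) + "\n")
        for r in reads:
            handle.write(
                f"{r.query_name}\t{r.chr}\t{r.bp}\t{r.read_type}\t{r.scenario}\t"
                f"{r.tdna_border}\t{'-' if r.tdna_pos is None else r.tdna_pos}\t"
                f"{r.orientation}\t{r.cigar1}\t{r.cigar2}\n"
            )


def read_ir_table(path: str | Path) -> list[InformativeRead]:
    reads = []
    with open(path) as handle:
        handle.readline()
        for line in handle:
            (name, chrom, bp, rtype, scenario, border, pos, orient, c1, c2) = (
                line.rstrip("\n").split("\t")
            )
            reads.append(
                InformativeRead(
                    query_name=name,
                    chr=chrom,
                    bp=int(bp),
                    read_type=rtype,
                    scenario=scenario,
                    tdna_border=border,
                    tdna_pos=None if pos == "-" else int(pos),
                    orientation=orient,
                    cigar1=parse_cigar(c1),
                    cigar2=parse_cigar(c2),
                )
            )
    return reads
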