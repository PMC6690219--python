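"""I/O layer: FASTA, FASTQ, SAM, GFF3, CIGAR strings, and the tool's own tables.

All coordinates are 1-based inclusive throughout the package, following the
SAM and GFF3 conventions, so no conversion happens at module boundaries.
SAM records are parsed with pysam and converted into small picklable
dataclasses (:class:`AlignmentRecord`) that downstream stages and worker
processes can consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class CigarError(ValueError):
    """Raised for a CIGAR string that does not follow the SAM grammar."""


class Gff3FormatError(ValueError):
    """Raised for malformed GFF3 input; the message names the line number."""


class TableFormatError(ValueError):
    """Raised for malformed call/truth tables."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _make_normalize_table() -> bytes:
    # uppercase A/C/G/T/N pass through, lowercase is uppercased,
    # every other letter (ambiguity codes) collapses to N
    table = bytearray(b"N" * 256)
    for b in b"ACGTN":
        table[b] = b
        table[b + 32] = b
    return bytes(table)


_NORMALIZE = _make_normalize_table()

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def normalize_sequence(seq: str) -> str:
    """Uppercase and restrict to the {A,C,G,T,N} alphabet."""
    return seq.encode("ascii").translate(_NORMALIZE).decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT).decode("ascii")[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """One named sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a (multi-record) FASTA file, normalizing the alphabet."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ReferenceSequence(rec.id, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(sequences: Iterable[ReferenceSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write ``(name, sequence)`` pairs as FASTQ with a flat quality string."""
    n = 0
    with open(path, "w") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------

_CIGAR_TOKEN = re.compile(r"(\d+)(\D)")
_VALID_OPS = frozenset("MIDNSHP=X")
_MATCH_OPS = frozenset("M=X")
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


@dataclass(frozen=True)
class CigarProfile:
    """Parsed CIGAR with the derived clip/match totals the caller relies on.

    Only soft clips (S) count towards the clip totals; hard clips carry no
    sequence and are ignored by the junction logic.
    """

    ops: tuple[tuple[str, int], ...] = ()

    @classmethod
    def from_string(cls, text: str) -> "CigarProfile":
        if text in ("*", ""):
            return cls(())
        ops: list[tuple[str, int]] = []
        pos = 0
        for match in _CIGAR_TOKEN.finditer(text):
            if match.start() != pos:
                raise CigarError(
                    f"malformed CIGAR {text!r}: unexpected {text[pos:match.start()]!r}"
                )
            length, op = int(match.group(1)), match.group(2)
            if op not in _VALID_OPS:
                raise CigarError(f"malformed CIGAR {text!r}: bad operation {op!r}")
            if length <= 0:
                raise CigarError(f"malformed CIGAR {text!r}: non-positive length")
            ops.append((op, length))
            pos = match.end()
        if pos != len(text):
            raise CigarError(f"malformed CIGAR {text!r}: trailing {text[pos:]!r}")
        return cls(tuple(ops))

    @classmethod
    def from_pysam(cls, cigartuples) -> "CigarProfile":
        if not cigartuples:
            return cls(())
        return cls(tuple(("MIDNSHP=XB"[op], length) for op, length in cigartuples))

    def _clip_at(self, index: int, step: int) -> int:
        # at most one soft clip per end; leading/trailing hard clips are skipped
        i = index
        if 0 <= i < len(self.ops) and self.ops[i][0] == "H":
            i += step
        if 0 <= i < len(self.ops) and self.ops[i][0] == "S":
            return self.ops[i][1]
        return 0

    @property
    def left_clip(self) -> int:
        return self._clip_at(0, 1)

    @property
    def right_clip(self) -> int:
        return self._clip_at(len(self.ops) - 1, -1)

    @property
    def total_clip(self) -> int:
        return self.left_clip + self.right_clip

    @property
    def total_match(self) -> int:
        return sum(n for op, n in self.ops if op in _MATCH_OPS)

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.ops if op in _QUERY_OPS)

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.ops if op in _REF_OPS)

    def __str__(self) -> str:
        if not self.ops:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.ops)


def parse_cigar(text: str) -> CigarProfile:
    """Parse a SAM CIGAR string; ``"*"`` yields an empty profile."""
    return CigarProfile.from_string(text)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One SAM alignment line, 1-based, reduced to what the pipeline needs."""

    query_name: str
    is_mapped: bool
    is_reverse: bool
    is_first_in_pair: bool
    reference_name: str | None
    position: int  # 1-based leftmost mapped base; 0 when unmapped
    mapq: int
    cigar: CigarProfile
    sequence: str
    mate_reference_name: str | None = None
    mate_position: int | None = None
    mate_is_mapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def reference_end(self) -> int:
        """1-based rightmost reference base consumed by the alignment."""
        return self.position + self.cigar.reference_length - 1

    @classmethod
    def from_pysam(cls, seg: "pysam.AlignedSegment") -> "AlignmentRecord":
        mapped = not seg.is_unmapped
        return cls(
            query_name=seg.query_name,
            is_mapped=mapped,
            is_reverse=seg.is_reverse,
            is_first_in_pair=(seg.is_read1 or not seg.is_paired),
            reference_name=seg.reference_name if mapped else None,
            position=(seg.reference_start + 1) if mapped else 0,
            mapq=seg.mapping_quality,
            cigar=CigarProfile.from_pysam(seg.cigartuples),
            sequence=seg.query_sequence or "",
            mate_reference_name=(
                seg.next_reference_name if seg.is_paired and not seg.mate_is_unmapped else None
            ),
            mate_position=(
                seg.next_reference_start + 1
                if seg.is_paired and not seg.mate_is_unmapped
                else None
            ),
            mate_is_mapped=seg.is_paired and not seg.mate_is_unmapped,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
        )

    @property
    def oriented_sequence(self) -> str:
        """The read sequence in its original (as-sequenced) orientation."""
        if self.is_reverse:
            return reverse_complement(self.sequence)
        return self.sequence


def read_sam(path: str | Path, include_secondary: bool = False) -> Iterator[AlignmentRecord]:
    """Stream primary alignment records from a SAM/BAM file.

    Secondary (0x100) and supplementary (0x800) alignments are dropped by
    default so that one read never contributes more than one record.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for seg in handle:
            if not include_secondary and (seg.is_secondary or seg.is_supplementary):
                continue
            yield AlignmentRecord.from_pysam(seg)


def sam_reference_lengths(path: str | Path) -> dict[str, int]:
    """Reference name -> length, from the SAM header."""
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        return dict(zip(handle.references, handle.lengths))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One GFF3 feature with 1-based inclusive coordinates."""

    seqid: str
    start: int
    end: int
    strand: str
    gene_id: str
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.gene_id!r}: start {self.start} > end {self.end}"
            )


_ATTR_ID = re.compile(r"(?:^|;)\s*(?:ID|Name)=([^;]+)")


def read_gff3(
    path: str | Path, feature_types: Sequence[str] | None = ("gene",)
) -> list[GeneFeature]:
    """Read features of the requested types (default: gene) from a GFF3 file.

    Directives (``##``) and comment lines are skipped; the gene identifier is
    taken from the ``ID`` (or ``Name``) attribute.
    """
    wanted = set(feature_types) if feature_types is not None else None
    features: list[GeneFeature] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if wanted is not None and ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise Gff3FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise Gff3FormatError(f"{path}: line {lineno}: start > end")
            # tolerate the unicode minus some annotation exports use
            strand = {"−": "-", "+": "+", "-": "-", ".": "."}.get(strand, ".")
            match = _ATTR_ID.search(attrs)
            gene_id = match.group(1) if match else f"{ftype}:{seqid}:{start}"
            features.append(GeneFeature(seqid, start, end, strand, gene_id, ftype))
    return features


# ---------------------------------------------------------------------------
# call and truth tables
# ---------------------------------------------------------------------------

CALL_TABLE_COLUMNS = (
    "chr",
    "position",
    "n_clr",
    "n_dir",
    "tdna_st",
    "tdna_end",
    "strand",
    "freq",
    "annotation",
    "approximate",
)

TRUTH_TABLE_COLUMNS = ("chr", "position", "tdna_st", "tdna_end", "orientation", "truncated")


def write_call_table(calls, path: str | Path, missing: str = "-") -> None:
    """Write insertion calls as the tool's TSV call table."""
    with open(path, "w") as handle:
        handle.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
        for call in calls:
            freq = missing if call.freq is None else f"{call.freq:.2f}"
            row = (
                call.chr,
                str(call.position),
                str(call.n_clr),
                str(call.n_dir),
                missing if call.tdna_st is None else str(call.tdna_st),
                missing if call.tdna_end is None else str(call.tdna_end),
                call.strand,
                freq,
                ",".join(call.annotation) if call.annotation else missing,
                "yes" if call.approximate else "no",
            )
            handle.write("\t".join(row) + "\n")


def read_call_table(path: str | Path, missing: str = "-"):
    """Read a call table back into :class:`~tdnaseeker.caller.InsertionCall`."""
    from .caller import InsertionCall  # local import: caller depends on formats

    calls = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != CALL_TABLE_COLUMNS:
            raise TableFormatError(f"{path}: unexpected call-table header {header}")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(CALL_TABLE_COLUMNS):
                raise TableFormatError(f"{path}: line {lineno}: wrong column count")
            (chrom, pos, n_clr, n_dir, st, end, strand, freq, anno, approx) = fields
            calls.append(
                InsertionCall(
                    chr=chrom,
                    position=int(pos),
                    n_clr=int(n_clr),
                    n_dir=int(n_dir),
                    tdna_st=None if st == missing else int(st),
                    tdna_end=None if end == missing else int(end),
                    strand=strand,
                    freq=None if freq == missing else float(freq),
                    annotation=[] if anno == missing else anno.split(","),
                    approximate=(approx == "yes"),
                )
            )
    return calls


def write_truth_table(truths, path: str | Path) -> None:
    """Write simulator ground truth as a BED-like TSV."""
    with open(path, "w") as handle:
        handle.write("\t".join(TRUTH_TABLE_COLUMNS) + "\n")
        for t in truths:
            handle.write(
                f"{t.chr}\t{t.position}\t{t.tdna_st}\t{t.tdna_end}\t"
                f"{t.orientation}\t{int(t.truncated)}\n"
            )


def read_truth_table(path: str | Path):
    from .simulate import TruthRecord  # local import: simulate depends on formats

    truths = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_TABLE_COLUMNS:
            raise TableFormatError(f"{path}: unexpected truth-table header {header}")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(TRUTH_TABLE_COLUMNS):
                raise TableFormatError(f"{path}: line {lineno}: wrong column count")
            chrom, pos, st, end, orientation, truncated = fields
            truths.append(
                TruthRecord(
                    chr=chrom,
                    position=int(pos),
                    tdna_st=int(st),
                    tdna_end=int(end),
                    orientation=orientation,
                    truncated=bool(int(truncated)),
                )
            )
    return truths


# ---------------------------------------------------------------------------
# aligner-backed record streaming
# ---------------------------------------------------------------------------

def align_reads(
    reads,
    target: str | Path | None = None,
    aligner=None,
    sam_path: str | Path | None = None,
) -> Iterator[AlignmentRecord]:
    """Yield alignment records for *reads* against *target*.

    Either an external aligner is invoked (default: ``bwa mem``), or a
    pre-computed SAM file is supplied via *sam_path*, in which case alignment
    is skipped entirely and the records are parsed from that file.  *reads*
    is a single FASTQ path or a ``(R1, R2)`` pair.
    """
    import tempfile

    from .aligner import BwaMem

    if sam_path is not None:
        yield from read_sam(sam_path)
        return
    if target is None:
        raise ValueError("either a target FASTA or a pre-computed SAM is required")
    if aligner is None:
        aligner = BwaMem()
    fastqs = [reads] if isinstance(reads, (str, Path)) else list(reads)
    with tempfile.TemporaryDirectory(prefix="tdnaseeker-align-") as tmp:
        out = Path(tmp) / "aligned.sam"
        aligner.map_reads(target, fastqs, out)
        yield from read_sam(out)
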