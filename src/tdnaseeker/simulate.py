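"""Synthetic benchmark data: truncated T-DNA copies, mutated genomes, reads.

The generator emulates the study design used to benchmark the caller:
a donor construct (a ~6.7 kb binary-vector T-DNA) is randomly truncated on
the left and/or right side — around half of the planted copies stay
complete, and every retained segment keeps at least 50 bp — then spliced
into a host genome at well-separated positions in either orientation.
Paired-end reads are drawn from the mutated genome with normally
distributed fragment sizes and uniform per-base substitution errors,
mirroring a wgsim-style simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import ReferenceSequence, reverse_complement

MIN_RETAINED = 50  # minimum usable donor segment, bp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# base byte -> 0..3 code (N and anything else coded 0; only used on the
# error-substitution path, where the replacement is random anyway)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


class PlacementError(RuntimeError):
    """Could not place the requested number of insertions; reports progress."""


@dataclass(frozen=True)
class TDNAConstruct:
    """The donor sequence whose full or truncated copies are planted/sought."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_RETAINED:
            raise ValueError(
                f"T-DNA construct {self.id!r} is {len(self.sequence)} bp; "
                f"at least {MIN_RETAINED} bp are required"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted insertion.

    ``position`` is the last original-genome base before the inserted
    sequence (1-based); ``tdna_st``/``tdna_end`` are the retained segment's
    coordinates on the full construct.
    """

    chr: str
    position: int
    tdna_st: int
    tdna_end: int
    orientation: str  # "forward" | "reverse"
    truncated: bool


@dataclass
class ReadSimParams:
    """Paired-end read simulation settings (wgsim-style)."""

    coverage: float
    read_length: int = 150
    fragment_mean: float = 500.0
    fragment_sd: float = 50.0
    base_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 36:
            raise ValueError("read_length must be >= 36")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.fragment_sd < 0:
            raise ValueError("fragment_sd must be non-negative")
        if self.fragment_mean <= 2 * self.read_length:
            warnings.warn(
                "fragment_mean <= 2 * read_length: mates will overlap",
                stacklevel=2,
            )


def random_genome(
    length: int,
    rng: np.random.Generator,
    n_chromosomes: int = 1,
    name_prefix: str = "chr",
) -> list[ReferenceSequence]:
    """A synthetic host genome with uniform base composition."""
    per = length // n_chromosomes
    genome = []
    for i in range(n_chromosomes):
        n = per if i < n_chromosomes - 1 else length - per * (n_chromosomes - 1)
        seq = _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
        genome.append(ReferenceSequence(f"{name_prefix}{i + 1}", seq))
    return genome


def random_tdna(
    rng: np.random.Generator, length: int = 6743, name: str = "tdna"
) -> TDNAConstruct:
    """A synthetic donor construct (default length matches a common vector)."""
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return TDNAConstruct(name, seq)


def truncate_tdna(
    construct: TDNAConstruct, rng: np.random.Generator
) -> tuple[str, int, int, bool]:
    """Return one (possibly truncated) donor segment.

    With probability 0.5 the full construct is kept; otherwise the left,
    right, or both ends are cut (uniform over the three modes), with cut
    points uniform subject to a retained length of at least 50 bp.
    """
    L = construct.length
    if L < MIN_RETAINED:
        raise ValueError("construct shorter than the minimum retained length")
    if rng.random() < 0.5:
        return construct.sequence, 1, L, False
    mode = ("left", "right", "both")[rng.integers(0, 3)]
    if mode == "left":
        st = int(rng.integers(2, L - MIN_RETAINED + 2))  # 2 .. L-49
        end = L
    elif mode == "right":
        st = 1
        end = int(rng.integers(MIN_RETAINED, L))  # 50 .. L-1
    else:
        st = int(rng.integers(2, L - MIN_RETAINED + 1))  # 2 .. L-50
        end = int(rng.integers(st + MIN_RETAINED - 1, L))  # st+49 .. L-1
    return construct.sequence[st - 1 : end], st, end, True


def insert_tdna(
    genome: Sequence[ReferenceSequence],
    construct: TDNAConstruct,
    n_insertions: int,
    rng: np.random.Generator,
    min_gap: int = 2000,
    positions: Sequence[tuple[str, int]] | None = None,
    max_tries_per_insertion: int = 1000,
) -> tuple[list[ReferenceSequence], list[TruthRecord]]:
    """Plant *n_insertions* donor copies into *genome*.

    Positions are drawn uniformly (chromosomes weighted by length), at least
    *min_gap* from every other insertion and from the sequence ends; each
    segment is reverse-complemented with probability 0.5.  Truth positions
    refer to the ORIGINAL genome coordinates.  An explicit list of
    ``(chr, position)`` placements can be supplied instead of random ones.
    """
    by_name = {s.id: s for s in genome}
    if positions is not None:
        if len(positions) != n_insertions:
            raise ValueError("positions must have length n_insertions")
        placements = [(c, int(p)) for c, p in positions]
    else:
        lengths = np.array([len(s) for s in genome], dtype=float)
        usable = np.maximum(lengths - 2 * min_gap, 0.0)
        if usable.sum() <= 0 and n_insertions > 0:
            raise PlacementError(f"no usable placement space (placed 0/{n_insertions})")
        weights = usable / usable.sum() if n_insertions else usable
        placements = []
        placed: dict[str, list[int]] = {s.id: [] for s in genome}
        for i in range(n_insertions):
            for _ in range(max_tries_per_insertion):
                ci = int(rng.choice(len(genome), p=weights))
                contig = genome[ci]
                pos = int(rng.integers(min_gap, len(contig) - min_gap + 1))
                if all(abs(pos - q) >= min_gap for q in placed[contig.id]):
                    placed[contig.id].append(pos)
                    placements.append((contig.id, pos))
                    break
            else:
                raise PlacementError(
                    f"could not satisfy min_gap={min_gap} (placed {i}/{n_insertions})"
                )

    truths: list[TruthRecord] = []
    segments: dict[str, list[tuple[int, str]]] = {s.id: [] for s in genome}
    for chrom, pos in placements:
        if chrom not in by_name:
            raise ValueError(f"unknown chromosome {chrom!r}")
        segment, st, end, truncated = truncate_tdna(construct, rng)
        orientation = "forward"
        if rng.random() < 0.5:
            orientation = "reverse"
            segment = reverse_complement(segment)
        truths.append(TruthRecord(chrom, pos, st, end, orientation, truncated))
        segments[chrom].append((pos, segment))

    mutated: list[ReferenceSequence] = []
    for contig in genome:
        inserts = sorted(segments[contig.id])
        if not inserts:
            mutated.append(contig)
            continue
        parts, prev = [], 0
        for pos, segment in inserts:
            parts.append(contig.sequence[prev:pos])
            parts.append(segment)
            prev = pos
        parts.append(contig.sequence[prev:])
        mutated.append(ReferenceSequence(contig.id, "".join(parts)))

    truths.sort(key=lambda t: (t.chr, t.position))
    return mutated, truths


def expected_pair_count(genome_length: int, coverage: float, read_length: int) -> int:
    """coverage * G / (2 * read_length), rounded."""
    return int(round(coverage * genome_length / (2.0 * read_length)))


def _apply_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return reads
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return reads
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    codes = (_CODE[reads[mask]] + shift) % 4
    reads[mask] = _BASES[codes]
    return reads


def simulate_reads(
    genome: Sequence[ReferenceSequence],
    params: ReadSimParams,
    fastq1: str | Path,
    fastq2: str | Path,
    name_prefix: str = "sim",
    chunk_size: int = 100_000,
) -> int:
    """Write paired-end FASTQ drawn from *genome*; returns the pair count.

    One mate is the forward start of the fragment, the other the
    reverse-complemented end; which mate is read 1 is decided per fragment
    with probability 0.5.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    qual = "I" * rl
    counter = 0
    total_pairs = 0
    with open(fastq1, "w") as out1, open(fastq2, "w") as out2:
        for contig in genome:
            L = len(contig)
            if L < rl:
                continue
            arr = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
            n_pairs = expected_pair_count(L, params.coverage, rl)
            done = 0
            while done < n_pairs:
                n = min(chunk_size, n_pairs - done)
                frag = np.rint(
                    rng.normal(params.fragment_mean, params.fragment_sd, size=n)
                ).astype(np.int64)
                # fragments longer than the contig are redrawn, then clipped
                for _ in range(100):
                    bad = frag > L
                    if not bad.any():
                        break
                    frag[bad] = np.rint(
                        rng.normal(params.fragment_mean, params.fragment_sd,
                                   size=int(bad.sum()))
                    ).astype(np.int64)
                np.clip(frag, rl, L, out=frag)
                start = (rng.random(n) * (L - frag + 1)).astype(np.int64)
                offsets = np.arange(rl, dtype=np.int64)
                fwd = arr[start[:, None] + offsets]
                rev = _COMP[arr[(start + frag - rl)[:, None] + offsets]][:, ::-1]
                fwd = np.ascontiguousarray(fwd)
                rev = np.ascontiguousarray(rev)
                flip = rng.random(n) < 0.5
                r1, r2 = fwd.copy(), rev.copy()
                r1[flip], r2[flip] = rev[flip], fwd[flip]
                _apply_errors(r1, params.base_error_rate, rng)
                _apply_errors(r2, params.base_error_rate, rng)
                lines1, lines2 = [], []
                for i in range(n):
                    name = f"{name_prefix}_{counter}"
                    counter += 1
                    s1 = r1[i].tobytes().decode("ascii")
                    s2 = r2[i].tobytes().decode("ascii")
                    lines1.append(f"@{name}\n{s1}\n+\n{qual}\n")
                    lines2.append(f"@{name}\n{s2}\n+\n{qual}\n")
                out1.write("".join(lines1))
                out2.write("".join(lines2))
                done += n
            total_pairs += n_pairs
    return total_pairs
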