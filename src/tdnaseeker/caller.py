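"""Windowed clustering of informative reads and insertion calling.

Reads are sorted per chromosome by their junction coordinate ``bp`` and
partitioned by chained adjacency: read *i* joins the open cluster iff
``|bp_i - bp_{i-1}| <= win``, with separate windows for soft-clipped
evidence (5 bp) and discordant evidence (500 bp, the library fragment
length).  Discordant clusters are then merged into the nearest soft-clip
cluster within the discordant window, since a single insertion produces
both kinds of evidence.  A cluster becomes a call when it holds at least
``min_support`` reads; the insertion position is the mode of the member
coordinates (soft-clip members when any exist), the strand is the majority
soft-clip orientation, and the retained T-DNA segment endpoints are the
modes of the per-border T-DNA coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .informative import CLR, DIR, InformativeRead

COMPLETE = "complete"
TRUNCATED = "truncated"
UNDETERMINED = "undetermined"


@dataclass
class InsertionCluster:
    """A group of informative reads supporting one candidate insertion."""

    chr: str
    members: list[InformativeRead]
    window_clr: int = 5
    window_dir: int = 500

    @property
    def clr_members(self) -> list[InformativeRead]:
        return [r for r in self.members if r.read_type == CLR]

    @property
    def dir_members(self) -> list[InformativeRead]:
        return [r for r in self.members if r.read_type == DIR]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class InsertionCall:
    """One called insertion, mirroring the output table layout."""

    chr: str
    position: int
    n_clr: int
    n_dir: int
    tdna_st: int | None
    tdna_end: int | None
    strand: str  # '+' | '-' | '.'
    freq: float | None = None
    annotation: list[str] = field(default_factory=list)
    approximate: bool = False  # discordant-only: position is not exact


def _mode(values: Sequence[int], tie: str = "min") -> int:
    """Most frequent value; ties resolved to the smallest or largest."""
    counts = Counter(values)
    best = max(counts.values())
    candidates = [v for v, n in counts.items() if n == best]
    return min(candidates) if tie == "min" else max(candidates)


def _chain_partition(
    reads: list[InformativeRead], win: int
) -> list[list[InformativeRead]]:
    """Chained-window partition of reads already sorted by bp."""
    if not reads:
        return []
    bps = np.array([r.bp for r in reads])
    breaks = np.flatnonzero(np.diff(bps) > win) + 1
    return [list(part) for part in np.split(np.array(reads, dtype=object), breaks)]


def cluster_reads(
    reads: Iterable[InformativeRead], win_clr: int = 5, win_dir: int = 500
) -> list[InsertionCluster]:
    """Cluster one chromosome's informative reads.

    CLR and DIR evidence are chained separately with their own windows and
    then merged: each DIR cluster joins the nearest CLR cluster whose
    position estimate lies within ``win_dir``; unmerged DIR clusters stand
    alone (discordant-only candidates).
    """
    reads = list(reads)
    if not reads:
        return []
    chroms = {r.chr for r in reads}
    if len(chroms) > 1:
        raise ValueError(f"cluster_reads expects one chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()

    clr = sorted((r for r in reads if r.read_type == CLR), key=lambda r: r.bp)
    dirs = sorted((r for r in reads if r.read_type == DIR), key=lambda r: r.bp)
    clr_groups = _chain_partition(clr, win_clr)
    dir_groups = _chain_partition(dirs, win_dir)

    clr_positions = [_mode([r.bp for r in g]) for g in clr_groups]
    merged_members = [list(g) for g in clr_groups]
    leftover_dir: list[list[InformativeRead]] = []
    for group in dir_groups:
        pos_d = _mode([r.bp for r in group])
        best, best_dist = None, None
        for i, pos_c in enumerate(clr_positions):
            dist = abs(pos_c - pos_d)
            if dist <= win_dir and (best_dist is None or dist < best_dist):
                best, best_dist = i, dist
        if best is None:
            leftover_dir.append(list(group))
        else:
            merged_members[best].extend(group)

    clusters = [
        InsertionCluster(chrom, sorted(members, key=lambda r: r.bp), win_clr, win_dir)
        for members in merged_members + leftover_dir
    ]
    clusters.sort(key=lambda c: call_position(c))
    return clusters


def call_position(cluster: InsertionCluster) -> int:
    """Mode of the member coordinates; CLR members win over DIR members.

    Ties break to the smallest coordinate.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    members = cluster.clr_members or cluster.members
    return _mode([r.bp for r in members], tie="min")


def call_insertion(
    cluster: InsertionCluster, tdna_length: int, min_support: int = 3
) -> InsertionCall | None:
    """Turn a cluster into a call, or ``None`` below the support threshold."""
    if len(cluster) < min_support:
        return None
    clr = cluster.clr_members
    n_fwd = sum(1 for r in clr if r.orientation == "forward")
    n_rev = sum(1 for r in clr if r.orientation == "reverse")
    if n_fwd > n_rev:
        strand = "+"
    elif n_rev > n_fwd:
        strand = "-"
    else:
        strand = "."
    starts = [r.tdna_pos for r in clr if r.tdna_border == "start" and r.tdna_pos]
    ends = [r.tdna_pos for r in clr if r.tdna_border == "end" and r.tdna_pos]
    tdna_st = _mode(starts, tie="min") if starts else None
    tdna_end = _mode(ends, tie="max") if ends else None
    if tdna_st is not None and tdna_end is not None and tdna_st > tdna_end:
        # conflicting border evidence; keep the invariant st <= end
        tdna_st, tdna_end = tdna_end, tdna_st
    return InsertionCall(
        chr=cluster.chr,
        position=max(call_position(cluster), 1),
        n_clr=len(clr),
        n_dir=len(cluster.dir_members),
        tdna_st=tdna_st,
        tdna_end=tdna_end,
        strand=strand,
        approximate=(len(clr) == 0),
    )


def call_insertions(
    reads: Iterable[InformativeRead],
    tdna_length: int,
    min_support: int = 3,
    win_clr: int = 5,
    win_dir: int = 500,
) -> list[InsertionCall]:
    """Cluster and call across chromosomes; calls sorted by (chr, position)."""
    by_chrom: dict[str, list[InformativeRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chr, []).append(r)
    calls: list[InsertionCall] = []
    for chrom in sorted(by_chrom):
        for cluster in cluster_reads(by_chrom[chrom], win_clr, win_dir):
            call = call_insertion(cluster, tdna_length, min_support)
            if call is not None:
                calls.append(call)
    calls.sort(key=lambda c: (c.chr, c.position))
    return calls


def classify_truncation(
    call: InsertionCall, tdna_length: int, border_slack: int = 25
) -> str:
    """Label a call complete/truncated/undetermined from its T-DNA endpoints.

    The border repeats of a T-DNA are commonly nibbled by a few bases at
    integration, so an endpoint within ``border_slack`` of the construct end
    still counts as that end being present.
    """
    st, end = call.tdna_st, call.tdna_end
    st_ok = None if st is None else st <= 1 + border_slack
    end_ok = None if end is None else end >= tdna_length - border_slack
    if st_ok is False or end_ok is False:
        return TRUNCATED
    if st_ok and end_ok:
        return COMPLETE
    return UNDETERMINED
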