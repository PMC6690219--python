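"""Gene annotation of insertion calls.

An insertion occupies zero width in reference coordinates, so a call is
labeled with every gene model whose interval contains the call's point
position.  The interval lookup uses an interval tree per chromosome.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .caller import InsertionCall
from .formats import GeneFeature


def build_feature_index(features: Iterable[GeneFeature]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over [start, end] (1-based inclusive)."""
    index: dict[str, IntervalTree] = {}
    for feat in features:
        tree = index.setdefault(feat.seqid, IntervalTree())
        # intervaltree is half-open; +1 makes the end inclusive
        tree.addi(feat.start, feat.end + 1, feat.gene_id)
    return index


def annotate_calls(
    calls: Sequence[InsertionCall], features: Iterable[GeneFeature]
) -> Sequence[InsertionCall]:
    """Fill ``call.annotation`` with the ids of genes containing the call.

    Pure in the inputs: repeated runs give identical, sorted labels; calls
    in intergenic space keep an empty annotation (rendered ``-``).
    """
    index = build_feature_index(features)
    for call in calls:
        tree = index.get(call.chr)
        if tree is None:
            call.annotation = []
            continue
        call.annotation = sorted({hit.data for hit in tree.at(call.position)})
    return calls
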