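# Methods

This note records the model behind `tdnaseeker`, the parameters that
matter, the numerical conventions, and what the synthetic benchmark does
and does not demonstrate.

## Evidence model

A T-DNA insertion is a zero-width event in reference coordinates: host
sequence `…g_p | g_{p+1}…` becomes `…g_p [segment] g_{p+1}…`, where the
segment is a contiguous slice `tdna_st..tdna_end` of the donor construct
(possibly the whole construct), in either orientation. Two read classes
witness it:

* **CLR (soft-clipped reads)** cross a junction: one part of the read
  matches the genome, the rest matches the donor. Mapped to the donor
  first, such a read shows a soft clip (CIGAR1 = `nSyM`); realigned to the
  genome it shows the complementary pattern (CIGAR2 = `mMxS`). We require
  `|n − m| ≤ 5` (clip/match consistency) before trusting the pair of
  alignments, and a donor-side clip of at least 20 bp before attempting
  realignment at all — shorter fragments align too ambiguously. Reads
  clipped ≥ 20 bp on *both* donor ends span an entire short insert and
  carry no single junction; they are excluded.
* **DIR (discordant pairs)** have one mate on the donor and one on the
  genome. They locate an insertion to within roughly the fragment length
  but cannot give a base-exact position or the orientation.

### Junction geometry

Each CLR read is classified by (i) which side of its genome alignment is
clipped and (ii) the relative strand of its donor and genome alignments
(equal strands ⇒ forward insertion). The four combinations are scenarios
A (right clip, forward), B (left clip, forward), D (right clip, reverse),
E (left clip, reverse); discordant mates are C (genome mate on the forward
strand, junction downstream) or F (reverse strand, junction upstream).

The construct endpoint a CLR read reports (`tdna_border`) is the one
adjacent to the junction, derived from the same geometry: right-clip +
forward and left-clip + reverse expose the segment **start** (the read
enters the donor at its lowest retained coordinate), the other two
combinations expose the segment **end**. `tdna_pos` is then the leftmost
(start) or rightmost (end) donor base covered by the alignment. We derive
the border from junction geometry rather than from which construct end the
alignment is numerically closer to: for short retained segments near one
end of the construct the proximity heuristic mislabels the border, while
the geometric rule is exact. The two rules agree everywhere else.

Junction coordinates are normalised so both junction faces vote for the
same base: `bp` = last matched genome base before a right clip, or (first
matched base − 1) for a left clip. On error-free data every CLR read of an
insertion at `p` reports `bp = p` exactly, up to chance microhomology
between the donor terminus and the adjacent host sequence (the aligner
extends the match while bases agree; the shift is geometric with ratio
1/4, so almost always ≤ 2 bp and absorbed by the 5 bp cluster window).

### Clustering and calling

Per chromosome, CLR and DIR evidence are sorted by `bp` and partitioned by
chained adjacency — element *i* joins the open cluster iff
`|bp_i − bp_{i−1}| ≤ win` — with `win_clr = 5` bp and `win_dir = 500` bp
(the library fragment length). Because one insertion yields both kinds of
evidence, each DIR cluster is merged into the nearest CLR cluster whose
position estimate lies within `win_dir`; DIR clusters with no such partner
stand alone and, if called, are flagged `approximate` with strand `.`.

A cluster with at least `min_support = 3` members becomes a call:

* `position` = mode of member `bp` (CLR members only when any exist; ties
  to the smallest coordinate);
* `strand` = majority CLR orientation (`.` on a tie or with no CLR);
* `tdna_st` = mode of `tdna_pos` over border-start members (tie →
  smallest), `tdna_end` = mode over border-end members (tie → largest);
  the outermost tie-breaks give the most conservative truncation estimate;
  an unobserved side is reported as `-`. In the degenerate case of
  conflicting evidence placing `tdna_st > tdna_end`, the two are swapped.

A call is *complete* when both observed endpoints lie within
`border_slack = 25` bp of the construct ends (border repeats are commonly
nibbled by a few bases at integration), *truncated* when an observed side
violates that, and *undetermined* when only a within-slack side was seen.

### Zygosity

For each call the ±500 bp reference-allele flank (ICF) is extracted and
all reads are remapped to these mini-references. Reads with MAPQ ≥ 30
whose aligned interval spans the junction by ≥ 5 bp on both sides count as
reference-allele evidence `N_span`; the insertion frequency is
`N_clr / (N_clr + N_span)`, reported to two decimals. `N_clr` is the
caller's cluster count (both junction faces), not recounted on the ICF and
not MAPQ-filtered — it is deliberately the same number printed in the call
table. Because both junctions contribute to `N_clr` but a single point
gates `N_span`, heterozygous loci tend to read slightly above 0.5
(typically 0.45–0.65 at 20x). Coarse labels: homozygous ≥ 0.8,
heterozygous ≥ 0.3, else low-frequency; thresholds are configurable and
deliberately wide.

### Annotation

An insertion occupies no reference width, so a call is annotated with
every gene-model interval (default feature type `gene`, 1-based inclusive)
containing its point position; an interval tree per chromosome backs the
lookup.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_clip` | 20 bp | donor-side soft clip required for a CLR candidate |
| `clip_tol` | 5 bp | allowed clip-vs-match disagreement between the two alignments |
| `win_clr` / `win_dir` | 5 / 500 bp | chained clustering windows (DIR window = fragment length) |
| `min_support` | 3 reads | minimum cluster size to emit a call |
| `flank` | 500 bp | ICF half-width for zygosity |
| `min_mapq` / `span` | 30 / 5 bp | spanning-read filter on the ICF |
| `tol` | 100 bp | truth-matching radius in the benchmark |
| `border_slack` | 25 bp | construct-end tolerance for the complete/truncated label |

`workers` (default 1) partitions stage-2 filtering across processes; the
output is identical to the sequential result by construction, so the
setting is purely a throughput knob.

## Simulation and benchmark

The generator reproduces the benchmark's study conditions: a donor of
6,743 bp (the length of a common activation-tagging vector); each planted
copy complete with probability 0.5, otherwise truncated on the left,
right, or both sides (uniform over the three modes) with uniform cut
points subject to a retained length ≥ 50 bp; orientation uniform; placed
uniformly with ≥ 2 kb between insertions and from contig ends (the spacing
keeps evidence clusters of neighbouring insertions separable and is well
below any realistic insertion density). Reads are 150 bp paired-end,
fragments N(500, 50²), with uniform per-base substitution errors at 1%;
read counts follow `coverage·G/(2·read_length)`. The host genome defaults
to an i.i.d. uniform-composition synthetic sequence so the benchmark is
fully self-contained; any FASTA can be substituted.

The acceptance script runs this protocol on a 10 Mb genome with 100
insertions at 5x/10x/40x/2x and reports F-scores under ±100 bp one-to-one
greedy matching. The test suite runs the same protocol at 2 Mb/40
insertions over three seeds (coverage trend) and 1 Mb/20 insertions
(truncation, orientation, and zygosity recovery) to keep the default run
fast; problem sizes are constants at the top of the respective files.

### What the synthetic benchmark does not show

* **Repetitive hosts.** An i.i.d. genome has no repeats, so candidate
  realignment is nearly always unique; on real genomes MAPQ-0 placements
  and repeat-borne false clusters are possible (multi-mapping reads are
  *not* filtered at the extraction stage; only the zygosity stage applies
  MAPQ ≥ 30).
* **Complex integration events**: concatemers/multi-copy loci, filler DNA
  at junctions, and insertion-borne genomic rearrangements (e.g. local
  copy-number changes) are not simulated and not resolved — a real locus
  of that kind typically surfaces as a discordant-only, `approximate`
  call.
* **Sequencing artefacts** beyond uniform substitutions (indels, quality
  gradients, adapter read-through, PCR duplicates) are absent; inputs are
  assumed pre-trimmed.

## Numerical conventions and degenerate inputs

* All coordinates are 1-based inclusive (SAM/GFF3 convention), including
  the emitted tables; the truth/call `position` is the last original
  genome base before the insertion.
* Secondary and supplementary alignments are ignored everywhere, so no
  read contributes more than one piece of evidence; hard clips never count
  as clip evidence (no bases available to realign).
* Mode tie-breaks are deterministic (documented above), so repeated runs
  and different worker counts produce byte-identical call tables.
* ICF records at contig edges are shortened with the junction offset
  adjusted; calls clipped at coordinate bounds are clamped to ≥ 1.
* Fragments drawn longer than their contig are redrawn (bounded) and then
  clipped; an empty FASTQ pair yields a clean zero-call run.
* The benchmark driver skips the zygosity stage: the F-score does not use
  it, and the all-read ICF remap dominates runtime. `tdnaseeker call`
  estimates it by default.
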