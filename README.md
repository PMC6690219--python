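# tdnaseeker

Detection of **complete and truncated T-DNA insertions** in a host genome
from paired-end whole-genome sequencing.

In *Agrobacterium*-mediated insertional mutagenesis, a T-DNA construct
(typically ~5–10 kb with 25 bp border repeats) integrates into the plant
genome — often not as an intact unit but truncated at the left and/or right
end. PCR-based recovery of insertion sites (TAIL-PCR, inverse PCR, plasmid
rescue) struggles precisely in the truncated case, because the expected
border sequence may be gone. `tdnaseeker` locates insertions directly from
WGS reads, and reports for each one:

* the insertion **position** (1-based host coordinate),
* the **retained construct segment** `tdna_st..tdna_end` (how much of the
  donor survived integration, hence whether it is truncated),
* the insertion **orientation** (strand),
* the **insertion frequency** `freq = N_clr / (N_clr + N_span)` as a
  zygosity proxy (~1 homozygous, ~0.5 heterozygous),
* overlapping **gene models** from a GFF3 annotation.

## Method

The pipeline runs in five stages, using `bwa mem` (or any soft-clip-aware
local aligner; every stage alternatively accepts a pre-computed SAM):

1. **Map all reads to the T-DNA construct** — it is tiny compared to the
   genome, so this pass is cheap and discards almost everything.
2. **Extract informative candidates (IR1)** — reads mapped to the T-DNA
   with a soft clip ≥ 20 bp (*CLR*, soft-clipped reads straddling a
   junction) and pairs where exactly one mate maps to the T-DNA (*DIR*,
   discordant pairs; the other mate is genome sequence near the junction).
3. **Realign candidates to the host genome (IR2)**, requiring the
   soft-clipped T-DNA bases and the genome-matched bases of the same read
   to agree within 5 bp (`|clip₁ − match₂| ≤ 5`).
4. **Classify and cluster.** Each IR2 becomes a sextuple
   `(chr, bp, read_type, tdna_border, tdna_pos, orientation)` in one of six
   junction scenarios (A/B: forward insertion; D/E: reverse; C/F:
   discordant, orientation unknown). Per chromosome, sorted evidence is
   clustered by the chained window rule `|bp_i − bp_{i−1}| ≤ win` with
   `win = 5` bp for CLR and `win = 500` bp (the library fragment length)
   for DIR; a cluster with ≥ 3 supporting reads becomes a call at
   `position = mode(bp₁, …, bp_n)`.
5. **Zygosity and annotation.** All reads are remapped to the ±500 bp
   reference-allele flanks of each call; reads with MAPQ ≥ 30 spanning the
   junction by ≥ 5 bp on both sides count as `N_span`.

A wgsim-style simulator (`tdnaseeker simulate`) plants randomly truncated
donor copies (retained length ≥ 50 bp, about half complete) into a genome
and emits reads plus a truth table, and `tdnaseeker benchmark` scores the
whole pipeline against that truth with ±100 bp matching
(precision, recall, F-score).

## Worked example

Simulate a 500 kb genome carrying 10 planted insertions at 20x, call, and
score:

```console
$ tdnaseeker simulate --synthetic-length 500000 --n 10 --coverage 20 --seed 7 --out demo
10 insertions planted, 36061 read pairs written to demo
$ tdnaseeker call -1 demo/sim_1.fq -2 demo/sim_2.fq -t demo/tdna.fa -g demo/genome.fa -o demo/out
701 IR1, 666 IR2, 10 calls -> demo/out/calls.tsv
$ head -6 demo/out/calls.tsv
chr	position	n_clr	n_dir	tdna_st	tdna_end	strand	freq	annotation	approximate
chr1	28121	27	41	1	6743	-	1.00	-	no
chr1	65787	25	43	1	6717	-	1.00	-	no
chr1	146946	20	44	1	6743	+	1.00	-	no
chr1	169861	17	50	5359	5918	+	1.00	-	no
chr1	214162	19	27	1	3628	-	1.00	-	no
$ tdnaseeker evaluate --calls demo/out/calls.tsv --truth demo/truth.tsv
TP=10	FP=0	FN=0
precision=1.0000	recall=1.0000	f_score=1.0000
```

Reading the call table: the insertion at 28,121 retained the whole
6,743 bp construct in reverse orientation (`tdna_st 1, tdna_end 6743`,
strand `-`); the one at 169,861 is a doubly truncated copy that kept only
construct bases 5,359–5,918. `freq 1.00` says every read pair covering the
locus carries the insertion allele (the simulated sample is homozygous);
`annotation -` means no GFF3 was supplied. A call with `approximate yes`
would rest on discordant pairs alone and have no base-exact position.

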