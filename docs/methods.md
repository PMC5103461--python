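# Methods

This note documents the models, estimators and numerical choices behind
`straindiverge`, and what the synthetic-data generator does and does not
emulate.

## Synthetic genomes and the divergence model

`make_ancestor` draws i.i.d. bases with P(G)+P(C) = `gc` (default 0.47, the
GC content typical of the sequenced strains). `evolve` substitutes each site
independently with probability *p*, choosing uniformly among the three
alternative bases. The divergence knob accepts either the raw difference
fraction *p* or a Jukes–Cantor distance *d*, connected by
p = (3/4)(1 − e^(−4d/3)). Substitutions are single-hit per site: at the
divergences of interest (d ≤ 0.25) the discrepancy between "one draw per
site with probability p" and a true Poisson substitution process is absorbed
by the JC conversion and is far below every tolerance used, while keeping
the planted truth exact — the truth object records every substituted site,
and the column-wise mismatch count of the truth-aligned pair equals the
planted count exactly (a conservation invariant the tests enforce).

Indels (per-site rate, geometric lengths) and N-runs are applied after
substitutions and default to **off**: the divergence and Kr statistics both
exclude gap/N columns, so clean runs isolate the estimators; indel-bearing
runs exercise the aligner's gap bridging and the uncalled-column rules.
Substitutions deleted by an indel or masked by an N-run are removed from the
truth set, so truth and track always count the same columns.

Read simulation draws uniform start positions per replicon (wrapping across
the origin for circular replicons) at expected depth
`base_coverage × copy_number`, with uniform substitution errors at
`read_error_rate` (default 1%) and constant quality scores. Read length
defaults to 115 nt, the library format of the study data. Not emulated:
quality-score profiles, indel errors, PCR duplicates, paired-end inserts,
repeat families, coverage bias. Consequently, passing tests demonstrate the
estimators' correctness under uniform sampling; they do not certify
robustness to mappability or GC-coverage artifacts in real libraries.

Gene planting lays out genes sequentially (geometric intergenic gaps, so
overlap is impossible by construction; an overfull plan raises). Introns per
gene are Poisson (default mean 7.5); intron and exon lengths are shifted
geometric with means 110 and 199 nt — the intron-rich architecture the
statistics module is meant to summarize. CDS are canonical by construction
(ATG start, non-stop body codons, terminal stop, frame-clean); a configurable
fraction is corrupted in one of three ways (bad start, internal stop, frame
break) to exercise the canonical-CDS filter.

## Sliding-window divergence

The reference-projected call track classifies each reference position, per
query, as match / mismatch / uncalled. Uncalled covers: not aligned, gap
column, either residue outside {A,C,G,T}, or covered by more than one
alignment column (the ambiguity rule; overlap counts are logged, never
fatal). With two queries the design is two-queries-vs-one-reference:
a position enters the window statistics only if called for **both** queries
(joint calledness; pairwise runs relax this to the single track).

Windows are 1 kb with 1-kb step; a window with fewer than 500 called
positions is discarded (the trailing partial window obeys the same rule).
Each retained window's track value is smoothed as the unweighted mean of its
own value and up to five retained windows per side, skipping discarded
windows and never crossing a scaffold boundary — smoothing is therefore a
contraction with constant tracks as fixed points, and it affects only the
plotted track, never the summaries. Scaffold and genome-wide summaries are
micro-averages (pooled mismatch and called counts), not means of window
values: a per-site rate robust to unequal called counts. A scaffold with no
retained window reports an undefined value, never 0.

The built-in aligner is deliberately minimal, for largely collinear genomes:
k-mers (k = 16) occurring exactly once in each sequence are anchors; the
longest strictly increasing chain (patience LIS) is kept; same-diagonal
anchor runs pair columns directly; diagonal changes up to `max_gap` (2 kb)
are closed with a global edit-distance alignment (edlib), larger ones split
blocks. Gap placement within a bridged region does not affect any statistic
because indel columns are uncalled either way — which is why an
edit-distance (linear-gap) alignment suffices here in place of an
affine-gap aligner. Pre-computed alignments can be imported as MAF to bypass
the aligner entirely.

## Alignment-free Kr from shustrings

The shulen at position *i* of X against Y is the length of the shortest
substring of X starting at *i* absent from Y (and, by default, from Y's
reverse complement — genome distance should be strand-agnostic; the flag
exists for oracle tests). Positions whose every prefix up to the scaffold
end occurs in Y carry the sentinel value (remaining length + 1) and are
excluded from the mean. Scaffolds are joined by a separator symbol that
matches nothing, preventing spurious cross-scaffold matches; the same
symbol represents N/ambiguity, so N-containing substrings never match.

The core is exact, not heuristic: matching statistics are computed with a
suffix automaton built over the reversed index text (the longest match
*starting* at *i* in forward coordinates equals the longest match *ending*
at the mirrored position of the reversed pair), giving O(|X| + |Y|) per
direction. The test suite verifies it against brute-force enumeration of
the definition on hundreds of random pairs, exactly.

The divergence estimator is self-calibrated: expected mean shulen as a
function of *p* is measured by seeded simulation at matched length and GC
over a fixed grid (14 points, 2·10⁻⁴ … 0.45), interpolated monotonically
(PCHIP on log p) and inverted numerically (Brent). This was chosen over
transcribing a closed-form expectation: the calibration is reproducible
from the package alone, automatically matches the implementation's exact
matching semantics (reverse complement, separators, sentinels), and its
accuracy is enforced by recovery tests (≤ a few % relative error at 1–2 Mb
for d between 7.6·10⁻⁴ and 0.073). Both directions (X vs Y, Y vs X) are
estimated and averaged — the estimate is symmetric by construction. The JC
correction maps π̂ to substitutions/site; estimates above 0.3 are flagged
unreliable but reported (the flag, not a null, because capped comparisons
remain interpretable qualitatively); π̂ ≥ 0.75 raises a saturation error;
an observation outside the calibrated range raises rather than
extrapolating, except that observations *above* the least-diverged
calibration point (longer matches than any calibrated pair) are returned
as 0 — the identical-genomes limit.

## Targeted assembly and copy number

Recruitment: a read joins the pool if either orientation aligns to a bait
with identity ≥ 0.95 over ≥ 40% of the read (k-mer seeding, k = 12, with
gap-tolerant verification of the best few seed diagonals). The seed read
maximizes summed depth support over its bait footprint; ties go to the
longer alignment, then the lexicographically smaller id, for determinism.

The contig is the consensus of an ungapped stacked alignment (gap columns
contribute nothing to counts — reads with indel errors simply fail the
identity gate). A column is fixed only when IC = 2 − H > 0.5 bits **and**
coverage ≥ `cov_min`; the fixed base is the majority count, ties resolved
toward the previous consensus base, else in fixed order A<C<G<T. IC is
defined in bits on the 4-letter alphabet — the one standard definition for
which a 0.5 gate is a meaningful mid-range threshold. The gates are applied
per column, and each side of the contig stops at its first non-qualifying
column; extension advances at most `read_length − 20` columns per round per
side so every new column is supported by reads anchored (≥ 20 bases,
identity ≥ 0.95) in already-fixed sequence. Before the first round the seed
footprint itself is majority-polished from k-mer-placed reads: the contig is
the MSA consensus from the start, so the seed read's own sequencing errors
cannot poison the identity gate (without this, a 5%-error seed rejects
virtually every read and extension stalls).

`cov_min` defaults to 100 — appropriate for the extreme depths of high-copy
replicons — and is configurable; the test suite assembles 10-kb replicons at
200× with `cov_min` = 20, recovering the sequence exactly with error-free
and with 5%-error reads. Circularity: a suffix of ≥ 100 bp aligning to the
prefix at ≥ 98% identity closes the circle; the overlap is trimmed and the
sequence normalized to its lexicographically minimal rotation (Booth's
algorithm); comparisons to a reference should use the strand-agnostic
canonical form since assembly orientation follows the seed read.

Copy number is the ratio of median per-position read depths
(target/nuclear), reported unrounded and as the nearest integer. Median
depth is integer-valued, so the resolution of the ratio is one part in the
nuclear median — at 10–20× nuclear depth that is 5–10%, which the recovery
tests accommodate by construction of their regimes.

## Gene architecture

N50/L50 use the cumulative ≥ 50%-of-total convention. GC% excludes N from
the denominator (N is reported separately). An intron is the gap between
consecutive CDS exons of one gene — UTR introns are invisible to CDS-only
models. Exon/intron mean lengths are pooled over all exons/introns rather
than per-gene means of means; the "% correct CDS" column is interpreted as
the canonical-CDS rate (ATG start, stop end, length divisible by 3, no
internal stop, strand-aware extraction). Repeat content requires an
external repeat annotator and is emitted as NA.

## Orthology and orphan genes

Best hits rank rows passing the thresholds (e-value strictly < 1e-5;
annotation mode additionally identity strictly > 50%) by minimal e-value,
then maximal aligned length — the alignment-length column of the 12-column
format — then maximal bitscore, then lexicographic subject id; the last two
tiers are declared purely for determinism. RBH requires reciprocity; the
three-way core requires all three pairwise links to close a triangle, and
open triangles are counted separately (inconsistent), never silently
merged into core or exclusive sets.

The orphan chain applies, in order: core membership, expression coverage
≥ 0.5 (genes missing from the expression table count as 0 and are logged),
no related-species hit with e < 1e-5, no broad-database hit with e < 1e-5.
Domain annotations are counted among survivors but never filter. Tightening
any threshold can only shrink the orphan set (a monotonicity property the
tests enforce). The expression step consumes a precomputed per-gene
coverage table; mapping RNA-seq reads is upstream of this package.

## Problem sizes and determinism

Every stochastic stage draws from a child stream of one root seed, keyed by
fixed labels, so sub-stage outputs are independent of call order and
identical configs give byte-identical outputs. The recovery benchmarks run
at 1–5 Mb for the divergence statistics, 1–2 Mb (5 replicates, shared
calibration) for Kr, and 100-kb nuclear / 9–20-kb high-copy replicons for
copy number — sizes at which the binomial/sampling error of each statistic
is several times smaller than the tolerance being checked, chosen so the
whole benchmark suite completes in minutes on one CPU.

## Known limitations

- The anchor aligner assumes collinearity; rearranged genomes should come
  in as MAF from a structure-aware aligner.
- Kr values are calibrated against the package's own simulation model;
  numerical agreement with other shustring implementations is not claimed —
  the contract is recovery of simulated divergence.
- The assembler is targeted: it reconstructs a single replicon per bait and
  does not scaffold, phase, or resolve interior repeats longer than a read.
- Copy-number estimates inherit the granularity of integer median depths.
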