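# Methods

This note records the models, parameter choices, numerical details,
and known limits of each pipeline stage, in the order data flows
through them.

## Canonical k-mer counting

K-mers are identified with the lexicographic minimum of their forward
and reverse-complement spelling, the convention of the standard
short-read counters, so counts are strand-independent. Internally a
k-mer is a 2-bit-packed `uint64` (A=0 < C=1 < G=2 < T=3, matching
ASCII order), which makes numeric sort order equal lexicographic order
and lets all window extraction run as vectorised shift-or passes.
Windows containing any non-ACGT base contribute nothing; the
surrounding windows are unaffected. `k` is capped at 31 by the 64-bit
packing; the practical range is 11–31, and canonical counting with
even `k` (where palindromic k-mers equal their own reverse complement)
draws a warning rather than an error so that toy examples remain
expressible. Defaults are k=21 for marker derivation and binning and
k=20 for assembly evaluation, the two stages' conventional choices.

Tables persist as two-column TSV (`kmer<TAB>count`, lexicographically
sorted) with a `#k=.. canonical=.. label=..` header line; histograms
as `multiplicity<TAB>count`. In-memory hash/array counting is the
contract — there is no disk-based or probabilistic counting, and no
compatibility with binary counter formats.

## Marker derivation and read binning

A marker (hap-mer) for parent A is a canonical k-mer with count ≥
`min_count` in A's table and count 0 in B's. `min_count` defaults to 2
for real short-read tables (suppressing error k-mers) and 1 for
noiseless simulated genomes. Uniqueness is applied first, then the
homopolymer filter, which deletes markers containing ≥ 5 identical
consecutive bases: nanopore reads systematically shorten homopolymer
runs, so such markers would fail to match reads from their own parent.
Marker sets from one derivation are disjoint by construction, and
filtering can only shrink them.

Reads are classified by a strict majority of marker-window hits; a tie
(including 0–0) is `unknown`, and reads shorter than k are `unknown`
with zero hits. No density normalisation is applied — with balanced
parental marker sets (symmetric divergence) the raw counts are
directly comparable and the rule stays auditable. An optional
`min_hits` threshold exists for sensitivity analysis but has no
claimed default. Binned reads are written as three FASTQ files
preserving input order; accounting reports read counts, base totals,
base fractions (to one decimal, Mb = 1e6 bases) and per-bin read-length
N50 — the smallest length such that reads at least that long contain
half the bin's bases. A `min_read_length` flag (default off) drops
short reads from the *written* bins only, mirroring the common
assembler-side length filter, while the accounting still covers every
input read. Unknown-bin reads are written but excluded from
downstream stages by default.

## Phasing and consensus evaluation

Marker occurrences are scanned in positional order per contig. A
switch is an adjacent pair of occurrences from different parents; the
switch rate divides switches by informative adjacencies
(`markers_observed - contigs_with_markers`). The default is this
plain adjacent-pair definition with no smoothing; a `block_tolerance`
parameter (number of consecutive discordant markers required before a
parent change is believed) reproduces Merqury-like block smoothing for
sensitivity analysis. The hamming rate is wrong-parent markers over
all markers observed. An assembly containing no marker occurrence at
all yields an explicitly `undefined` report (rates `None`), never a
silent zero.

Consensus quality follows the k-mer survival argument: if a fraction
X/N of assembly windows is unsupported by the trusted read set, and a
single base error destroys k overlapping windows, the per-base error
rate is `E = 1 - (1 - X/N)^(1/k)`, reported as Phred
`QV = -10 log10(E)`. "Trusted" means count ≥ `error_cutoff` in the
read table, where the cutoff defaults to the first valley of the read
spectrum (shared with the genome-size stage). A query with X = 0 is
reported at `qv_cap` (default 99) with an explicit perfect flag rather
than infinity. K-mer completeness is the fraction of trusted read
k-mers present in the assembly; other-parent content is the fraction
of distinct assembly k-mers that are the other parent's markers.

HERS (high-error-rate subsequences) are maximal runs of positions
covered by no window whose canonical k-mer is trusted, computed by an
O(L) coverage-difference scan and emitted as 0-based half-open BED
(human-readable reports use 1-based coordinates). Contigs shorter
than k are one interval. HERS basespace is monotonically
non-decreasing in the error cutoff.

## Genome-size estimation

The estimator is the transparent peak/cutoff form of the spectrum
method: `G = sum_m m*h(m) / c`. The error cutoff is the spectrum's
first local minimum scanning from m=1; a monotone non-increasing
spectrum has no signal peak and raises a flagged failure. The
error-excluded size restricts the sum to m ≥ cutoff. In homozygous
mode the peak depth c is located by argmax above the cutoff and then
refined as the abundance-weighted centroid of the
full-width-at-half-maximum region around it — the refinement removes
the ±1 discretisation of the argmax (two near-tied bins at the mode
otherwise move the estimate by ~7% at 14× depth) and is exact on
noiseless uniform spectra. Spectra are tail-pooled above multiplicity
10,000 before estimation.

Heterozygous mode requires the caller's `expected_hom_cov` (a
configuration error otherwise; the CLI rejects such configs before any
computation) and uses it as c. Note the value is *k-mer-level*
coverage — base coverage times the window-per-read factor (L−k+1)/L
times the error-survival factor (1−e)^k. The mode additionally
demands evidence of a half-depth mode in the band [0.25c, 0.75c],
where a diploid sample's haplotype-specific k-mers sit: the detector
requires a statistically significant descent (difference > 3 sd under
Poisson counting noise) between positions inside the band. A binned,
single-haplotype read set rises monotonically through the band and is
flagged failed — the intended behaviour for haplotype-partitioned
reads, whose binning removed the half-depth peak, not an error of the
method. The band's abundance share is reported as a heterozygosity
indicator.

This estimator makes no claim of numerical equivalence with iterative
spectrum-fitting tools; it exercises the same mode logic (homozygous /
heterozygous, error exclusion, failure on binned read sets) on
simulations with known truth, where it recovers size within 5% at
≥ 15× depth.

## Gene-cluster calling

Loci are chained per chromosome in start order; a gene joins the
current chain while its start minus the previous gene's end (floored
at 0 for overlapping or abutting genes) is at most `max_gap`. Chains
with at least `min_members` — and, if a density is configured, at
least `min_density` members per base of span — become clusters. The
MTC preset is min_members=4, max_gap=2 Mb, no density term; the MRC
preset is min_members=5, max_gap=2 Mb, density ≥ 1 per 2 Mb. Spans
shorter than 2 Mb with ≥ 5 members pass the density test arithmetically.
Consecutive-gap chaining (single-linkage) rather than all-pairs
distance is used because it scales linearly, matches standard
cluster-calling practice, and admits the multi-megabase cluster spans
seen in real resistance-gene clusters; gap measurement end-to-start
between consecutive genes is one of several defensible readings of
"separated by no more than 2 Mb" and is fixed here. MRC calling in
practice is often done by eye; an operationalised rule will not
reproduce subjective cluster tables exactly, and no such equivalence
is claimed.

BLAST-hit overlap merging is interval union per chromosome (bookended
intervals merge; covered basespace is preserved), and two-callset
verification keeps predictions overlapping any verifying hit by at
least `min_overlap` bases (default 1 bp — the threshold used by the
original analyses is not documented), returned whole, never clipped.
GFF3 input (1-based inclusive) is converted to the internal 0-based
half-open convention on read; BED output is 0-based half-open.

## Synthetic trio generator

The generator emulates the statistical structure the pipeline assumes,
at desk scale. Defaults: 2 Mb uniform-random parents, haplotype B
derived from A by 0.5% per-base SNPs and 0.05% indels (geometric
lengths, p=0.5); F1 long reads drawn by fair coin from the two
haplotypes at lognormal lengths (mean 15 kb, sigma 0.5 in log space —
raising the scale pushes read N50 past 20 kb), 18× coverage, 1.8%
total error split 50/25/25 across mismatch/insertion/deletion with
deletions twice as likely inside homopolymer runs ≥ 3 (the nanopore
error mode motivating the homopentamer marker filter); parental
paired 150 bp short reads at 15× with 0.5% substitution error and
normal insert sizes around 3× read length. These proportions scale
the conditions of a real F1 trio-binning study (≈ 800 Mb haplotypes,
18× long reads per haplotype, ~15× parental short reads) down to
runtimes of seconds-to-minutes.

Every generator is deterministic under its seed (sub-generators use
`SeedSequence` spawns of it), and each emits a truth table: the
variant list with coordinates on both haplotypes, and per-read origin
haplotype, origin coordinates, and planted error count, so binning
accuracy and error recovery are scored exactly rather than
approximately.

What the simulation does *not* model — and what passing tests
therefore do not demonstrate — includes GC and composition skew,
repeat families and segmental duplication (the dominant difficulty for
real assembly and the main source of ambiguous markers), structural
variants beyond short indels, chimeric/adapter reads, contamination,
and organelle sequence. Binning accuracy of ~100% on the default trio
reflects clean unique-sequence genomes at 0.5% divergence; real
repeat-rich genomes bin worse, and the unknown bin is correspondingly
larger in practice.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on inputs from a few hundred bases to a
few hundred kilobases with brute-force dictionary/regex/position-set
oracles. The acceptance checks use the generator's default 2 Mb trio
for binning recovery, 200–500 kb genomes at 18× for genome-size
recovery across seeds, and 4 planted clusters over ~20 Mb layouts for
cluster recovery. These sizes were chosen so the whole suite completes
in a couple of minutes while every statistical tolerance (binomial 3σ,
5% size recovery, ±0.3 points error-rate recovery) still binds.
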