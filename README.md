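# triobin

K-mer based trio binning and evaluation of haplotype-resolved genome
assemblies, with a synthetic-trio generator for end-to-end validation.

## The problem

When an F1 individual is sequenced with long reads and both parents
(F0) with short reads, the offspring's reads can be partitioned by
inheritance before assembly: a 21-mer present in one parent's reads
and absent from the other's (a *hap-mer*) marks any read carrying it
as coming from that parent's haplotype. Assembling each bin separately
yields two fully phased haplotype drafts instead of a collapsed
mosaic. The same hap-mers then grade the result: how often adjacent
markers along a contig disagree (switch errors), how many wrong-parent
markers a draft contains, and how much of the assembly's k-mer content
is supported by the parents' reads.

`triobin` implements this workflow as a tested, reusable library and
CLI aimed at plant and animal genomicists working with F1 hybrids —
originally motivated by highly heterozygous crops where collapsed
assemblies are unusable:

- **kmer_core** — canonical k-mer counting over FASTA/FASTQ (plain or
  gzip), set algebra, multiplicity histograms, TSV persistence;
- **trio_binning** — parent-unique marker derivation (count ≥
  `min_count` in one parent, absent in the other), homopentamer marker
  filtering, strict-majority read classification into
  `parent_a`/`parent_b`/`unknown` bins;
- **phase_eval** — per-contig hap-mer profiles (blob-plot input),
  switch and hamming rates, k-mer completeness, other-parent content,
  consensus QV, and HERS (high-error-rate subsequence) BED intervals;
- **genome_size** — homozygous/heterozygous spectrum-based genome-size
  estimation with error-k-mer exclusion;
- **feature_clusters** — interval merging/intersection and gene-cluster
  calling for terpene-synthase (MTC) and NLR resistance (MRC) clusters;
- **sim_trio** — deterministic synthetic trios with truth tables.

## The statistics, briefly

*Markers.* With parental count tables $A$ and $B$ over canonical
21-mers, the marker sets are
$M_A = \{x : A(x) \ge c_{\min},\ B(x) = 0\}$ (symmetrically $M_B$),
minus any k-mer containing a homopolymer run of ≥ 5 bases (nanopore
homopolymer errors make those markers unreliable). A read is binned by
strict majority of its marker-window hits; ties (including 0–0) are
`unknown`.

*Consensus quality.* If $X$ of $N$ assembly k-mer windows are absent
from the trusted parental set, the per-base error rate is
$E = 1 - (1 - X/N)^{1/k}$ and $\mathrm{QV} = -10\log_{10} E$; base
precision is $100\,(1 - 10^{-\mathrm{QV}/10})$ %.

*Switch rate.* Scanning marker occurrences positionally along each
contig, a switch is an adjacent pair from different parents;
the rate divides switches by informative adjacencies (markers observed
minus contigs with ≥ 1 marker).

*Genome size.* With spectrum $h(m)$ (number of distinct k-mers at
multiplicity $m$) and coverage peak $c$,
$\hat G = \sum_m m\,h(m) / c$; the error-excluded variant drops
$m$ below the spectrum's first valley. Heterozygous mode takes $c$
from the caller (`expected_hom_cov`) and requires a half-depth mode in
$[0.25c, 0.75c]$ — absent on binned (single-haplotype) read sets,
which are flagged as failures rather than estimated.

*Gene clusters.* Single-linkage chaining of same-chromosome genes with
consecutive end-to-start gaps ≤ 2 Mb; MTC keeps chains of ≥ 4 terpene
synthases, MRC keeps chains of ≥ 5 NLRs at ≥ 1 NLR per 2 Mb of span.

## Worked example

```python
from triobin import sim_trio, kmer_core, trio_binning, phase_eval

config = sim_trio.TrioSimConfig(genome_length=500_000, seed=11)
hap_a, hap_b, variants = sim_trio.simulate_parents(config)
reads, truth = sim_trio.simulate_f1_long_reads(hap_a, hap_b, config)

spec = kmer_core.KmerSpec(21)
table_a = kmer_core.count_kmers([hap_a], spec, "parent_a")
table_b = kmer_core.count_kmers([hap_b], spec, "parent_b")
ma, mb = trio_binning.derive_unique_markers(table_a, table_b, min_count=1)
ma = trio_binning.filter_homopolymer_markers(ma)
mb = trio_binning.filter_homopolymer_markers(mb)
print(f"markers: {len(ma):,} (A) / {len(mb):,} (B)")

summary, _ = trio_binning.classify_readset(reads, ma, mb)
for name in trio_binning.BINS:
    s = summary.per_bin[name]
    print(f"{name}: {s.read_count} reads, {s.base_total:,} bases "
          f"({summary.fraction_pct(name)}%), N50 {s.n50}")

trusted = kmer_core.count_kmers([hap_a, hap_b], spec)
qv = phase_eval.estimate_qv((s for _, s in reads[:200]), trusted)
print(f"read QV {qv.qv:.2f} -> per-base error {100*qv.error_rate:.2f}%")
```

prints

```
markers: 50,218 (A) / 50,226 (B)
parent_a: 302 reads, 4,677,300 bases (52.0%), N50 18343
parent_b: 299 reads, 4,325,760 bases (48.0%), N50 16724
unknown: 0 reads, 0 bases (0.0%), N50 None
read QV 17.43 -> per-base error 1.81%
```

Every read of this 500 kb trio carries markers and lands in its true
parent's bin (the truth table in `truth` lets you verify), and the QV
machinery recovers the simulator's planted 1.8 % read error from the
k-mer spectra alone.

The same pipeline is available from the shell:

```
triobin run --out runs/demo --seed 11 --genome-length 500000
triobin clusters genes.gff3 --preset mtc -o clusters/
```

Each run directory carries a JSON-lines manifest with sha256 checksums;
rerunning with the same seed and config reproduces every artifact
byte-for-byte.

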