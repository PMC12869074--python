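"""Synthetic trio generator: parental haplotypes, F1 long reads, short reads.

The generator emulates the statistical structure the pipeline assumes:

* two parental haplotypes diverged by SNPs (default 0.5% per base) and
  small indels (0.05%, geometric lengths);
* F1 long reads drawn 50/50 from the two haplotypes at lognormal
  lengths (mean 15 kb by default, N50 tunable above 20 kb via the
  length sigma), 18x coverage, 1.8% total error split across
  mismatches, insertions and deletions, with deletions more likely
  inside homopolymer runs >= 3 (the nanopore error mode that motivates
  the homopentamer marker filter);
* parental paired short reads, 150 bp at 15x with 0.5% substitution
  error, insert sizes normal around 3x read length;
* gene layouts with planted clusters for cluster-calling recovery.

Base composition is uniform (no GC skew, no repeat families): the
binning and evaluation logic, not assembly difficulty, is under test.
Every generator is deterministic under a fixed seed, and each emits a
truth table so downstream accuracy can be scored exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _codec, io
from .errors import ConfigurationError
from .feature_clusters import GeneLocus


@dataclass
class TrioSimConfig:
    """Desk-scale defaults proportioned to a full trio-binning study."""

    genome_length: int = 2_000_000
    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    indel_length_geometric_p: float = 0.5
    long_read_mean: float = 15_000.0
    long_read_sigma: float = 0.5          # sigma of log length
    long_read_coverage: float = 18.0
    long_read_error: float = 0.018        # total per-base error
    long_read_error_split: tuple[float, float, float] = (0.5, 0.25, 0.25)  # mm, ins, del
    homopolymer_del_bias: float = 2.0     # deletion multiplier inside runs >= 3
    short_read_length: int = 150
    short_read_coverage: float = 15.0
    short_read_error: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "long_read_error", "short_read_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.long_read_coverage <= 0 or self.short_read_coverage <= 0:
            raise ConfigurationError("coverage must be positive")
        if abs(sum(self.long_read_error_split) - 1.0) > 1e-9:
            raise ConfigurationError("long_read_error_split must sum to 1")


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)


def _homopolymer_mask(bases: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Positions lying inside a run of >= min_run identical bases."""
    n = bases.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.concatenate(([True], bases[1:] != bases[:-1]))
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def simulate_parents(
    config: TrioSimConfig,
) -> tuple[str, str, pd.DataFrame]:
    """Generate haplotype A (random DNA) and B (A + SNPs + indels).

    Returns (hap_a, hap_b, variants) where the variant table lists
    every planted difference with coordinates on both haplotypes.
    """
    rng = np.random.default_rng(config.seed)
    a = _random_genome(rng, config.genome_length)

    snp_pos = np.flatnonzero(rng.random(a.size) < config.snp_rate)
    indel_pos = np.flatnonzero(rng.random(a.size) < config.indel_rate)
    indel_pos = indel_pos[~np.isin(indel_pos, snp_pos)]

    b = a.copy()
    snp_alt = (a[snp_pos] + rng.integers(1, 4, size=snp_pos.size)) % 4
    b_snp = b.copy()
    b_snp[snp_pos] = snp_alt.astype(np.uint8)

    # apply indels left-to-right, tracking the coordinate offset
    records = []
    segments = []
    cursor = 0
    offset = 0
    is_ins = rng.random(indel_pos.size) < 0.5
    lengths = rng.geometric(config.indel_length_geometric_p, size=indel_pos.size)
    for pos, ins, ln in zip(indel_pos.tolist(), is_ins.tolist(), lengths.tolist()):
        segments.append(b_snp[cursor:pos])
        pos_b = pos + offset
        if ins:
            insert = rng.integers(0, 4, size=ln).astype(np.uint8)
            segments.append(insert)
            segments.append(b_snp[pos : pos + 1])
            records.append(("INS", pos, pos_b, int(ln), "", _codec.decode_bases(insert)))
            offset += ln
            cursor = pos + 1
        else:
            ln = min(ln, a.size - pos)
            records.append(("DEL", pos, pos_b, int(ln), _codec.decode_bases(a[pos : pos + ln]), ""))
            offset -= ln
            cursor = pos + ln
    segments.append(b_snp[cursor:])
    b_final = np.concatenate(segments) if segments else b_snp

    snp_records = [
        ("SNP", int(p), int(p), 1, _codec.decode_bases(a[p : p + 1]), _codec.decode_bases(snp_alt[i : i + 1]))
        for i, p in enumerate(snp_pos.tolist())
    ]
    variants = pd.DataFrame(
        snp_records + records,
        columns=["type", "pos_a", "pos_b", "length", "ref", "alt"],
    ).sort_values("pos_a", ignore_index=True)
    return _codec.decode_bases(a), _codec.decode_bases(b_final), variants


def _draw_lengths(rng: np.random.Generator, config: TrioSimConfig, n: int) -> np.ndarray:
    mu = math.log(config.long_read_mean) - config.long_read_sigma**2 / 2.0
    return np.maximum(rng.lognormal(mu, config.long_read_sigma, size=n).astype(np.int64), 100)


def _inject_errors(
    frag: np.ndarray,
    hp_mask: np.ndarray,
    rng: np.random.Generator,
    config: TrioSimConfig,
) -> tuple[np.ndarray, int]:
    """Apply mismatch/insertion/deletion errors; returns (read, n_errors)."""
    e = config.long_read_error
    if e == 0:
        return frag, 0
    w_mm, w_ins, w_del = config.long_read_error_split
    p_mm, p_ins, p_del = e * w_mm, e * w_ins, e * w_del
    del_p = np.where(hp_mask, min(p_del * config.homopolymer_del_bias, 1.0), p_del)
    u = rng.random(frag.size)
    ev = np.zeros(frag.size, dtype=np.uint8)
    ev[u < p_mm] = 1
    ev[(u >= p_mm) & (u < p_mm + p_ins)] = 2
    ev[(u >= p_mm + p_ins) & (u < p_mm + p_ins + del_p)] = 3

    out_src = frag.copy()
    mm = ev == 1
    out_src[mm] = (out_src[mm] + rng.integers(1, 4, size=int(mm.sum())).astype(np.uint8)) % 4
    rep = np.ones(frag.size, dtype=np.int64)
    rep[ev == 3] = 0
    rep[ev == 2] = 2
    out = np.repeat(out_src, rep)
    ins_idx = np.cumsum(rep)[ev == 2] - 1
    out[ins_idx] = rng.integers(0, 4, size=ins_idx.size).astype(np.uint8)
    return out, int((ev != 0).sum())


def simulate_f1_long_reads(
    hap_a: str,
    hap_b: str,
    config: TrioSimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """F1 long reads with truth labels.

    Reads alternate between haplotypes via a fair coin, lognormal
    lengths, until coverage (relative to the mean haplotype length) is
    reached.  Returns ``(records, truth)`` where records are
    ``(read_id, sequence)`` and truth maps each read to its origin
    haplotype, origin coordinates, and planted error count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    haps = [
        _codec.encode_bases(hap_a),
        _codec.encode_bases(hap_b),
    ]
    hp_masks = [_homopolymer_mask(h) for h in haps]
    mean_len = (len(hap_a) + len(hap_b)) / 2.0
    target = config.long_read_coverage * mean_len
    records: list[tuple[str, str]] = []
    truth_rows = []
    total = 0
    i = 0
    while total < target:
        hap_idx = int(rng.integers(0, 2))
        hap = haps[hap_idx]
        L = int(min(_draw_lengths(rng, config, 1)[0], hap.size))
        start = int(rng.integers(0, hap.size - L + 1))
        frag = hap[start : start + L]
        read, n_err = _inject_errors(frag, hp_masks[hap_idx][start : start + L], rng, config)
        rid = f"read{i:06d}"
        records.append((rid, _codec.decode_bases(read)))
        truth_rows.append((rid, "parent_a" if hap_idx == 0 else "parent_b", start, L, n_err))
        total += read.size
        i += 1
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "origin", "origin_start", "origin_length", "errors"]
    )
    return records, truth


def simulate_parent_short_reads(
    haplotype: str,
    config: TrioSimConfig,
    seed_offset: int = 2,
) -> list[tuple[str, str, str]]:
    """Error-bearing paired short reads as (read_id, seq_fwd, seq_rev) triples.

    Pair count is ceil(coverage * G / (2 * read_length)); inserts are
    normal around 3x read length; errors are substitutions only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_offset]))
    hap = _codec.encode_bases(haplotype)
    G = hap.size
    rl = config.short_read_length
    n_pairs = math.ceil(config.short_read_coverage * G / (2 * rl))
    inserts = np.clip(
        rng.normal(3 * rl, 0.1 * 3 * rl, size=n_pairs), 2 * rl, max(G, 2 * rl)
    ).astype(np.int64)
    starts = rng.integers(0, np.maximum(G - inserts + 1, 1), size=n_pairs)
    out = []
    for j in range(n_pairs):
        s, ins = int(starts[j]), int(inserts[j])
        frag = hap[s : s + ins]
        r1 = frag[:rl].copy()
        r2 = (3 - frag[-rl:][::-1]).copy()  # reverse complement
        for r in (r1, r2):
            errs = np.flatnonzero(rng.random(r.size) < config.short_read_error)
            r[errs] = (r[errs] + rng.integers(1, 4, size=errs.size).astype(np.uint8)) % 4
        out.append((f"pair{j:06d}", _codec.decode_bases(r1), _codec.decode_bases(r2)))
    return out


def write_fastq(records, path: io.PathLike, qual_char: str = "I") -> None:
    """Write (id, seq) records as FASTQ with a constant placeholder quality."""
    with io.open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_fasta(named_seqs, path: io.PathLike, comment: str = "") -> None:
    with io.open_text(path, "wt") as fh:
        for name, seq in named_seqs:
            header = f">{name}"
            if comment:
                header += f" {comment}"
            fh.write(header + "\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


@dataclass
class ClusterSpecEntry:
    n_genes: int
    span: int
    position: int


def make_gene_layout(
    chrom_length: int,
    cluster_specs: Sequence[tuple[int, int, int]],
    background_genes: int = 0,
    seed: int = 0,
    chrom: str = "chr1",
    gene_length: int = 3_000,
    category: str = "TPS",
) -> tuple[list[GeneLocus], list[list[str]]]:
    """Plant gene clusters plus scattered background genes.

    ``cluster_specs`` is a list of ``(n_genes, span, position)``;
    cluster genes are evenly spaced across the span.  Returns
    ``(loci, planted)`` where ``planted`` lists the member ids of each
    planted cluster.  Overlapping cluster specs are rejected.
    """
    rng = np.random.default_rng(seed)
    spans = sorted((pos, pos + span) for n, span, pos in cluster_specs)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ConfigurationError("overlapping cluster specs")
    if spans and (spans[0][0] < 0 or spans[-1][1] > chrom_length):
        raise ConfigurationError("cluster specs do not fit the chromosome")

    loci: list[GeneLocus] = []
    planted: list[list[str]] = []
    for ci, (n, span, pos) in enumerate(cluster_specs):
        if n * gene_length > span:
            raise ConfigurationError(f"cluster {ci}: {n} genes do not fit span {span}")
        starts = np.linspace(pos, pos + span - gene_length, n).astype(np.int64)
        ids = []
        for gi, s in enumerate(starts.tolist()):
            lid = f"c{ci}_g{gi}"
            loci.append(GeneLocus(chrom, int(s), int(s) + gene_length, "+", lid, category))
            ids.append(lid)
        planted.append(ids)
    for bi in range(background_genes):
        s = int(rng.integers(0, chrom_length - gene_length))
        loci.append(GeneLocus(chrom, s, s + gene_length, "+", f"bg_{bi}", category))
    return loci, planted


def simulate_trio(config: TrioSimConfig, out_dir: io.PathLike | None = None):
    """Convenience bundle: parents, long reads, short reads, truth tables.

    When ``out_dir`` is given the standard files are written there
    (FASTA haplotypes, F1 FASTQ, paired parental FASTQ, truth TSVs)
    with the seed echoed in a header comment.
    """
    hap_a, hap_b, variants = simulate_parents(config)
    long_reads, truth = simulate_f1_long_reads(hap_a, hap_b, config)
    pairs_a = simulate_parent_short_reads(hap_a, config, seed_offset=2)
    pairs_b = simulate_parent_short_reads(hap_b, config, seed_offset=3)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comment = f"seed={config.seed}"
        write_fasta([("hap_a", hap_a)], out / "hap_a.fasta", comment)
        write_fasta([("hap_b", hap_b)], out / "hap_b.fasta", comment)
        write_fastq(long_reads, out / "f1_long_reads.fastq")
        write_fastq(
            [(f"{rid}/1", s1) for rid, s1, _ in pairs_a]
            + [(f"{rid}/2", s2) for rid, _, s2 in pairs_a],
            out / "parent_a_short.fastq",
        )
        write_fastq(
            [(f"{rid}/1", s1) for rid, s1, _ in pairs_b]
            + [(f"{rid}/2", s2) for rid, _, s2 in pairs_b],
            out / "parent_b_short.fastq",
        )
        variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        truth.to_csv(out / "long_read_truth.tsv", sep="\t", index=False)
    return hap_a, hap_b, variants, long_reads, truth, pairs_a, pairs_b
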