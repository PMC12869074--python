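"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — dictionaries, regexes, and
per-position loops — and shares no code with the package internals.
"""
from __future__ import annotations

import re

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(seqs, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k].upper()
            if any(c not in "ACGT" for c in w):
                continue
            c = canonical(w)
            counts[c] = counts.get(c, 0) + 1
    return counts


def unique_markers(counts_a: dict, counts_b: dict, min_count: int) -> tuple[set, set]:
    ma = {k for k, v in counts_a.items() if v >= min_count and k not in counts_b}
    mb = {k for k, v in counts_b.items() if v >= min_count and k not in counts_a}
    return ma, mb


def has_homopolymer(kmer: str, max_run: int = 5) -> bool:
    return re.search(r"(A{%d}|C{%d}|G{%d}|T{%d})" % ((max_run,) * 4), kmer) is not None


def marker_hits(seq: str, markers: set[str], k: int) -> int:
    hits = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        if canonical(w) in markers:
            hits += 1
    return hits


def unsupported_windows(seq: str, trusted: set[str], k: int) -> tuple[int, int]:
    """(total valid windows, windows whose canonical k-mer is untrusted)."""
    total = bad = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        total += 1
        if canonical(w) not in trusted:
            bad += 1
    return total, bad


def hers_intervals(seq: str, trusted: set[str], k: int) -> list[tuple[int, int]]:
    """Per-position coverage: unverified runs as half-open intervals."""
    L = len(seq)
    verified = [False] * L
    for i in range(L - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        if canonical(w) in trusted:
            for p in range(i, i + k):
                verified[p] = True
    out = []
    start = None
    for p in range(L):
        if not verified[p] and start is None:
            start = p
        elif verified[p] and start is not None:
            out.append((start, p))
            start = None
    if start is not None:
        out.append((start, L))
    return out


def covered_positions(intervals) -> set[tuple[str, int]]:
    return {(c, p) for c, s, e in intervals for p in range(s, e)}


def intersect_allpairs(preds, hits, min_overlap: int = 1) -> list:
    kept = []
    for pc, ps, pe in sorted(preds):
        for hc, hs, he in hits:
            if pc == hc and min(pe, he) - max(ps, hs) >= min_overlap:
                kept.append((pc, ps, pe))
                break
    return kept


def cluster_components(loci, max_gap: int) -> list[set[str]]:
    """Transitive closure of the consecutive-gap relation, per chromosome."""
    by_chrom: dict[str, list] = {}
    for g in loci:
        by_chrom.setdefault(g.chrom, []).append(g)
    comps = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.locus_id))
        comp = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            if max(cur.start - prev.end, 0) <= max_gap:
                comp.append(cur)
            else:
                comps.append({g.locus_id for g in comp})
                comp = [cur]
        comps.append({g.locus_id for g in comp})
    return comps
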