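"""Canonical k-mer extraction, counting, set algebra, and multiplicity histograms.

A *canonical* k-mer is the lexicographically smaller of a k-mer and its
reverse complement, giving strand-independent identity — the convention
used by the short-read counters this stage stands in for.  Tables are
held in memory as sorted packed-code arrays (see :mod:`triobin._codec`)
and persist as plain two-column TSV dumps sorted lexicographically.

The binning stage counts 21-mers; the Merqury-style evaluation stage
counts 20-mers.  ``k`` is therefore configurable per stage.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from . import _codec, io
from .errors import ConfigurationError

#: stage defaults: parent-unique marker derivation / read binning
DEFAULT_BINNING_K = 21
#: stage defaults: assembly evaluation (completeness, QV, hap-mer profiles)
DEFAULT_EVAL_K = 20


@dataclass(frozen=True)
class KmerSpec:
    """k-mer length and strand-collapsing convention for one stage.

    Recommended range is 11–31 with odd k when canonical (an odd k-mer
    can never equal its own reverse complement); values outside that are
    accepted for toy inputs but an even canonical k draws a warning.
    """

    k: int
    canonical: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.k <= _codec.MAX_K):
            raise ConfigurationError(f"k must be in [1, {_codec.MAX_K}], got {self.k}")
        if self.canonical and self.k % 2 == 0:
            warnings.warn(
                f"even k={self.k} with canonical counting: palindromic k-mers "
                "are their own reverse complement",
                stacklevel=2,
            )


def canonicalize(kmer: str, spec: KmerSpec) -> str:
    """Return the canonical form (lexicographic min of kmer and revcomp).

    Idempotent; raises ValueError on non-ACGT characters or wrong length
    so callers can skip the offending window.
    """
    if len(kmer) != spec.k:
        raise ValueError(f"k-mer length {len(kmer)} != spec.k {spec.k}")
    code = _codec.encode_kmer(kmer)
    if not spec.canonical:
        return kmer.upper()
    rc = _codec.revcomp_code(code, spec.k)
    return _codec.decode_kmer(min(code, rc), spec.k)


class KmerCountTable:
    """Counts of canonical k-mers, stored as sorted packed codes.

    Numeric code order equals lexicographic k-mer order, so the arrays
    double as the sorted text-dump order.
    """

    def __init__(
        self,
        spec: KmerSpec,
        kmers: np.ndarray,
        counts: np.ndarray,
        source_label: str = "",
    ):
        kmers = np.asarray(kmers, dtype=np.uint64)
        counts = np.asarray(counts, dtype=np.int64)
        if kmers.shape != counts.shape:
            raise ValueError("kmers and counts must have equal length")
        if kmers.size and not np.all(kmers[1:] > kmers[:-1]):
            order = np.argsort(kmers, kind="stable")
            kmers, counts = kmers[order], counts[order]
            if np.any(kmers[1:] == kmers[:-1]):
                raise ValueError("duplicate k-mer codes in table")
        if np.any(counts < 1):
            raise ValueError("all counts must be >= 1")
        self.spec = spec
        self.kmers = kmers
        self.counts = counts
        self.source_label = source_label

    # -- construction -------------------------------------------------
    @classmethod
    def from_codes(cls, spec: KmerSpec, codes: np.ndarray, source_label: str = "") -> "KmerCountTable":
        kmers, counts = np.unique(np.asarray(codes, dtype=np.uint64), return_counts=True)
        return cls(spec, kmers, counts.astype(np.int64), source_label)

    @classmethod
    def from_dict(cls, spec: KmerSpec, mapping: dict[str, int], source_label: str = "") -> "KmerCountTable":
        codes = np.array([_codec.encode_kmer(k) for k in mapping], dtype=np.uint64)
        if spec.canonical and codes.size:
            codes = _codec.canonical_codes(codes, spec.k)
        counts = np.array(list(mapping.values()), dtype=np.int64)
        uniq, inverse = np.unique(codes, return_inverse=True)
        summed = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(summed, inverse, counts)
        return cls(spec, uniq, summed, source_label)

    # -- basic accounting ---------------------------------------------
    @property
    def total_distinct(self) -> int:
        return int(self.kmers.size)

    @property
    def total_abundance(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.total_distinct

    def __contains__(self, kmer: str | int) -> bool:
        return self.count_of(kmer) > 0

    def count_of(self, kmer: str | int) -> int:
        code = _codec.encode_kmer(kmer) if isinstance(kmer, str) else int(kmer)
        if self.spec.canonical and isinstance(kmer, str):
            code = min(code, _codec.revcomp_code(code, self.spec.k))
        i = np.searchsorted(self.kmers, np.uint64(code))
        if i < self.kmers.size and self.kmers[i] == code:
            return int(self.counts[i])
        return 0

    def counts_for(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised lookup; absent codes count 0."""
        codes = np.asarray(codes, dtype=np.uint64)
        idx = np.searchsorted(self.kmers, codes)
        idx_c = np.minimum(idx, max(self.kmers.size - 1, 0))
        hit = (self.kmers.size > 0) & (self.kmers[idx_c] == codes)
        out = np.zeros(codes.size, dtype=np.int64)
        out[hit] = self.counts[idx_c[hit]]
        return out

    def member_mask(self, codes: np.ndarray, min_count: int = 1) -> np.ndarray:
        """Boolean mask of codes present with count >= min_count."""
        return self.counts_for(codes) >= min_count

    def kmers_with_count_at_least(self, min_count: int) -> np.ndarray:
        return self.kmers[self.counts >= min_count]

    def items(self) -> Iterator[tuple[str, int]]:
        for code, count in zip(self.kmers.tolist(), self.counts.tolist()):
            yield _codec.decode_kmer(code, self.spec.k), int(count)

    def as_dict(self) -> dict[str, int]:
        return dict(self.items())

    # -- persistence ---------------------------------------------------
    def to_tsv(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            fh.write(f"#k={self.spec.k}\tcanonical={int(self.spec.canonical)}\tlabel={self.source_label}\n")
            for kmer, count in self.items():
                fh.write(f"{kmer}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: io.PathLike) -> "KmerCountTable":
        mapping: dict[str, int] = {}
        spec = None
        label = ""
        with io.open_text(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    fields = dict(f.split("=", 1) for f in line[1:].split("\t") if "=" in f)
                    if "k" in fields:
                        spec = KmerSpec(int(fields["k"]), bool(int(fields.get("canonical", "1"))))
                        label = fields.get("label", "")
                    continue
                kmer, count = line.split("\t")
                mapping[kmer] = int(count)
        if spec is None:
            if not mapping:
                raise ValueError(f"empty k-mer table without header: {path}")
            spec = KmerSpec(len(next(iter(mapping))))
        return cls.from_dict(spec, mapping, source_label=label)


def count_kmers(sequences, spec: KmerSpec, source_label: str = "") -> KmerCountTable:
    """Count every valid k-window of the input under the spec's convention.

    ``sequences`` may be a FASTA/FASTQ path (gzip ok) or an iterable of
    records / ``(id, seq)`` tuples / plain strings.  Windows containing
    non-ACGT characters contribute nothing; empty input yields an empty
    table.
    """
    chunks: list[np.ndarray] = []
    for rec in io.iter_records(sequences):
        codes, _ = _codec.window_codes(str(rec.seq), spec.k, spec.canonical)
        if codes.size:
            chunks.append(codes)
    if not chunks:
        return KmerCountTable(spec, np.empty(0, np.uint64), np.empty(0, np.int64), source_label)
    return KmerCountTable.from_codes(spec, np.concatenate(chunks), source_label)


@dataclass
class KmerHistogram:
    """Multiplicity spectrum: h(m) = number of distinct k-mers seen m times."""

    spec: KmerSpec
    #: dense counts indexed by multiplicity; index 0 unused (always 0)
    dense: np.ndarray = field(repr=False)

    @property
    def bins(self) -> dict[int, int]:
        m = np.flatnonzero(self.dense)
        return {int(i): int(self.dense[i]) for i in m}

    @property
    def max_multiplicity(self) -> int:
        nz = np.flatnonzero(self.dense)
        return int(nz[-1]) if nz.size else 0

    @property
    def total_abundance(self) -> int:
        m = np.arange(self.dense.size, dtype=np.int64)
        return int((m * self.dense).sum())

    @property
    def total_distinct(self) -> int:
        return int(self.dense.sum())

    def h(self, m: int) -> int:
        return int(self.dense[m]) if 0 <= m < self.dense.size else 0

    @classmethod
    def from_bins(cls, spec: KmerSpec, bins: dict[int, int]) -> "KmerHistogram":
        if any(m < 1 for m in bins):
            raise ValueError("multiplicities must be >= 1")
        size = (max(bins) + 1) if bins else 1
        dense = np.zeros(size, dtype=np.int64)
        for m, h in bins.items():
            dense[m] = h
        return cls(spec, dense)

    def pool_tail(self, max_multiplicity: int) -> "KmerHistogram":
        """Pool all bins above ``max_multiplicity`` into the final bin,
        preserving total abundance (mass moved as m * h(m) / cap)."""
        if self.max_multiplicity <= max_multiplicity:
            return self
        dense = self.dense[: max_multiplicity + 1].copy()
        m = np.arange(self.dense.size, dtype=np.int64)
        tail_abundance = int((m[max_multiplicity + 1 :] * self.dense[max_multiplicity + 1 :]).sum())
        dense[max_multiplicity] += tail_abundance // max_multiplicity
        return KmerHistogram(self.spec, dense)

    def to_tsv(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            fh.write(f"#k={self.spec.k}\tcanonical={int(self.spec.canonical)}\n")
            for m, h in self.bins.items():
                fh.write(f"{m}\t{h}\n")

    @classmethod
    def from_tsv(cls, path: io.PathLike) -> "KmerHistogram":
        bins: dict[int, int] = {}
        spec = None
        with io.open_text(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    fields = dict(f.split("=", 1) for f in line[1:].split("\t") if "=" in f)
                    if "k" in fields:
                        spec = KmerSpec(int(fields["k"]), bool(int(fields.get("canonical", "1"))))
                    continue
                m, h = line.split("\t")
                bins[int(m)] = int(h)
        return cls.from_bins(spec or KmerSpec(DEFAULT_BINNING_K), bins)


def histogram(table: KmerCountTable) -> KmerHistogram:
    """Tally the multiplicity spectrum of a count table.

    Invariant: sum over m of m * h(m) equals the table's total abundance.
    """
    if table.total_distinct == 0:
        return KmerHistogram(table.spec, np.zeros(1, dtype=np.int64))
    dense = np.bincount(table.counts)
    return KmerHistogram(table.spec, dense.astype(np.int64))
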