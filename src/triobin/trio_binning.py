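"""Parent-unique marker derivation and F1 long-read binning.

A marker (hap-mer) is a canonical k-mer present in exactly one parent's
read set: it must reach ``min_count`` occurrences in its own parent and
be entirely absent from the other.  Markers containing homopentamer
runs (>=5 identical bases) are optionally removed, since nanopore reads
systematically shorten homopolymers and such markers would misfire.

Reads are classified by a strict majority of marker hits: the bin is
the parent with strictly more marker windows; a tie (including 0-0)
goes to the ``unknown`` bin.  No density normalisation is applied; an
optional minimum-hit threshold is exposed for sensitivity analysis.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from . import _codec, io
from .errors import ConfigurationError
from .kmer_core import KmerCountTable, KmerSpec

PARENT_A = "parent_a"
PARENT_B = "parent_b"
UNKNOWN = "unknown"
BINS = (PARENT_A, PARENT_B, UNKNOWN)

#: default homopolymer run length that disqualifies a marker
DEFAULT_MAX_RUN = 5


class MarkerSet:
    """A parent's hap-mer set, stored as sorted packed codes."""

    def __init__(
        self,
        parent_label: str,
        spec: KmerSpec,
        codes: np.ndarray,
        min_count_used: int = 1,
        homopolymer_filtered: bool = False,
    ):
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size and not np.all(codes[1:] > codes[:-1]):
            codes = np.unique(codes)
        self.parent_label = parent_label
        self.spec = spec
        self.codes = codes
        self.min_count_used = min_count_used
        self.homopolymer_filtered = homopolymer_filtered

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str | int) -> bool:
        code = _codec.encode_kmer(kmer) if isinstance(kmer, str) else int(kmer)
        if isinstance(kmer, str) and self.spec.canonical:
            code = min(code, _codec.revcomp_code(code, self.spec.k))
        i = np.searchsorted(self.codes, np.uint64(code))
        return bool(i < self.codes.size and self.codes[i] == code)

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership test for an array of packed codes."""
        codes = np.asarray(codes, dtype=np.uint64)
        if self.codes.size == 0:
            return np.zeros(codes.size, dtype=bool)
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.minimum(idx, self.codes.size - 1)
        return self.codes[idx_c] == codes

    def members(self) -> Iterator[str]:
        for code in self.codes.tolist():
            yield _codec.decode_kmer(code, self.spec.k)

    def to_tsv(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            fh.write(
                f"#k={self.spec.k}\tcanonical={int(self.spec.canonical)}"
                f"\tlabel={self.parent_label}\tmin_count={self.min_count_used}"
                f"\thomopolymer_filtered={int(self.homopolymer_filtered)}\n"
            )
            for kmer in self.members():
                fh.write(kmer + "\n")

    @classmethod
    def from_tsv(cls, path: io.PathLike) -> "MarkerSet":
        kmers: list[int] = []
        spec, label, min_count, filtered = None, "", 1, False
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
                        min_count = int(fields.get("min_count", "1"))
                        filtered = bool(int(fields.get("homopolymer_filtered", "0")))
                    continue
                kmers.append(_codec.encode_kmer(line.split("\t")[0]))
        if spec is None:
            raise ValueError(f"marker TSV missing header: {path}")
        return cls(label, spec, np.array(kmers, dtype=np.uint64), min_count, filtered)


def derive_unique_markers(
    table_a: KmerCountTable,
    table_b: KmerCountTable,
    min_count: int = 1,
    label_a: str = PARENT_A,
    label_b: str = PARENT_B,
) -> tuple[MarkerSet, MarkerSet]:
    """Parent-unique k-mers: count >= min_count in one parent, absent in the other.

    The returned sets are disjoint by construction.
    """
    if table_a.spec != table_b.spec:
        raise ConfigurationError(
            f"parental tables disagree on k-mer spec: {table_a.spec} vs {table_b.spec}"
        )
    strong_a = table_a.kmers_with_count_at_least(min_count)
    strong_b = table_b.kmers_with_count_at_least(min_count)
    only_a = strong_a[~_isin_sorted(strong_a, table_b.kmers)]
    only_b = strong_b[~_isin_sorted(strong_b, table_a.kmers)]
    return (
        MarkerSet(label_a, table_a.spec, only_a, min_count),
        MarkerSet(label_b, table_b.spec, only_b, min_count),
    )


def _isin_sorted(values: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    if sorted_ref.size == 0:
        return np.zeros(values.size, dtype=bool)
    idx = np.minimum(np.searchsorted(sorted_ref, values), sorted_ref.size - 1)
    return sorted_ref[idx] == values


def filter_homopolymer_markers(markers: MarkerSet, max_run: int = DEFAULT_MAX_RUN) -> MarkerSet:
    """Drop markers containing a run of >= max_run identical bases."""
    if max_run < 2:
        raise ConfigurationError(f"max_run must be >= 2, got {max_run}")
    k = markers.spec.k
    if markers.codes.size == 0 or max_run > k:
        keep = markers.codes
    else:
        bases = _codec.codes_to_base_matrix(markers.codes, k)
        eq = bases[:, 1:] == bases[:, :-1]
        # run of max_run equal bases == max_run-1 consecutive equal-neighbour flags
        w = max_run - 1
        cs = np.concatenate([np.zeros((eq.shape[0], 1), np.int32), np.cumsum(eq, axis=1, dtype=np.int32)], axis=1)
        has_run = ((cs[:, w:] - cs[:, :-w]) == w).any(axis=1)
        keep = markers.codes[~has_run]
    return MarkerSet(
        markers.parent_label, markers.spec, keep, markers.min_count_used, homopolymer_filtered=True
    )


@dataclass
class ReadClassification:
    """Per-read bin decision with the marker-hit evidence behind it."""

    read_id: str
    read_length: int
    hits_a: int
    hits_b: int
    bin: str

    def __post_init__(self) -> None:
        if self.bin not in BINS:
            raise ValueError(f"bin must be one of {BINS}")


def classify_read(
    read,
    markers_a: MarkerSet,
    markers_b: MarkerSet,
    min_hits: int = 0,
) -> ReadClassification:
    """Assign one read by strict majority of marker-window hits.

    ``read`` is a SeqRecord or ``(id, seq)`` tuple.  A tie — including
    zero hits on both sides — or a winning count below ``min_hits``
    yields ``unknown``.  Reads shorter than k are unknown with 0 hits.
    """
    if hasattr(read, "seq"):
        rid, seq = read.id, str(read.seq)
    else:
        rid, seq = read
    spec = markers_a.spec
    codes, _ = _codec.window_codes(seq, spec.k, spec.canonical)
    hits_a = int(markers_a.contains_codes(codes).sum())
    hits_b = int(markers_b.contains_codes(codes).sum())
    if hits_a > hits_b and hits_a >= min_hits:
        decision = PARENT_A
    elif hits_b > hits_a and hits_b >= min_hits:
        decision = PARENT_B
    else:
        decision = UNKNOWN
    return ReadClassification(rid, len(seq), hits_a, hits_b, decision)


@dataclass
class BinStats:
    read_count: int = 0
    base_total: int = 0
    base_fraction: float = 0.0
    n50: int | None = None


@dataclass
class BinningSummary:
    """Aggregate accounting over the three bins.

    Base fractions sum to 1 and per-bin totals sum to the input totals;
    both invariants are checked at construction.
    """

    per_bin: dict[str, BinStats] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(s.read_count for s in self.per_bin.values())

    @property
    def total_bases(self) -> int:
        return sum(s.base_total for s in self.per_bin.values())

    def fraction_pct(self, bin_name: str, ndigits: int = 1) -> float:
        """Base fraction of a bin as a percentage, rounded for reporting."""
        return round(100.0 * self.per_bin[bin_name].base_fraction, ndigits)

    @classmethod
    def from_totals(
        cls, bases_by_bin: dict[str, int], reads_by_bin: dict[str, int] | None = None
    ) -> "BinningSummary":
        """Build a summary from per-bin base totals alone (N50 unknown)."""
        total = sum(bases_by_bin.values())
        per_bin = {}
        for name in BINS:
            bases = bases_by_bin.get(name, 0)
            per_bin[name] = BinStats(
                read_count=(reads_by_bin or {}).get(name, 0),
                base_total=bases,
                base_fraction=bases / total if total else 0.0,
            )
        return cls(per_bin)

    def to_tsv(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            fh.write("bin\treads\tbases\tfraction_pct\tn50\n")
            for name in BINS:
                s = self.per_bin.get(name, BinStats())
                n50 = "" if s.n50 is None else s.n50
                fh.write(f"{name}\t{s.read_count}\t{s.base_total}\t{self.fraction_pct(name)}\t{n50}\n")


def read_length_n50(lengths: Iterable[int]) -> int | None:
    """Smallest length L such that reads >= L hold >= 50% of the bases."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0 or arr.sum() == 0:
        return None
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, arr.size - 1)])


def summarize_bins(classifications: Iterable[ReadClassification]) -> BinningSummary:
    """Aggregate read counts, base totals, base fractions, and per-bin N50."""
    lengths: dict[str, list[int]] = {name: [] for name in BINS}
    for c in classifications:
        lengths[c.bin].append(c.read_length)
    total = sum(sum(v) for v in lengths.values())
    per_bin = {}
    for name in BINS:
        bases = sum(lengths[name])
        per_bin[name] = BinStats(
            read_count=len(lengths[name]),
            base_total=bases,
            base_fraction=bases / total if total else 0.0,
            n50=read_length_n50(lengths[name]),
        )
    return BinningSummary(per_bin)


def classify_readset(
    reads,
    markers_a: MarkerSet,
    markers_b: MarkerSet,
    out_dir: io.PathLike | None = None,
    min_hits: int = 0,
    min_read_length: int = 0,
) -> tuple[BinningSummary, list[ReadClassification]]:
    """Classify a read set, optionally writing the three FASTQ bins.

    Record order is preserved within each bin.  ``min_read_length``
    (default off) drops shorter reads from the *written* bins only —
    the returned accounting still covers every input read.  Returns
    ``(summary, per-read classifications)``.
    """
    handles = {}
    writers_open = out_dir is not None
    if writers_open:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handles = {name: open(out_dir / f"{name}.fastq", "w") for name in BINS}
    results: list[ReadClassification] = []
    try:
        from Bio import SeqIO

        for rec in io.iter_records(reads):
            c = classify_read(rec, markers_a, markers_b, min_hits=min_hits)
            results.append(c)
            if writers_open and c.read_length >= min_read_length:
                if "phred_quality" not in rec.letter_annotations:
                    rec.letter_annotations["phred_quality"] = [40] * len(rec.seq)
                SeqIO.write(rec, handles[c.bin], "fastq")
    finally:
        for fh in handles.values():
            fh.close()
    summary = summarize_bins(results)
    if writers_open:
        summary.to_tsv(Path(out_dir) / "bin_summary.tsv")
        with open(Path(out_dir) / "per_read.tsv", "w") as fh:
            fh.write("read_id\tlength\thits_a\thits_b\tbin\n")
            for c in results:
                fh.write(f"{c.read_id}\t{c.read_length}\t{c.hits_a}\t{c.hits_b}\t{c.bin}\n")
    return summary, results
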