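"""Merqury/yak-style evaluation of phased assemblies.

Four families of metrics, all k-mer based and alignment-free:

* **hap-mer profiles** — per-contig counts of each parent's marker
  k-mers, the raw material of a blob plot (x = parent-A hap-mers,
  y = parent-B hap-mers, point size = contig length);
* **phasing** — switch rate (adjacent marker occurrences from different
  parents, normalised by informative adjacencies) and hamming rate
  (wrong-parent markers over all markers);
* **consensus quality** — the fraction of assembly k-mers unsupported
  by a trusted read k-mer set converts to a per-base error rate
  ``E = 1 - (1 - X/N)^(1/k)`` and a Phred ``QV = -10*log10(E)``;
* **HERS** — high-error-rate subsequences: maximal runs of basespace
  covered by no window whose canonical k-mer is trusted, emitted as
  0-based half-open BED intervals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _codec, io
from .errors import ConfigurationError, UndefinedMetricError
from .kmer_core import KmerCountTable
from .trio_binning import MarkerSet

#: Phred value reported when no unsupported k-mer is found
DEFAULT_QV_CAP = 99.0


@dataclass
class ContigHapmers:
    contig_id: str
    length: int
    hapmers_a: int
    hapmers_b: int


@dataclass
class HapmerProfile:
    contigs: list[ContigHapmers] = field(default_factory=list)

    def to_tsv(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            fh.write("contig\tlength\thapmers_a\thapmers_b\n")
            for c in self.contigs:
                fh.write(f"{c.contig_id}\t{c.length}\t{c.hapmers_a}\t{c.hapmers_b}\n")


@dataclass
class PhasingReport:
    """Switch/hamming rates plus optional completeness and contamination."""

    switch_rate: float | None
    hamming_rate: float | None
    markers_observed: int
    switches: int
    contigs_with_markers: int
    undefined: bool = False
    completeness: float | None = None
    other_parent_fraction: float | None = None


@dataclass
class QvReport:
    total_kmers: int
    unsupported_kmers: int
    error_rate: float
    qv: float
    qv_cap: float = DEFAULT_QV_CAP
    perfect: bool = False


@dataclass
class HersRegions:
    """Sorted, disjoint unverified intervals (0-based half-open BED)."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    @property
    def interval_count(self) -> int:
        return len(self.intervals)

    def to_bed(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            for chrom, s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def _check_marker_pair(markers_a: MarkerSet, markers_b: MarkerSet) -> None:
    if markers_a.spec != markers_b.spec:
        raise ConfigurationError("marker sets disagree on k-mer spec")


def hapmer_profile(contigs, markers_a: MarkerSet, markers_b: MarkerSet) -> HapmerProfile:
    """Per-contig marker-window counts for each parent."""
    _check_marker_pair(markers_a, markers_b)
    spec = markers_a.spec
    profile = HapmerProfile()
    for rec in io.iter_records(contigs):
        codes, _ = _codec.window_codes(str(rec.seq), spec.k, spec.canonical)
        profile.contigs.append(
            ContigHapmers(
                rec.id,
                len(rec.seq),
                int(markers_a.contains_codes(codes).sum()),
                int(markers_b.contains_codes(codes).sum()),
            )
        )
    return profile


def phase_metrics(
    contigs,
    markers_expected: MarkerSet,
    markers_other: MarkerSet,
    block_tolerance: int = 1,
) -> PhasingReport:
    """Switch and hamming rates of an assembly against its expected parent.

    Marker occurrences are scanned in positional order along each
    contig; a switch is an adjacent pair of occurrences from different
    parents, and the rate divides switches by informative adjacencies
    (markers observed minus contigs carrying at least one marker).
    ``block_tolerance`` > 1 requires that many consecutive discordant
    markers before a parent change is believed (Merqury-like smoothing);
    the default 1 is the plain adjacent-pair definition.

    An assembly with zero marker occurrences yields an ``undefined``
    report with rates ``None`` rather than a silent 0.
    """
    _check_marker_pair(markers_expected, markers_other)
    spec = markers_expected.spec
    switches = 0
    observed = 0
    wrong = 0
    contigs_with = 0
    for rec in io.iter_records(contigs):
        codes, _ = _codec.window_codes(str(rec.seq), spec.k, spec.canonical)
        in_exp = markers_expected.contains_codes(codes)
        in_oth = markers_other.contains_codes(codes)
        any_marker = in_exp | in_oth
        labels = np.where(in_exp[any_marker], 0, 1)  # positional order preserved
        if labels.size == 0:
            continue
        contigs_with += 1
        observed += labels.size
        wrong += int((labels == 1).sum())
        if block_tolerance > 1:
            labels = _smooth_blocks(labels, block_tolerance)
        switches += int(np.count_nonzero(labels[1:] != labels[:-1]))
    if observed == 0:
        return PhasingReport(None, None, 0, 0, 0, undefined=True)
    adjacencies = observed - contigs_with
    switch_rate = switches / adjacencies if adjacencies > 0 else 0.0
    return PhasingReport(
        switch_rate=switch_rate,
        hamming_rate=wrong / observed,
        markers_observed=observed,
        switches=switches,
        contigs_with_markers=contigs_with,
    )


def _smooth_blocks(labels: np.ndarray, tolerance: int) -> np.ndarray:
    """Suppress discordant runs shorter than ``tolerance`` markers."""
    out = labels.copy()
    current = out[0]
    i = 1
    while i < out.size:
        if out[i] != current:
            j = i
            while j < out.size and out[j] == out[i]:
                j += 1
            if j - i < tolerance:
                out[i:j] = current
            else:
                current = out[i]
            i = j
        else:
            i += 1
    return out


def kmer_completeness(
    reliable_read_kmers: KmerCountTable,
    assembly_kmers: KmerCountTable,
    error_cutoff: int = 1,
) -> float:
    """Fraction of reliable (count >= cutoff) read k-mers present in the assembly."""
    if reliable_read_kmers.spec.k != assembly_kmers.spec.k:
        raise ConfigurationError("read and assembly tables disagree on k")
    reliable = reliable_read_kmers.kmers_with_count_at_least(error_cutoff)
    if reliable.size == 0:
        raise UndefinedMetricError("no reliable read k-mers above the error cutoff")
    found = assembly_kmers.member_mask(reliable).sum()
    return float(found / reliable.size)


def other_parent_fraction(assembly_kmers: KmerCountTable, other_markers: MarkerSet) -> float:
    """Fraction of distinct assembly k-mers that are the *other* parent's markers."""
    if assembly_kmers.spec.k != other_markers.spec.k:
        raise ConfigurationError("assembly table and markers disagree on k")
    if assembly_kmers.total_distinct == 0:
        return 0.0
    hits = other_markers.contains_codes(assembly_kmers.kmers).sum()
    return float(hits / assembly_kmers.total_distinct)


def estimate_qv(
    query_sequences,
    trusted_kmers: KmerCountTable,
    error_cutoff: int = 1,
    qv_cap: float = DEFAULT_QV_CAP,
) -> QvReport:
    """Consensus QV of query sequence against a trusted k-mer set.

    A query window is unsupported when its canonical k-mer is absent
    from the trusted set (entries below ``error_cutoff`` count as
    absent).  With X unsupported of N windows, the per-base error rate
    is ``E = 1 - (1 - X/N)^(1/k)`` and ``QV = -10*log10(E)``; X = 0 is
    reported as ``qv_cap`` with the perfect flag set.
    """
    spec = trusted_kmers.spec
    trusted = trusted_kmers.kmers_with_count_at_least(error_cutoff)
    total = 0
    unsupported = 0
    for rec in io.iter_records(query_sequences):
        codes, _ = _codec.window_codes(str(rec.seq), spec.k, spec.canonical)
        total += codes.size
        if codes.size and trusted.size:
            idx = np.minimum(np.searchsorted(trusted, codes), trusted.size - 1)
            unsupported += int((trusted[idx] != codes).sum())
        else:
            unsupported += int(codes.size)
    if total == 0:
        raise UndefinedMetricError("no valid query k-mer windows; QV undefined")
    if unsupported == 0:
        return QvReport(total, 0, 0.0, qv_cap, qv_cap, perfect=True)
    error_rate = 1.0 - (1.0 - unsupported / total) ** (1.0 / spec.k)
    return QvReport(total, unsupported, error_rate, -10.0 * math.log10(error_rate), qv_cap)


def precision_from_qv(qv: float) -> float:
    """Phred QV -> base-level precision percent, 100*(1 - 10^(-qv/10))."""
    if qv <= 0:
        raise ConfigurationError("qv must be positive")
    return round(100.0 * (1.0 - 10.0 ** (-qv / 10.0)), 2)


def find_hers(
    contigs,
    trusted_kmers: KmerCountTable,
    error_cutoff: int = 1,
) -> HersRegions:
    """High-error-rate subsequences: basespace no trusted k-mer window covers.

    A position is verified iff at least one window containing it has a
    trusted canonical k-mer; maximal unverified runs become intervals.
    Contigs shorter than k are entirely unverifiable and emitted whole.
    """
    spec = trusted_kmers.spec
    k = spec.k
    trusted = trusted_kmers.kmers_with_count_at_least(error_cutoff)
    regions = HersRegions()
    for rec in io.iter_records(contigs):
        L = len(rec.seq)
        if L < k:
            regions.intervals.append((rec.id, 0, L))
            continue
        codes, starts = _codec.window_codes(str(rec.seq), k, spec.canonical)
        if codes.size and trusted.size:
            idx = np.minimum(np.searchsorted(trusted, codes), trusted.size - 1)
            good = starts[trusted[idx] == codes]
        else:
            good = np.empty(0, np.int64)
        cov = np.zeros(L + 1, dtype=np.int32)
        np.add.at(cov, good, 1)
        np.add.at(cov, good + k, -1)
        verified = np.cumsum(cov[:L]) > 0
        # maximal runs of unverified positions
        edges = np.flatnonzero(np.diff(np.concatenate(([0], (~verified).astype(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            regions.intervals.append((rec.id, int(s), int(e)))
    regions.intervals.sort()
    return regions


def write_metrics_tsv(path: io.PathLike, report: PhasingReport, qv: QvReport | None = None) -> None:
    """Flat TSV dump of a phasing report (and optional QV report)."""
    rows: list[tuple[str, object]] = [
        ("switch_rate", report.switch_rate),
        ("hamming_rate", report.hamming_rate),
        ("markers_observed", report.markers_observed),
        ("switches", report.switches),
        ("undefined", int(report.undefined)),
        ("completeness", report.completeness),
        ("other_parent_fraction", report.other_parent_fraction),
    ]
    if qv is not None:
        rows += [
            ("qv", qv.qv),
            ("error_rate", qv.error_rate),
            ("total_kmers", qv.total_kmers),
            ("unsupported_kmers", qv.unsupported_kmers),
            ("perfect", int(qv.perfect)),
        ]
    with io.open_text(path, "wt") as fh:
        fh.write("metric\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{'' if value is None else value}\n")
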