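"""Interval utilities and gene-cluster calling for TPS / NLR loci.

Cluster rules implemented:

* **MTC** (major terpene cluster): >= 4 terpene-synthase genes with
  each consecutive inter-gene gap <= 2 Mb;
* **MRC** (major resistance cluster): >= 5 NLR genes at a density of
  at least one per 2 Mb over the cluster span.

Chaining is single-linkage on consecutive end-to-start gaps (abutting
or overlapping genes have gap 0), so cluster spans may greatly exceed
the gap limit — as real multi-Mb resistance clusters do.

Also here: merging of overlapping BLAST-hit intervals into putative
loci, and the two-callset verification step that keeps full-length
predictions overlapping at least one verifying hit.

All internal coordinates are 0-based half-open; GFF3 (1-based
inclusive) is converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from . import io
from .errors import UndefinedMetricError

MB = 1_000_000

#: preset cluster rules
MTC_RULE = {"min_members": 4, "max_gap": 2 * MB, "min_density": None}
MRC_RULE = {"min_members": 5, "max_gap": 2 * MB, "min_density": 1.0 / (2 * MB)}


@dataclass(frozen=True)
class GeneLocus:
    chrom: str
    start: int
    end: int
    strand: str = "."
    locus_id: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.locus_id!r}: [{self.start}, {self.end})")


@dataclass
class GeneCluster:
    chrom: str
    start: int
    end: int
    member_ids: list[str]

    @property
    def member_count(self) -> int:
        return len(self.member_ids)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def density_per_mb(self) -> float:
        return self.member_count / (self.span / MB) if self.span > 0 else float("inf")


@dataclass
class ClusterReport:
    clusters: list[GeneCluster] = field(default_factory=list)
    total_genes: int = 0

    @property
    def clustered_genes(self) -> int:
        return sum(c.member_count for c in self.clusters)

    @property
    def clustered_fraction(self) -> float | None:
        if self.total_genes == 0:
            return None
        return cluster_fraction(self.clustered_genes, self.total_genes)

    def to_tsv(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            fh.write("chrom\tstart\tstop\tmembers\tcontent\n")
            for c in self.clusters:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.member_count}\t{','.join(c.member_ids)}\n")

    def to_bed(self, path: io.PathLike) -> None:
        with io.open_text(path, "wt") as fh:
            for i, c in enumerate(self.clusters, 1):
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tcluster{i}_n{c.member_count}\n")


Interval = tuple[str, int, int]


def _validate(intervals: Iterable[Interval]) -> list[Interval]:
    out = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if start >= end:
            raise ValueError(f"malformed interval {iv!r} (start >= end)")
        out.append((chrom, start, end))
    return out


def merge_overlaps(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of overlapping or bookended intervals, per chromosome.

    Output sorted and disjoint; total covered bases are preserved.
    """
    by_chrom: dict[str, IntervalTree] = {}
    for chrom, start, end in _validate(intervals):
        by_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        tree = by_chrom[chrom]
        tree.merge_overlaps(strict=False)  # strict=False also merges bookended
        out.extend((chrom, iv.begin, iv.end) for iv in sorted(tree))
    return out


def intersect_callsets(
    predictions: Iterable[Interval],
    verifying_hits: Iterable[Interval],
    min_overlap: int = 1,
) -> list[Interval]:
    """Keep predictions with >= min_overlap bases of overlap with any hit.

    Predictions are returned whole, never clipped — the verifying set
    only gates membership.
    """
    preds = _validate(predictions)
    hits_by_chrom: dict[str, IntervalTree] = {}
    for chrom, start, end in _validate(verifying_hits):
        hits_by_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = []
    for chrom, start, end in sorted(preds):
        tree = hits_by_chrom.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(start, end):
            if min(end, hit.end) - max(start, hit.begin) >= min_overlap:
                kept.append((chrom, start, end))
                break
    return kept


def call_clusters(
    loci: Sequence[GeneLocus],
    min_members: int,
    max_gap: int,
    min_density: float | None = None,
) -> ClusterReport:
    """Chain loci into clusters and report the clustered fraction.

    Loci are sorted per chromosome by start; consecutive loci join a
    chain while the end-to-start gap (floored at 0) is <= ``max_gap``.
    Chains with >= ``min_members`` and, when given, density >=
    ``min_density`` (members per base of span) become clusters.  Each
    locus belongs to at most one cluster; results are independent of
    input order.
    """
    report = ClusterReport(total_genes=len(loci))
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.locus_id))
        chain: list[GeneLocus] = []
        for g in genes:
            if chain and max(g.start - chain[-1].end, 0) <= max_gap:
                chain.append(g)
            else:
                _flush_chain(chain, min_members, min_density, report)
                chain = [g]
        _flush_chain(chain, min_members, min_density, report)
    report.clusters.sort(key=lambda c: (c.chrom, c.start))
    return report


def _flush_chain(
    chain: list[GeneLocus],
    min_members: int,
    min_density: float | None,
    report: ClusterReport,
) -> None:
    if len(chain) < min_members:
        return
    start = min(g.start for g in chain)
    end = max(g.end for g in chain)
    cluster = GeneCluster(chain[0].chrom, start, end, [g.locus_id for g in chain])
    if min_density is not None and cluster.span > 0:
        if cluster.member_count / cluster.span < min_density:
            return
    report.clusters.append(cluster)


def cluster_fraction(clustered: int, total: int) -> float:
    """Percent of genes found in clusters, to one decimal."""
    if total <= 0:
        raise UndefinedMetricError("total gene count is zero; fraction undefined")
    if not (0 <= clustered <= total):
        raise ValueError("clustered count must lie in [0, total]")
    return round(100.0 * clustered / total, 1)


# -- GFF3 / BED I/O ----------------------------------------------------

def read_gff_loci(
    path: io.PathLike,
    feature_types: tuple[str, ...] = ("gene",),
    category_attr: str = "category",
) -> list[GeneLocus]:
    """Read gene features from GFF3 (1-based inclusive -> half-open)."""
    loci = []
    with io.open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            loci.append(
                GeneLocus(
                    chrom=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    locus_id=attrs.get("ID", ""),
                    category=attrs.get(category_attr, ""),
                )
            )
    return loci


def read_bed_intervals(path: io.PathLike) -> list[Interval]:
    out = []
    with io.open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            out.append((cols[0], int(cols[1]), int(cols[2])))
    return _validate(out)


def write_gff_loci(loci: Iterable[GeneLocus], path: io.PathLike, source: str = "triobin") -> None:
    with io.open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            attrs = f"ID={g.locus_id}"
            if g.category:
                attrs += f";category={g.category}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
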