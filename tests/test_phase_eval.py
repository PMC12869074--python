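"""Hap-mer profiles, switch/hamming rates, completeness, QV, and HERS tests."""
import math

import numpy as np
import pytest

import bruteforce as bf
from conftest import random_dna
from triobin import kmer_core, phase_eval
from triobin.errors import UndefinedMetricError
from triobin.kmer_core import KmerCountTable, KmerSpec, count_kmers
from triobin.phase_eval import (
    estimate_qv,
    find_hers,
    hapmer_profile,
    kmer_completeness,
    other_parent_fraction,
    phase_metrics,
    precision_from_qv,
)


class TestHapmerProfile:
    def test_parent_a_segment_has_no_b_hapmers(self, small_trio, small_trio_markers):
        _, hap_a, _, _, _, _ = small_trio
        ma, mb = small_trio_markers
        prof = hapmer_profile([("c1", hap_a[:20_000])], ma, mb)
        c = prof.contigs[0]
        assert c.hapmers_b == 0 and c.hapmers_a > 0
        assert c.hapmers_a <= c.length - 21 + 1  # bounded by window count

    def test_markerless_contig(self, small_trio_markers, rng):
        ma, mb = small_trio_markers
        prof = hapmer_profile([("c1", "ACGT" * 30)], ma, mb)
        assert (prof.contigs[0].hapmers_a, prof.contigs[0].hapmers_b) == (0, 0)

    def test_counts_match_bruteforce_lookup(self, small_trio, small_trio_markers):
        _, hap_a, hap_b, _, _, _ = small_trio
        ma, mb = small_trio_markers
        set_a, set_b = set(ma.members()), set(mb.members())
        contigs = [("a", hap_a[:3_000]), ("b", hap_b[10_000:13_000])]
        prof = hapmer_profile(contigs, ma, mb)
        for (cid, seq), c in zip(contigs, prof.contigs):
            assert c.hapmers_a == bf.marker_hits(seq, set_a, 21)
            assert c.hapmers_b == bf.marker_hits(seq, set_b, 21)

    def test_empty_assembly(self, small_trio_markers):
        ma, mb = small_trio_markers
        assert hapmer_profile([], ma, mb).contigs == []


def _marker_sets_from_kmers(k, kmers_a, kmers_b):
    from triobin import _codec
    from triobin.trio_binning import MarkerSet

    spec = KmerSpec(k)
    ca = sorted({_codec.encode_kmer(bf.canonical(x)) for x in kmers_a})
    cb = sorted({_codec.encode_kmer(bf.canonical(x)) for x in kmers_b})
    return (
        MarkerSet("parent_a", spec, np.array(ca, dtype=np.uint64)),
        MarkerSet("parent_b", spec, np.array(cb, dtype=np.uint64)),
    )


class TestPhaseMetrics:
    def test_pure_contig_has_zero_rates(self, small_trio, small_trio_markers):
        _, hap_a, _, _, _, _ = small_trio
        ma, mb = small_trio_markers
        rep = phase_metrics([("c", hap_a)], ma, mb)
        assert rep.switch_rate == 0.0 and rep.hamming_rate == 0.0
        assert rep.markers_observed > 0

    def test_strict_alternation_gives_rate_one(self):
        # contig whose marker occurrences alternate parents at every step
        ma, mb = _marker_sets_from_kmers(5, ["ACACA"], ["AGAGA"])
        contig = "ACACATTAGAGATTACACATTAGAGATT"
        rep = phase_metrics([("c", contig)], ma, mb)
        assert rep.markers_observed == 4
        assert rep.switch_rate == 1.0

    def test_planted_other_parent_block(self, small_trio, small_trio_markers):
        # one B-block inside an A contig: exactly 2 switches, hamming = m/n
        _, hap_a, hap_b, _, _, _ = small_trio
        ma, mb = small_trio_markers
        contig = hap_a[:40_000] + hap_b[45_000:55_000] + hap_a[60_000:100_000]
        rep = phase_metrics([("c", contig)], ma, mb)
        assert rep.switches == 2
        # enumeration oracle over positional marker labels
        set_a, set_b = set(ma.members()), set(mb.members())
        labels = []
        for i in range(len(contig) - 20):
            w = bf.canonical(contig[i : i + 21])
            if w in set_a:
                labels.append("a")
            elif w in set_b:
                labels.append("b")
        oracle_switches = sum(1 for x, y in zip(labels, labels[1:]) if x != y)
        assert rep.switches == oracle_switches
        assert rep.hamming_rate == pytest.approx(labels.count("b") / len(labels))
        assert rep.markers_observed == len(labels)

    def test_zero_marker_assembly_flagged(self, small_trio_markers):
        ma, mb = small_trio_markers
        rep = phase_metrics([("c", "ACGT" * 20)], ma, mb)
        assert rep.undefined and rep.switch_rate is None

    def test_block_tolerance_smooths_single_stray(self):
        ma, mb = _marker_sets_from_kmers(5, ["ACACA"], ["AGAGA"])
        contig = "ACACATTAGAGATTACACATT"  # a, b, a
        strict = phase_metrics([("c", contig)], ma, mb)
        smooth = phase_metrics([("c", contig)], ma, mb, block_tolerance=2)
        assert strict.switches == 2 and smooth.switches == 0

    def test_switch_invariant_under_reverse_complement(self, small_trio, small_trio_markers):
        _, hap_a, hap_b, _, _, _ = small_trio
        ma, mb = small_trio_markers
        contig = hap_a[:30_000] + hap_b[40_000:50_000] + hap_a[55_000:80_000]
        fwd = phase_metrics([("c", contig)], ma, mb)
        rev = phase_metrics([("c", bf.revcomp(contig))], ma, mb)
        assert fwd.switches == rev.switches
        assert fwd.markers_observed == rev.markers_observed


class TestCompleteness:
    def test_full_and_empty(self, small_trio):
        _, hap_a, _, _, _, _ = small_trio
        spec = KmerSpec(21)
        reads = count_kmers([hap_a], spec)
        assert kmer_completeness(reads, count_kmers([hap_a], spec)) == 1.0
        other = count_kmers([random_dna(np.random.default_rng(0), 50_000)], spec)
        assert kmer_completeness(reads, other) < 0.01

    def test_five_percent_deletion(self, small_trio):
        _, hap_a, _, _, _, _ = small_trio
        spec = KmerSpec(21)
        reads = count_kmers([hap_a], spec)
        rng = np.random.default_rng(9)
        keep = rng.random(reads.kmers.size) >= 0.05
        assembly = KmerCountTable(spec, reads.kmers[keep], reads.counts[keep])
        expected = keep.sum() / reads.kmers.size
        assert kmer_completeness(reads, assembly) == pytest.approx(expected, abs=1e-12)

    def test_no_reliable_kmers_flagged(self):
        spec = KmerSpec(5)
        reads = KmerCountTable.from_dict(spec, {"AACCA": 1})
        with pytest.raises(UndefinedMetricError):
            kmer_completeness(reads, reads, error_cutoff=10)


class TestOtherParentFraction:
    def test_correct_haplotype_is_zero(self, small_trio, small_trio_markers):
        _, hap_a, _, _, _, _ = small_trio
        _, mb = small_trio_markers
        assembly = count_kmers([hap_a], KmerSpec(21))
        assert other_parent_fraction(assembly, mb) == 0.0

    def test_other_genome_matches_direct_computation(self, small_trio, small_trio_markers):
        _, _, hap_b, _, _, _ = small_trio
        _, mb = small_trio_markers
        assembly = count_kmers([hap_b], KmerSpec(21))
        hits = mb.contains_codes(assembly.kmers).sum()
        assert other_parent_fraction(assembly, mb) == pytest.approx(hits / assembly.total_distinct)
        assert other_parent_fraction(assembly, mb) > 0

    def test_monotone_in_contamination(self, small_trio, small_trio_markers):
        _, hap_a, hap_b, _, _, _ = small_trio
        _, mb = small_trio_markers
        fracs = []
        for x in (0, 10_000, 30_000):
            assembly = count_kmers([hap_a[: 60_000 - x] + hap_b[60_000 - x : 60_000]], KmerSpec(21))
            fracs.append(other_parent_fraction(assembly, mb))
        assert fracs[0] <= fracs[1] <= fracs[2]


class TestEstimateQv:
    def test_perfect_query_capped_and_flagged(self, small_trio):
        _, hap_a, _, _, _, _ = small_trio
        trusted = count_kmers([hap_a], KmerSpec(21))
        rep = estimate_qv([hap_a[:10_000]], trusted)
        assert rep.perfect and rep.qv == rep.qv_cap

    def test_closed_form(self):
        # N=1000, X=50, k=21: recompute E and QV directly
        k, N, X = 21, 1000, 50
        E = 1 - (1 - X / N) ** (1 / k)
        seq = random_dna(np.random.default_rng(4), N + k - 1)
        trusted = count_kmers([seq], KmerSpec(k))
        rep = estimate_qv([seq], trusted)  # all supported
        assert rep.total_kmers == N
        # synthetic report arithmetic against the formula
        import triobin.phase_eval as pe

        assert pytest.approx(-10 * math.log10(E)) == -10 * math.log10(
            1 - (1 - X / N) ** (1 / k)
        )

    def test_single_substitution_unsupports_k_windows(self, rng):
        k = 21
        seq = random_dna(rng, 2_000)
        trusted = count_kmers([seq], KmerSpec(k))
        pos = 1_000
        base = "A" if seq[pos] != "A" else "C"
        mutated = seq[:pos] + base + seq[pos + 1 :]
        rep = estimate_qv([mutated], trusted)
        total, bad = bf.unsupported_windows(mutated, set(m for m, _ in trusted.items()), k)
        assert rep.unsupported_kmers == bad
        assert rep.total_kmers == total
        # all k windows covering the error are unsupported (no chance rescue here)
        assert rep.unsupported_kmers == k
        # E approximates the per-base error rate 1/2000
        assert rep.error_rate == pytest.approx(1 / 2_000, rel=0.05)

    def test_qv_strictly_decreasing_in_unsupported_count(self):
        k, N = 21, 10_000
        qvs = []
        for X in (1, 10, 100, 1000):
            E = 1 - (1 - X / N) ** (1 / k)
            qvs.append(-10 * math.log10(E))
        assert all(a > b for a, b in zip(qvs, qvs[1:]))

    def test_error_cutoff_discards_weak_support(self, rng):
        k = 21
        seq = random_dna(rng, 500)
        trusted = count_kmers([seq], KmerSpec(k))  # all counts == 1 (repeats aside)
        rep = estimate_qv([seq], trusted, error_cutoff=2)
        assert rep.unsupported_kmers > 0  # singletons no longer trusted


class TestPrecisionFromQv:
    @pytest.mark.parametrize(
        "qv,expected",
        [(24.42, 99.64), (24.35, 99.63), (10.0, 90.00)],
    )
    def test_examples(self, qv, expected):
        assert precision_from_qv(qv) == expected

    def test_roundtrip_with_qv_formula(self):
        E = 0.0036
        qv = -10 * math.log10(E)
        assert precision_from_qv(qv) == pytest.approx(100 * (1 - E), abs=0.005)


class TestFindHers:
    def test_error_free_assembly_has_no_intervals(self, small_trio):
        _, hap_a, _, _, _, _ = small_trio
        trusted = count_kmers([hap_a], KmerSpec(21))
        regions = find_hers([("c", hap_a)], trusted)
        assert regions.interval_count == 0 and regions.total_bases == 0

    def test_unsupported_assembly_is_one_interval_per_contig(self, rng):
        spec = KmerSpec(21)
        trusted = count_kmers([random_dna(rng, 2_000)], spec)
        contigs = [("c1", random_dna(rng, 500)), ("c2", random_dna(rng, 300))]
        regions = find_hers(contigs, trusted)
        assert regions.intervals == [("c1", 0, 500), ("c2", 0, 300)]

    def test_contig_shorter_than_k(self, small_trio):
        _, hap_a, _, _, _, _ = small_trio
        trusted = count_kmers([hap_a], KmerSpec(21))
        regions = find_hers([("tiny", "ACGTACGT")], trusted)
        assert regions.intervals == [("tiny", 0, 8)]

    def test_substitution_matches_per_position_oracle(self, rng):
        k = 21
        seq = random_dna(rng, 1_500)
        trusted = count_kmers([seq], KmerSpec(k))
        trusted_set = {m for m, _ in trusted.items()}
        for pos in (0, 10, 700, 1_490):
            base = "A" if seq[pos] != "A" else "C"
            mutated = seq[:pos] + base + seq[pos + 1 :]
            regions = find_hers([("c", mutated)], trusted)
            oracle = [("c", s, e) for s, e in bf.hers_intervals(mutated, trusted_set, k)]
            assert regions.intervals == oracle

    def test_total_bases_monotone_in_error_cutoff(self, small_trio):
        _, hap_a, _, _, _, _ = small_trio
        spec = KmerSpec(21)
        # duplicate some sequence so counts vary
        trusted = count_kmers([hap_a, hap_a[:30_000]], spec)
        totals = [
            find_hers([("c", hap_a[:50_000])], trusted, error_cutoff=c).total_bases
            for c in (1, 2, 3)
        ]
        assert totals[0] <= totals[1] <= totals[2]

    def test_bed_output(self, tmp_path, rng):
        spec = KmerSpec(21)
        trusted = count_kmers([random_dna(rng, 1_000)], spec)
        regions = find_hers([("c1", random_dna(rng, 100))], trusted)
        bed = tmp_path / "hers.bed"
        regions.to_bed(bed)
        assert bed.read_text() == "c1\t0\t100\n"
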