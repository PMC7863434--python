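"""Grouping of dispersed host reads into equivalent regions."""

import itertools

import numpy as np
import pytest

from vir.align import AlignmentRecord
from vir.dispersion import (
    DispersionConfig,
    ReadGroup,
    annotate_groups,
    collect_host_loci,
    merge_loci_into_regions,
    merge_read_groups,
    solve_dispersion_sample,
)
from vir.intervals import GenomicInterval
from vir.io import ChimericTableRow
from vir.refine import ChimericPair


def aln(start, end, ref="host1", strand="+", secondary=False):
    return AlignmentRecord("r", ref, start, end, strand,
                           0x100 if secondary else 0, [("M", end - start)],
                           end - start, 1.0, is_secondary=secondary)


def pair(pid, loci, species="virus1"):
    first = loci[0]
    row = ChimericTableRow(
        pair_id=pid,
        host_locus=GenomicInterval("host1", first[0], first[1]),
        viral_ref=species, viral_span=100,
        host_read_seq="A" * 100, viral_read_seq="C" * 100, sample_id="s",
    )
    alns = [aln(s, e, secondary=i > 0) for i, (s, e) in enumerate(loci)]
    return ChimericPair(row=row, host_alignments=alns), {pid: alns}


def group(gid, members, loci, species="virus1"):
    return ReadGroup(group_id=gid, member_pair_ids=set(members),
                     loci=[GenomicInterval("host1", s, e) for s, e in loci],
                     viral_species=species)


class TestCollectLoci:
    def test_primary_plus_secondaries(self):
        p, alns = pair("p", [(100, 250), (900, 1050), (5000, 5150)])
        loci = collect_host_loci([p], alns)
        assert len(loci["p"]) == 3

    def test_duplicates_collapse(self):
        p, _ = pair("p", [(100, 250)])
        loci = collect_host_loci([p], {"p": [aln(100, 250), aln(100, 250)]})
        assert len(loci["p"]) == 1

    def test_missing_read_errors(self):
        p, _ = pair("p", [(100, 250)])
        p.host_alignments = []
        with pytest.raises(KeyError):
            collect_host_loci([p], {})


class TestMergeLociIntoRegions:
    def test_gap_merge_and_min_reads(self):
        """Loci at [100,250), [900,1050), [5000,5150) with a 1000 bp gap
        threshold: the first two merge (gap 650), the third stays separate
        and its lone read is set aside as ungrouped."""
        loci = {"a": [GenomicInterval("host1", 100, 250)],
                "b": [GenomicInterval("host1", 900, 1050)],
                "c": [GenomicInterval("host1", 5000, 5150)]}
        species = dict.fromkeys(loci, "virus1")
        groups, ungrouped = merge_loci_into_regions(loci, species, DispersionConfig())
        assert len(groups) == 1
        assert groups[0].member_pair_ids == {"a", "b"}
        assert groups[0].loci == [GenomicInterval("host1", 100, 1050)]
        assert ungrouped == ["c"]

    def test_single_locus_single_group(self):
        loci = {p: [GenomicInterval("host1", 500, 650)] for p in "abc"}
        groups, ungrouped = merge_loci_into_regions(
            loci, dict.fromkeys(loci, "v"), DispersionConfig())
        assert len(groups) == 1 and not ungrouped

    def test_species_split_same_region(self):
        loci = {p: [GenomicInterval("host1", 500, 650)] for p in "abcd"}
        species = {"a": "v1", "b": "v1", "c": "v2", "d": "v2"}
        groups, _ = merge_loci_into_regions(loci, species, DispersionConfig())
        assert sorted(g.viral_species for g in groups) == ["v1", "v2"]


class TestMergeReadGroups:
    def test_share_exactly_at_threshold_not_merged(self):
        a = group("a", ["r1", "r2", "r3", "r4", "r5"], [(0, 100)])
        b = group("b", ["r1", "r2", "r3", "r4", "r6"], [(5000, 5100)])
        merged = merge_read_groups([a, b], DispersionConfig())
        assert len(merged) == 2  # 4/5 = 0.80 is not "more than" 80%

    def test_containment_merges(self):
        a = group("a", ["r1", "r2", "r3", "r4", "r5"], [(0, 100)])
        b = group("b", ["r1", "r2", "r3", "r4", "r5", "r6"], [(5000, 5100)])
        merged = merge_read_groups([a, b], DispersionConfig())
        assert len(merged) == 1
        assert merged[0].member_pair_ids == set("r1 r2 r3 r4 r5 r6".split())
        assert len(merged[0].loci) == 2

    def test_chain_collapses_by_iteration(self):
        a = group("a", ["r1", "r2", "r3", "r4", "r5"], [(0, 100)])
        b = group("b", ["r1", "r2", "r3", "r4", "r5", "r6"], [(5000, 5100)])
        c = group("c", ["r2", "r3", "r4", "r5", "r6"], [(9000, 9100)])
        merged = merge_read_groups([a, b, c], DispersionConfig())
        assert len(merged) == 1

    def test_species_never_merge(self):
        a = group("a", ["r1", "r2"], [(0, 100)], species="v1")
        b = group("b", ["r1", "r2"], [(0, 100)], species="v2")
        assert len(merge_read_groups([a, b], DispersionConfig())) == 2

    def _random_groups(self, rng, n_groups, n_reads=8):
        reads = [f"r{i}" for i in range(n_reads)]
        groups = []
        for gi in range(n_groups):
            k = int(rng.integers(1, n_reads + 1))
            members = list(rng.choice(reads, size=k, replace=False))
            start = int(rng.integers(0, 50)) * 1000
            groups.append(group(f"g{gi}", members, [(start, start + 100)]))
        return groups

    @staticmethod
    def _fixed_points(groups, threshold=0.8):
        """All partitions reachable by exhaustively exploring merge orders."""
        def share(a, b):
            return len(a & b) / min(len(a), len(b))

        results = set()
        def explore(state):
            mergeable = [
                (i, j) for i in range(len(state)) for j in range(i + 1, len(state))
                if share(state[i], state[j]) > threshold
            ]
            if not mergeable:
                results.add(frozenset(state))
                return
            for i, j in mergeable:
                nxt = [s for k, s in enumerate(state) if k not in (i, j)]
                nxt.append(state[i] | state[j])
                explore(nxt)
        explore([frozenset(g.member_pair_ids) for g in groups])
        return results

    def test_fixed_point_matches_enumeration(self, rng):
        """The deterministic merge lands on a fixed point of the exhaustive
        merge-order enumeration, and permuting the input order of groups
        never changes the outcome."""
        for _ in range(12):
            groups = self._random_groups(rng, int(rng.integers(2, 6)))
            merged = merge_read_groups(groups, DispersionConfig())
            got = frozenset(frozenset(g.member_pair_ids) for g in merged)
            assert got in self._fixed_points(groups)
            for perm in itertools.islice(itertools.permutations(groups), 4):
                again = merge_read_groups(list(perm), DispersionConfig())
                assert frozenset(frozenset(g.member_pair_ids) for g in again) == got

    def test_final_groups_share_at_most_threshold(self, rng):
        for _ in range(10):
            groups = self._random_groups(rng, 6, n_reads=10)
            merged = merge_read_groups(groups, DispersionConfig())
            for a, b in itertools.combinations(merged, 2):
                shared = len(a.member_pair_ids & b.member_pair_ids)
                assert shared / min(a.size, b.size) <= 0.8 + 1e-12


class TestSolveDispersion:
    def test_five_grouped_two_ungrouped(self):
        """Seven chimeric pairs, five sharing multi-mapped loci and two
        isolated singletons: one group of five plus two ungrouped reads."""
        copies = [(i * 10_000, i * 10_000 + 150) for i in range(3)]
        pairs = []
        alignments = {}
        for i in range(5):
            p, a = pair(f"m{i}", copies)
            pairs.append(p)
            alignments.update(a)
        for i, start in enumerate((200_000, 300_000)):
            p, a = pair(f"iso{i}", [(start, start + 150)])
            pairs.append(p)
            alignments.update(a)
        res = solve_dispersion_sample(pairs, alignments)
        assert len(res.groups) == 1
        assert res.groups[0].member_pair_ids == {f"m{i}" for i in range(5)}
        assert sorted(res.ungrouped) == ["iso0", "iso1"]

    def test_read_conservation(self):
        rng = np.random.default_rng(5)
        pairs = []
        alignments = {}
        for i in range(12):
            n_loci = int(rng.integers(1, 4))
            loci = [(int(s) * 3000, int(s) * 3000 + 150)
                    for s in rng.choice(30, size=n_loci, replace=False)]
            p, a = pair(f"p{i}", loci)
            pairs.append(p)
            alignments.update(a)
        res = solve_dispersion_sample(pairs, alignments)
        in_groups = [pid for g in res.groups for pid in g.member_pair_ids]
        assert sorted(in_groups + res.ungrouped) == sorted(p.pair_id for p in pairs)
        assert len(in_groups) == len(set(in_groups))

    def test_empty_input(self):
        res = solve_dispersion_sample([], {})
        assert res.groups == [] and res.ungrouped == []

    def test_annotation_attachment(self):
        g = group("g", ["r1", "r2"], [(100, 400), (9000, 9300)])
        annots = [(GenomicInterval("host1", 200, 260), "EVE-1"),
                  (GenomicInterval("host1", 9100, 9500), "TE-7"),
                  (GenomicInterval("host1", 700_000, 700_100), "far")]
        annotate_groups([g], annots)
        assert g.annotations == ["EVE-1", "TE-7"]
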