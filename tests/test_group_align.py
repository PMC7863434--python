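"""Realignment to the equivalent region, side prediction and junction calls."""

import numpy as np
import pytest

from vir.align import revcomp
from vir.dispersion import ReadGroup
from vir.group_align import (
    SIDE_LEFT,
    SIDE_RIGHT,
    SIDE_UNINFORMATIVE,
    GroupAlignConfig,
    assemble_junction,
    call_integration,
    realign_group,
    side_from_flags,
)
from vir.intervals import GenomicInterval
from vir.io import ChimericTableRow
from vir.refine import ChimericPair

from conftest import random_seq


def make_pair(pid, host_seq, viral_seq, locus=(0, 150)):
    row = ChimericTableRow(
        pair_id=pid,
        host_locus=GenomicInterval("host1", locus[0], locus[1]),
        viral_ref="virus1", viral_span=min(100, len(viral_seq)),
        host_read_seq=host_seq, viral_read_seq=viral_seq, sample_id="s",
    )
    return ChimericPair(row=row)


class TestSideFromFlags:
    def test_canonical_right_pair(self):
        assert side_from_flags(73, 133) == SIDE_RIGHT

    def test_canonical_left_pair(self):
        assert side_from_flags(185, 117) == SIDE_LEFT

    def test_both_mapped_uninformative(self):
        assert side_from_flags(97, 145) == SIDE_UNINFORMATIVE

    def test_both_unmapped_uninformative(self):
        assert side_from_flags(77, 141) == SIDE_UNINFORMATIVE

    def test_irrelevant_bits_do_not_change_side(self):
        for extra in (0x200, 0x400, 0x800, 0x600):
            assert side_from_flags(73 | extra, 133 | extra) == SIDE_RIGHT
            assert side_from_flags(185 | extra, 117 | extra) == SIDE_LEFT


class TestRealignGroup:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.region = random_seq(rng, 1200)
        self.alien = random_seq(rng, 150)
        self.group = ReadGroup("g", {"p0"}, [GenomicInterval("host1", 0, 1200)], "virus1")

    def test_host_substring_viral_alien(self):
        p = make_pair("p0", self.region[300:450], self.alien)
        out = realign_group(self.group, self.region, [p])
        assert out[0].host_rec is not None and out[0].viral_rec is None
        assert out[0].side == SIDE_RIGHT
        assert (out[0].flag_host, out[0].flag_viral) == (73, 133)

    def test_both_alien_uninformative(self):
        rng = np.random.default_rng(1)
        p = make_pair("p0", random_seq(rng, 150), self.alien)
        out = realign_group(self.group, self.region, [p])
        assert out[0].side == SIDE_UNINFORMATIVE

    def test_junction_read_soft_clips(self):
        """A read carrying 90 host + 60 viral nt aligns with a 60 nt clip at
        the junction position."""
        viral = random_seq(np.random.default_rng(2), 400)
        read = self.region[510:600] + viral[:60]
        p = make_pair("p0", read, self.alien)
        out = realign_group(self.group, self.region, [p])
        rec = out[0].host_rec
        assert rec.trailing_clip == 60
        assert rec.end == 600

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            realign_group(self.group, "", [])


class TestAssembleJunction:
    def test_tiling_reads_reconstruct_junction(self, rng):
        junction = random_seq(rng, 400)
        reads = [(f"r{i:02d}", junction[s : s + 80])
                 for i, s in enumerate(range(0, 321, 40))]
        consensus, fragmentary = assemble_junction(reads)
        assert junction in consensus or revcomp(junction) in consensus
        assert not fragmentary

    def test_single_read_returned(self):
        consensus, fragmentary = assemble_junction([("r0", "ACGTACGTTTACGCA")])
        assert consensus == "ACGTACGTTTACGCA"
        assert fragmentary

    def test_disjoint_reads_flagged_fragmentary(self, rng):
        a, b = random_seq(rng, 90), random_seq(rng, 60)
        consensus, fragmentary = assemble_junction([("a", a), ("b", b)])
        assert consensus == a  # longest fragment
        assert fragmentary

    def test_no_reads(self):
        assert assemble_junction([]) == ("", False)


class TestCallIntegration:
    def _build(self, rng, n_right=4, n_left=4, spanning=3):
        """A synthetic group around an insertion at region position 1000:
        forward host mates upstream with fully-viral mates, reverse host
        mates downstream, plus junction-spanning clipped host mates."""
        region = random_seq(rng, 2000)
        virus = random_seq(rng, 800)
        point = 1000
        # pin the junction-adjacent bases so no micro-homology blurs the
        # breakpoint: the region shows A's, the virus G/C at every base a
        # spanning read abuts against
        region = region[:point - 1] + "AA" + region[point + 1:]
        virus = "C" + virus[1:600] + "G" * 70 + virus[670:]
        pairs = []
        for i in range(n_right):
            host = region[point - 650 + i * 17 : point - 500 + i * 17]
            pairs.append(make_pair(f"r{i}", host, virus[i * 11 : i * 11 + 150]))
        for i in range(n_left):
            host = revcomp(region[point + 500 + i * 13 : point + 650 + i * 13])
            pairs.append(make_pair(f"l{i}", host, virus[200 + i * 7 : 350 + i * 7]))
        for i in range(spanning):
            host = region[point - 100 + i * 5 : point] + virus[:50 + i * 5]
            pairs.append(make_pair(f"sR{i}", host, virus[400:550]))
            host = revcomp(virus[600 : 650 + i * 5] + region[point : point + 100 - i * 5])
            pairs.append(make_pair(f"sL{i}", host, virus[100:250]))
        group = ReadGroup("g", {p.pair_id for p in pairs},
                          [GenomicInterval("host1", 0, 2000)], "virus1")
        return group, region, pairs, point

    def test_both_sides_resolved_breakpoints_exact(self, rng):
        group, region, pairs, point = self._build(rng)
        call = call_integration(group, region, pairs)
        assert call.resolved == "both"
        assert call.left_support >= 4 and call.right_support >= 4
        assert call.breakpoint_right == point
        assert call.breakpoint_left == point

    def test_forward_only_right_only(self, rng):
        group, region, pairs, _ = self._build(rng, n_right=3, n_left=0, spanning=0)
        group.member_pair_ids = {p.pair_id for p in pairs}
        call = call_integration(group, region, pairs)
        assert call.resolved == "right_only"
        assert call.left_support == 0

    def test_uninformative_group_suppressed(self, rng):
        region = random_seq(rng, 1000)
        pairs = [make_pair("p0", random_seq(rng, 150), random_seq(rng, 150))]
        group = ReadGroup("g", {"p0"}, [GenomicInterval("host1", 0, 1000)], "virus1")
        assert call_integration(group, region, pairs) is None

    def test_realignment_sam_emitted(self, rng, tmp_path):
        from vir.group_align import write_realignment_sam
        from vir.io import read_alignments

        group, region, pairs, _ = self._build(rng)
        realigned = realign_group(group, region, pairs)
        path = tmp_path / "realign.sam"
        write_realignment_sam(realigned, group.group_id, len(region), path)
        recs = list(read_alignments(path))  # mapped records only
        assert recs and all(r.ref_name == group.group_id for r in recs)
        assert all(0 <= r.start < r.end <= len(region) for r in recs)
        flags = {r.flag for r in recs}
        assert flags & {73, 185}  # informative host mates on both strands

    def test_breakpoints_mapped_to_genome_coordinates(self, rng):
        group, region, pairs, point = self._build(rng)
        origin = GenomicInterval("host1", 50_000, 52_000)
        call = call_integration(group, region, pairs, region_origin=origin)
        assert call.breakpoint_right == 50_000 + point
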