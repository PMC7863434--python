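"""Chimeric-pair filtering: complexity, viral span, and host proximity."""

import numpy as np
import pytest

from vir.align import build_seed_index, revcomp
from vir.intervals import GenomicInterval
from vir.io import ChimericTableRow
from vir.refine import (
    STATUS_COMPLEXITY,
    STATUS_KEPT,
    STATUS_PROXIMAL,
    STATUS_SHORT_VIRAL,
    ChimericPair,
    RefineConfig,
    dinucleotide_coverage,
    refine_candidates,
)

from conftest import random_seq


def brute_dinucleotide_coverage(seq: str) -> float:
    best = 0.0
    for a in "ACGT":
        for b in "ACGT":
            d = a + b
            covered = set()
            for i in range(len(seq) - 1):
                if seq[i : i + 2] == d:
                    covered.update((i, i + 1))
            best = max(best, len(covered) / len(seq))
    return best


def make_row(pair_id="p1", host_start=1000, viral_seq=None, host_seq=None,
             span=None, ref="host1", viral_ref="virus1"):
    viral_seq = viral_seq or "ACGT" * 38  # low complexity? no: period-4
    host_seq = host_seq or "TTGACCAGTAC" * 14
    return ChimericTableRow(
        pair_id=pair_id,
        host_locus=GenomicInterval(ref, host_start, host_start + len(host_seq)),
        viral_ref=viral_ref,
        viral_span=len(viral_seq) if span is None else span,
        host_read_seq=host_seq[:150],
        viral_read_seq=viral_seq[:152],
        sample_id="s",
    )


class TestDinucleotideCoverage:
    def test_pure_dinucleotide_repeat(self):
        assert dinucleotide_coverage("AC" * 10) == 1.0

    def test_homopolymer(self):
        assert dinucleotide_coverage("A" * 10) == 1.0

    def test_period_four_repeat(self):
        assert dinucleotide_coverage("ACGT" * 5) == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            seq = random_seq(rng, int(rng.integers(2, 60)), alphabet="ACGT")
            assert dinucleotide_coverage(seq) == pytest.approx(brute_dinucleotide_coverage(seq))

    def test_reverse_complement_invariant(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 40)
            assert dinucleotide_coverage(seq) == pytest.approx(
                dinucleotide_coverage(revcomp(seq)))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dinucleotide_coverage("A")


class TestFilters:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.host = "".join(rng.choice(list("ACGT"), size=120_000))
        self.genome = {"host1": self.host}
        self.indexes = {"host1": build_seed_index(self.host)}

    def run(self, rows, **cfg):
        return refine_candidates(rows, {}, self.genome, RefineConfig(**cfg),
                                 indexes=self.indexes)

    def test_low_complexity_dropped(self, rng):
        row = make_row(viral_seq="TA" * 75)
        res = self.run([row])
        assert res.dropped[0].status == STATUS_COMPLEXITY

    def test_random_read_kept(self, rng):
        seq = random_seq(rng, 150)
        assert brute_dinucleotide_coverage(seq) < 0.8
        res = self.run([make_row(viral_seq=seq)])
        assert res.kept and res.kept[0].status == STATUS_KEPT

    def test_exact_threshold_dropped(self):
        # AC covers exactly 16 of 20 positions: coverage 0.80, strict "< 80%"
        seq = ("ACACACACACACACAC" + "GTGT") * 5
        seq = seq[:150] if len(seq) >= 150 else seq
        cov = brute_dinucleotide_coverage("ACACACACACACACAC" + "GTGT")
        assert cov == pytest.approx(0.8)
        res = self.run([make_row(viral_seq="ACACACACACACACAC" + "GTGT", span=20)])
        assert res.dropped[0].status == STATUS_COMPLEXITY

    @pytest.mark.parametrize("span,status", [
        (29, STATUS_SHORT_VIRAL), (30, STATUS_KEPT), (150, STATUS_KEPT)])
    def test_viral_span_boundary(self, rng, span, status):
        row = make_row(viral_seq=random_seq(rng, 150), span=span)
        res = self.run([row])
        got = (res.kept + res.dropped)[0].status
        assert got == status

    def test_proximal_copy_dropped_distal_kept(self, rng):
        # viral read identical to host sequence 5 kb downstream -> dropped;
        # an identical copy 50 kb away is outside the 10 kb window -> kept
        near = make_row(pair_id="near", host_start=20_000,
                        viral_seq=self.host[25_000:25_150])
        far = make_row(pair_id="far", host_start=20_000,
                       viral_seq=self.host[70_000:70_150])
        clean = make_row(pair_id="clean", host_start=20_000,
                         viral_seq=random_seq(rng, 150))
        res = self.run([near, far, clean])
        status = {p.pair_id: p.status for p in res.kept + res.dropped}
        assert status == {"near": STATUS_PROXIMAL, "far": STATUS_KEPT,
                          "clean": STATUS_KEPT}


class TestRefineCandidates:
    def setup_method(self):
        rng = np.random.default_rng(13)
        self.host = "".join(rng.choice(list("ACGT"), size=60_000))
        self.genome = {"host1": self.host}
        self.indexes = {"host1": build_seed_index(self.host)}
        self.rng = rng

    def test_toy_table_report(self):
        rows = [
            make_row("low", viral_seq="AT" * 76),
            make_row("short", viral_seq=random_seq(self.rng, 150), span=10),
            make_row("prox", host_start=10_000, viral_seq=self.host[14_000:14_150]),
            make_row("ok1", viral_seq=random_seq(self.rng, 150)),
            make_row("ok2", viral_seq=random_seq(self.rng, 150)),
        ]
        res = refine_candidates(rows, {}, self.genome, indexes=self.indexes)
        assert sorted(p.pair_id for p in res.kept) == ["ok1", "ok2"]
        assert res.report == {STATUS_COMPLEXITY: 1, STATUS_SHORT_VIRAL: 1,
                              STATUS_PROXIMAL: 1}
        assert res.stop_message is None

    def test_all_filtered_emits_stop_message(self):
        rows = [make_row("low", viral_seq="GC" * 76)]
        res = refine_candidates(rows, {}, self.genome, indexes=self.indexes)
        assert res.kept == [] and res.stop_message

    def test_empty_table_emits_stop_message(self):
        res = refine_candidates([], {}, self.genome, indexes=self.indexes)
        assert res.kept == [] and res.stop_message

    def test_filters_are_order_insensitive_predicates(self):
        """The kept set equals the intersection of the three standalone
        predicates, regardless of application order."""
        from vir.refine import filter_complexity, filter_proximal_host_hit, filter_viral_span

        rows = [
            make_row("low", viral_seq="AT" * 76, span=10),
            make_row("short", viral_seq=random_seq(self.rng, 150), span=10),
            make_row("prox", host_start=10_000, viral_seq=self.host[14_000:14_150]),
            make_row("ok", viral_seq=random_seq(self.rng, 150)),
        ]
        combined = refine_candidates(rows, {}, self.genome, indexes=self.indexes)
        survivors = None
        cfg = RefineConfig()
        for filt in (filter_complexity, filter_viral_span):
            pairs = [ChimericPair(row=r) for r in rows]
            filt(pairs, cfg)
            ids = {p.pair_id for p in pairs if p.status == STATUS_KEPT}
            survivors = ids if survivors is None else survivors & ids
        pairs = [ChimericPair(row=r) for r in rows]
        filter_proximal_host_hit(pairs, self.genome, cfg, self.indexes)
        survivors &= {p.pair_id for p in pairs if p.status == STATUS_KEPT}
        assert {p.pair_id for p in combined.kept} == survivors
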