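"""Confusion-matrix benchmarking of integration calls against simulation truth.

The evaluation unit is the sample: a carrier counts as detected when some
call's equivalent region overlaps the true insertion point within a
tolerance (default 1000 bp, the dispersion merge distance) and names the
right viral species. Because the very point of solving dispersion is that a
call's equivalent region spans every repeat copy, a call anchored at a
different copy of the true repeat still detects the sample as long as its
region contains the true locus; a stricter locus-level outcome (the best
anchor copy must itself overlap the truth) is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .group_align import IntegrationCall
from .simulate import SimTruth


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, outcome: str) -> None:
        """Tally an outcome; compound outcomes like 'FN+FP' count both."""
        for part in outcome.split("+"):
            setattr(self, part.lower(), getattr(self, part.lower()) + 1)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricSet:
    """Standard confusion-matrix metrics; a metric whose denominator is zero
    is reported as None (not available), never silently zero-filled."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    balanced_accuracy: Optional[float]
    mcc: Optional[float]


def metrics(cm: ConfusionMatrix) -> MetricSet:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn

    def ratio(num: float, den: float) -> Optional[float]:
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    bal = None if sens is None or spec is None else (sens + spec) / 2
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    return MetricSet(
        accuracy=(tp + tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        balanced_accuracy=bal,
        mcc=mcc,
    )


@dataclass
class SampleOutcome:
    sample_id: str
    sample_level: str  # TP/FP/TN/FN
    locus_level: str
    n_calls: int


def match_calls(
    calls: Sequence[IntegrationCall],
    truth: SimTruth,
    tolerance: int = 1000,
) -> SampleOutcome:
    """Score one sample's calls against its truth record.

    Sample level: a carrier is TP when any call's region overlaps the true
    insertion point +/- tolerance with the right viral species, else FN; a
    non-carrier is TN with no calls and FP otherwise. Locus level: some
    call's region must overlap the true repeat copy itself; a carrier whose
    only calls sit elsewhere scores FN+FP (the event was missed and a
    spurious locus was reported).
    """
    def region_hits(call: IntegrationCall, slop_target, slop: int) -> bool:
        if truth.viral_span is not None and call.viral_species != truth.viral_span.ref_name:
            return False
        return any(iv.overlaps(slop_target, slop=slop) for iv in call.region)

    if not truth.carrier:
        level = "TN" if not calls else "FP"
        return SampleOutcome(truth.sample_id, level, level, len(calls))
    assert truth.insertion_point is not None
    from .intervals import GenomicInterval

    point = GenomicInterval(truth.insertion_interval.ref_name,
                            truth.insertion_point, truth.insertion_point + 1)
    sample = "TP" if any(region_hits(c, point, tolerance) for c in calls) else "FN"
    copy_iv = truth.copy_interval or point
    if any(region_hits(c, copy_iv, 0) for c in calls):
        locus = "TP"
    else:
        locus = "FN+FP" if calls else "FN"
    return SampleOutcome(truth.sample_id, sample, locus, len(calls))


@dataclass
class GridCell:
    label: str
    run: Callable[[int], tuple[Sequence[IntegrationCall], SimTruth]]
    n_reps: int = 3


def benchmark_grid(
    cells: Sequence[GridCell],
    base_seed: int,
    tolerance: int = 1000,
) -> pd.DataFrame:
    """Run every cell's pipeline for its replicates and tabulate confusion
    counts and metrics. Deterministic given ``base_seed``; a failing
    replicate is recorded in the ``error`` column and the grid continues.
    """
    rows = []
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s) for s in ss.generate_state(sum(c.n_reps for c in cells)) >> 1]
    k = 0
    for cell in cells:
        cm_sample = ConfusionMatrix()
        cm_locus = ConfusionMatrix()
        errors = []
        for rep in range(cell.n_reps):
            seed = seeds[k]
            k += 1
            try:
                calls, truth = cell.run(seed)
            except Exception as exc:  # keep the grid going
                errors.append(f"rep{rep}: {exc}")
                continue
            outcome = match_calls(calls, truth, tolerance)
            cm_sample.add(outcome.sample_level)
            cm_locus.add(outcome.locus_level)
        row = {"cell": cell.label, "n_reps": cell.n_reps,
               "tp": cm_sample.tp, "fp": cm_sample.fp,
               "tn": cm_sample.tn, "fn": cm_sample.fn,
               "locus_tp": cm_locus.tp, "locus_fn": cm_locus.fn,
               "error": ";".join(errors)}
        if cm_sample.total:
            m = metrics(cm_sample)
            row.update({
                "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                "specificity": m.specificity, "precision": m.precision,
                "f1": m.f1, "balanced_accuracy": m.balanced_accuracy, "mcc": m.mcc,
            })
        rows.append(row)
    return pd.DataFrame(rows)
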