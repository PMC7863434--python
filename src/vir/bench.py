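"""Ready-made benchmark grids over the synthetic data generator.

These helpers wire the generator to the module-1 pipeline for the standard
study designs: single-sample grids over locus class x insert length x
coverage (with matched no-insert controls), and pooled designs with one
carrier per pool. All randomness derives from one base seed through
``numpy`` seed sequences, so every grid is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import build_seed_index
from .evaluate import match_calls
from .pipeline import Module1Config, run_module1
from .simulate import (
    SimConfig,
    SimTruth,
    build_host_genome,
    default_viral_source,
    insert_viral_fragment,
    make_pool,
    simulate_reads,
)

DEFAULT_CLASSES = ("UL", "Rep10", "Rep100")
DEFAULT_LENGTHS = (300, 600, 900)


def _class_code(cls: str) -> int:
    return sum(ord(c) * (i + 1) for i, c in enumerate(cls))


def _seed_for(base: int, *path: int) -> int:
    """A derived 31-bit seed, stable in the base seed and the path."""
    return int(np.random.SeedSequence((base, *path)).generate_state(1)[0] >> 1)


@dataclass
class GridRun:
    table: pd.DataFrame  # one row per simulated sample
    sensitivity: Optional[float]  # over carrier samples, in [0, 1]
    specificity: Optional[float]  # over control samples, in [0, 1]


class _GenomeCache:
    """One host genome (and its seed index) per replicate seed."""

    def __init__(self, genome_length: int, error_rate: float):
        self.base = SimConfig(genome_length=genome_length, error_rate=error_rate)
        self.virus = default_viral_source(self.base.viral_length)
        self._cache: dict[int, tuple] = {}

    def get(self, seed: int):
        if seed not in self._cache:
            host, placements = build_host_genome(self.base, seed)
            index = build_seed_index(host, 13)
            self._cache[seed] = (host, placements, index)
        return self._cache[seed]


def single_sample_grid(
    base_seed: int,
    classes: Sequence[str] = DEFAULT_CLASSES,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    coverages: Sequence[float] = (5, 15, 30),
    n_reps: int = 3,
    genome_length: int = 1_000_000,
    error_rate: float = 0.001,
    n_controls_per_rep: int = 1,
    tolerance: int = 1000,
    config: Optional[Module1Config] = None,
) -> GridRun:
    """Carrier detection over the single-sample benchmark design, plus
    matched no-insert controls simulated from the unmodified genome."""
    cache = _GenomeCache(genome_length, error_rate)
    rows = []
    for rep in range(n_reps):
        host, placements, index = cache.get(_seed_for(base_seed, 0, rep))
        for cls in classes:
            for length in lengths:
                cfg = SimConfig(genome_length=genome_length, insert_length=length,
                                insert_class=cls, error_rate=error_rate)
                cell_seed = _seed_for(base_seed, 1, rep, _class_code(cls), length)
                modified, truth = insert_viral_fragment(
                    host, placements, cache.virus, cfg, cell_seed,
                    sample_id=f"{cls}_{length}_r{rep}",
                )
                for cov in coverages:
                    reads = simulate_reads(modified, cfg, _seed_for(cell_seed, int(cov)),
                                           coverage=cov)
                    res = run_module1(reads, host, cache.virus, config,
                                      sample_id=truth.sample_id, host_index=index)
                    outcome = match_calls(res.calls, truth, tolerance)
                    rows.append({
                        "sample": truth.sample_id, "rep": rep, "class": cls,
                        "length": length, "coverage": cov, "carrier": True,
                        "n_chimeric": len(res.scan.rows),
                        "n_kept": len(res.refine.kept),
                        "n_calls": len(res.calls),
                        "outcome": outcome.sample_level,
                        "locus_outcome": outcome.locus_level,
                        "sdg": res.gain.sdg if res.gain else float("nan"),
                    })
        for ci in range(n_controls_per_rep):
            for cov in coverages:
                cfg = SimConfig(genome_length=genome_length, error_rate=error_rate)
                reads = simulate_reads(host, cfg, _seed_for(base_seed, 2, rep, ci, int(cov)),
                                       coverage=cov)
                res = run_module1(reads, host, cache.virus, config,
                                  sample_id=f"control_r{rep}_{cov}x", host_index=index)
                truth = SimTruth(sample_id=f"control_r{rep}_{cov}x", carrier=False)
                outcome = match_calls(res.calls, truth, tolerance)
                rows.append({
                    "sample": truth.sample_id, "rep": rep, "class": "none",
                    "length": 0, "coverage": cov, "carrier": False,
                    "n_chimeric": len(res.scan.rows),
                    "n_kept": len(res.refine.kept),
                    "n_calls": len(res.calls),
                    "outcome": outcome.sample_level,
                    "locus_outcome": outcome.locus_level,
                    "sdg": float("nan"),
                })
    table = pd.DataFrame(rows)
    carriers = table[table.carrier]
    controls = table[~table.carrier]
    sens = float((carriers.outcome == "TP").mean()) if len(carriers) else None
    spec = float((controls.outcome == "TN").mean()) if len(controls) else None
    return GridRun(table=table, sensitivity=sens, specificity=spec)


def pool_grid(
    base_seed: int,
    pool_sizes: Sequence[int],
    pool_coverages: Sequence[float] = (30, 60),
    classes: Sequence[str] = ("UL", "Rep10", "Rep100"),
    lengths: Sequence[int] = (300, 600, 900),
    n_reps: int = 2,
    genome_length: int = 1_000_000,
    error_rate: float = 0.001,
    tolerance: int = 1000,
    config: Optional[Module1Config] = None,
) -> pd.DataFrame:
    """Carrier detection in pools with exactly one integration carrier.

    Returns one row per simulated pool; sensitivity per pool size is the
    mean of ``detected`` within that size.
    """
    cache = _GenomeCache(genome_length, error_rate)
    rows = []
    for rep in range(n_reps):
        host, placements, index = cache.get(_seed_for(base_seed, 10, rep))
        for cls in classes:
            for length in lengths:
                cfg0 = SimConfig(genome_length=genome_length, insert_length=length,
                                 insert_class=cls, error_rate=error_rate)
                cell_seed = _seed_for(base_seed, 11, rep, _class_code(cls), length)
                modified, truth = insert_viral_fragment(
                    host, placements, cache.virus, cfg0, cell_seed,
                    sample_id=f"{cls}_{length}_r{rep}",
                )
                for size in pool_sizes:
                    for cov in pool_coverages:
                        cfg = SimConfig(genome_length=genome_length, insert_length=length,
                                        insert_class=cls, error_rate=error_rate,
                                        pool_size=size)
                        reads = make_pool(modified, host, cfg,
                                          _seed_for(cell_seed, size, int(cov)),
                                          pool_coverage=cov)
                        res = run_module1(reads, host, cache.virus, config,
                                          sample_id=f"{truth.sample_id}_n{size}_{cov}x",
                                          host_index=index)
                        outcome = match_calls(res.calls, truth, tolerance)
                        rows.append({
                            "rep": rep, "class": cls, "length": length,
                            "pool_size": size, "pool_coverage": cov,
                            "carrier_coverage": cov / size,
                            "n_chimeric": len(res.scan.rows),
                            "n_kept": len(res.refine.kept),
                            "n_calls": len(res.calls),
                            "detected": outcome.sample_level == "TP",
                        })
    return pd.DataFrame(rows)


def pool_sensitivity_by_size(table: pd.DataFrame) -> pd.Series:
    """Detection rate per pool size, index sorted ascending."""
    return table.groupby("pool_size")["detected"].mean().sort_index()
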