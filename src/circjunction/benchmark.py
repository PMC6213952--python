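"""Desk-scale benchmark harness: simulate, detect, score.

Reproduces the simulation experiments (depth sweeps, read-length and
linear-noise robustness, precision) on the bundled simulator: a 500 kb
synthetic genome with 50 genes and 30 preset circRNAs per run, averaged
over a few seeds.
"""

from __future__ import annotations

import statistics
import tempfile
from dataclasses import dataclass

from .candidate_clustering import DetectionParams, detect_circRNAs
from .evaluation import EvalResult, evaluate_detection
from .read_simulator import SimConfig, run_simulation


@dataclass
class ConditionResult:
    config: SimConfig
    eval: EvalResult


def run_condition(
    seed: int,
    depth_circ: float = 10.0,
    depth_linear: float = 10.0,
    read_len: int = 100,
    genome_length: int = 500_000,
    n_genes: int = 50,
    n_circ: int = 30,
    error_rate: float = 0.01,
    params: DetectionParams | None = None,
    workdir: str | None = None,
) -> ConditionResult:
    """One simulate-detect-score pass under the standard study conditions."""
    config = SimConfig(
        genome_length=genome_length, n_genes=n_genes, n_circ=n_circ,
        depth_circ=depth_circ, depth_linear=depth_linear,
        read_len=read_len, error_rate=error_rate, seed=seed,
    )
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        sim = run_simulation(config, tmp)
        candidates = detect_circRNAs(sim.sam_path, params)
        ev = evaluate_detection(candidates, sim.truth, boundary_tol=0)
    return ConditionResult(config, ev)


def mean_sensitivity(seeds: list[int], **kw) -> float:
    return statistics.mean(run_condition(s, **kw).eval.sensitivity for s in seeds)


def mean_precision(seeds: list[int], **kw) -> float:
    return statistics.mean(run_condition(s, **kw).eval.precision for s in seeds)
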