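"""Monte-Carlo coverage engine.

Repeatedly generates a synthetic graph from a degree model, runs one or more
interval methods (the patchwork bootstrap with cross-validated patch size,
and the SRS competitors), and tabulates per-method empirical coverage and
mean interval width against the population truth.  Coverage of a 95% interval
should sit near 95%; its Monte-Carlo standard error is sqrt(c(1−c)/reps).

All randomness derives from ``rng_seed``: repetition r uses the generator
seeded with ``[rng_seed, r]``, so any single repetition is replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bootstrap import ConfidenceInterval, efron_ci, resample_patches
from .cv import SeedWaveGrid, cross_validate
from .degree_models import DegreeModel
from .lsmi import lsmi, sample_seeds, subpatch
from .netgen import generate_graph
from .srs import nci, qci, srs_sample
from .targets import Target

__all__ = ["ExperimentConfig", "CoverageReport", "run_experiment", "fig2_diagnostic"]

logger = logging.getLogger(__name__)

#: an interval method: (graph, config, rng) -> {target string: interval}
MethodFn = Callable[[object, "ExperimentConfig", np.random.Generator], dict]


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell block of the coverage study."""

    model: DegreeModel
    n: int
    targets: tuple = ("mean",)
    methods: tuple = ("FPB", "NCI", "QCI")
    grid: SeedWaveGrid = field(default_factory=SeedWaveGrid)
    B: int = 500
    M: int = 50
    mc_reps: int = 200
    alpha: float = 0.05
    rng_seed: int = 0
    proxy_size: int = 100
    proxy_reps: int = 13
    cv_selector: str | None = "mean"  # statistic the patch size is tuned on
    weights: str = "inverse_degree"
    truth: str = "model"  # population values; "realization" uses per-graph values

    def __post_init__(self):
        if self.mc_reps < 1:
            raise ValueError("mc_reps must be ≥ 1")
        if self.truth not in ("model", "realization"):
            raise ValueError("truth must be 'model' or 'realization'")


@dataclass(frozen=True)
class CoverageRow:
    model: str
    n: int
    method: str
    target: str
    coverage_pct: float
    mean_width: float
    mc_reps: int
    se_pct: float


@dataclass(frozen=True)
class CoverageReport:
    rows: tuple[CoverageRow, ...]
    failed_reps: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def row(self, method: str, target) -> CoverageRow:
        t = str(Target.parse(target))
        for r in self.rows:
            if r.method == method and r.target == t:
                return r
        raise KeyError((method, t))


def _fpb_method(graph, config: ExperimentConfig, rng) -> dict[str, ConfidenceInterval]:
    report = cross_validate(
        graph,
        config.grid,
        config.B,
        rng,
        target=list(config.targets),
        selector=config.cv_selector,
        proxy_size=config.proxy_size,
        proxy_reps=config.proxy_reps,
        alpha=config.alpha,
        weights=config.weights,
    )
    return {t: sel.interval for t, sel in report.selections.items()}


def _srs_methods(graph, config: ExperimentConfig, rng, want_nci, want_qci):
    """NCI and QCI share one SRS draw, as in the benchmark design."""
    sample = srs_sample(graph, config.M, rng)
    out: dict[str, dict[str, ConfidenceInterval]] = {"NCI": {}, "QCI": {}}
    for t in config.targets:
        tgt = Target.parse(t)
        if tgt.kind != "fk":
            raise ValueError("NCI/QCI are defined for f(k) targets only")
        if want_nci:
            out["NCI"][str(tgt)] = nci(sample, tgt.k, config.alpha)
        if want_qci:
            out["QCI"][str(tgt)] = qci(sample, tgt.k, config.B, rng, config.alpha)
    return out


def run_experiment(
    config: ExperimentConfig,
    extra_methods: Mapping[str, MethodFn] | None = None,
) -> CoverageReport:
    """Run the coverage study defined by ``config``.

    ``extra_methods`` maps method names to custom interval callables with the
    ``(graph, config, rng) -> {target: interval}`` signature; built-in names
    are FPB, NCI and QCI.
    """
    extra_methods = dict(extra_methods or {})
    known = {"FPB", "NCI", "QCI", *extra_methods}
    unknown = set(config.methods) - known
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    targets = [str(Target.parse(t)) for t in config.targets]
    truths = {t: Target.parse(t).true_value(config.model) for t in targets}

    hits: dict[tuple[str, str], int] = {}
    widths: dict[tuple[str, str], list[float]] = {}
    for method in config.methods:
        for t in targets:
            hits[(method, t)] = 0
            widths[(method, t)] = []

    completed = 0
    failed = 0
    max_failures = max(1, int(0.05 * config.mc_reps))
    for rep in range(config.mc_reps):
        rng = np.random.default_rng([config.rng_seed, rep])
        try:
            graph = generate_graph(config.model, config.n, rng)
            if config.truth == "realization":
                rep_truths = {t: Target.parse(t).graph_value(graph) for t in targets}
            else:
                rep_truths = truths
            intervals: dict[str, dict[str, ConfidenceInterval]] = {}
            if "FPB" in config.methods:
                intervals["FPB"] = _fpb_method(graph, config, rng)
            want_nci = "NCI" in config.methods
            want_qci = "QCI" in config.methods
            if want_nci or want_qci:
                intervals.update(_srs_methods(graph, config, rng, want_nci, want_qci))
            for name, fn in extra_methods.items():
                if name in config.methods:
                    intervals[name] = {
                        str(Target.parse(t)): ci for t, ci in fn(graph, config, rng).items()
                    }
        except Exception:
            failed += 1
            logger.exception("repetition %d failed (seed [%s, %d])", rep, config.rng_seed, rep)
            if failed > max_failures:
                raise RuntimeError(f"more than 5% of repetitions failed ({failed})")
            continue
        completed += 1
        for method in config.methods:
            for t in targets:
                ci = intervals[method][t]
                if ci.contains(rep_truths[t]):
                    hits[(method, t)] += 1
                widths[(method, t)].append(ci.width)

    rows = []
    model_label = f"{config.model.family}({', '.join(f'{p:g}' for p in config.model.params)})"
    for method in config.methods:
        for t in targets:
            c = hits[(method, t)] / completed if completed else float("nan")
            rows.append(
                CoverageRow(
                    model=model_label,
                    n=config.n,
                    method=method,
                    target=t,
                    coverage_pct=100.0 * c,
                    mean_width=float(np.mean(widths[(method, t)])) if completed else float("nan"),
                    mc_reps=completed,
                    se_pct=100.0 * float(np.sqrt(c * (1 - c) / completed)) if completed else float("nan"),
                )
            )
    return CoverageReport(tuple(rows), failed_reps=failed)


@dataclass(frozen=True)
class WaveSummary:
    wave: int
    sd: float
    mean: float
    ci: ConfidenceInterval
    values: np.ndarray


def fig2_diagnostic(
    model: DegreeModel,
    n: int,
    seed_count: int,
    wave_list: Sequence[int],
    B: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> list[WaveSummary]:
    """Bootstrap mean-degree spread as a function of wave depth.

    One graph, one LSMI; for each requested wave depth the same patch set is
    truncated and bootstrapped, exposing the bias–variance trade-off: deeper
    waves shrink the bootstrap SD of the mean-degree replicates while pulling
    the histogram away from the seeds-only centre.
    """
    graph = generate_graph(model, n, rng)
    seeds = sample_seeds(graph, seed_count, rng)
    patchset = lsmi(graph, seeds, max(wave_list))
    out = []
    for w in wave_list:
        sample = resample_patches(subpatch(patchset, seed_count, w), B, rng)
        values = sample.mean_degree
        out.append(
            WaveSummary(
                wave=w,
                sd=float(values.std(ddof=1)) if B > 1 else 0.0,
                mean=float(values.mean()),
                ci=efron_ci(values, alpha, target="mean"),
                values=values,
            )
        )
    return out
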