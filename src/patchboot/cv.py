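"""Data-driven choice of the seed-wave combination (patch size).

The patchwork bootstrap's tuning parameter is the patch size: the number of
seeds m and the wave depth w.  Small patches give high-variance intervals;
deep patches add bias.  The selection procedure grows ONE maximal LSMI
(m_l seeds, d waves), derives every (m_i, w) combination from it by nested
sub-sampling, bootstraps each combination into a percentile interval, and
scores each interval by how often it covers cheap *proxy* point estimates —
seeds-only estimates from small independent uniform vertex samples.  The
combination whose proxy coverage is closest to the nominal level wins; ties
prefer narrower intervals, then fewer waves, then fewer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import lsmi as lsmi_mod
from .bootstrap import ConfidenceInterval, efron_ci, resample_patches
from .lsmi import sample_seeds, subpatch
from .netgen import SimpleGraph
from .targets import Target

__all__ = ["SeedWaveGrid", "ComboResult", "CVReport", "proxy_estimates", "cross_validate"]


@dataclass(frozen=True)
class SeedWaveGrid:
    """The J = l·d candidate combinations: seed counts × wave depths."""

    seed_counts: tuple[int, ...] = (20, 30, 40, 50)
    wave_depths: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        counts = self.seed_counts
        if not counts or any(c <= 0 for c in counts) or list(counts) != sorted(set(counts)):
            raise ValueError("seed counts must be positive and strictly increasing")
        if not self.wave_depths or any(w < 0 for w in self.wave_depths):
            raise ValueError("wave depths must be non-negative")

    @property
    def combos(self) -> list[tuple[int, int]]:
        return [(m, w) for w in self.wave_depths for m in self.seed_counts]

    @property
    def J(self) -> int:
        return len(self.seed_counts) * len(self.wave_depths)

    @property
    def max_seeds(self) -> int:
        return max(self.seed_counts)

    @property
    def max_waves(self) -> int:
        return max(self.wave_depths)


@dataclass(frozen=True)
class ComboResult:
    m: int
    w: int
    ci: ConfidenceInterval
    proxy_coverage: float

    @property
    def width(self) -> float:
        return self.ci.width


@dataclass(frozen=True)
class TargetSelection:
    target: str
    combos: tuple[ComboResult, ...]
    chosen_index: int

    @property
    def chosen(self) -> ComboResult:
        return self.combos[self.chosen_index]

    @property
    def interval(self) -> ConfidenceInterval:
        return self.chosen.ci


@dataclass(frozen=True)
class CVReport:
    """Per-combination table and the selected combination, per target."""

    selections: dict[str, TargetSelection]
    alpha: float

    def __getitem__(self, target) -> TargetSelection:
        return self.selections[str(Target.parse(target))]

    @property
    def single(self) -> TargetSelection:
        if len(self.selections) != 1:
            raise ValueError("report holds several targets; index by target")
        return next(iter(self.selections.values()))

    def to_records(self) -> list[dict]:
        rows = []
        for sel in self.selections.values():
            for i, c in enumerate(sel.combos):
                rows.append(
                    {
                        "target": sel.target,
                        "seeds": c.m,
                        "waves": c.w,
                        "lower": c.ci.lower,
                        "upper": c.ci.upper,
                        "width": c.width,
                        "proxy_coverage": c.proxy_coverage,
                        "chosen": i == sel.chosen_index,
                    }
                )
        return rows


def proxy_estimates(
    graph: SimpleGraph,
    proxy_size: int,
    proxy_reps: int,
    rng: np.random.Generator,
    target,
) -> np.ndarray:
    """Seeds-only point estimates from independent uniform vertex samples.

    Each repetition draws ``proxy_size`` vertices without replacement and
    evaluates the target on their degrees alone — cheap, unbiased anchors
    for judging candidate intervals.
    """
    target = Target.parse(target)
    if not 1 <= proxy_size <= graph.n:
        raise ValueError(f"proxy_size={proxy_size} outside 1..{graph.n}")
    degs = graph.degrees
    out = np.empty(proxy_reps)
    for t in range(proxy_reps):
        sample = rng.choice(graph.n, size=proxy_size, replace=False)
        out[t] = target.from_degrees(degs[sample])
    return out


def _select(combos: Sequence[ComboResult], level: float) -> int:
    key = lambda ic: (abs(ic[1].proxy_coverage - level), ic[1].width, ic[1].w, ic[1].m)
    return min(enumerate(combos), key=key)[0]


def cross_validate(
    graph: SimpleGraph,
    grid: SeedWaveGrid,
    B: int,
    rng: np.random.Generator,
    target="mean",
    selector=None,
    proxy_size: int = 100,
    proxy_reps: int = 13,
    alpha: float = 0.05,
    weights: str = "inverse_degree",
) -> CVReport:
    """Select the seed-wave combination and return its interval, per target.

    ``target`` may be a single target or a sequence; all targets share the
    single LSMI, the per-combination bootstrap samples and the proxy vertex
    samples.

    ``selector`` controls the selection policy.  ``None`` scores each target's
    own interval table against its own proxies (per-target selection).  A
    statistic (e.g. ``"mean"``) runs the proxy-coverage selection on that one
    statistic and applies the chosen combination to every target — the
    one-combination-per-network usage, where the patch size is tuned once and
    all degree-distribution intervals are read from the same patches.
    """
    targets = [Target.parse(t) for t in (target if isinstance(target, (list, tuple)) else [target])]
    selector_tgt = None if selector is None else Target.parse(selector)
    score_targets = list(targets)
    if selector_tgt is not None and selector_tgt not in score_targets:
        score_targets.append(selector_tgt)
    if proxy_reps < 2:
        raise ValueError("proxy_reps must be ≥ 2")
    if graph.n < grid.max_seeds:
        raise ValueError("graph order smaller than the largest seed count")
    if graph.n < proxy_size:
        raise ValueError("graph order smaller than the proxy sample size")
    level = 1.0 - alpha

    seeds = sample_seeds(graph, grid.max_seeds, rng)
    patchset = lsmi_mod.lsmi(graph, seeds, grid.max_waves)

    # one bootstrap sample per combination, shared across targets
    samples = {
        (m, w): resample_patches(subpatch(patchset, m, w), B, rng, weights=weights)
        for (m, w) in grid.combos
    }
    # one proxy set shared by all combinations and targets
    proxy_vertices = [
        rng.choice(graph.n, size=proxy_size, replace=False) for _ in range(proxy_reps)
    ]
    degs = graph.degrees

    tables: dict[Target, tuple[ComboResult, ...]] = {}
    for tgt in score_targets:
        proxies = np.array([tgt.from_degrees(degs[vs]) for vs in proxy_vertices])
        combos = []
        for (m, w) in grid.combos:
            ci = efron_ci(samples[(m, w)].statistic(tgt), alpha, target=str(tgt))
            cov = float(np.mean((proxies >= ci.lower) & (proxies <= ci.upper)))
            combos.append(ComboResult(m, w, ci, cov))
        tables[tgt] = tuple(combos)

    shared_choice = None
    if selector_tgt is not None:
        shared_choice = _select(tables[selector_tgt], level)
    selections = {
        str(tgt): TargetSelection(
            str(tgt),
            tables[tgt],
            _select(tables[tgt], level) if shared_choice is None else shared_choice,
        )
        for tgt in targets
    }
    return CVReport(selections=selections, alpha=alpha)
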