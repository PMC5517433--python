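"""Labeled Snowball sampling with Multiple Inclusions (LSMI).

A *patch* is the ego network grown around one uniformly sampled *seed* for a
fixed number of *waves*.  Within a patch no edge is traced twice: wave j+1
explores the previously untraced edges incident to the vertices recorded at
wave j.  A new vertex reached through r distinct untraced edges in the same
wave is recorded r times (the "multiple inclusions"); a vertex already
recorded in an earlier wave of the same patch is never re-recorded.  Patches
from different seeds are grown independently and may overlap, like the
overlapping blocks of a time-series block bootstrap.

For every recorded vertex the *full* degree in the input graph is stored:
the sampling design assumes the graph is observable up to 2d−1 waves around
any seed, so degrees of wave-d vertices are known exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .netgen import SimpleGraph

__all__ = ["Patch", "PatchSet", "sample_seeds", "lsmi", "subpatch"]


@dataclass(frozen=True)
class Patch:
    """One seed's ego network: the seed degree plus per-wave non-seed records.

    ``waves[j]`` (0-indexed list position = wave j+1) is the multiset of
    ``(vertex, degree)`` inclusion records reached at that wave.
    """

    seed: int
    seed_degree: int
    waves: tuple[tuple[tuple[int, int], ...], ...] = ()

    def truncated(self, w: int) -> "Patch":
        return Patch(self.seed, self.seed_degree, self.waves[:w])

    def nonseed_degrees(self) -> list[int]:
        return [deg for wave in self.waves for _, deg in wave]


@dataclass(frozen=True)
class PatchSet:
    """The LSMI output: one patch per seed, in seed-sampling order.

    The seed order supports nested sub-sampling: the first m patches truncated
    to w waves form the (m, w) seed-wave combination of the same LSMI run.
    """

    patches: tuple[Patch, ...]
    d_max: int

    @property
    def m(self) -> int:
        return len(self.patches)

    def seed_degrees(self) -> np.ndarray:
        return np.array([p.seed_degree for p in self.patches], dtype=np.int64)

    def nonseed_degrees(self) -> np.ndarray:
        """All non-seed degree records pooled across patches and waves."""
        out = [deg for p in self.patches for deg in p.nonseed_degrees()]
        return np.array(out, dtype=np.int64)

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "d_max": self.d_max,
            "patches": [
                {
                    "seed": p.seed,
                    "seed_degree": p.seed_degree,
                    "waves": [[[v, d] for v, d in wave] for wave in p.waves],
                }
                for p in self.patches
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PatchSet":
        payload = json.loads(text)
        patches = tuple(
            Patch(
                rec["seed"],
                rec["seed_degree"],
                tuple(tuple((v, d) for v, d in wave) for wave in rec["waves"]),
            )
            for rec in payload["patches"]
        )
        return cls(patches, payload["d_max"])


def sample_seeds(graph: SimpleGraph, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of ``m`` distinct vertices; order retained for nesting."""
    if not 1 <= m <= graph.n:
        raise ValueError(f"seed count m={m} outside 1..{graph.n}")
    return rng.choice(graph.n, size=m, replace=False)


def _grow_patch(graph: SimpleGraph, seed: int, d: int) -> Patch:
    adjacency = graph.adjacency
    traced: set[tuple[int, int]] = set()
    recorded: set[int] = {seed}
    frontier: list[int] = [seed]
    waves: list[tuple[tuple[int, int], ...]] = []
    for _ in range(d):
        new_records: list[tuple[int, int]] = []
        for v in frontier:
            for u in sorted(adjacency[v]):
                key = (v, u) if v <= u else (u, v)
                if key in traced:
                    continue
                traced.add(key)
                if u in recorded:
                    continue  # edge traced, but no new inclusion
                new_records.append((u, len(adjacency[u])))
        waves.append(tuple(new_records))
        fresh = sorted({v for v, _ in new_records})
        recorded.update(fresh)
        frontier = fresh
        if not frontier:
            waves.extend(() for _ in range(d - len(waves)))
            break
    return Patch(seed, len(adjacency[seed]), tuple(waves))


def lsmi(graph: SimpleGraph, seeds: Sequence[int], d: int) -> PatchSet:
    """Grow a ``d``-wave patch around each seed (independently per seed)."""
    if d < 0:
        raise ValueError("wave depth d must be ≥ 0")
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    for s in seeds:
        if not 0 <= s < graph.n:
            raise ValueError(f"seed {s} is not a vertex of the graph")
    return PatchSet(tuple(_grow_patch(graph, int(s), d) for s in seeds), d)


def subpatch(patchset: PatchSet, m: int, w: int) -> PatchSet:
    """First ``m`` patches truncated to ``w`` waves — a pure view, no resampling."""
    if not 1 <= m <= patchset.m:
        raise ValueError(f"m={m} outside 1..{patchset.m}")
    if not 0 <= w <= patchset.d_max:
        raise ValueError(f"w={w} outside 0..{patchset.d_max}")
    return PatchSet(tuple(p.truncated(w) for p in patchset.patches[:m]), w)
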