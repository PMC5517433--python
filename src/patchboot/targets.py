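"""Target statistics: which function of the degree distribution is estimated.

Two targets are supported — the network mean degree, and the probability
``f(k)`` of observing a vertex of a given degree k.  A target can be given
as a string (``"mean"``, ``"f(3)"`` or ``"fk:3"``) or constructed directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["Target", "mean_degree", "fk"]

_FK_RE = re.compile(r"^(?:f\((\d+)\)|fk:(\d+))$")


@dataclass(frozen=True)
class Target:
    kind: str  # "mean" or "fk"
    k: int | None = None

    def __post_init__(self):
        if self.kind not in ("mean", "fk"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "fk" and (self.k is None or self.k < 0):
            raise ValueError("fk target requires k ≥ 0")

    @classmethod
    def parse(cls, spec) -> "Target":
        if isinstance(spec, Target):
            return spec
        if spec == "mean":
            return cls("mean")
        m = _FK_RE.match(str(spec))
        if not m:
            raise ValueError(f"cannot parse target {spec!r}; use 'mean' or 'f(k)'")
        return cls("fk", int(m.group(1) or m.group(2)))

    def __str__(self) -> str:
        return "mean" if self.kind == "mean" else f"f({self.k})"

    # -- evaluation helpers ------------------------------------------------
    def true_value(self, model) -> float:
        """Population value under a degree model."""
        return model.mean() if self.kind == "mean" else float(model.pmf(self.k))

    def graph_value(self, graph) -> float:
        """Realised value on an observed graph."""
        degs = graph.degrees
        if self.kind == "mean":
            return float(degs.mean())
        return float(np.mean(degs == self.k))

    def from_degrees(self, degrees: np.ndarray) -> float:
        """Seeds-only point estimate from a plain degree sample."""
        degrees = np.asarray(degrees)
        if self.kind == "mean":
            return float(degrees.mean())
        return float(np.mean(degrees == self.k))


def mean_degree() -> Target:
    return Target("mean")


def fk(k: int) -> Target:
    return Target("fk", k)
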