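"""Simple-random-sampling competitor intervals for f(k).

Two baselines used to benchmark the patchwork bootstrap:

* NCI — the normality-based interval ``f̂(k) ± z·σ̂`` with the
  finite-population-corrected variance
  ``σ̂² = ((n − M)/n)·f̂(1 − f̂)/(M − 1)``.  It assumes the graph order n is
  known — an information advantage the patchwork method does not get.
* QCI — the Efron percentile interval of B with-replacement resamples of the
  M sampled degrees.

Endpoints are reported exactly as the formulas produce them (the NCI is not
truncated to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bootstrap import ConfidenceInterval, efron_ci
from .netgen import SimpleGraph

__all__ = ["SRSample", "srs_sample", "nci", "qci"]


@dataclass(frozen=True)
class SRSample:
    """Degrees of M vertices drawn uniformly without replacement; n is the
    (known) graph order."""

    degrees: np.ndarray
    n: int

    def __post_init__(self):
        if self.M > self.n:
            raise ValueError("sample size exceeds graph order")
        if self.M and int(np.min(self.degrees)) < 0:
            raise ValueError("degrees must be non-negative")

    @property
    def M(self) -> int:
        return len(self.degrees)


def srs_sample(graph: SimpleGraph, M: int, rng: np.random.Generator) -> SRSample:
    """Uniform without-replacement sample of M vertex degrees."""
    if not 1 <= M <= graph.n:
        raise ValueError(f"M={M} outside 1..{graph.n}")
    vertices = rng.choice(graph.n, size=M, replace=False)
    return SRSample(degrees=graph.degrees[vertices], n=graph.n)


def nci(sample: SRSample, k: int, alpha: float = 0.05) -> ConfidenceInterval:
    """Normal interval for f(k) with finite-population correction."""
    M, n = sample.M, sample.n
    if M < 2:
        raise ValueError("NCI variance requires M ≥ 2")
    fhat = float(np.mean(sample.degrees == k))
    var = ((n - M) / n) * fhat * (1.0 - fhat) / (M - 1)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return ConfidenceInterval(fhat - half, fhat + half, 1.0 - alpha, target=f"f({k})")


def qci(
    sample: SRSample, k: int, B: int, rng: np.random.Generator, alpha: float = 0.05
) -> ConfidenceInterval:
    """SRS quantile bootstrap interval for f(k) (Efron percentile rule)."""
    if B < 1:
        raise ValueError("B must be ≥ 1")
    M = sample.M
    resamples = rng.choice(sample.degrees, size=(B, M), replace=True)
    props = np.mean(resamples == k, axis=1)
    return efron_ci(props, alpha, target=f"f({k})")
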