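"""Weighted within-patch resampling and Efron percentile intervals.

Given an LSMI patch set, each bootstrap replicate redraws the observed seed
degrees uniformly with replacement and the pooled non-seed degree records
with replacement with probability proportional to 1/degree.  A non-seed is
reached along an edge, so its inclusion probability is proportional to its
degree; the inverse weighting removes that size bias (a Horvitz–Thompson
correction).  From the two resampled multisets the degree-distribution
estimator is

    f*(k) = ( #seeds*(k) + (1 − p0*) · #nonseeds*(k) ) / ( m + N ),  k ≥ 1,
    f*(0) = p0*  (the proportion of zeros among resampled seeds),

and the mean-degree estimator is mu* = Σ_k k·f*(k).  Confidence intervals are
Efron percentile intervals: empirical quantiles of the B replicate values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lsmi import PatchSet
from .targets import Target

__all__ = [
    "BootstrapSample",
    "ConfidenceInterval",
    "resample_patches",
    "f_star",
    "mu_star",
    "efron_ci",
]


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    target: str = ""

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class BootstrapSample:
    """B bootstrap replicates of the degree-distribution estimator.

    ``fk[b, k]`` is replicate b's estimate of f(k) on the grid 0..kmax (the
    largest degree observed in the patch-set view); each row is a probability
    vector.  ``combo`` records the (seeds, waves) view the sample came from.
    """

    fk: np.ndarray
    combo: tuple[int, int]

    @property
    def B(self) -> int:
        return self.fk.shape[0]

    @property
    def mean_degree(self) -> np.ndarray:
        """Per-replicate mu* = Σ k f*(k)."""
        return self.fk @ np.arange(self.fk.shape[1], dtype=float)

    def statistic(self, target) -> np.ndarray:
        """Per-replicate values of a target statistic."""
        target = Target.parse(target)
        if target.kind == "mean":
            return self.mean_degree
        if target.k >= self.fk.shape[1]:
            return np.zeros(self.B)
        return self.fk[:, target.k]


def _combine(seed_counts: np.ndarray, nonseed_counts: np.ndarray) -> np.ndarray:
    """Rows of f* from per-k seed and non-seed counts (vectorised over rows)."""
    m = seed_counts.sum(axis=1, keepdims=True).astype(float)
    n_ns = nonseed_counts.sum(axis=1, keepdims=True).astype(float)
    p0 = seed_counts[:, :1] / m
    fk = (seed_counts + (1.0 - p0) * nonseed_counts) / (m + n_ns)
    fk[:, 0] = p0[:, 0]
    return fk


def _count_rows(samples: np.ndarray, kmax: int) -> np.ndarray:
    """Per-row histogram of integer samples over 0..kmax."""
    B, width = samples.shape
    offsets = (np.arange(B) * (kmax + 1))[:, None]
    flat = (samples + offsets).ravel()
    return np.bincount(flat, minlength=B * (kmax + 1)).reshape(B, kmax + 1)


def f_star(seed_degrees: Sequence[int], nonseed_degrees: Sequence[int]) -> np.ndarray:
    """Degree-distribution estimate from one pair of resampled multisets."""
    s = np.asarray(seed_degrees, dtype=np.int64)
    ns = np.asarray(nonseed_degrees, dtype=np.int64)
    if s.size == 0:
        raise ValueError("seed multiset must be non-empty")
    if ns.size and ns.min() < 1:
        raise ValueError("non-seed records must have degree ≥ 1")
    kmax = int(max(s.max(), ns.max() if ns.size else 0))
    return _combine(
        _count_rows(s[None, :], kmax), _count_rows(ns[None, :], kmax) if ns.size else np.zeros((1, kmax + 1), dtype=np.int64)
    )[0]


def mu_star(seed_degrees: Sequence[int], nonseed_degrees: Sequence[int]) -> float:
    """Bootstrap mean-degree estimate; equals Σ k·f*(k)."""
    fk = f_star(seed_degrees, nonseed_degrees)
    return float(fk @ np.arange(fk.size, dtype=float))


def resample_patches(
    patchset_view: PatchSet,
    B: int,
    rng: np.random.Generator,
    weights: str = "inverse_degree",
) -> BootstrapSample:
    """Bootstrap a patch-set view: B replicates of the f*(k) vector.

    Per replicate, the m observed seed degrees are resampled uniformly with
    replacement, and the N pooled non-seed degree records are resampled with
    replacement with probability ∝ 1/degree (``weights="uniform"`` disables
    the correction, for ablation).  The replicate sizes m and N equal the
    observed counts, keeping the information volume fixed.
    """
    if B < 1:
        raise ValueError("B must be ≥ 1")
    if weights not in ("inverse_degree", "uniform"):
        raise ValueError(f"unknown weights {weights!r}")
    s = patchset_view.seed_degrees()
    if s.size == 0:
        raise ValueError("patch set has no seeds")
    ns = patchset_view.nonseed_degrees()
    if patchset_view.d_max > 0 and ns.size == 0:
        warnings.warn(
            "no non-seed records in a view with waves > 0; "
            "falling back to seeds-only resampling",
            RuntimeWarning,
        )
    kmax = int(max(s.max(), ns.max() if ns.size else 0))
    seed_samples = rng.choice(s, size=(B, s.size), replace=True)
    seed_counts = _count_rows(seed_samples, kmax)
    if ns.size:
        if weights == "inverse_degree":
            w = 1.0 / ns
            w /= w.sum()
            ns_samples = rng.choice(ns, size=(B, ns.size), replace=True, p=w)
        else:
            ns_samples = rng.choice(ns, size=(B, ns.size), replace=True)
        nonseed_counts = _count_rows(ns_samples, kmax)
    else:
        nonseed_counts = np.zeros((B, kmax + 1), dtype=np.int64)
    fk = _combine(seed_counts, nonseed_counts)
    return BootstrapSample(fk=fk, combo=(patchset_view.m, patchset_view.d_max))


def efron_ci(values, alpha: float = 0.05, target: str = "") -> ConfidenceInterval:
    """Efron percentile interval from bootstrap replicate values.

    Endpoints are the 1-based order statistics at ranks ceil(B·α/2) and
    ceil(B·(1−α/2)) of the sorted replicates.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    B = vals.size
    if B == 0:
        raise ValueError("empty bootstrap sample")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if B < 2.0 / alpha:
        warnings.warn(
            f"B={B} bootstrap replicates is small for alpha={alpha}; "
            "interval endpoints are extreme order statistics",
            RuntimeWarning,
        )
    lo_rank = max(1, int(np.ceil(B * alpha / 2.0)))
    hi_rank = max(1, int(np.ceil(B * (1.0 - alpha / 2.0))))
    return ConfidenceInterval(
        lower=float(vals[lo_rank - 1]),
        upper=float(vals[hi_rank - 1]),
        level=1.0 - alpha,
        target=target,
    )
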