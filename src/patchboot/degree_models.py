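"""Parametric degree laws used as ground truth and as network generators.

Two families drive the synthetic studies:

* zero-truncated Poisson ``ztp(rate)`` — the classical sparse-graph law with
  the zero class removed, ``f(k) = e^{-λ} λ^k / (k! (1 - e^{-λ}))`` for k ≥ 1;
* polylogarithmic ``polylog(exponent, scale)`` — a discrete law with a
  power-law body and geometric cutoff,
  ``f(k) = k^{-λ} z^k / Li_λ(z)`` with ``z = exp(-1/θ)``, k ≥ 1,

plus an ``empirical`` family (an explicit finite probability table) for
user-supplied degree distributions.  Both parametric families put no mass at
k = 0: they model networks whose isolated vertices have been removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["DegreeModel", "ztp", "polylog_model", "empirical_model", "polylog"]

#: absolute truncation error for the polylogarithm series
_LI_TOL = 1e-12
#: pmf tail mass beyond which the sampling table is truncated
_TAIL_MASS = 1e-10


def polylog(s: float, z: float, tol: float = _LI_TOL, max_terms: int = 10_000_000) -> float:
    """Polylogarithm ``Li_s(z) = Σ_{k≥1} z^k / k^s`` for 0 < z < 1.

    Direct series with Kahan compensated summation; terminates when an upper
    bound on the remaining tail (geometric for s ≥ 0, crude geometric bound
    after the term peak for s < 0) drops below ``tol``.
    """
    if not (0.0 < z < 1.0):
        raise ValueError(f"polylog series requires 0 < z < 1, got z={z}")
    log_z = math.log(z)
    total = 0.0
    comp = 0.0  # Kahan compensation
    for k in range(1, max_terms + 1):
        term = math.exp(k * log_z - s * math.log(k))
        y = term - comp
        t = total + y
        comp = (t - total) - y
        total = t
        # ratio of consecutive terms r_k = z·(k/(k+1))^s is < 1 and decreasing
        # towards z once k > -s/ln(1/z); then the tail is geometrically bounded
        ratio = z * ((k + 1.0) / k) ** (-s) if s < 0 else z
        if ratio < 1.0 and term * ratio / (1.0 - ratio) < tol:
            return total
    raise ArithmeticError("polylogarithm series did not converge")  # pragma: no cover


def _check_params(family: str, params: Sequence[float]) -> None:
    if family == "ztp":
        if len(params) != 1 or params[0] <= 0:
            raise ValueError(f"ztp requires a single rate λ > 0, got {params}")
    elif family == "polylog":
        if len(params) != 2 or params[0] < 0 or params[1] <= 0:
            raise ValueError(
                f"polylog requires exponent λ ≥ 0 and scale θ > 0, got {params}"
            )
    elif family == "empirical":
        p = np.asarray(params, dtype=float)
        if p.ndim != 1 or p.size == 0 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("empirical family requires a probability vector over k=0..K")
    else:
        raise ValueError(f"unknown degree-model family {family!r}")


@dataclass(frozen=True)
class DegreeModel:
    """A named parametric degree law: pmf, mean and random sampling.

    Parameters
    ----------
    family:
        ``"ztp"``, ``"polylog"`` or ``"empirical"``.
    params:
        ``ztp``: (rate λ,); ``polylog``: (exponent λ, scale θ) with
        ``z = exp(-1/θ)``; ``empirical``: probabilities for k = 0..K.
    """

    family: str
    params: tuple = field(default=())

    def __post_init__(self) -> None:
        _check_params(self.family, self.params)

    # -- pmf -------------------------------------------------------------
    def pmf(self, k) -> np.ndarray | float:
        """Probability of degree ``k`` (vectorised over integer arrays)."""
        karr = np.asarray(k)
        scalar = karr.ndim == 0
        karr = np.atleast_1d(karr).astype(int)
        if np.any(karr < 0):
            raise ValueError("degree must be a non-negative integer")
        if self.family == "ztp":
            (lam,) = self.params
            out = stats.poisson.pmf(karr, lam) / (1.0 - math.exp(-lam))
            out[karr == 0] = 0.0
        elif self.family == "polylog":
            lam, theta = self.params
            z = math.exp(-1.0 / theta)
            norm = polylog(lam, z)
            with np.errstate(divide="ignore"):
                out = np.where(
                    karr >= 1,
                    np.exp(
                        karr * math.log(z)
                        - lam * np.log(np.where(karr >= 1, karr, 1))
                    )
                    / norm,
                    0.0,
                )
        else:
            p = np.asarray(self.params, dtype=float)
            out = np.where(karr < p.size, p[np.minimum(karr, p.size - 1)], 0.0)
        return float(out[0]) if scalar else out

    # -- mean ------------------------------------------------------------
    def mean(self) -> float:
        """Population mean degree ``Σ k f(k)``."""
        if self.family == "ztp":
            (lam,) = self.params
            return lam / (1.0 - math.exp(-lam))
        if self.family == "polylog":
            lam, theta = self.params
            z = math.exp(-1.0 / theta)
            return polylog(lam - 1.0, z) / polylog(lam, z)
        p = np.asarray(self.params, dtype=float)
        return float(np.arange(p.size) @ p)

    # -- sampling --------------------------------------------------------
    def pmf_table(self, tail_mass: float = _TAIL_MASS) -> tuple[np.ndarray, np.ndarray]:
        """Support values and probabilities, truncated where the remaining
        tail mass falls below ``tail_mass`` (then renormalised)."""
        if self.family == "empirical":
            p = np.asarray(self.params, dtype=float)
            return np.arange(p.size), p / p.sum()
        kmax = 1
        while True:
            ks = np.arange(0, kmax + 1)
            probs = self.pmf(ks)
            if probs.sum() >= 1.0 - tail_mass:
                break
            kmax *= 2
            if kmax > 10**7:  # pragma: no cover - guards divergent laws
                raise ArithmeticError("pmf tail does not reach the requested mass")
        # trim to the first index where cumulative mass is achieved
        cum = np.cumsum(probs)
        stop = int(np.searchsorted(cum, 1.0 - tail_mass)) + 1
        ks, probs = ks[:stop], probs[:stop]
        return ks, probs / probs.sum()

    def sample_degrees(
        self, n: int, rng: np.random.Generator, even_sum: bool = True
    ) -> np.ndarray:
        """Draw ``n`` i.i.d. degrees via an inverse-CDF table.

        With ``even_sum=True`` (the pairing-model requirement) an odd total is
        repaired by redrawing one uniformly chosen entry from the same law
        until the total is even, which leaves the marginal law intact.
        """
        if n < 1:
            raise ValueError("n must be ≥ 1")
        ks, probs = self.pmf_table()
        seq = rng.choice(ks, size=n, p=probs)
        if even_sum:
            while seq.sum() % 2 == 1:
                i = rng.integers(n)
                seq[i] = rng.choice(ks, p=probs)
        return seq


def ztp(rate: float) -> DegreeModel:
    """Zero-truncated Poisson degree law with the given rate."""
    return DegreeModel("ztp", (rate,))


def polylog_model(exponent: float, scale: float) -> DegreeModel:
    """Polylogarithmic degree law ``f(k) ∝ k^{-exponent} e^{-k/scale}``, k ≥ 1."""
    return DegreeModel("polylog", (exponent, scale))


def empirical_model(probs: Sequence[float]) -> DegreeModel:
    """Finite probability table over degrees 0..K."""
    return DegreeModel("empirical", tuple(float(p) for p in probs))
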