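"""Monte-Carlo "range of spuriousness" for a necessity effect.

A nonzero CE-FDH necessity effect does not by itself show that X is necessary
for Y: an ordinary linear correlation between X and Y already produces empty
space in the upper-left corner of the scatter.  The range of spuriousness is
the null distribution of the necessity effect under exactly that alternative:
many synthetic datasets sharing only the sample size and the Pearson
correlation of the real data, each scored with CE-FDH, summarised by a
nonparametric percentile interval.  An observed effect that does not exceed
the interval is explainable by the correlation alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BivariateSample,
    ParameterError,
    cefdh_effect,
)

__all__ = [
    "SpuriousnessConfig",
    "SpuriousnessResult",
    "EffectClassification",
    "simulate_bivariate_normal",
    "range_of_spuriousness",
    "classify_effect",
]


@dataclass(frozen=True)
class SpuriousnessConfig:
    """Parameters of a range-of-spuriousness run.

    Parameters
    ----------
    n : int
        Sample size of each synthetic dataset (matches the empirical study).
    r : float
        Target population Pearson correlation, ``|r| < 1``.
    reps : int
        Number of synthetic datasets (default 1000).
    ci_level : float
        Coverage of the percentile interval (default 0.95).
    seed : int
        Master seed; replicate streams are derived from it per index.
    quantile_method : str
        Quantile estimator passed to :func:`numpy.quantile` (default
        ``"linear"``, interpolation of order statistics).
    """

    n: int
    r: float
    reps: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    quantile_method: str = "linear"

    def __post_init__(self):
        if self.n < 3:
            raise ParameterError(f"n must be >= 3, got {self.n}")
        if not abs(self.r) < 1:
            raise ParameterError(f"|r| must be < 1, got {self.r}")
        if self.reps < 2:
            raise ParameterError(f"reps must be >= 2, got {self.reps}")
        if not 0 < self.ci_level < 1:
            raise ParameterError(f"ci_level must be in (0, 1), got {self.ci_level}")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "reps": self.reps,
            "ci_level": self.ci_level,
            "seed": self.seed,
            "quantile_method": self.quantile_method,
        }


@dataclass(frozen=True)
class SpuriousnessResult:
    """Simulated necessity-effect distribution and its percentile bounds."""

    d_values: np.ndarray
    lower: float
    upper: float
    config: SpuriousnessConfig

    def to_dict(self, include_d_values: bool = False) -> dict:
        out = {
            "config": self.config.to_dict(),
            "lower": self.lower,
            "upper": self.upper,
            "d_mean": float(self.d_values.mean()),
            "d_median": float(np.median(self.d_values)),
            "d_min": float(self.d_values.min()),
            "d_max": float(self.d_values.max()),
        }
        if include_d_values:
            out["d_values"] = [float(v) for v in self.d_values]
        return out


@dataclass(frozen=True)
class EffectClassification:
    """Verdict on an observed effect relative to a range of spuriousness.

    ``below`` and ``within`` mean the effect is not significantly stronger
    than the X-Y correlation alone would produce; only ``above`` supports a
    necessity claim.  Equality with a bound counts as ``within``.
    """

    d_observed: float
    verdict: str  # "below" | "within" | "above"
    lower: float
    upper: float

    def to_dict(self) -> dict:
        return {
            "d_observed": self.d_observed,
            "verdict": self.verdict,
            "lower": self.lower,
            "upper": self.upper,
        }


def simulate_bivariate_normal(n: int, r: float, seed) -> BivariateSample:
    """Draw ``n`` pairs from a standard bivariate normal with correlation ``r``.

    Zero means, unit variances; the correlation matrix is applied through its
    Cholesky factor, so the population correlation is exactly ``r``.  ``seed``
    may be an integer or a :class:`numpy.random.SeedSequence` (the latter is
    used internally for per-replicate streams).  Identical ``(n, r, seed)``
    give identical samples.
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    if not abs(r) < 1:
        raise ParameterError(f"|r| must be < 1, got {r}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    # Cholesky factor of [[1, r], [r, 1]]
    x = z[:, 0]
    y = r * z[:, 0] + np.sqrt(1.0 - r * r) * z[:, 1]
    return BivariateSample(x, y)


def range_of_spuriousness(config: SpuriousnessConfig) -> SpuriousnessResult:
    """Compute the range of spuriousness for ``config``.

    Replicate ``i`` draws a fresh bivariate-normal dataset of size ``config.n``
    with correlation ``config.r`` from a stream derived from
    ``(config.seed, i)`` and scores it with CE-FDH.  The bounds are the
    empirical ``(1 - ci_level)/2`` and ``1 - (1 - ci_level)/2`` quantiles of
    the ``reps`` effect values.  Deterministic given the config.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.reps)
    d_values = np.empty(config.reps, dtype=float)
    for i, child in enumerate(children):
        sample = simulate_bivariate_normal(config.n, config.r, child)
        d_values[i] = cefdh_effect(sample).d
    d_values.flags.writeable = False
    alpha = 1.0 - config.ci_level
    lower, upper = np.quantile(
        d_values, [alpha / 2.0, 1.0 - alpha / 2.0], method=config.quantile_method
    )
    return SpuriousnessResult(
        d_values=d_values, lower=float(lower), upper=float(upper), config=config
    )


def classify_effect(d_observed: float, result: SpuriousnessResult) -> EffectClassification:
    """Classify ``d_observed`` against the range of spuriousness in ``result``."""
    if not 0.0 <= d_observed <= 1.0:
        raise ParameterError(f"d_observed must be in [0, 1], got {d_observed}")
    if d_observed < result.lower:
        verdict = "below"
    elif d_observed > result.upper:
        verdict = "above"
    else:
        verdict = "within"
    return EffectClassification(
        d_observed=d_observed, verdict=verdict, lower=result.lower, upper=result.upper
    )
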