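"""CE-FDH ceiling estimation and the necessity-effect permutation test.

Necessary condition analysis (NCA) asks whether a low value of a condition X
precludes a high value of an outcome Y.  Its effect size is the area of the
empty region in the upper-left corner of the X-Y scatter, expressed as a
fraction of the scope rectangle (X_max - X_min) x (Y_max - Y_min).  The
ceiling envelopment with free disposal hull (CE-FDH) technique realises that
empty region with a non-decreasing step function through the upper-left
frontier points ("peers") of the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BivariateSample",
    "CeilingResult",
    "PermutationResult",
    "NCAError",
    "DataError",
    "DegenerateScopeError",
    "ParameterError",
    "find_peers",
    "cefdh_effect",
    "permutation_test",
]


class NCAError(Exception):
    """Base class for all errors raised by this package."""


class DataError(NCAError):
    """Input data violate a structural requirement (length, finiteness, ...)."""


class DegenerateScopeError(NCAError):
    """The scope rectangle has zero area, so the necessity effect is undefined.

    Attributes
    ----------
    dimension : str
        Which dimension collapsed: ``"x"``, ``"y"`` or ``"both"``.
    """

    def __init__(self, dimension: str):
        self.dimension = dimension
        super().__init__(
            f"necessity effect undefined: all {dimension} values are identical, "
            "the scope rectangle has zero area"
        )


class ParameterError(NCAError, ValueError):
    """A configuration parameter is outside its admissible range."""


@dataclass(frozen=True)
class BivariateSample:
    """Paired observations of a condition ``x`` and an outcome ``y``.

    Values must be finite and the two vectors equal-length with at least two
    pairs.  Arrays are copied and made read-only on construction.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise DataError("x and y must be one-dimensional vectors")
        if x.shape[0] != y.shape[0]:
            raise DataError(
                f"x and y must have equal length (got {x.shape[0]} and {y.shape[0]})"
            )
        if x.shape[0] < 2:
            raise DataError(f"need at least 2 paired observations, got {x.shape[0]}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DataError("x and y must contain only finite values (no NaN/Inf)")
        x = x.copy()
        y = y.copy()
        x.flags.writeable = False
        y.flags.writeable = False
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.shape[0])

    @property
    def pearson_r(self) -> float:
        """Sample Pearson correlation between x and y."""
        return float(np.corrcoef(self.x, self.y)[0, 1])


@dataclass(frozen=True)
class CeilingResult:
    """CE-FDH ceiling of a sample and the necessity effect it implies.

    ``peers`` are the frontier points, strictly increasing in both x and y;
    ``ceiling_zone`` is the empty area between the step ceiling and the top of
    the scope; ``d = ceiling_zone / scope`` is the necessity effect.
    """

    peers: np.ndarray  # shape (k, 2), columns (x, y)
    ceiling_zone: float
    scope: float
    d: float

    def to_dict(self) -> dict:
        return {
            "peers": [[float(a), float(b)] for a, b in self.peers],
            "ceiling_zone": self.ceiling_zone,
            "scope": self.scope,
            "d": self.d,
        }


@dataclass(frozen=True)
class PermutationResult:
    """Permutation-test assessment of an observed necessity effect.

    ``p_value`` uses the add-one convention
    ``(1 + #{null_d >= d_observed}) / (1 + reps)`` so that p is never zero.
    """

    d_observed: float
    null_d: np.ndarray
    p_value: float
    reps: int
    seed: int

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "d_observed": self.d_observed,
            "p_value": self.p_value,
            "reps": self.reps,
            "seed": self.seed,
        }
        if include_null:
            out["null_d"] = [float(v) for v in self.null_d]
        return out


def find_peers(sample: BivariateSample) -> np.ndarray:
    """Return the upper-left frontier points of ``sample``.

    A point (xi, yi) is a peer iff no other observation (xj, yj) satisfies
    xj <= xi and yj >= yi with at least one inequality strict (weak dominance
    toward the upper left).  One representative is kept for duplicated points.

    Returns an array of shape (k, 2) sorted ascending in x; the peer y values
    are then strictly increasing as well.  Comparisons are exact: no epsilon
    is applied to floating-point ties.
    """
    x, y = sample.x, sample.y
    order = np.lexsort((-y, x))  # x ascending, y descending within ties
    xs, ys = x[order], y[order]
    keep = np.empty(xs.shape[0], dtype=bool)
    best = -np.inf
    for i in range(xs.shape[0]):
        keep[i] = ys[i] > best
        if keep[i]:
            best = ys[i]
    return np.column_stack((xs[keep], ys[keep]))


def cefdh_effect(sample: BivariateSample) -> CeilingResult:
    """Estimate the CE-FDH necessity effect of ``sample``.

    The step ceiling is ``ceiling(x) = max{y_i : peer i with x_i <= x}``; the
    ceiling zone is the exact area between the ceiling and the line
    ``y = Y_max`` over ``[X_min, X_max]``:

        C = sum_i (x_{i+1} - x_i) * (Y_max - y_i),   x_{k+1} := X_max

    and ``d = C / S`` with scope ``S = (X_max - X_min) * (Y_max - Y_min)``.

    Raises
    ------
    DegenerateScopeError
        If all x values or all y values coincide (zero-area scope).
    """
    x, y = sample.x, sample.y
    x_range = float(x.max() - x.min())
    y_range = float(y.max() - y.min())
    if x_range == 0.0 and y_range == 0.0:
        raise DegenerateScopeError("both x and y")
    if x_range == 0.0:
        raise DegenerateScopeError("x")
    if y_range == 0.0:
        raise DegenerateScopeError("y")

    peers = find_peers(sample)
    px, py = peers[:, 0], peers[:, 1]
    y_max = float(y.max())
    x_right = np.append(px[1:], float(x.max()))
    ceiling_zone = float(np.sum((x_right - px) * (y_max - py)))
    scope = x_range * y_range
    d = ceiling_zone / scope
    # clip away sign noise from cancellation; d is a ratio of exact areas
    d = min(max(d, 0.0), 1.0)
    return CeilingResult(peers=peers, ceiling_zone=ceiling_zone, scope=scope, d=d)


def permutation_test(sample: BivariateSample, reps: int, seed: int) -> PermutationResult:
    """Permutation test of the necessity effect of ``sample``.

    Each of ``reps`` null draws permutes y uniformly at random against the
    fixed x (destroying any dependence while preserving both marginals) and
    recomputes the CE-FDH effect.  Replicate-level RNG streams are derived
    from ``(seed, replicate index)``, so identical inputs give bit-identical
    results irrespective of execution order.
    """
    if reps < 1:
        raise ParameterError(f"reps must be >= 1, got {reps}")
    observed = cefdh_effect(sample)
    children = np.random.SeedSequence(seed).spawn(reps)
    null_d = np.empty(reps, dtype=float)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        permuted = BivariateSample(sample.x, rng.permutation(sample.y))
        null_d[i] = cefdh_effect(permuted).d
    null_d.flags.writeable = False
    p_value = (1 + int(np.sum(null_d >= observed.d))) / (1 + reps)
    return PermutationResult(
        d_observed=observed.d, null_d=null_d, p_value=p_value, reps=reps, seed=seed
    )
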