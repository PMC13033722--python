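"""Model/Results interface over the CE-FDH estimator.

``NecessityAnalysis`` is built from paired (x, y) data; ``fit()`` estimates
the CE-FDH ceiling and returns a ``NecessityResults`` object carrying the
effect size, the frontier, and methods for the permutation test, the range of
spuriousness and a text summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    BivariateSample,
    CeilingResult,
    PermutationResult,
    cefdh_effect,
    permutation_test,
)
from .spuriousness import (
    EffectClassification,
    SpuriousnessConfig,
    SpuriousnessResult,
    classify_effect,
    range_of_spuriousness,
)

__all__ = ["NecessityAnalysis", "NecessityResults"]


class NecessityAnalysis:
    """Necessary condition analysis of an outcome y on a condition x.

    Parameters
    ----------
    x, y : array_like
        Paired observations of the condition and the outcome.

    Examples
    --------
    >>> res = NecessityAnalysis([1, 2, 3, 4], [1, 3, 2, 4]).fit()
    >>> round(res.d, 4)
    0.5556
    """

    def __init__(self, x, y):
        self.sample = BivariateSample(np.asarray(x, dtype=float), np.asarray(y, dtype=float))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, x: str, y: str) -> "NecessityAnalysis":
        """Build the model from two named columns of a DataFrame.

        Rows with a missing value in either column are dropped listwise.
        """
        from .io import sample_from_frame

        sample, _ = sample_from_frame(data, x, y)
        model = cls.__new__(cls)
        model.sample = sample
        return model

    @property
    def nobs(self) -> int:
        return self.sample.n

    def fit(self) -> "NecessityResults":
        """Estimate the CE-FDH ceiling and necessity effect."""
        return NecessityResults(self, cefdh_effect(self.sample))


class NecessityResults:
    """CE-FDH fit of a :class:`NecessityAnalysis`.

    Attributes
    ----------
    d : float
        Necessity effect, the ceiling zone as a fraction of the scope.
    ceiling_zone, scope : float
        Empty upper-left area and the area of the scope rectangle.
    peers : ndarray of shape (k, 2)
        Frontier points, strictly increasing in x and in y.
    """

    def __init__(self, model: NecessityAnalysis, ceiling: CeilingResult):
        self.model = model
        self.ceiling = ceiling

    @property
    def d(self) -> float:
        return self.ceiling.d

    @property
    def ceiling_zone(self) -> float:
        return self.ceiling.ceiling_zone

    @property
    def scope(self) -> float:
        return self.ceiling.scope

    @property
    def peers(self) -> np.ndarray:
        return self.ceiling.peers

    @property
    def nobs(self) -> int:
        return self.model.sample.n

    @property
    def corr(self) -> float:
        """Sample Pearson correlation of the underlying data."""
        return self.model.sample.pearson_r

    def permutation_test(self, reps: int = 1000, seed: int = 0) -> PermutationResult:
        """Permutation test of the effect (y permuted against fixed x)."""
        return permutation_test(self.model.sample, reps=reps, seed=seed)

    def spuriousness(
        self,
        reps: int = 1000,
        ci_level: float = 0.95,
        seed: int = 0,
        r: float | None = None,
    ) -> SpuriousnessResult:
        """Range of spuriousness at this sample's size and correlation.

        ``r`` defaults to the sample Pearson correlation, mirroring the check
        "could this effect arise from the correlation alone?".
        """
        config = SpuriousnessConfig(
            n=self.nobs,
            r=self.corr if r is None else r,
            reps=reps,
            ci_level=ci_level,
            seed=seed,
        )
        return range_of_spuriousness(config)

    def classify(self, spur: SpuriousnessResult) -> EffectClassification:
        """Verdict of this fit's effect against a range of spuriousness."""
        return classify_effect(self.d, spur)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        rows = [
            ("No. observations", f"{self.nobs:d}"),
            ("No. peers", f"{self.peers.shape[0]:d}"),
            ("Ceiling zone (C)", f"{self.ceiling_zone:.4f}"),
            ("Scope (S)", f"{self.scope:.4f}"),
            ("Necessity effect d", f"{self.d:.4f}"),
            ("Pearson r", f"{self.corr:.4f}"),
        ]
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Necessary Condition Analysis (CE-FDH)", "=" * 38]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<NecessityResults d={self.d:.4f} n={self.nobs}>"
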