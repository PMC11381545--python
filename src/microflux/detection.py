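"""Detection-limit model: gamma fit to pooled log2 per-million abundances.

Whether a species counts as "present" in a sample depends on the
sequencing depth, so presence is called against a data-driven detection
threshold rather than abundance > 0.  All nonzero abundances in the
cohort are pooled, log2-transformed on the per-million scale, and fitted
with a maximum-likelihood gamma distribution; the threshold is the
distribution's lower quantile (1% by default) and a species is present
only when its log2 per-million abundance strictly exceeds it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AbundanceMatrix, PresenceMatrix

MIN_FIT_VALUES = 100


class GammaDetectionModel(BaseEstimator, TransformerMixin):
    """Gamma detection threshold on pooled log2 per-million abundances.

    Parameters
    ----------
    percentile : float in (0, 1)
        Lower quantile of the fitted gamma distribution used as the
        presence threshold (default 0.01, i.e. the 1st percentile).

    Attributes
    ----------
    gamma_shape_, gamma_rate_ : float
        Maximum-likelihood gamma parameters (rate = 1/scale).
    threshold_ : float
        Presence threshold on the log2 per-million scale.
    n_fit_values_ : int
        Number of pooled positive log2 values used in the fit.

    Notes
    -----
    The gamma support is (0, inf): nonzero abundances whose log2
    per-million value is <= 0 are excluded from the fit.  They can still
    never exceed a positive threshold, so calling stays conservative.
    """

    def __init__(self, percentile: float = 0.01):
        self.percentile = percentile

    def fit(self, X, y=None):
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must lie in (0, 1)")
        values = self._pooled_log2(X)
        values = values[values > 0]
        if values.size < MIN_FIT_VALUES:
            raise ValueError(
                f"need >= {MIN_FIT_VALUES} positive pooled log2 values to fit the "
                f"detection model, got {values.size}; generate a larger cohort "
                "(e.g. with microflux.synthetic)"
            )
        if np.ptp(values) == 0:
            raise ValueError("degenerate abundance data: all pooled values identical")
        shape, _, scale = stats.gamma.fit(values, floc=0)
        self.gamma_shape_ = float(shape)
        self.gamma_rate_ = float(1.0 / scale)
        self.threshold_ = float(stats.gamma.ppf(self.percentile, shape, scale=scale))
        self.n_fit_values_ = int(values.size)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Binary presence calls: log2 per-million abundance > threshold."""
        if not hasattr(self, "threshold_"):
            raise ValueError("GammaDetectionModel is not fitted")
        values = X.values if isinstance(X, AbundanceMatrix) else pd.DataFrame(X)
        with np.errstate(divide="ignore"):
            log2 = np.log2(values.where(values > 0))
        return (log2 > self.threshold_).fillna(False).astype(bool)

    def quantile(self, percentile: float) -> float:
        """Threshold the fitted model implies at another percentile."""
        return float(
            stats.gamma.ppf(percentile, self.gamma_shape_, scale=1.0 / self.gamma_rate_)
        )

    @staticmethod
    def _pooled_log2(X) -> np.ndarray:
        values = X.values if isinstance(X, AbundanceMatrix) else pd.DataFrame(X)
        arr = values.to_numpy(dtype=float).ravel()
        arr = arr[arr > 0]
        return np.log2(arr)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "gamma_shape": self.gamma_shape_,
                "gamma_rate": self.gamma_rate_,
                "percentile": self.percentile,
                "threshold": self.threshold_,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GammaDetectionModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        model = cls(percentile=d["percentile"])
        model.gamma_shape_ = d["gamma_shape"]
        model.gamma_rate_ = d["gamma_rate"]
        model.threshold_ = d["threshold"]
        model.n_fit_values_ = -1
        return model


def fit_detection_model(abundances: AbundanceMatrix, percentile: float = 0.01) -> GammaDetectionModel:
    """Fit the pooled gamma detection model to a cohort's abundances."""
    return GammaDetectionModel(percentile=percentile).fit(abundances)


def call_presence(abundances: AbundanceMatrix, model: GammaDetectionModel) -> PresenceMatrix:
    """Apply a fitted detection model, keeping the sample metadata attached."""
    return PresenceMatrix(model.transform(abundances), abundances.metadata)
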