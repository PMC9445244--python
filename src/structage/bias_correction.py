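"""Age-dependent prediction-bias correction.

Brain-age regressors systematically overestimate young and underestimate
old subjects (regression to the mean).  The bias is estimated on validation
residuals (predicted - true age) with a LOWESS smoother against true age,
and the resulting curve is parametrized by a cubic smoothing spline
(smoothing parameter 0.1) for fast evaluation.  Outside the validation age
range the bias is clamped to its boundary values.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .gcnn import AgePrediction

__all__ = ["BiasModel", "fit_bias", "apply_bias"]

MIN_VALIDATION_PAIRS = 30


@dataclass
class BiasModel:
    """Per-structure residual-vs-age correction curve."""

    structure_config: str
    lowess_points: np.ndarray  # (n, 2): (age, bias years)
    smoothing_param: float
    age_range: tuple[float, float]
    spline: BSpline | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self.spline is not None

    def bias(self, age: float | np.ndarray) -> np.ndarray:
        """Expected prediction error (years) at the given reference age,
        clamped to the fitted age range."""
        if not self.is_fitted:
            raise RuntimeError("bias model is not fitted")
        a = np.clip(np.asarray(age, dtype=np.float64), *self.age_range)
        return self.spline(a)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "BiasModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a BiasModel")
        return model


def fit_bias(
    true_ages: np.ndarray,
    predicted_ages: np.ndarray,
    structure_config: str = "structure",
    lowess_frac: float = 0.3,
    lowess_it: int = 2,
    smoothing_param: float = 0.1,
) -> BiasModel:
    """Fit the bias curve from validation (true age, raw prediction) pairs.

    Residuals r = predicted - true are LOWESS-smoothed against true age
    (fraction 0.3, 2 robustness iterations); the smooth curve is then fit
    with a cubic smoothing spline (penalty 0.1).
    """
    t = np.asarray(true_ages, dtype=np.float64)
    p = np.asarray(predicted_ages, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError("true and predicted age arrays must align")
    if t.size < MIN_VALIDATION_PAIRS:
        raise ValueError(
            f"need >= {MIN_VALIDATION_PAIRS} validation pairs, got {t.size}"
        )
    resid = p - t
    curve = lowess(resid, t, frac=lowess_frac, it=lowess_it, return_sorted=True)
    # collapse duplicate ages (spline abscissae must be strictly increasing)
    ages, idx = np.unique(curve[:, 0], return_index=True)
    vals = np.array([curve[curve[:, 0] == a, 1].mean() for a in ages])
    if ages.size < 4:  # not enough distinct ages for a cubic spline
        vals_c = float(vals.mean())
        ages = np.array([t.min() - 1, t.min(), t.max(), t.max() + 1])
        vals = np.full(4, vals_c)
    spline = make_smoothing_spline(ages, vals, lam=smoothing_param)
    return BiasModel(
        structure_config=structure_config,
        lowess_points=np.column_stack([ages, vals]),
        smoothing_param=smoothing_param,
        age_range=(float(ages.min()), float(ages.max())),
        spline=spline,
    )


def apply_bias(
    model: BiasModel,
    prediction: AgePrediction | float,
    reference_age: float | None = None,
) -> float:
    """Corrected age = raw aggregated estimate - bias(reference age).

    ``reference_age`` defaults to the raw predicted age itself (in
    deployment the true age is the unknown being estimated); pass the true
    age explicitly for evaluation-style plots.
    """
    if not model.is_fitted:
        raise RuntimeError("bias model is not fitted")
    raw = prediction.aggregated if isinstance(prediction, AgePrediction) else float(prediction)
    ref = raw if reference_age is None else float(reference_age)
    corrected = float(raw - model.bias(ref))
    if isinstance(prediction, AgePrediction):
        prediction.corrected = corrected
    return corrected
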