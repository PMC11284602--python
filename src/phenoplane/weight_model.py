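"""Fruit-area to fresh-weight regression.

The default functional form is a simple ordinary-least-squares line
weight = slope * area + intercept; a log-log power-law variant is available
behind the ``form`` flag.  Predictions are floored at 0 g.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFit

__all__ = ["WeightModel", "fit_weight_model", "predict_weight"]


@dataclass(frozen=True)
class WeightModel:
    slope: float       # g per cm^2 (or log-log exponent)
    intercept: float   # g (or log-g offset)
    r_squared: float
    n: int
    form: str = "linear"

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must be in [0, 1]")
        if self.form not in ("linear", "loglog"):
            raise ValueError(f"unknown form {self.form!r}")

    def to_json(self) -> str:
        return json.dumps({
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "n": self.n, "form": self.form,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "WeightModel":
        p = json.loads(text)
        return cls(slope=p["slope"], intercept=p["intercept"],
                   r_squared=p["r_squared"], n=int(p["n"]),
                   form=p.get("form", "linear"))


def fit_weight_model(areas, weights, form: str = "linear") -> WeightModel:
    """OLS fit of fresh weight (g) on fruit area (cm^2).

    ``r_squared`` is 1 - SSres/SStot.  Raises :class:`DegenerateFit` for
    constant areas (no slope identifiable).
    """
    x = np.asarray(areas, dtype=float)
    y = np.asarray(weights, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("areas and weights must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise DegenerateFit("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if form == "loglog":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-log fit requires positive areas and weights")
        x, y = np.log(x), np.log(y)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise DegenerateFit("all areas are equal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    residuals = y - (slope * x + intercept)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = float(min(max(r2, 0.0), 1.0))
    return WeightModel(slope=slope, intercept=intercept, r_squared=r2,
                       n=n, form=form)


def predict_weight(model: WeightModel, area: float) -> float:
    """Predicted fresh weight in grams, floored at 0."""
    if not area >= 0:
        raise ValueError("area must be non-negative")
    if model.form == "loglog":
        if area == 0:
            return 0.0
        return float(np.exp(model.intercept + model.slope * np.log(area)))
    return max(0.0, model.slope * area + model.intercept)
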