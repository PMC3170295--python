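"""Per-population regression fits.

Three ordinary-least-squares models are fitted to each simulated
population, all with the log GHQ-12 Likert score as the dependent
variable:

* ``LOG_RATIO`` — one predictor, the log-transformed ERI ratio;
* ``RATIO`` — one predictor, the untransformed ERI ratio;
* ``EFFORT_REWARD`` — two predictors, the effort and reward scores.

Each fit records the unadjusted R^2 and, per predictor, the coefficient
and the two-sided t-test p-value (n - k - 1 residual degrees of freedom,
intercept always included).  A coefficient is "significant" when
p < 0.05 strictly.  For the two-predictor model the joint indicator
``both_significant`` is also recorded.

A population whose predictor has zero variance (possible only under
point-mass marginals) cannot be fitted; it yields a flagged result with
``excluded=True`` and NaN statistics rather than an exception, so a grid
run survives it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ModelId", "RegressionResult", "build_design", "fit_linear_model", "ALL_MODELS"]

SIGNIFICANCE_LEVEL = 0.05


class ModelId(str, Enum):
    LOG_RATIO = "LOG_RATIO"
    RATIO = "RATIO"
    EFFORT_REWARD = "EFFORT_REWARD"


ALL_MODELS = (ModelId.LOG_RATIO, ModelId.RATIO, ModelId.EFFORT_REWARD)

_PREDICTORS: dict[ModelId, tuple[str, ...]] = {
    ModelId.LOG_RATIO: ("log_eri_ratio",),
    ModelId.RATIO: ("eri_ratio",),
    ModelId.EFFORT_REWARD: ("effort", "reward"),
}


def predictor_names(model_id: ModelId) -> tuple[str, ...]:
    return _PREDICTORS[ModelId(model_id)]


@dataclass(frozen=True)
class RegressionResult:
    model_id: ModelId
    r_squared: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    significant: dict[str, bool]
    both_significant: bool | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.excluded:
            if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
                raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
            for name, p in self.p_values.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"p-value for {name!r} outside [0, 1]")


def build_design(scored: pd.DataFrame, model_id: ModelId) -> tuple[np.ndarray, np.ndarray]:
    """Dependent vector (log GHQ score) and predictor matrix for one model.

    ``scored`` is the frame produced by
    :func:`nabiassim.instruments.score_population`; the log transforms are
    taken from it, so the GHQ offset applied at scoring time carries
    through.
    """
    model_id = ModelId(model_id)
    if len(scored) == 0:
        raise ValueError("empty scored collection")
    required = {"log_ghq", *_PREDICTORS[model_id]}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"scored frame missing columns: {sorted(missing)}")
    y = scored["log_ghq"].to_numpy(dtype=float)
    X = scored[list(_PREDICTORS[model_id])].to_numpy(dtype=float)
    return y, X


def fit_linear_model(y: np.ndarray, X: np.ndarray, model_id: ModelId) -> RegressionResult:
    """OLS of y on X with intercept; R^2 unadjusted, p-values two-sided t."""
    model_id = ModelId(model_id)
    names = _PREDICTORS[model_id]
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(names):
        raise ValueError(f"{model_id.value} expects {len(names)} predictors, got {X.shape[1]}")
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    k = X.shape[1]
    if y.shape[0] < k + 2:
        raise ValueError(f"need at least {k + 2} observations for {k} predictor(s)")

    if np.any(np.ptp(X, axis=0) == 0):
        nan = {name: float("nan") for name in names}
        return RegressionResult(
            model_id=model_id,
            r_squared=float("nan"),
            coefficients=dict(nan),
            p_values=dict(nan),
            significant={name: False for name in names},
            both_significant=False if model_id is ModelId.EFFORT_REWARD else None,
            excluded=True,
        )

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design: predictors are perfectly collinear")
    fit = sm.OLS(y, design).fit()
    coefs = {name: float(fit.params[i + 1]) for i, name in enumerate(names)}
    pvals = {name: float(fit.pvalues[i + 1]) for i, name in enumerate(names)}
    signif = {name: p < SIGNIFICANCE_LEVEL for name, p in pvals.items()}
    both = all(signif.values()) if model_id is ModelId.EFFORT_REWARD else None
    return RegressionResult(
        model_id=model_id,
        r_squared=float(fit.rsquared),
        coefficients=coefs,
        p_values=pvals,
        significant=signif,
        both_significant=both,
    )
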