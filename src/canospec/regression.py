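"""Simple linear and quadratic regression with significance stars.

Index–trait and green-fraction–trait relationships are evaluated by
ordinary least squares; the coefficient of determination R² and a
significance annotation at the nominal alpha levels 0.05 / 0.01 / 0.001
(*, **, ***; ns otherwise) summarize each relationship.  The quadratic form
exists for green-fraction relationships, which become curvilinear once
canopy cover passes roughly 45 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegressionResult", "fit_linear", "fit_quadratic", "stars_for", "results_table"]

ALPHA_CUTS = (0.05, 0.01, 0.001)


def stars_for(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    stars: str
    n: int
    model_form: Literal["linear", "quadratic"]
    quad_coef: float | None = None  # x² coefficient, quadratic form only

    def annotate(self, digits: int = 2) -> str:
        """Cell text in the reporting-table style, e.g. ``0.61***``."""
        star = "" if self.stars == "ns" else self.stars
        return f"{self.r2:.{digits}f}{star or ' ns'}"


def _validate_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: x is constant")
    return x, y


def fit_linear(x, y) -> RegressionResult:
    """Least-squares line with R² and the two-sided slope t-test (n − 2 df)."""
    x, y = _validate_xy(x, y, 3)
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        p_value=float(res.pvalue),
        stars=stars_for(float(res.pvalue)),
        n=x.size,
        model_form="linear",
    )


def fit_quadratic(x, y) -> RegressionResult:
    """Least-squares fit of y on (x, x²); p-value from the overall F test."""
    x, y = _validate_xy(x, y, 4)
    X = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate regression: design matrix rank-deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("degenerate regression: y is constant")
    r2 = 1.0 - sse / sst
    df_model, df_resid = 2, x.size - 3
    if df_resid <= 0:
        raise ValueError("not enough observations for the quadratic F test")
    if sse == 0:
        p = 0.0
    else:
        f_stat = ((sst - sse) / df_model) / (sse / df_resid)
        p = float(stats.f.sf(f_stat, df_model, df_resid))
    return RegressionResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=float(r2),
        p_value=p,
        stars=stars_for(p),
        n=x.size,
        model_form="quadratic",
        quad_coef=float(beta[2]),
    )


def results_table(
    data: pd.DataFrame,
    predictors: list[str],
    traits: list[str],
    by: str | None = "date_id",
    quadratic_for: tuple[str, ...] = (),
) -> pd.DataFrame:
    """R²-with-stars table: rows = predictors, columns = trait × date.

    ``by=None`` pools all rows; otherwise per-group columns plus an "All"
    column per trait are produced.  Predictors named in ``quadratic_for``
    additionally get a ``<predictor> (quad)`` row.
    """
    groups: list[tuple[str, pd.DataFrame]] = []
    if by is not None:
        groups.extend((str(g), sub) for g, sub in data.groupby(by, sort=True))
    groups.append(("All", data))

    rows = {}
    for pred in predictors:
        forms = [("linear", pred, fit_linear)]
        if pred in quadratic_for:
            forms.append(("quadratic", f"{pred} (quad)", fit_quadratic))
        for _, label, fitter in forms:
            cells = {}
            for trait in traits:
                for gname, sub in groups:
                    key = f"{trait}|{gname}"
                    try:
                        cells[key] = fitter(sub[pred], sub[trait]).annotate()
                    except ValueError:
                        cells[key] = "—"
            rows[label] = cells
    return pd.DataFrame.from_dict(rows, orient="index")
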