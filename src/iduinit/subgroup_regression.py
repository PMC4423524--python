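"""Precision-weighted regression of log EFR rates on subgroup covariates.

The 12 sex x career-bin x incarceration subgroups give one point each:
response ln(lambda_EFR), design indicators for male, career 6-10, career
>=11 and ever-incarcerated (baselines female / 0-5 / never), and weights
equal to the bootstrap precision 1 / Var(ln lambda) of each subgroup.
Inference is standard weighted least squares with the t distribution on
n - p degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .efr_estimation import EFREstimate

__all__ = ["TERMS", "RegressionResult", "build_design", "wls_fit", "fit_subgroups"]

TERMS = ("intercept", "male", "career_6_10", "career_ge11", "ever_prison")


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    weights_used: dict[str, float]
    n_points: int
    df_resid: int


def build_design(
    estimates: Sequence[EFREstimate],
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Response, design matrix and precision weights from subgroup estimates.

    Every estimate must carry a positive rate and a positive log-scale
    bootstrap variance; a zero rate has no finite log and the caller is told
    to exclude or merge that subgroup rather than have it dropped silently.
    """
    if not estimates:
        raise ValueError("no subgroup estimates supplied")
    rows, y, w, labels = [], [], [], []
    for est in estimates:
        if est.key.sex is None or est.key.career_bin is None or est.key.prison is None:
            raise ValueError(
                f"subgroup {est.key.label()!r} must be fully classified by "
                f"sex, career bin and prison history"
            )
        if not est.lambda_efr > 0.0:
            raise ValueError(
                f"subgroup {est.key.label()!r} has lambda_EFR = 0: ln(lambda) "
                f"is undefined; exclude this subgroup or merge it with a "
                f"neighbour before regressing"
            )
        if est.log_lambda_var is None or not est.log_lambda_var > 0.0:
            raise ValueError(
                f"subgroup {est.key.label()!r} lacks a positive bootstrap "
                f"variance of ln(lambda); run the bootstrap first"
            )
        rows.append(
            [
                1.0,
                1.0 if est.key.sex == "M" else 0.0,
                1.0 if est.key.career_bin == "6-10" else 0.0,
                1.0 if est.key.career_bin == ">=11" else 0.0,
                1.0 if est.key.prison == "ever" else 0.0,
            ]
        )
        y.append(np.log(est.lambda_efr))
        w.append(1.0 / est.log_lambda_var)
        labels.append(est.key.label())
    design = pd.DataFrame(rows, columns=TERMS, index=labels)
    return np.asarray(y), design, np.asarray(w)


def _collinear_terms(design: pd.DataFrame) -> list[str]:
    """Name the design columns involved in a rank deficiency (QR pivoting)."""
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank >= x.shape[1]:
        return []
    from scipy.linalg import qr

    _, r, piv = qr(x, pivoting=True)
    dropped = piv[rank:]
    return sorted(design.columns[i] for i in dropped)


def wls_fit(
    response: np.ndarray, design: pd.DataFrame, weights: np.ndarray
) -> RegressionResult:
    """Weighted least squares with t-based inference on n - p df.

    Coefficients solve the weighted normal equations; standard errors use
    the weighted residual variance.  Scaling all weights by a constant
    leaves everything invariant.
    """
    y = np.asarray(response, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0.0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    if len(y) <= design.shape[1]:
        raise ValueError(
            f"need more points ({len(y)}) than terms ({design.shape[1]})"
        )
    bad = _collinear_terms(design)
    if bad:
        raise ValueError(f"design is rank deficient; collinear terms: {bad}")
    model = sm.WLS(y, design.to_numpy(), weights=w)
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    terms = list(design.columns)
    return RegressionResult(
        coefficients={t: float(res.params[i]) for i, t in enumerate(terms)},
        standard_errors={t: float(res.bse[i]) for i, t in enumerate(terms)},
        p_values={t: float(res.pvalues[i]) for i, t in enumerate(terms)},
        conf_int={t: (float(ci[i, 0]), float(ci[i, 1])) for i, t in enumerate(terms)},
        weights_used={lab: float(wt) for lab, wt in zip(design.index, w)},
        n_points=len(y),
        df_resid=int(res.df_resid),
    )


def fit_subgroups(estimates: Sequence[EFREstimate]) -> RegressionResult:
    """Convenience: build the design from subgroup estimates and fit."""
    y, x, w = build_design(estimates)
    return wls_fit(y, x, w)
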