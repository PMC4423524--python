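"""Piecewise-constant per-annum first-incarceration model.

The career year of first incarceration, X, follows a discrete piecewise
geometric law: a per-annum incarceration probability p1 in career years
1-5, p2 in years 6-10 and p3 thereafter, so the survival function is

    P(X > t) = (1-p1)^t                                 0 <= t <= 5
             = (1-p1)^5 (1-p2)^(t-5)                    5 <  t <= 10
             = (1-p1)^5 (1-p2)^5 (1-p3)^(t-10)          t  > 10

A cross-sectional survey observes, for each respondent, the career length
t at interview and whether first incarceration has already happened
(ever = X <= t).  The likelihood is a product of P(X <= t)^m_t P(X > t)^n_t
over career lengths, maximised here by cyclic one-dimensional ascent with
profile-likelihood confidence intervals at the chi-square(1) cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "IncarcerationRates",
    "IncarcerationFit",
    "survival_X",
    "pmf_X",
    "log_likelihood",
    "fit_incarceration",
    "never_incarcerated_curve",
]

_P_LO = 1e-6
_P_HI = 1.0 - 1e-6
# chi-square(1) 95% quantile / 2: profile log-likelihood drop for the CI
_PROFILE_CUT = 1.9207294


class IncarcerationRates(NamedTuple):
    """Per-annum first-incarceration probabilities for career years 1-5,
    6-10 and >=11."""

    p1: float
    p2: float
    p3: float


@dataclass
class IncarcerationFit:
    rates: IncarcerationRates
    log_likelihood: float
    profile_cis: tuple[tuple[float, float], ...]
    n_ever: int
    n_never: int
    converged: bool
    flags: list[str] = field(default_factory=list)


def _check_t(t) -> int:
    if isinstance(t, float) and not t.is_integer():
        raise ValueError(f"career years must be whole, got {t}")
    t = int(t)
    if t < 0:
        raise ValueError(f"career years must be >= 0, got {t}")
    return t


def survival_X(t, rates: IncarcerationRates) -> float:
    """P(X > t): probability of never having been incarcerated by career
    year t."""
    t = _check_t(t)
    p1, p2, p3 = rates
    if t <= 5:
        return (1.0 - p1) ** t
    if t <= 10:
        return (1.0 - p1) ** 5 * (1.0 - p2) ** (t - 5)
    return (1.0 - p1) ** 5 * (1.0 - p2) ** 5 * (1.0 - p3) ** (t - 10)


def pmf_X(x, rates: IncarcerationRates) -> float:
    """P(X = x) for whole career years x >= 1."""
    x = _check_t(x)
    if x < 1:
        raise ValueError(f"first-incarceration year must be >= 1, got {x}")
    return survival_X(x - 1, rates) - survival_X(x, rates)


def _counts(
    career_years: np.ndarray, ever: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin respondents into (t, m_t ever, n_t never) count triples."""
    career_years = np.asarray(career_years, dtype=int)
    ever = np.asarray(ever, dtype=bool)
    if career_years.size == 0:
        raise ValueError("no records")
    if np.any(career_years < 0):
        raise ValueError("career_years must be >= 0")
    if np.any(ever & (career_years == 0)):
        raise ValueError(
            "impossible observation: ever incarcerated with career length 0 "
            "(the model assigns P(X <= 0) = 0)"
        )
    t_max = int(career_years.max())
    m = np.bincount(career_years[ever], minlength=t_max + 1)
    n = np.bincount(career_years[~ever], minlength=t_max + 1)
    t = np.arange(t_max + 1)
    keep = (m + n) > 0
    return t[keep], m[keep], n[keep]


def _loglik_counts(t: np.ndarray, m: np.ndarray, n: np.ndarray, rates) -> float:
    p1, p2, p3 = rates
    # log S(t) is piecewise-linear in the three log(1-p_k)
    a1 = np.minimum(t, 5)
    a2 = np.clip(t - 5, 0, 5)
    a3 = np.maximum(t - 10, 0)
    log_s = np.zeros_like(t, dtype=float)
    with np.errstate(invalid="ignore"):
        for a, p in ((a1, p1), (a2, p2), (a3, p3)):
            lp = np.log1p(-p) if p < 1.0 else -np.inf
            log_s = log_s + np.where(a > 0, a * lp, 0.0)
    s = np.exp(log_s)
    out = 0.0
    # never-incarcerated terms: n_t * log S(t)
    nz = n > 0
    if np.any(nz & np.isneginf(log_s)):
        return -np.inf
    out += float(np.sum(n[nz] * log_s[nz]))
    # ever terms: m_t * log(1 - S(t)); impossible when S(t) = 1
    mz = m > 0
    if np.any(mz & (s >= 1.0)):
        return -np.inf
    out += float(np.sum(m[mz] * np.log1p(-s[mz])))
    return out


def log_likelihood(records, rates: IncarcerationRates) -> float:
    """Log-likelihood of (career_years, ever_incarcerated) data.

    ``records`` is a DataFrame with those columns or a sequence of
    (career_years, ever) pairs.  Returns -inf where the data are impossible
    under ``rates`` (someone ever-incarcerated at a career length the model
    gives survival 1).
    """
    career, ever = _extract(records)
    t, m, n = _counts(career, ever)
    return _loglik_counts(t, m, n, tuple(rates))


def _extract(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return (
            records["career_years"].to_numpy(),
            records["ever_incarcerated"].to_numpy(),
        )
    pairs = list(records)
    career = np.array([p[0] for p in pairs])
    ever = np.array([bool(p[1]) for p in pairs])
    return career, ever


def _ascend(
    t: np.ndarray,
    m: np.ndarray,
    n: np.ndarray,
    start: Sequence[float],
    free: Sequence[bool] = (True, True, True),
    tol: float = 1e-9,
    max_cycles: int = 200,
) -> tuple[list[float], float]:
    """Cyclic coordinate-wise 1-D maximisation of the log-likelihood."""
    p = list(start)
    best = _loglik_counts(t, m, n, p)
    for _ in range(max_cycles):
        prev = best
        for k in range(3):
            if not free[k]:
                continue

            def neg(v, k=k):
                q = list(p)
                q[k] = v
                return -_loglik_counts(t, m, n, q)

            res = minimize_scalar(
                neg, bounds=(_P_LO, _P_HI), method="bounded",
                options={"xatol": 1e-10},
            )
            if -res.fun > best:
                p[k] = float(res.x)
                best = -res.fun
        if best - prev < tol:
            break
    return p, best


def fit_incarceration(
    records, sex: str | None = None, tol: float = 1e-9, profile_ci: bool = True
) -> IncarcerationFit:
    """Maximum-likelihood piecewise incarceration rates with profile CIs.

    Maximises the likelihood over (p1, p2, p3) in [1e-6, 1-1e-6]^3 by
    cyclic coordinate-wise line search (the surface is smooth and nearly
    separable across the three career segments), restarted from three
    corners of the cube to guard against stalls on ridges.  Each 95%
    profile CI is the set of values of one rate whose profile
    log-likelihood (maximised over the other two) stays within
    chi-square_1(0.95)/2 of the optimum, located by bisection.
    Career segments with no respondents are flagged as unidentified and
    keep CIs spanning essentially [0, 1].
    """
    if isinstance(records, pd.DataFrame) and sex is not None:
        records = records.loc[records["sex"] == sex]
    career, ever = _extract(records)
    t, m, n = _counts(career, ever)
    n_ever, n_never = int(m.sum()), int(n.sum())
    flags = []
    if n_ever == 0:
        flags.append("no ever-incarcerated respondents: rates at lower bound")
    if n_never == 0:
        flags.append("no never-incarcerated respondents: rates at upper bound")
    # exposure per segment: respondents whose career reaches into it
    exposure = [int((career >= 1).sum()), int((career >= 6).sum()),
                int((career >= 11).sum())]
    for k, e in enumerate(exposure):
        if e == 0:
            flags.append(f"p{k + 1} unidentified: no careers reach segment {k + 1}")

    starts = [(0.1, 0.1, 0.1), (_P_LO, _P_LO, _P_LO), (0.5, 0.5, 0.5),
              (_P_HI, _P_HI, _P_HI)]
    best_p, best_ll = None, -np.inf
    for s in starts:
        p, ll = _ascend(t, m, n, s, tol=tol)
        if ll > best_ll:
            best_p, best_ll = p, ll
    converged = np.isfinite(best_ll)

    cis = []
    cut = best_ll - _PROFILE_CUT
    for k in range(3):
        if exposure[k] == 0:
            cis.append((0.0, 1.0))
            continue
        if not profile_ci:
            cis.append((float("nan"), float("nan")))
            continue
        cis.append(
            (
                _profile_edge(t, m, n, k, best_p, best_ll, cut, lower=True),
                _profile_edge(t, m, n, k, best_p, best_ll, cut, lower=False),
            )
        )
    return IncarcerationFit(
        rates=IncarcerationRates(*best_p),
        log_likelihood=best_ll,
        profile_cis=tuple(cis),
        n_ever=n_ever,
        n_never=n_never,
        converged=bool(converged),
        flags=flags,
    )


def _profile_ll(t, m, n, k, value, warm) -> float:
    """Log-likelihood maximised over the two rates other than p_k."""
    start = list(warm)
    start[k] = value
    free = [i != k for i in range(3)]
    _, ll = _ascend(t, m, n, start, free=free, tol=1e-10, max_cycles=100)
    return ll


def _profile_edge(t, m, n, k, p_hat, ll_hat, cut, lower: bool) -> float:
    """Bisect for the profile-CI edge of p_k on one side of the MLE."""
    bound = _P_LO if lower else _P_HI
    if _profile_ll(t, m, n, k, bound, p_hat) >= cut:
        return 0.0 if lower else 1.0
    a, b = (bound, p_hat[k]) if lower else (p_hat[k], bound)
    # invariant: profile >= cut at the MLE side, < cut at the outer side
    for _ in range(60):
        mid = 0.5 * (a + b)
        inside = _profile_ll(t, m, n, k, mid, p_hat) >= cut
        if lower:
            if inside:
                b = mid
            else:
                a = mid
        else:
            if inside:
                a = mid
            else:
                b = mid
        if abs(b - a) < 1e-7:
            break
    return 0.5 * (a + b)


def never_incarcerated_curve(records) -> pd.DataFrame:
    """Observed ln(proportion never incarcerated) by career year.

    The data behind the diagnostic survival plot: for each whole career
    length, the number of respondents and the log proportion never
    incarcerated (NaN where the proportion is 0).
    """
    career, ever = _extract(records)
    t, m, n = _counts(career, ever)
    prop = n / (m + n)
    with np.errstate(divide="ignore"):
        logp = np.where(prop > 0, np.log(np.where(prop > 0, prop, 1.0)), np.nan)
    return pd.DataFrame(
        {"career_years": t, "n_respondents": m + n, "prop_never": prop,
         "log_prop_never": logp}
    )
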