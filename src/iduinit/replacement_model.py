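"""Discrete-time injector replacement rate and the unit-replacement quit rate.

The replacement rate R is the expected number of EFR-weighted initiations
over a full injecting career — the analogue of an epidemic's reproduction
number for a behaviourally transmitted practice.  A career lasts IC whole
years with P(IC > t) = (1-q)(1-c)^t (immediate quit probability q at
initiation, per-annum cessation probability c thereafter), and in each
surviving career year t the injector accrues the per-annum EFR initiation
rate appropriate to their career bin and incarceration status at that time:

    R = sum_t P(IC > t) [ lambda_never(bin(t)) P(X > t)
                          + lambda_ever(bin(t)) (1 - P(X > t)) ]

with X the first-incarceration year of the piecewise incarceration model.
Career years are indexed t = 0, 1, 2, ... and bin 0-5 covers t in {0..5}.
The infinite tail over t >= 11 is two geometric series (ratios (1-c) and
(1-c)(1-p3)) summed in closed form, so R is exact to floating point.

Because q enters only through the common factor (1-q), R(p, c, q) =
(1-q) f(p, c); setting R = 1 and using the convention q = c for the
initially reported R gives the quit rate required for a stable population:
q' = 1 - (1-c) / R(p, c, q=c).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .efr_estimation import SubgroupKey, subgroup_estimate, EmptySubgroupError
from .incarceration_model import IncarcerationRates, fit_incarceration, survival_X
from .synthetic_cohort import CAREER_BINS

__all__ = [
    "CareerParams",
    "EFRLookupTable",
    "ReplacementResult",
    "QuitRateResult",
    "career_survival",
    "expected_career_length",
    "efr_lookup",
    "replacement_rate",
    "replacement_rate_triple_sum",
    "quit_rate_for_unit_replacement",
    "efr_table_from_cohort",
    "replacement_ci",
]

_BIN_INDEX = {b: i for i, b in enumerate(CAREER_BINS)}


@dataclass(frozen=True)
class CareerParams:
    """Injecting-career law: P(IC > t) = (1-q)(1-c)^t.

    c is the per-annum cessation probability (cessation includes death);
    q is the probability that a freshly initiated novice quits immediately
    and never injects again (zero career years).
    """

    c: float
    q: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.c <= 1.0:
            raise ValueError(
                f"cessation rate c must be in (0, 1] (c = 0 gives an "
                f"infinite expected career), got {self.c}"
            )
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"quit rate q must be in [0, 1], got {self.q}")


def career_survival(t, params: CareerParams) -> float:
    """P(IC > t) for whole years t >= 0."""
    if isinstance(t, float) and not t.is_integer():
        raise ValueError(f"career years must be whole, got {t}")
    t = int(t)
    if t < 0:
        raise ValueError(f"career years must be >= 0, got {t}")
    return (1.0 - params.q) * (1.0 - params.c) ** t


def expected_career_length(params: CareerParams) -> float:
    """E[IC] = (1-q)/c years."""
    return (1.0 - params.q) / params.c


def _bin_index(t: int) -> int:
    return 0 if t <= 5 else (1 if t <= 10 else 2)


@dataclass
class EFRLookupTable:
    """Per-annum EFR initiation rates by stratum, career bin and
    incarceration status.

    ``strata`` maps stratum name (e.g. "pooled", "F", "M") to
    ``{"never": (l1, l2, l3), "ever": (l1, l2, l3)}`` with one rate per
    career bin 0-5 / 6-10 / >=11.  ``weights`` optionally gives the
    population share of each stratum for combined replacement rates.
    """

    strata: Mapping[str, Mapping[str, Sequence[float]]]
    weights: Mapping[str, float] | None = None

    def __post_init__(self):
        if not self.strata:
            raise ValueError("EFR lookup table has no strata")
        for name, entry in self.strata.items():
            for status in ("never", "ever"):
                if status not in entry:
                    raise ValueError(f"stratum {name!r} missing {status!r} rates")
                rates = entry[status]
                if len(rates) != 3 or any(r < 0 for r in rates):
                    raise ValueError(
                        f"stratum {name!r} {status!r} must give three "
                        f"nonnegative per-bin rates, got {rates}"
                    )

    def rate(self, stratum: str, status: str, bin_idx: int) -> float:
        if stratum not in self.strata:
            raise KeyError(
                f"unknown stratum {stratum!r}; have {sorted(self.strata)}"
            )
        return float(self.strata[stratum][status][bin_idx])


def efr_lookup(t: int, x, stratum: str, table: EFRLookupTable) -> float:
    """EFR rate applying in career year t given first incarceration at x.

    x may be math.inf (never incarcerated).  Incarceration switches the
    rate from the never column to the ever column from year x onward.
    """
    if t < 0:
        raise ValueError(f"career year must be >= 0, got {t}")
    if x != math.inf and x < 1:
        raise ValueError(f"first-incarceration year must be >= 1 or inf, got {x}")
    status = "ever" if x <= t else "never"
    return table.rate(stratum, status, _bin_index(int(t)))


@dataclass
class ReplacementResult:
    """R with its per-career-year decomposition.

    ``per_year_terms`` holds the addends for t = 0..10 followed by the
    closed-form tail over t >= 11; they sum to R.  ``f_value`` = R/(1-q)
    is the quit-free factor f(p, c).
    """

    R: float
    per_year_terms: list[float] = field(default_factory=list)
    f_value: float = float("nan")
    truncation_error_bound: float = 0.0
    by_stratum: dict[str, float] = field(default_factory=dict)


def _replacement_single(
    table: EFRLookupTable,
    stratum: str,
    rates: IncarcerationRates,
    params: CareerParams,
) -> ReplacementResult:
    c, q = params.c, params.q
    ln = [table.rate(stratum, "never", i) for i in range(3)]
    le = [table.rate(stratum, "ever", i) for i in range(3)]
    terms = []
    for t in range(11):
        s = survival_X(t, rates)
        b = _bin_index(t)
        terms.append(
            (1.0 - q) * (1.0 - c) ** t * (ln[b] * s + le[b] * (1.0 - s))
        )
    # tail over t >= 11: split the bracket into lambda_ever[2] plus
    # (lambda_never[2] - lambda_ever[2]) S(t); S(t) = S(10) (1-p3)^(t-10)
    a = 1.0 - c
    r2 = a * (1.0 - rates.p3)
    s10 = survival_X(10, rates)
    tail = (1.0 - q) * le[2] * a**11 / c
    if r2 > 0.0:
        tail += (
            (1.0 - q)
            * (ln[2] - le[2])
            * s10
            * (1.0 - rates.p3)
            * a**11
            / (1.0 - r2)
        )
    terms.append(tail)
    R = float(sum(terms))
    return ReplacementResult(
        R=R,
        per_year_terms=terms,
        f_value=R / (1.0 - q) if q < 1.0 else float("nan"),
        truncation_error_bound=0.0,
    )


def replacement_rate(
    table: EFRLookupTable,
    stratum: str | Sequence[str] | None = None,
    rates: IncarcerationRates | Mapping[str, IncarcerationRates] = None,
    params: CareerParams = None,
    tol: float = 1e-12,
) -> ReplacementResult:
    """Expected career-total EFR initiations R.

    Single stratum: pass its name and one incarceration-rate triple.
    Several strata: pass a list of names plus per-stratum incarceration
    rates; the result is the weight-averaged R (weights from the table,
    equal by default) with per-stratum values reported.  The year-by-year
    sum uses closed-form geometric tails, so ``tol`` only bounds the
    brute-force cross-check mode (:func:`replacement_rate_triple_sum`).
    """
    if params is None:
        raise ValueError("career parameters required")
    if stratum is None:
        stratum = list(table.strata)
        if len(stratum) == 1:
            stratum = stratum[0]
    if isinstance(stratum, str):
        if not isinstance(rates, IncarcerationRates):
            rates = IncarcerationRates(*rates)
        return _replacement_single(table, stratum, rates, params)
    names = list(stratum)
    if isinstance(rates, IncarcerationRates) or (
        not isinstance(rates, Mapping) and rates is not None
    ):
        rates = {name: IncarcerationRates(*rates) for name in names}
    results = {
        name: _replacement_single(table, name, IncarcerationRates(*rates[name]), params)
        for name in names
    }
    if table.weights:
        wsum = sum(table.weights[n] for n in names)
        w = {n: table.weights[n] / wsum for n in names}
    else:
        w = {n: 1.0 / len(names) for n in names}
    R = sum(w[n] * results[n].R for n in names)
    return ReplacementResult(
        R=float(R),
        per_year_terms=[],
        f_value=float(R / (1.0 - params.q)) if params.q < 1.0 else float("nan"),
        truncation_error_bound=0.0,
        by_stratum={n: results[n].R for n in names},
    )


def replacement_rate_triple_sum(
    table: EFRLookupTable,
    stratum: str,
    rates: IncarcerationRates,
    params: CareerParams,
    tol: float = 1e-12,
) -> ReplacementResult:
    """Brute-force triple sum over (t, x) including the never-incarcerated
    mass, truncated when the remaining career mass is below ``tol``.

    Serves as an internal cross-check of the closed-form evaluation; the
    two agree to ~1e-10 for any parameter set.
    """
    c, q = params.c, params.q
    rates = IncarcerationRates(*rates)
    lam_max = max(
        max(table.strata[stratum]["never"]), max(table.strata[stratum]["ever"])
    )
    # truncate when remaining mass bounds the tail below tol
    t_max = 11
    while (1.0 - q) * (1.0 - c) ** t_max / c * lam_max > tol and t_max < 100000:
        t_max += 1
    total = 0.0
    terms = []
    for t in range(t_max + 1):
        ic = career_survival(t, params)
        sx = survival_X(t, rates)
        contrib = ic * (
            efr_lookup(t, math.inf, stratum, table) * sx
            + table.rate(stratum, "ever", _bin_index(t)) * (1.0 - sx)
        )
        terms.append(contrib)
        total += contrib
    bound = (1.0 - q) * (1.0 - c) ** (t_max + 1) / c * lam_max
    return ReplacementResult(
        R=float(total),
        per_year_terms=terms,
        f_value=float(total / (1.0 - q)) if q < 1.0 else float("nan"),
        truncation_error_bound=float(bound),
    )


@dataclass(frozen=True)
class QuitRateResult:
    q_prime: float
    already_below_replacement: bool

    @property
    def clamped(self) -> float:
        return max(0.0, self.q_prime)


def quit_rate_for_unit_replacement(R_at_q_equal_c: float, c: float) -> QuitRateResult:
    """Quit rate q' that would bring the replacement rate to exactly 1.

    Uses R(p, c, q) = (1-q) f(p, c) with f estimated from the q = c run:
    q' = 1 - (1-c)/R(c, p, c).  A negative q' (R already below 1-c) is
    returned unclamped with the flag set.
    """
    if not R_at_q_equal_c > 0.0:
        raise ValueError(f"R must be > 0, got {R_at_q_equal_c}")
    if not 0.0 <= c < 1.0:
        raise ValueError(f"c must be in [0, 1), got {c}")
    qp = 1.0 - (1.0 - c) / R_at_q_equal_c
    return QuitRateResult(q_prime=float(qp), already_below_replacement=qp < 0.0)


# ---------------------------------------------------------------------------
# Estimation from cohort data
# ---------------------------------------------------------------------------


def efr_table_from_cohort(
    records: pd.DataFrame, by_sex: bool = False
) -> EFRLookupTable:
    """Point-estimate EFR lookup table from a respondent table.

    Pooled by default (one "pooled" stratum); ``by_sex`` gives "F" and "M"
    strata weighted by their respondent counts.
    """
    if by_sex:
        strata, weights = {}, {}
        for s in ("F", "M"):
            strata[s] = {
                status: tuple(
                    subgroup_estimate(
                        records,
                        SubgroupKey(sex=s, career_bin=b, prison=status),
                    ).lambda_efr
                    for b in CAREER_BINS
                )
                for status in ("never", "ever")
            }
            weights[s] = int((records["sex"] == s).sum())
        return EFRLookupTable(strata=strata, weights=weights)
    strata = {
        "pooled": {
            status: tuple(
                subgroup_estimate(
                    records, SubgroupKey(career_bin=b, prison=status)
                ).lambda_efr
                for b in CAREER_BINS
            )
            for status in ("never", "ever")
        }
    }
    return EFRLookupTable(strata=strata)


def replacement_ci(
    records: pd.DataFrame,
    params: CareerParams | Sequence[CareerParams],
    n_boot: int = 500,
    level: float = 0.95,
    seed: int = 0,
    mode: str = "joint",
    by_sex: bool = False,
):
    """Bootstrap percentile CI for R from cohort data.

    Each replicate resamples respondents with replacement, rebuilds the
    bin x prison EFR table and -- in the default ``"joint"`` mode -- refits
    the incarceration rates, then re-evaluates R.  ``"efr"`` mode holds the
    incarceration rates at their full-data fit and propagates EFR
    uncertainty only.  Returns ((low, high), replicate values, number of
    failed replicates); replicates whose resample empties a subgroup are
    dropped, with a warning above 5% failures.

    ``params`` may be a list of career-parameter scenarios, in which case
    all scenarios share the same resamples (and incarceration refits) and
    a list of intervals plus a (n_scenarios, n_ok) value array is returned.
    """
    if mode not in ("joint", "efr"):
        raise ValueError(f"mode must be 'joint' or 'efr', got {mode!r}")
    single = isinstance(params, CareerParams)
    scenarios = [params] if single else list(params)
    if not scenarios:
        raise ValueError("no career-parameter scenarios given")
    rng = np.random.default_rng(seed)
    n = len(records)
    if n == 0:
        raise ValueError("empty cohort")
    base_fit = fit_incarceration(records, profile_ci=False)
    if mode == "efr" and by_sex:
        fixed_rates = {
            s: fit_incarceration(records, sex=s, profile_ci=False).rates
            for s in ("F", "M")
        }
    values: list[list[float]] = []
    n_fail = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = records.iloc[idx].reset_index(drop=True)
        try:
            tab = efr_table_from_cohort(rep, by_sex=by_sex)
            if mode == "joint":
                if by_sex:
                    rates = {
                        s: fit_incarceration(rep, sex=s, profile_ci=False).rates
                        for s in ("F", "M")
                    }
                else:
                    rates = fit_incarceration(rep, profile_ci=False).rates
            else:
                rates = fixed_rates if by_sex else base_fit.rates
            values.append(
                [replacement_rate(tab, rates=rates, params=p).R for p in scenarios]
            )
        except (EmptySubgroupError, ValueError):
            n_fail += 1
    if n_fail > 0.05 * n_boot:
        warnings.warn(
            f"{n_fail}/{n_boot} bootstrap replicates failed (empty subgroup "
            f"after resampling); interval may be unreliable"
        )
    if not values:
        raise ValueError("every bootstrap replicate failed")
    vals = np.asarray(values).T  # (n_scenarios, n_ok)
    alpha = 1.0 - level
    cis = [
        (float(lo), float(hi))
        for lo, hi in (
            np.quantile(v, [alpha / 2.0, 1.0 - alpha / 2.0]) for v in vals
        )
    ]
    if single:
        return cis[0], vals[0], n_fail
    return cis, vals, n_fail
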