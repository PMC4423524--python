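"""Equivalent-of-full-responsibility (EFR) initiation rates.

An injector who was present at an initiation shares responsibility for it
equally with every other established injector present.  A respondent who
reports k past-year initiations with m OTHER injectors present at the most
recent one therefore carries an EFR rate of k / (m + 1) initiations per
annum.  Subgroup rates are means of these individual rates, with
respondents reporting zero initiations contributing zeros, and confidence
intervals come from a nonparametric paired bootstrap that resamples each
respondent's (k, m) pair jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import CAREER_BINS, PRISON_STATUSES, SEXES, career_bin

__all__ = [
    "SubgroupKey",
    "EFREstimate",
    "respondent_efr",
    "subgroup_estimate",
    "bootstrap_ci",
    "estimate_with_ci",
    "descriptive_counts",
    "headline_subgroup_keys",
    "regression_subgroup_keys",
    "estimate_table",
    "EmptySubgroupError",
]


class EmptySubgroupError(ValueError):
    """No respondents match the requested subgroup."""


@dataclass(frozen=True)
class SubgroupKey:
    """A subgroup of respondents; unset fields are pooled over.

    ``career_bin`` uses the labels 0-5 / 6-10 / >=11 derived from whole
    career years; ``prison`` is "never" / "ever".
    """

    sex: str | None = None
    region: str | None = None
    career_bin: str | None = None
    prison: str | None = None

    def __post_init__(self):
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES} or None, got {self.sex!r}")
        if self.region is not None and self.region not in ("GGC", "Else"):
            raise ValueError(f"region must be GGC/Else or None, got {self.region!r}")
        if self.career_bin is not None and self.career_bin not in CAREER_BINS:
            raise ValueError(
                f"career_bin must be one of {CAREER_BINS} or None, got {self.career_bin!r}"
            )
        if self.prison is not None and self.prison not in PRISON_STATUSES:
            raise ValueError(
                f"prison must be one of {PRISON_STATUSES} or None, got {self.prison!r}"
            )

    def mask(self, records: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(records), dtype=bool)
        if self.sex is not None:
            m &= (records["sex"] == self.sex).to_numpy()
        if self.region is not None:
            m &= (records["region"] == self.region).to_numpy()
        if self.career_bin is not None:
            bins = records["career_years"].map(career_bin)
            m &= (bins == self.career_bin).to_numpy()
        if self.prison is not None:
            m &= (
                records["ever_incarcerated"] == (self.prison == "ever")
            ).to_numpy()
        return m

    def label(self) -> str:
        parts = [
            self.sex or "",
            self.region or "",
            self.career_bin or "",
            self.prison or "",
        ]
        s = "/".join(p for p in parts if p)
        return s or "All"


@dataclass
class EFREstimate:
    """Point and bootstrap summaries of one subgroup's EFR initiation rate."""

    key: SubgroupKey
    n_respondents: int
    n_initiators: int
    n_initiations: int
    mean_initiations_pa: float
    mean_others_present: float
    lambda_efr: float
    ci: tuple[float, float] | None = None
    log_lambda_var: float | None = None
    n_dropped_missing: int = 0
    n_zero_replicates: int = 0


def respondent_efr(n_initiations_py: int, n_others_recent) -> float:
    """Per-annum EFR rate of one respondent: k initiations split k/(m+1).

    Zero initiations give rate 0 regardless of the (unasked) others count.
    A positive count with a missing others count is unusable and raises.
    """
    if n_initiations_py < 0:
        raise ValueError("n_initiations_py must be >= 0")
    if n_initiations_py == 0:
        return 0.0
    if n_others_recent is None or (
        not isinstance(n_others_recent, str) and pd.isna(n_others_recent)
    ):
        raise ValueError(
            "unusable initiator: n_others_recent missing with positive initiations"
        )
    if n_others_recent < 0:
        raise ValueError("n_others_recent must be >= 0")
    return n_initiations_py / (n_others_recent + 1.0)


def _usable_arrays(
    records: pd.DataFrame, key: SubgroupKey, exclude_non_past_year: bool = False
) -> tuple[np.ndarray, np.ndarray, int, pd.DataFrame]:
    """Subgroup (k, m) arrays with unusable initiators dropped.

    Returns (n_initiations, efr_values, n_dropped_missing, usable_frame).
    Initiators whose others-present count is missing cannot be assigned a
    responsibility share and are excluded from numerators and denominators
    alike; the count is reported.  Non-initiators keep efr 0 with m ignored.
    """
    m = key.mask(records)
    if exclude_non_past_year:
        m &= records["injected_past_year"].to_numpy()
    sub = records.loc[m]
    if len(sub) == 0:
        raise EmptySubgroupError(f"no respondents in subgroup {key.label()!r}")
    k = sub["n_initiations_py"].to_numpy()
    others = sub["n_others_recent"].to_numpy(dtype=float, na_value=np.nan)
    unusable = (k > 0) & ~np.isfinite(others)
    sub = sub.loc[~unusable]
    k = k[~unusable]
    others = others[~unusable]
    if len(sub) == 0:
        raise EmptySubgroupError(
            f"subgroup {key.label()!r} empty after dropping initiators with "
            f"missing others-present counts"
        )
    efr = np.where(k > 0, k / (others + 1.0), 0.0)
    return k, efr, int(unusable.sum()), sub


def subgroup_estimate(
    records: pd.DataFrame, key: SubgroupKey, exclude_non_past_year: bool = False
) -> EFREstimate:
    """Point estimates for one subgroup (no bootstrap fields).

    ``mean_initiations_pa`` is total initiations over respondents;
    ``lambda_efr`` is the mean individual EFR rate, zeros included;
    ``mean_others_present`` averages over initiators only.  Setting
    ``exclude_non_past_year`` drops respondents who did not inject in the
    past year (sensitivity analysis; their responsibility is treated as 0
    by removal).
    """
    k, efr, n_dropped, sub = _usable_arrays(records, key, exclude_non_past_year)
    init = k > 0
    others = sub["n_others_recent"].to_numpy(dtype=float, na_value=np.nan)
    return EFREstimate(
        key=key,
        n_respondents=len(sub),
        n_initiators=int(init.sum()),
        n_initiations=int(k.sum()),
        mean_initiations_pa=float(k.sum() / len(sub)),
        mean_others_present=float(others[init].mean()) if init.any() else float("nan"),
        lambda_efr=float(efr.mean()),
        n_dropped_missing=n_dropped,
    )


def bootstrap_ci(
    records: pd.DataFrame,
    key: SubgroupKey,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    exclude_non_past_year: bool = False,
) -> tuple[tuple[float, float], float, int]:
    """Percentile bootstrap CI for the subgroup EFR rate.

    Respondents are resampled with replacement within the subgroup, each
    carrying its (initiations, others-present) pair jointly, and the mean
    EFR rate recomputed per replicate.  Returns ``((low, high),
    var(ln lambda over positive replicates), number of all-zero replicates)``.
    The log-scale variance feeds the precision weights of the subgroup
    regression; replicates with zero rate carry no finite log and are
    excluded from it (and counted).  Deterministic given the seed.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    _, efr, _, _ = _usable_arrays(records, key, exclude_non_past_year)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = efr.size
    means = np.empty(n_boot)
    # chunked so n_boot x n index blocks stay modest in memory
    chunk = max(1, int(5e6) // max(n, 1))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        means[start:stop] = efr[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    pos = means > 0.0
    n_zero = int(n_boot - pos.sum())
    if pos.sum() >= 2:
        log_var = float(np.var(np.log(means[pos]), ddof=1))
    else:
        log_var = float("nan")
    if not pos.any():
        raise ValueError(
            f"all bootstrap replicates zero in subgroup {key.label()!r}; "
            f"CI undefined"
        )
    return (float(lo), float(hi)), log_var, n_zero


def estimate_with_ci(
    records: pd.DataFrame,
    key: SubgroupKey,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    exclude_non_past_year: bool = False,
) -> EFREstimate:
    """Point estimate plus bootstrap CI and log-scale variance."""
    est = subgroup_estimate(records, key, exclude_non_past_year)
    ci, log_var, n_zero = bootstrap_ci(
        records, key, n_boot=n_boot, level=level, seed=seed,
        exclude_non_past_year=exclude_non_past_year,
    )
    est.ci = ci
    est.log_lambda_var = log_var
    est.n_zero_replicates = n_zero
    return est


def headline_subgroup_keys() -> list[SubgroupKey]:
    """The subgroup rows of the headline EFR table: all respondents, then
    never/ever incarcerated within each of sex, region and career bin."""
    keys = [SubgroupKey()]
    keys += [SubgroupKey(prison=p) for p in PRISON_STATUSES]
    keys += [SubgroupKey(sex=s, prison=p) for s in SEXES for p in PRISON_STATUSES]
    keys += [
        SubgroupKey(region=r, prison=p) for r in ("GGC", "Else") for p in PRISON_STATUSES
    ]
    keys += [
        SubgroupKey(career_bin=b, prison=p)
        for b in CAREER_BINS
        for p in PRISON_STATUSES
    ]
    return keys


def regression_subgroup_keys() -> list[SubgroupKey]:
    """The 12 sex x career-bin x prison subgroups used by the regression."""
    return [
        SubgroupKey(sex=s, career_bin=b, prison=p)
        for s in SEXES
        for b in CAREER_BINS
        for p in PRISON_STATUSES
    ]


def estimate_table(
    records: pd.DataFrame,
    keys: Iterable[SubgroupKey] | None = None,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    exclude_non_past_year: bool = False,
) -> list[EFREstimate]:
    """Estimates with CIs for a list of subgroups (default: headline rows).

    Each subgroup gets an independent bootstrap stream derived from ``seed``
    so that adding or reordering rows does not perturb the others.
    """
    if keys is None:
        keys = headline_subgroup_keys()
    out = []
    for i, key in enumerate(keys):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        out.append(
            estimate_with_ci(
                records, key, n_boot=n_boot, level=level, seed=rng,
                exclude_non_past_year=exclude_non_past_year,
            )
        )
    return out


def descriptive_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive initiator counts: overall, by past-year injection status,
    by career bin, and the zero-others fraction by prison history.

    Returns a tidy table with columns group / n / n_initiators / fraction.
    Initiators here are respondents reporting >=1 past-year initiation
    (regardless of whether their others-present count is usable);
    ``fraction`` for the zero-others rows is the share of initiators who
    reported no other injector present.
    """
    rows = []
    k = records["n_initiations_py"].to_numpy() if len(records) else np.array([], int)
    init = k > 0

    def add(group: str, mask: np.ndarray) -> None:
        n = int(mask.sum())
        ni = int((mask & init).sum())
        rows.append(
            {
                "group": group,
                "n": n,
                "n_initiators": ni,
                "fraction": ni / n if n else 0.0,
            }
        )

    all_mask = np.ones(len(records), dtype=bool)
    add("all", all_mask)
    if len(records):
        ipy = records["injected_past_year"].to_numpy()
        add("injected_past_year", ipy)
        add("not_injected_past_year", ~ipy)
        bins = records["career_years"].map(career_bin).to_numpy()
        for b in CAREER_BINS:
            add(f"career_{b}", bins == b)
        add("career_>5", bins != "0-5")
        others = records["n_others_recent"].to_numpy(dtype=float, na_value=np.nan)
        ever = records["ever_incarcerated"].to_numpy()
        for label, m in (("never", ~ever), ("ever", ever)):
            ini = init & m
            n_ini = int(ini.sum())
            n_zero = int((ini & (others == 0)).sum())
            rows.append(
                {
                    "group": f"initiators_zero_others_{label}_prison",
                    "n": n_ini,
                    "n_initiators": n_zero,
                    "fraction": n_zero / n_ini if n_ini else 0.0,
                }
            )
    else:
        add("injected_past_year", all_mask)
        add("not_injected_past_year", all_mask)
        for b in CAREER_BINS:
            add(f"career_{b}", all_mask)
        add("career_>5", all_mask)
    return pd.DataFrame(rows)


def pooled_consistency(estimates: Sequence[EFREstimate]) -> bool:
    """Check that initiation totals of pooled rows equal their partitions."""
    by_key = {e.key: e for e in estimates}
    all_row = by_key.get(SubgroupKey())
    parts = [by_key.get(SubgroupKey(prison=p)) for p in PRISON_STATUSES]
    if all_row is None or any(p is None for p in parts):
        return True
    return all_row.n_initiations == sum(p.n_initiations for p in parts)
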