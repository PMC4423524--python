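"""Seeded synthetic survey cohorts of injection drug users (IDUs).

Emulates the record structure of a cross-sectional, anonymous injector
survey such as Scotland's Needle Exchange Surveillance Initiative (NESI,
2008-2009): one row per respondent with sex, region, age group, injecting
career length in whole years, incarceration history, past-year injection
status, the number of initiations of novice injectors the respondent was
present at in the past year, and the number of OTHER established injectors
present at the most recent such initiation (respondent and novice excluded).

The generator is parameterised by a :class:`CohortConfig` whose defaults are
calibrated to the published NESI summary tables, so that every downstream
stage (EFR estimation, incarceration-rate likelihood, replacement rate) can
be exercised and checked against known ground truth without access to the
unpublished raw survey data.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "REGIONS",
    "AGE_GROUPS",
    "CAREER_BINS",
    "PRISON_STATUSES",
    "COLUMNS",
    "career_bin",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_initiator_prob",
    "default_initiation_count_mean",
]

SEXES = ("F", "M")
REGIONS = ("GGC", "Else")
AGE_GROUPS = ("<35", ">=35")
CAREER_BINS = ("0-5", "6-10", ">=11")
PRISON_STATUSES = ("never", "ever")

COLUMNS = [
    "id",
    "sex",
    "region",
    "age_group",
    "career_years",
    "ever_incarcerated",
    "injected_past_year",
    "n_initiations_py",
    "n_others_recent",
]


def career_bin(career_years: int) -> str:
    """Map whole career years to the three analysis bins 0-5 / 6-10 / >=11."""
    if career_years < 0:
        raise ValueError(f"career_years must be >= 0, got {career_years}")
    if career_years <= 5:
        return "0-5"
    if career_years <= 10:
        return "6-10"
    return ">=11"


# ---------------------------------------------------------------------------
# Default calibration: published NESI 2008-2009 summary estimates.
#
# Initiator fractions and mean past-year initiation counts among initiators,
# by career bin x incarceration history (pooled over sex, which the survey's
# logistic analysis found non-influential for initiator status).
# ---------------------------------------------------------------------------

_BIN_PRISON_INITIATOR_FRAC = {
    ("0-5", "never"): 102 / 482,
    ("0-5", "ever"): 82 / 318,
    ("6-10", "never"): 40 / 286,
    ("6-10", "ever"): 69 / 440,
    (">=11", "never"): 23 / 259,
    (">=11", "ever"): 127 / 715,
}

_BIN_PRISON_COUNT_MEAN = {
    ("0-5", "never"): 531 / 102,
    ("0-5", "ever"): 233 / 82,
    ("6-10", "never"): 180 / 40,
    ("6-10", "ever"): 219 / 69,
    (">=11", "never"): 78 / 23,
    (">=11", "ever"): 453 / 127,
}


def default_initiator_prob() -> dict[tuple[str, str, str], float]:
    """Default P(>=1 past-year initiation) keyed by (sex, career bin, prison)."""
    return {
        (s, b, p): _BIN_PRISON_INITIATOR_FRAC[(b, p)]
        for s in SEXES
        for (b, p) in _BIN_PRISON_INITIATOR_FRAC
    }


def default_initiation_count_mean() -> dict[tuple[str, str, str], float]:
    """Default mean past-year initiation count among initiators, same keys."""
    return {
        (s, b, p): _BIN_PRISON_COUNT_MEAN[(b, p)]
        for s in SEXES
        for (b, p) in _BIN_PRISON_COUNT_MEAN
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Probabilities are per annum where they describe yearly hazards
    (``career_cessation_gen`` and the incarceration rate triples) and plain
    proportions otherwise.  ``incarceration_rates_by_sex`` maps sex to the
    per-annum first-incarceration probabilities (p1, p2, p3) applying in
    career years 1-5, 6-10 and >=11.  ``initiator_prob`` and
    ``initiation_count_mean`` are keyed by (sex, career bin, prison status).
    """

    n_respondents: int = 2500
    prop_female: float = 702 / 2500
    prop_region_ggc: float = 922 / 2500
    prop_age_under35: float = 0.55
    career_cessation_gen: float = 0.08
    career_cap_years: int = 40
    incarceration_rates_by_sex: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"F": (0.07, 0.06, 0.04), "M": (0.19, 0.05, 0.03)}
    )
    initiator_prob: Mapping[tuple[str, str, str], float] = field(
        default_factory=default_initiator_prob
    )
    initiation_count_mean: Mapping[tuple[str, str, str], float] = field(
        default_factory=default_initiation_count_mean
    )
    others_present_mean: float = 2.5
    prop_injected_past_year: float = 2139 / 2536
    missing_others_rate: float = 7 / 450
    missing_covariate_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming the first invalid field."""
        if not (isinstance(self.n_respondents, (int, np.integer)) and self.n_respondents >= 1):
            raise ValueError(f"n_respondents must be a positive integer, got {self.n_respondents}")
        for name in (
            "prop_female",
            "prop_region_ggc",
            "prop_age_under35",
            "career_cessation_gen",
            "prop_injected_past_year",
            "missing_others_rate",
            "missing_covariate_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.career_cessation_gen <= 0.0:
            raise ValueError(
                "career_cessation_gen must be > 0 (career-length draw is geometric)"
            )
        if self.career_cap_years < 11:
            raise ValueError(
                f"career_cap_years must be >= 11 so every incarceration piece is "
                f"exercisable, got {self.career_cap_years}"
            )
        for sex in SEXES:
            if sex not in self.incarceration_rates_by_sex:
                raise ValueError(f"incarceration_rates_by_sex missing sex {sex!r}")
            triple = self.incarceration_rates_by_sex[sex]
            if len(triple) != 3 or not all(0.0 <= p <= 1.0 for p in triple):
                raise ValueError(
                    f"incarceration_rates_by_sex[{sex!r}] must be three probabilities, "
                    f"got {triple}"
                )
        for sex in SEXES:
            for b in CAREER_BINS:
                for pr in PRISON_STATUSES:
                    key = (sex, b, pr)
                    if key not in self.initiator_prob:
                        raise ValueError(f"initiator_prob missing key {key}")
                    if not (0.0 <= self.initiator_prob[key] <= 1.0):
                        raise ValueError(
                            f"initiator_prob[{key}] must be in [0, 1], "
                            f"got {self.initiator_prob[key]}"
                        )
                    if key not in self.initiation_count_mean:
                        raise ValueError(f"initiation_count_mean missing key {key}")
                    if self.initiation_count_mean[key] < 1.0:
                        raise ValueError(
                            f"initiation_count_mean[{key}] is a mean count among "
                            f"initiators and must be >= 1, got "
                            f"{self.initiation_count_mean[key]}"
                        )
        if self.others_present_mean < 0.0:
            raise ValueError(
                f"others_present_mean must be >= 0, got {self.others_present_mean}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")


@dataclass(frozen=True)
class GroundTruth:
    """The generating parameters plus the analytic expectations they imply."""

    config: CohortConfig

    def expected_mean_initiations_pa(self, sex: str, bin_: str, prison: str) -> float:
        """E[past-year initiations per respondent] within the subgroup."""
        key = (sex, bin_, prison)
        return self.config.initiator_prob[key] * self.config.initiation_count_mean[key]

    def expected_lambda_efr(self, sex: str, bin_: str, prison: str) -> float:
        """E[EFR rate per respondent] within the subgroup.

        With the others-present count K ~ Poisson(mu) independent of the
        initiation count, E[1/(K+1)] = (1 - exp(-mu)) / mu.
        """
        mu = self.config.others_present_mean
        inv_share = 1.0 if mu == 0.0 else (1.0 - np.exp(-mu)) / mu
        return self.expected_mean_initiations_pa(sex, bin_, prison) * inv_share

    def var_initiations(self, sex: str, bin_: str, prison: str) -> float:
        """Variance of the per-respondent initiation count within the subgroup.

        The count is 0 with probability 1-pi and geometric on {1,2,...} with
        mean m otherwise (variance m(m-1)).
        """
        key = (sex, bin_, prison)
        pi = self.config.initiator_prob[key]
        m = self.config.initiation_count_mean[key]
        # law of total variance over initiator status
        return pi * m * (m - 1.0) + pi * (1.0 - pi) * m * m


def _sample_first_incarceration(
    rng: np.random.Generator, rates: tuple[float, float, float], size: int
) -> np.ndarray:
    """Draw first-incarceration career year X from the piecewise process.

    Year-by-year Bernoulli with rate p1 in career years 1-5, p2 in 6-10 and
    p3 thereafter; returns inf when incarceration never occurs (possible when
    p3 = 0).  Sampled piecewise as three geometric stage times.
    """
    p1, p2, p3 = rates
    x = np.full(size, np.inf)

    def _geom(p: float, n: int) -> np.ndarray:
        if p <= 0.0:
            return np.full(n, np.inf)
        if p >= 1.0:
            return np.ones(n)
        return rng.geometric(p, size=n).astype(float)

    g1 = _geom(p1, size)
    in1 = g1 <= 5
    x[in1] = g1[in1]
    rest = ~in1
    n2 = int(rest.sum())
    g2 = _geom(p2, n2)
    in2 = g2 <= 5
    idx2 = np.flatnonzero(rest)
    x[idx2[in2]] = 5.0 + g2[in2]
    idx3 = idx2[~in2]
    g3 = _geom(p3, idx3.size)
    x[idx3] = 10.0 + g3
    return x


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a synthetic respondent table plus its ground truth.

    Returns a DataFrame with columns :data:`COLUMNS` (``n_others_recent`` is
    a nullable integer: missing for non-initiators by design, and missing
    completely at random for a small fraction of initiators) and a
    :class:`GroundTruth` carrying the generating parameters for recovery
    tests.  Identical configs (including seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    sex = np.where(rng.random(n) < config.prop_female, "F", "M")
    region = np.where(rng.random(n) < config.prop_region_ggc, "GGC", "Else")
    age_group = np.where(rng.random(n) < config.prop_age_under35, "<35", ">=35")

    # career length: geometric number of completed years, truncated at the cap
    career = np.minimum(
        rng.geometric(config.career_cessation_gen, size=n) - 1, config.career_cap_years
    )

    ever = np.zeros(n, dtype=bool)
    for s in SEXES:
        m = sex == s
        x = _sample_first_incarceration(
            rng, tuple(config.incarceration_rates_by_sex[s]), int(m.sum())
        )
        ever[m] = x <= career[m]

    injected_py = rng.random(n) < config.prop_injected_past_year

    bins = np.where(career <= 5, "0-5", np.where(career <= 10, "6-10", ">=11"))
    prison = np.where(ever, "ever", "never")
    p_init = np.empty(n)
    count_mean = np.empty(n)
    for s in SEXES:
        for b in CAREER_BINS:
            for pr in PRISON_STATUSES:
                m = (sex == s) & (bins == b) & (prison == pr)
                p_init[m] = config.initiator_prob[(s, b, pr)]
                count_mean[m] = config.initiation_count_mean[(s, b, pr)]

    is_init = rng.random(n) < p_init
    n_init = np.zeros(n, dtype=int)
    if is_init.any():
        # shifted-geometric count on {1, 2, ...} with the configured mean
        mu = count_mean[is_init]
        n_init[is_init] = rng.geometric(1.0 / mu)

    n_others = np.full(n, -1, dtype=float)
    n_others[is_init] = rng.poisson(config.others_present_mean, size=int(is_init.sum()))
    miss_others = is_init & (rng.random(n) < config.missing_others_rate)
    n_others[~is_init | miss_others] = np.nan

    miss_cov = rng.random(n) < config.missing_covariate_rate
    age_col = pd.array(age_group, dtype="string")
    age_col[miss_cov] = pd.NA

    df = pd.DataFrame(
        {
            "id": pd.array([f"R{i:06d}" for i in range(n)], dtype="string"),
            "sex": pd.array(sex, dtype="string"),
            "region": pd.array(region, dtype="string"),
            "age_group": age_col,
            "career_years": career.astype("int64"),
            "ever_incarcerated": ever,
            "injected_past_year": injected_py,
            "n_initiations_py": n_init.astype("int64"),
            "n_others_recent": pd.array(
                [int(v) if np.isfinite(v) else None for v in n_others], dtype="Int64"
            ),
        }
    )
    return df, GroundTruth(config=replace(config))


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Missing values are encoded as empty fields; booleans
# as True/False.  Writing is canonicalised so identical cohorts give
# byte-identical files.
# ---------------------------------------------------------------------------


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a respondent table as comma-separated text (missing = empty)."""
    df = records.loc[:, COLUMNS].copy()
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n", na_rep="")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def read_cohort(path) -> pd.DataFrame:
    """Read a respondent table written by :func:`write_cohort`.

    Validates column presence, category codes and value ranges; errors name
    the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(
        path,
        dtype={
            "id": "string",
            "sex": "string",
            "region": "string",
            "age_group": "string",
            "n_others_recent": "Int64",
        },
        keep_default_na=True,
        na_values=[""],
    )
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file missing columns: {missing_cols}")
    df = df.loc[:, COLUMNS]
    if len(df) == 0:
        return df.astype(
            {
                "career_years": "int64",
                "ever_incarcerated": "bool",
                "injected_past_year": "bool",
                "n_initiations_py": "int64",
            }
        )

    def _bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValueError(f"row {row}: {what}")

    _bad(~df["sex"].isin(SEXES), f"sex must be one of {SEXES}")
    _bad(~df["region"].isin(REGIONS), f"region must be one of {REGIONS}")
    _bad(
        df["age_group"].notna() & ~df["age_group"].isin(AGE_GROUPS),
        f"age_group must be one of {AGE_GROUPS} or empty",
    )
    for col in ("career_years", "n_initiations_py"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _bad(vals.isna(), f"{col} must be an integer")
        _bad(vals < 0, f"{col} must be >= 0")
        _bad(vals != vals.astype("int64"), f"{col} must be a whole number")
        df[col] = vals.astype("int64")
    for col in ("ever_incarcerated", "injected_past_year"):
        as_str = df[col].astype("string").str.strip()
        ok = as_str.isin(["True", "False"])
        _bad(~ok, f"{col} must be True or False")
        df[col] = (as_str == "True").astype(bool)
    _bad(
        df["n_others_recent"].notna() & (df["n_others_recent"] < 0),
        "n_others_recent must be >= 0 or empty",
    )
    return df


def cohort_digest(records: pd.DataFrame) -> str:
    """SHA-256 digest of the canonical text serialisation of a cohort."""
    buf = io.StringIO()
    records.loc[:, COLUMNS].to_csv(buf, index=False, lineterminator="\n", na_rep="")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
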