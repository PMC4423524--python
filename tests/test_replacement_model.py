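"""Career law, replacement-rate evaluation and quit-rate inversion."""

import math

import numpy as np
import pandas as pd
import pytest

from iduinit import (
    CareerParams,
    CohortConfig,
    EFRLookupTable,
    IncarcerationRates,
    NESI_EFR_POOLED,
    NESI_INCARCERATION_OVERALL,
    career_survival,
    efr_lookup,
    efr_table_from_cohort,
    expected_career_length,
    generate_cohort,
    quit_rate_for_unit_replacement,
    replacement_ci,
    replacement_rate,
    replacement_rate_triple_sum,
)
from conftest import make_counts_cohort


def _flat_table(lam):
    return EFRLookupTable(
        strata={"pooled": {"never": (lam,) * 3, "ever": (lam,) * 3}}
    )


class TestCareerLaw:
    def test_survival_at_zero(self):
        assert career_survival(0, CareerParams(c=0.3, q=0.25)) == pytest.approx(0.75)

    def test_survival_geometric(self):
        assert career_survival(3, CareerParams(c=0.5, q=0.0)) == pytest.approx(0.125)

    def test_expected_length(self):
        assert expected_career_length(CareerParams(c=0.05, q=0.05)) == pytest.approx(19.0)

    def test_zero_cessation_rejected(self):
        with pytest.raises(ValueError, match="cessation"):
            CareerParams(c=0.0, q=0.1)

    def test_expected_length_matches_survival_sum(self):
        params = CareerParams(c=0.1, q=0.2)
        # E[IC] = sum_{t>=0} P(IC > t)
        total = sum(career_survival(t, params) for t in range(3000))
        assert total == pytest.approx(expected_career_length(params), rel=1e-9)


class TestLookup:
    def test_ever_rate_after_incarceration(self):
        assert efr_lookup(3, 2, "pooled", NESI_EFR_POOLED) == 0.26

    def test_never_rate_before_incarceration(self):
        assert efr_lookup(3, 7, "pooled", NESI_EFR_POOLED) == 0.46

    def test_never_incarcerated_long_career(self):
        assert efr_lookup(11, math.inf, "pooled", NESI_EFR_POOLED) == 0.11

    def test_unknown_stratum(self):
        with pytest.raises(KeyError, match="stratum"):
            efr_lookup(1, math.inf, "nope", NESI_EFR_POOLED)

    def test_bad_incarceration_year(self):
        with pytest.raises(ValueError):
            efr_lookup(1, 0, "pooled", NESI_EFR_POOLED)


class TestReplacementRate:
    @pytest.mark.parametrize("c, expected", [(0.05, 4.8), (0.10, 2.7), (0.15, 1.9)])
    def test_published_overall_scenarios(self, c, expected):
        res = replacement_rate(
            NESI_EFR_POOLED,
            "pooled",
            NESI_INCARCERATION_OVERALL,
            CareerParams(c=c, q=c),
        )
        assert round(res.R, 1) == expected

    def test_terms_sum_to_R(self):
        res = replacement_rate(
            NESI_EFR_POOLED, "pooled", NESI_INCARCERATION_OVERALL,
            CareerParams(c=0.07, q=0.02),
        )
        assert sum(res.per_year_terms) == pytest.approx(res.R, abs=1e-12)
        assert res.f_value == pytest.approx(res.R / 0.98)

    def test_constant_lambda_closed_form(self):
        """With equal rates everywhere the incarceration process cancels and
        R = lambda (1-q)/c exactly."""
        for lam, c, q in ((0.3, 0.05, 0.05), (1.2, 0.2, 0.0), (0.07, 0.5, 0.9)):
            res = replacement_rate(
                _flat_table(lam), "pooled", IncarcerationRates(0.14, 0.05, 0.04),
                CareerParams(c=c, q=q),
            )
            assert res.R == pytest.approx(lam * (1 - q) / c, abs=1e-10)

    def test_full_quit_gives_zero(self):
        res = replacement_rate(
            NESI_EFR_POOLED, "pooled", NESI_INCARCERATION_OVERALL,
            CareerParams(c=0.1, q=1.0),
        )
        assert res.R == 0.0

    def test_proportional_to_one_minus_q(self):
        base = replacement_rate(
            NESI_EFR_POOLED, "pooled", NESI_INCARCERATION_OVERALL,
            CareerParams(c=0.1, q=0.0),
        )
        for q in (0.2, 0.5, 0.95):
            res = replacement_rate(
                NESI_EFR_POOLED, "pooled", NESI_INCARCERATION_OVERALL,
                CareerParams(c=0.1, q=q),
            )
            assert res.R == pytest.approx((1 - q) * base.R, rel=1e-12)

    def test_triple_sum_form_agrees(self):
        """The explicit (t, x) double expansion with never-incarcerated mass
        matches the survival-form closed evaluation to 1e-10."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            table = EFRLookupTable(
                strata={
                    "pooled": {
                        "never": tuple(rng.uniform(0, 1, 3)),
                        "ever": tuple(rng.uniform(0, 1, 3)),
                    }
                }
            )
            rates = IncarcerationRates(*rng.uniform(0.01, 0.4, 3))
            params = CareerParams(c=float(rng.uniform(0.03, 0.4)),
                                  q=float(rng.uniform(0, 0.9)))
            a = replacement_rate(table, "pooled", rates, params)
            b = replacement_rate_triple_sum(table, "pooled", rates, params, tol=1e-14)
            assert a.R == pytest.approx(b.R, abs=1e-10)
            assert b.truncation_error_bound < 1e-10

    def test_monotonicity_probes(self):
        table = NESI_EFR_POOLED
        rates = NESI_INCARCERATION_OVERALL

        def R(c=0.1, q=0.1, bump=None):
            t = table
            if bump:
                status, idx, eps = bump
                strata = {
                    "pooled": {
                        s: tuple(
                            v + (eps if s == status and i == idx else 0.0)
                            for i, v in enumerate(table.strata["pooled"][s])
                        )
                        for s in ("never", "ever")
                    }
                }
                t = EFRLookupTable(strata=strata)
            return replacement_rate(t, "pooled", rates, CareerParams(c=c, q=q)).R

        base = R()
        assert R(c=0.12) < base  # higher cessation, shorter careers
        assert R(q=0.15) < base  # more immediate quitting
        for status in ("never", "ever"):
            for idx in range(3):
                assert R(bump=(status, idx, 0.01)) > base

    def test_multi_stratum_weighted_combination(self):
        table = EFRLookupTable(
            strata={
                "F": {"never": (0.2,) * 3, "ever": (0.2,) * 3},
                "M": {"never": (0.4,) * 3, "ever": (0.4,) * 3},
            },
            weights={"F": 1.0, "M": 3.0},
        )
        params = CareerParams(c=0.1, q=0.0)
        res = replacement_rate(
            table, rates=IncarcerationRates(0.1, 0.1, 0.1), params=params
        )
        # flat tables: R_F = 2.0, R_M = 4.0, weights 1:3
        assert res.by_stratum["F"] == pytest.approx(2.0, abs=1e-10)
        assert res.by_stratum["M"] == pytest.approx(4.0, abs=1e-10)
        assert res.R == pytest.approx(0.25 * 2.0 + 0.75 * 4.0, abs=1e-10)

    def test_monte_carlo_career_oracle(self):
        """Simulated careers (immediate quit, yearly cessation hazard,
        piecewise incarceration switching the accrual rate) agree with the
        analytic R within 3 Monte-Carlo standard errors."""
        table = NESI_EFR_POOLED
        rates = NESI_INCARCERATION_OVERALL
        params = CareerParams(c=0.10, q=0.10)
        analytic = replacement_rate(table, "pooled", rates, params).R

        n = 400_000
        rng = np.random.default_rng(77)
        quit = rng.random(n) < params.q
        g = rng.geometric(params.c, size=n)  # active years for non-quitters
        g[quit] = 0
        # first-incarceration year via the piecewise geometric stages
        g1 = rng.geometric(rates.p1, size=n).astype(float)
        g2 = rng.geometric(rates.p2, size=n).astype(float)
        g3 = rng.geometric(rates.p3, size=n).astype(float)
        x = np.where(g1 <= 5, g1, np.where(g2 <= 5, 5 + g2, 10 + g3))
        ln = np.array(table.strata["pooled"]["never"])
        le = np.array(table.strata["pooled"]["ever"])
        # active years t = 0..g-1 split per career bin, then never/ever within
        # each bin according to whether t < x
        tot0 = np.minimum(g, 6)
        tot1 = np.clip(g - 6, 0, 5)
        tot2 = np.maximum(g - 11, 0)
        m = np.minimum(g, x)  # active-never years are t < min(g, x)
        nev0 = np.minimum(m, 6)
        nev1 = np.clip(m - 6, 0, 5)
        nev2 = np.maximum(m - 11, 0)
        accrual = (
            ln[0] * nev0 + le[0] * (tot0 - nev0)
            + ln[1] * nev1 + le[1] * (tot1 - nev1)
            + ln[2] * nev2 + le[2] * (tot2 - nev2)
        )
        mc = accrual.mean()
        se = accrual.std(ddof=1) / np.sqrt(n)
        assert abs(mc - analytic) < 3.0 * se


class TestQuitRate:
    @pytest.mark.parametrize(
        "R, c, expected",
        [(4.8, 0.05, 0.80), (2.7, 0.10, 0.67), (1.9, 0.15, 0.55), (5.5, 0.05, 0.83)],
    )
    def test_published_values(self, R, c, expected):
        qr = quit_rate_for_unit_replacement(R, c)
        assert round(qr.q_prime, 2) == expected
        assert not qr.already_below_replacement

    def test_boundary_zero(self):
        qr = quit_rate_for_unit_replacement(0.9, 0.1)
        assert qr.q_prime == pytest.approx(0.0, abs=1e-15)

    def test_below_replacement_flagged_not_clamped(self):
        qr = quit_rate_for_unit_replacement(0.5, 0.1)
        assert qr.q_prime < 0.0
        assert qr.already_below_replacement
        assert qr.clamped == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            quit_rate_for_unit_replacement(0.0, 0.1)
        with pytest.raises(ValueError):
            quit_rate_for_unit_replacement(2.0, 1.0)

    def test_reinserting_q_prime_returns_unit_replacement(self):
        """Re-evaluating the model at q' gives R = 1 to 1e-9."""
        for c in (0.05, 0.10, 0.15):
            res = replacement_rate(
                NESI_EFR_POOLED, "pooled", NESI_INCARCERATION_OVERALL,
                CareerParams(c=c, q=c),
            )
            qp = quit_rate_for_unit_replacement(res.R, c).q_prime
            res1 = replacement_rate(
                NESI_EFR_POOLED, "pooled", NESI_INCARCERATION_OVERALL,
                CareerParams(c=c, q=qp),
            )
            assert res1.R == pytest.approx(1.0, abs=1e-9)


class TestCohortEstimation:
    def test_efr_table_pooled_shape(self, small_cohort):
        df, _ = small_cohort
        table = efr_table_from_cohort(df)
        assert set(table.strata) == {"pooled"}
        for status in ("never", "ever"):
            assert len(table.strata["pooled"][status]) == 3

    def test_efr_table_by_sex_weights(self, small_cohort):
        df, _ = small_cohort
        table = efr_table_from_cohort(df, by_sex=True)
        assert set(table.strata) == {"F", "M"}
        assert table.weights["F"] + table.weights["M"] == len(df)

    def test_degenerate_cohort_zero_width_interval(self):
        # six cells of mutually identical respondents: every resample that
        # retains all cells reproduces the same EFR table, hence the same R
        blocks = [
            make_counts_cohort(40, 40, 40, n_others=1, career_years=t, ever=e)
            for t in (3, 8, 12)
            for e in (False, True)
        ]
        df = pd.concat(blocks, ignore_index=True)
        (lo, hi), vals, n_fail = replacement_ci(
            df, CareerParams(c=0.1, q=0.1), n_boot=40, seed=0, mode="efr"
        )
        assert lo == pytest.approx(hi)

    def test_single_replicate_collapses(self, small_cohort):
        df, _ = small_cohort
        (lo, hi), vals, _ = replacement_ci(
            df, CareerParams(c=0.1, q=0.1), n_boot=1, seed=3, mode="efr"
        )
        assert lo == pytest.approx(hi)
        assert vals.size == 1

    def test_scenarios_share_resamples(self, small_cohort):
        df, _ = small_cohort
        scenarios = [CareerParams(c=0.05, q=0.05), CareerParams(c=0.15, q=0.15)]
        cis, vals, _ = replacement_ci(df, scenarios, n_boot=30, seed=9, mode="efr")
        assert len(cis) == 2
        assert vals.shape[0] == 2
        # lower cessation keeps injectors active longer: larger R
        assert cis[0][0] > cis[1][0]

    def test_joint_interval_covers_generating_R(self):
        """Joint EFR + incarceration bootstrap intervals cover the analytic
        replacement rate of the generating parameters in most seeds.

        The generating config uses sex-identical incarceration rates, so the
        pooled estimator targets exactly the generating process and the
        analytic R is available in closed form.
        """
        params = CareerParams(c=0.05, q=0.05)
        shared = (0.14, 0.05, 0.04)
        cfg = CohortConfig(
            n_respondents=1000,
            incarceration_rates_by_sex={"F": shared, "M": shared},
        )
        strata = {
            "pooled": {
                status: tuple(
                    _truth_lambda(cfg, "M", b, status)  # sex-independent maps
                    for b in ("0-5", "6-10", ">=11")
                )
                for status in ("never", "ever")
            }
        }
        target = replacement_rate(
            EFRLookupTable(strata=strata), "pooled",
            IncarcerationRates(*shared), params,
        ).R
        covered = 0
        n_seeds = 8
        for seed in range(n_seeds):
            df, _ = generate_cohort(
                CohortConfig(
                    n_respondents=1000,
                    incarceration_rates_by_sex={"F": shared, "M": shared},
                    seed=1000 + seed,
                )
            )
            (lo, hi), _, _ = replacement_ci(
                df, params, n_boot=60, seed=seed, mode="joint"
            )
            if lo <= target <= hi:
                covered += 1
        # ~95% nominal coverage; 8 trials should nearly always cover >= 6
        assert covered >= 6


def _truth_lambda(cfg, sex, b, status):
    mu = cfg.others_present_mean
    inv = (1 - np.exp(-mu)) / mu
    return cfg.initiator_prob[(sex, b, status)] * cfg.initiation_count_mean[
        (sex, b, status)
    ] * inv
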