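import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airequity.health import (
    DEFAULT_CRFS,
    ConcentrationResponseFunction,
    avoided_cases,
    impact_assessment,
    pool_auto,
    pool_fixed,
    pool_random,
)

CRF = ConcentrationResponseFunction

# hand-derived oracle values (independent closed-form arithmetic)
AVOIDED_ORACLE = 0.46480447699550176  # 0.008 * 10000 * (1 - exp(-0.005827))
IMPACT_ORACLE = 0.5421545853092269  # 0.008 * 10000 * (1 - exp(-0.0068))
FIXED_SE_ORACLE = 0.0017888543819998318  # (1/0.002^2 + 1/0.004^2)^-0.5


class TestAvoidedCases:
    def test_closed_form(self):
        got = avoided_cases(0.008, 10_000, 0.005827, 1.0)
        assert got == pytest.approx(AVOIDED_ORACLE, rel=1e-12)
        assert got == pytest.approx(0.4648, abs=5e-5)

    def test_zero_delta(self):
        assert avoided_cases(0.008, 10_000, 0.005827, 0.0) == 0.0

    def test_saturation_bound(self):
        got = avoided_cases(0.008, 10_000, 20.0, 1.0)
        assert got < 80.0
        assert got == pytest.approx(80.0, rel=1e-8)

    def test_negative_delta_negative(self):
        assert avoided_cases(0.008, 10_000, 0.005827, -1.0) < 0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            avoided_cases(0.008, 10_000, 0.005827, float("nan"))
        with pytest.raises(ValueError):
            avoided_cases(0.008, 10_000, float("inf"), 1.0)

    @given(
        inc=st.floats(1e-4, 0.05),
        pop=st.floats(1.0, 1e6),
        beta=st.floats(1e-5, 0.05),
        dc=st.floats(1e-4, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_argument(self, inc, pop, beta, dc):
        base = avoided_cases(inc, pop, beta, dc)
        assert avoided_cases(inc * 1.01, pop, beta, dc) > base
        assert avoided_cases(inc, pop * 1.01, beta, dc) > base
        assert avoided_cases(inc, pop, beta * 1.01, dc) > base
        assert avoided_cases(inc, pop, beta, dc * 1.01) > base

    @given(beta=st.floats(1e-7, 1e-4), dc=st.floats(1e-3, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_small_signal_limit(self, beta, dc):
        if abs(beta * dc) >= 1e-3:
            return
        exact = avoided_cases(0.008, 10_000, beta, dc)
        linear = 0.008 * 10_000 * beta * dc
        assert exact == pytest.approx(linear, rel=1e-3)


class TestPoolFixed:
    def test_hand_inverse_variance(self):
        got = pool_fixed([CRF("a", 0.006, 0.002), CRF("b", 0.010, 0.004)])
        assert got.beta_pooled == pytest.approx(0.0068, rel=1e-12)
        assert got.se_pooled == pytest.approx(FIXED_SE_ORACLE, rel=1e-12)

    def test_single_effect_unchanged(self):
        got = pool_fixed([CRF("a", 0.0058269, 0.001)])
        assert got.beta_pooled == pytest.approx(0.0058269)
        assert got.se_pooled == pytest.approx(0.001)

    def test_two_identical_halve_variance(self):
        got = pool_fixed([CRF("a", 0.007, 0.002), CRF("b", 0.007, 0.002)])
        assert got.beta_pooled == pytest.approx(0.007)
        assert got.se_pooled == pytest.approx(0.002 / math.sqrt(2), rel=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError, match="zero standard error"):
            pool_fixed([CRF("a", 0.006, 0.0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])


class TestPoolRandom:
    def test_homogeneous_reduces_to_fixed(self):
        effects = [CRF("a", 0.0068, 0.002), CRF("b", 0.0069, 0.002)]
        rand = pool_random(effects)
        fixed = pool_fixed(effects)
        assert rand.tau2 == 0.0
        assert rand.beta_pooled == pytest.approx(fixed.beta_pooled, rel=1e-12)
        assert rand.se_pooled == pytest.approx(fixed.se_pooled, rel=1e-12)

    def test_heterogeneous_hand_dl(self):
        effects = [CRF("a", 0.006, 0.002), CRF("b", 0.020, 0.002)]
        got = pool_random(effects)
        # hand DL: Q = 24.5, tau2 = 23.5/250000 = 9.4e-5, se = 0.007
        assert got.heterogeneity_Q == pytest.approx(24.5, rel=1e-12)
        assert got.tau2 == pytest.approx(9.4e-5, rel=1e-12)
        assert got.beta_pooled == pytest.approx(0.013, rel=1e-12)
        assert got.se_pooled == pytest.approx(0.007, rel=1e-9)
        assert got.se_pooled > pool_fixed(effects).se_pooled

    def test_identical_effects_zero_tau2(self):
        got = pool_random([CRF("a", 0.007, 0.002), CRF("b", 0.007, 0.002)])
        assert got.tau2 == 0.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="two effects"):
            pool_random([CRF("a", 0.006, 0.002)])

    def test_oracle_equivalence_tau2_zero(self, rng):
        # random-effects with tau2 forced to 0 must equal fixed effects
        for _ in range(20):
            k = rng.integers(2, 6)
            effects = [
                CRF(f"e{i}", rng.normal(0.006, 0.0001), rng.uniform(0.001, 0.004))
                for i in range(k)
            ]
            rand = pool_random(effects)
            fixed = pool_fixed(effects)
            if rand.tau2 == 0.0:
                assert rand.beta_pooled == pytest.approx(fixed.beta_pooled, rel=1e-12)
                assert rand.se_pooled == pytest.approx(fixed.se_pooled, rel=1e-12)


class TestPoolAuto:
    def test_homogeneous_chooses_fixed(self):
        got = pool_auto([CRF("a", 0.0068, 0.002), CRF("b", 0.0069, 0.002)])
        assert got.method == "fixed"

    def test_heterogeneous_chooses_random(self):
        got = pool_auto([CRF("a", 0.006, 0.002), CRF("b", 0.020, 0.002)])
        assert got.method == "random"

    def test_single_effect_fixed(self):
        assert pool_auto([CRF("a", 0.006, 0.002)]).method == "fixed"


class TestFromRelativeRisk:
    def test_beta_from_rr(self):
        crf = CRF.from_relative_risk("k", 1.06)
        assert crf.beta == pytest.approx(math.log(1.06) / 10, rel=1e-12)

    def test_default_betas(self):
        by_name = {c.name: c for c in DEFAULT_CRFS}
        assert by_name["krewski"].beta == pytest.approx(0.0058269, abs=5e-8)
        assert by_name["jerrett"].beta == pytest.approx(0.0157004, abs=5e-8)

    def test_ci_gives_se(self):
        crf = CRF.from_relative_risk("k", 1.06, rr_ci=(1.04, 1.08))
        expect = (math.log(1.08) - math.log(1.04)) / (2 * 1.959963984540054 * 10)
        assert crf.se_beta == pytest.approx(expect, rel=1e-9)


class TestImpactAssessment:
    def one_tract(self):
        return pd.DataFrame(
            {
                "tract_id": ["T0"],
                "county_id": ["A"],
                "population": [10_000.0],
                "incidence_per_person_year": [0.008],
                "vulnerability_score": [50.0],
            }
        )

    def test_single_tract_pooled_beta(self):
        crfs = [CRF("a", 0.006, 0.002), CRF("b", 0.010, 0.004)]
        table = impact_assessment(
            self.one_tract(), pd.Series({"T0": 1.0}), crfs, "fixed"
        )
        assert table.loc[0, "avoided_deaths"] == pytest.approx(
            IMPACT_ORACLE, rel=1e-12
        )
        assert table.loc[0, "avoided_deaths_se"] > 0

    def test_zero_delta_zero_table(self, toy_tracts):
        exposures = pd.Series(0.0, index=toy_tracts["tract_id"].to_numpy())
        table = impact_assessment(toy_tracts, exposures)
        assert (table["avoided_deaths"] == 0).all()
        assert (table["avoided_deaths_se"] == 0).all()

    def test_partition_conservation(self, toy_tracts, rng):
        exposures = pd.Series(
            rng.uniform(0, 1, 4), index=toy_tracts["tract_id"].to_numpy()
        )
        table = impact_assessment(toy_tracts, exposures)
        merged = table.merge(toy_tracts[["tract_id", "county_id"]], on="tract_id")
        by_county = merged.groupby("county_id")["avoided_deaths"].sum()
        assert by_county.sum() == pytest.approx(table["avoided_deaths"].sum(), rel=1e-12)

    def test_row_order_ascending(self, toy_tracts):
        shuffled = toy_tracts.iloc[[2, 0, 3, 1]]
        exposures = pd.Series(0.5, index=toy_tracts["tract_id"].to_numpy())
        table = impact_assessment(shuffled, exposures)
        assert list(table["tract_id"]) == sorted(table["tract_id"])

    def test_invalid_pooling_mode(self, toy_tracts):
        exposures = pd.Series(0.5, index=toy_tracts["tract_id"].to_numpy())
        with pytest.raises(ValueError, match="pooling mode"):
            impact_assessment(toy_tracts, exposures, None, "bogus")

    def test_bounded_by_total_deaths(self, toy_tracts):
        exposures = pd.Series(100.0, index=toy_tracts["tract_id"].to_numpy())
        table = impact_assessment(toy_tracts, exposures)
        ceiling = (
            toy_tracts.sort_values("tract_id")["population"].to_numpy()
            * toy_tracts.sort_values("tract_id")["incidence_per_person_year"].to_numpy()
        )
        assert (table["avoided_deaths"].to_numpy() <= ceiling + 1e-12).all()

    def test_sign_follows_delta(self, toy_tracts):
        exposures = pd.Series(
            [0.5, -0.5, 0.0, 1.0], index=toy_tracts["tract_id"].to_numpy()
        )
        table = impact_assessment(toy_tracts, exposures)
        assert np.all(np.sign(table["avoided_deaths"]) == np.sign(table["delta_c"]))


class TestParameterRecovery:
    def test_beta_recovered_from_aggregate(self, small_region):
        from scipy.optimize import brentq

        from airequity.exposure import aggregate_to_tracts

        beta_star = 0.0058269
        tracts = small_region.tracts
        dc = (
            aggregate_to_tracts(
                small_region.scenario_deltas["scenario"], small_region.weights
            )
            .reindex(tracts["tract_id"])
            .to_numpy()
        )
        inc = tracts["incidence_per_person_year"].to_numpy()
        pop = tracts["population"].to_numpy()
        target = float(np.sum(avoided_cases(inc, pop, beta_star, dc)))

        recovered = brentq(
            lambda b: float(np.sum(avoided_cases(inc, pop, b, dc))) - target,
            1e-6, 0.1, xtol=1e-15, rtol=1e-14,
        )
        assert recovered == pytest.approx(beta_star, rel=1e-6)
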