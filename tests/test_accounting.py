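import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pregtrends import (
    GROUPS,
    DEFAULT_INTENTION_MAP,
    PopulationGroup,
    ExposureSurface,
    RateSurface,
    PregnancyAccounts,
    group_pregnancies,
    total_abortions,
    miscarriages,
    pregnancy_identity,
    compute_accounts,
    intention_split,
    indicator_table,
    INDICATORS,
)
from pregtrends.accounting import implied_births

from conftest import random_surfaces

F = len(GROUPS)


class TestPopulationGroups:
    def test_six_stable_ordered_groups(self):
        assert len(GROUPS) == 6
        assert len(set(GROUPS)) == 6
        assert GROUPS == tuple(sorted(GROUPS, key=lambda g: GROUPS.index(g)))

    def test_intention_map_is_total_and_follows_need_status(self):
        assert set(DEFAULT_INTENTION_MAP) == set(GROUPS)
        for g in GROUPS:
            expected = "intended" if g.need_status == "no_need" else "unintended"
            assert DEFAULT_INTENTION_MAP[g] == expected

    def test_unknown_statuses_rejected(self):
        with pytest.raises(ValueError):
            PopulationGroup("divorced", "no_need")
        with pytest.raises(ValueError):
            PopulationGroup("married", "sometimes")


class TestGroupPregnancies:
    def test_direct_product(self):
        w = np.full((F, 1, 1), 1000.0)
        rates = RateSurface(
            omega=np.full((F, 1, 1), 0.1), alpha=np.full((F, 1, 1), 0.5)
        )
        out = group_pregnancies(w, rates, period_width=1.0)
        assert np.allclose(out, 100.0)

    def test_zero_exposure_gives_zero(self):
        w = np.zeros((F, 1, 1))
        rates = RateSurface(
            omega=np.full((F, 1, 1), 0.3), alpha=np.full((F, 1, 1), 0.5)
        )
        assert np.all(group_pregnancies(w, rates) == 0.0)

    def test_sum_matches_brute_force_loop(self):
        exposure, rates = random_surfaces(seed=1)
        out = group_pregnancies(exposure, rates, period_width=5.0)
        # independent triple loop oracle
        for c in range(out.shape[1]):
            for t in range(out.shape[2]):
                total = sum(
                    exposure.women[f, c, t] * rates.omega[f, c, t] * 5.0
                    for f in range(F)
                )
                assert np.isclose(out[:, c, t].sum(), total)

    def test_dimension_mismatch_raises(self):
        rates = RateSurface(
            omega=np.full((F, 2, 2), 0.1), alpha=np.full((F, 2, 2), 0.5)
        )
        with pytest.raises(ValueError):
            group_pregnancies(np.ones((F, 3, 2)), rates)


class TestTotalAbortions:
    def test_two_group_arithmetic(self):
        # (w, omega, alpha) = (1000, 0.1, 0.5) and (500, 0.2, 0.25)
        w = np.zeros((F, 1, 1))
        om = np.full((F, 1, 1), 1e-9)
        al = np.full((F, 1, 1), 0.5)
        w[0], om[0], al[0] = 1000.0, 0.1, 0.5
        w[1], om[1], al[1] = 500.0, 0.2, 0.25
        out = total_abortions(w, RateSurface(om, al), period_width=1.0)
        assert np.allclose(out, 75.0)

    def test_alpha_to_zero_limit(self):
        exposure, rates = random_surfaces(seed=2)
        rates.alpha[:] = 1e-12
        assert np.all(total_abortions(exposure, rates) < 1e-3)

    def test_matches_brute_force_triple_loop(self):
        exposure, rates = random_surfaces(seed=3)
        out = total_abortions(exposure, rates, period_width=5.0)
        C, T = out.shape
        for c in range(C):
            for t in range(T):
                oracle = sum(
                    exposure.women[f, c, t]
                    * rates.omega[f, c, t]
                    * rates.alpha[f, c, t]
                    * 5.0
                    for f in range(F)
                )
                assert np.isclose(out[c, t], oracle)

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            RateSurface(omega=np.ones((F, 1, 1)), alpha=np.full((F, 1, 1), 1.2))


class TestMiscarriagesAndIdentity:
    def test_one_per_ten_abortions(self):
        assert miscarriages(100.0, 0.0) == pytest.approx(10.0)

    def test_one_per_five_births(self):
        assert miscarriages(0.0, 100.0) == pytest.approx(20.0)

    def test_zero_inputs(self):
        assert miscarriages(0.0, 0.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            miscarriages(-1.0, 0.0)
        with pytest.raises(ValueError):
            pregnancy_identity(-1.0, 0.0)

    @pytest.mark.parametrize(
        "births,abortions,expected",
        [(1.0, 0.0, 1.2), (0.0, 1.0, 1.1), (100.0, 50.0, 175.0)],
    )
    def test_pregnancy_identity_values(self, births, abortions, expected):
        assert pregnancy_identity(births, abortions) == pytest.approx(expected)

    @given(
        b=st.floats(min_value=0, max_value=1e7),
        a=st.floats(min_value=0, max_value=1e7),
    )
    @settings(max_examples=1000, deadline=None)
    def test_identity_equals_components(self, b, a):
        assert pregnancy_identity(b, a) == pytest.approx(
            b + a + miscarriages(a, b), rel=1e-12, abs=1e-9
        )


class TestAccountsConservation:
    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_pregnancies_conserved(self, seed):
        exposure, rates = random_surfaces(seed)
        acc = compute_accounts(exposure, rates)
        np.testing.assert_allclose(
            acc.Omega, acc.births_implied + acc.Psi + acc.miscarriages,
            rtol=1e-12,
        )
        # group-level totals agree with summed groups exactly
        np.testing.assert_array_equal(acc.Omega, acc.omega_f.sum(axis=0))
        np.testing.assert_array_equal(acc.Psi, acc.psi_f.sum(axis=0))

    def test_abortions_within_group_pregnancies(self):
        exposure, rates = random_surfaces(seed=7)
        acc = compute_accounts(exposure, rates)
        assert np.all(acc.psi_f >= 0)
        assert np.all(acc.psi_f <= acc.omega_f)

    def test_linearity_in_exposure(self):
        exposure, rates = random_surfaces(seed=8)
        acc1 = compute_accounts(exposure, rates)
        ind1 = indicator_table(acc1, exposure.total_women)
        exposure.women = exposure.women * 2.0
        acc2 = compute_accounts(exposure, rates)
        ind2 = indicator_table(acc2, exposure.total_women)
        np.testing.assert_allclose(acc2.Omega, 2 * acc1.Omega, rtol=1e-12)
        np.testing.assert_allclose(acc2.Psi, 2 * acc1.Psi, rtol=1e-12)
        for name in INDICATORS:
            if name.startswith("pct_"):
                np.testing.assert_allclose(ind2[name], ind1[name], rtol=1e-10)

    def test_aggregation_order_independence(self):
        exposure, rates = random_surfaces(seed=9)
        acc = compute_accounts(exposure, rates)
        by_group_then_country = acc.omega_f.sum(axis=0).sum(axis=0)
        by_country_then_group = acc.omega_f.sum(axis=1).sum(axis=0)
        np.testing.assert_allclose(
            by_group_then_country, by_country_then_group, rtol=1e-12
        )


class TestIntentionSplit:
    def test_no_need_only_means_zero_unintended(self):
        w = np.zeros((F, 1, 1))
        for i, g in enumerate(GROUPS):
            if g.need_status == "no_need":
                w[i] = 1000.0
        rates = RateSurface(
            omega=np.full((F, 1, 1), 0.1), alpha=np.full((F, 1, 1), 0.1)
        )
        split = intention_split(compute_accounts(w, rates))
        assert split["pregnancies_unintended"] == pytest.approx(0.0)

    def test_symmetric_surface_splits_one_third_intended(self):
        w = np.full((F, 1, 1), 1000.0)
        rates = RateSurface(
            omega=np.full((F, 1, 1), 0.1), alpha=np.full((F, 1, 1), 0.1)
        )
        acc = compute_accounts(w, rates)
        split = intention_split(acc)
        # 2 of 6 groups are no-need under the default map
        assert split["pregnancies_intended"] == pytest.approx(acc.Omega / 3)
        assert split["pregnancies_unintended"] == pytest.approx(2 * acc.Omega / 3)

    def test_split_conserves_totals(self):
        exposure, rates = random_surfaces(seed=10)
        acc = compute_accounts(exposure, rates)
        split = intention_split(acc)
        np.testing.assert_allclose(
            split["pregnancies_intended"] + split["pregnancies_unintended"],
            acc.Omega, rtol=1e-12,
        )
        np.testing.assert_allclose(
            split["births_intended"] + split["births_unintended"],
            acc.births_implied, rtol=1e-12,
        )

    def test_unmapped_group_rejected(self):
        exposure, rates = random_surfaces(seed=11)
        acc = compute_accounts(exposure, rates)
        partial = {g: "unintended" for g in GROUPS[:-1]}
        with pytest.raises(ValueError):
            intention_split(acc, partial)


class TestIndicatorTable:
    def test_emits_full_published_indicator_set(self):
        exposure, rates = random_surfaces(seed=12)
        ind = indicator_table(compute_accounts(exposure, rates), exposure.total_women)
        assert tuple(ind) == INDICATORS
        assert len(INDICATORS) == 14

    def test_percent_complements_and_outcome_shares(self):
        exposure, rates = random_surfaces(seed=13)
        ind = indicator_table(compute_accounts(exposure, rates), exposure.total_women)
        np.testing.assert_allclose(
            ind["pct_pregnancies_unintended"] + ind["pct_pregnancies_intended"],
            100.0, rtol=1e-10,
        )
        np.testing.assert_allclose(
            ind["pct_births_unintended"] + ind["pct_births_intended"],
            100.0, rtol=1e-10,
        )
        outcome_total = (
            ind["pct_pregnancies_abortion"]
            + ind["pct_pregnancies_miscarriage"]
            + 100.0 * compute_accounts(exposure, rates).births_implied
            / compute_accounts(exposure, rates).Omega
        )
        np.testing.assert_allclose(outcome_total, 100.0, rtol=1e-10)

    def test_toy_abortion_rate(self):
        # Omega=200, Psi=50, 10,000 women, 1-year convention -> 5 per 1,000
        omega_f = np.full((F, 1, 1), 200.0 / F)
        psi_f = np.full((F, 1, 1), 50.0 / F)
        acc = PregnancyAccounts(
            omega_f=omega_f, psi_f=psi_f, births_f=implied_births(omega_f, psi_f)
        )
        ind = indicator_table(acc, np.full((1, 1), 10000.0), period_width=1.0)
        assert ind["abortion_rate"][0, 0] == pytest.approx(5.0)

    def test_nonpositive_women_rejected(self):
        exposure, rates = random_surfaces(seed=14)
        acc = compute_accounts(exposure, rates)
        with pytest.raises(ValueError):
            indicator_table(acc, np.zeros_like(exposure.total_women))


class TestExposureSurface:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ExposureSurface(
                countries=["a"], periods=[1990],
                women=-np.ones((F, 1, 1)), births=np.ones((1, 1)),
            )

    def test_frame_round_trip(self):
        exposure, _ = random_surfaces(seed=15)
        back = ExposureSurface.from_frames(
            exposure.to_frame(), exposure.births_frame()
        )
        np.testing.assert_allclose(back.women, exposure.women)
        np.testing.assert_allclose(back.births, exposure.births)
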