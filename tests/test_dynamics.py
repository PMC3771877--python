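import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisweep import (
    PopState,
    SingleStrainParams,
    TwoStrainParams,
    equilibria_single_CI,
    equilibrium_single_noCI,
    invasion_when_rare,
    invert_equilibrium_for_F,
    iterate,
    iterate_single,
    recursion_slope,
    step_single_CI,
    step_single_noCI,
    step_two_strain,
)
from cisweep.reporting import round_half_away

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_ci_step(p, F, mu, H):
    """Explicit ova-class x hatch-outcome bookkeeping for one CI generation.

    Ova: infected from infected mothers (weight F p (1-mu), always hatch),
    uninfected from infected mothers (F p mu) and from uninfected mothers
    (1-p); uninfected ova fertilized by an infected male (probability p)
    hatch at relative rate H, otherwise fully.
    """
    infected_ova = F * p * (1.0 - mu)
    uninfected_ova = F * p * mu + (1.0 - p)
    hatch_uninf = (1.0 - p) * 1.0 + p * H
    hatched_infected = infected_ova
    hatched_uninfected = uninfected_ova * hatch_uninf
    return hatched_infected / (hatched_infected + hatched_uninfected)


def scan_fixed_points(F, mu, H, grid=1e-5, tol=1e-8):
    """Interior fixed points by sign-change scan + bisection, using the
    brute-force step (independent of the quadratic route)."""
    p = np.arange(grid, 1.0, grid)
    f = brute_force_ci_step(p, F, mu, H) - p
    sign_change = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
    roots = []
    for i in sign_change:
        lo, hi = p[i], p[i + 1]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if (brute_force_ci_step(lo, F, mu, H) - lo) * (
                brute_force_ci_step(mid, F, mu, H) - mid
            ) <= 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        roots.append(0.5 * (lo + hi))
    return roots


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

valid_F = st.floats(min_value=0.7, max_value=1.3)
valid_mu = st.floats(min_value=0.0, max_value=0.2)
valid_H = st.floats(min_value=0.0, max_value=1.0)
unit = st.floats(min_value=0.0, max_value=1.0)


@st.composite
def pop_states(draw):
    a = draw(st.floats(min_value=0.0, max_value=1.0))
    r = draw(st.floats(min_value=0.0, max_value=1.0))
    o = draw(st.floats(min_value=0.0, max_value=1.0))
    total = a + r + o
    if total == 0.0:
        return PopState(p_A=0.0, p_R=0.0, p_O=1.0)
    return PopState(p_A=a / total, p_R=r / total, p_O=o / total)


@st.composite
def two_strain_params_st(draw):
    return TwoStrainParams(
        F_A=draw(valid_F),
        mu_A=draw(valid_mu),
        F_R=draw(valid_F),
        mu_R=draw(valid_mu),
        H=draw(valid_H),
    )


# ---------------------------------------------------------------------------
# PopState / Trajectory
# ---------------------------------------------------------------------------


class TestPopState:
    def test_third_class_derived(self):
        s = PopState(p_A=0.2, p_R=0.3)
        assert s.p_O == pytest.approx(0.5, abs=1e-15)

    def test_renormalized_exactly(self):
        s = PopState(p_A=0.2 + 1e-10, p_R=0.3, p_O=0.5)
        assert s.p_A + s.p_R + s.p_O == pytest.approx(1.0, abs=1e-15)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PopState(p_A=0.5, p_R=0.5, p_O=0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            PopState(p_A=-0.2, p_R=0.6, p_O=0.6)


class TestTrajectory:
    def test_zero_generations(self, two_strain_params, displacement_start):
        traj = iterate(displacement_start, two_strain_params, 0)
        assert len(traj) == 1
        assert traj[0] == displacement_start

    def test_negative_generations(self, two_strain_params, displacement_start):
        with pytest.raises(ValueError):
            iterate(displacement_start, two_strain_params, -1)

    def test_generation_indexing(self, two_strain_params, displacement_start):
        traj = iterate(displacement_start, two_strain_params, 5)
        assert [t for t, _ in traj] == [0, 1, 2, 3, 4, 5]

    def test_csv_roundtrip(self, tmp_path, two_strain_params, displacement_start):
        import pandas as pd

        traj = iterate(displacement_start, two_strain_params, 10)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["generation", "p_A", "p_R", "p_O"]
        np.testing.assert_allclose(df["p_A"], traj.p_A, atol=1e-15)

    def test_monotone_approach_to_stable_equilibrium(self):
        # fisherian single-strain: p_A strictly increases from below p_s
        params = TwoStrainParams(F_A=1.061, mu_A=0.023, F_R=1.0, mu_R=0.0, H=1.0)
        traj = iterate(PopState(p_A=0.054, p_R=0.0), params, 200)
        assert np.all(np.diff(traj.p_A) > 0)


# ---------------------------------------------------------------------------
# single strain, no CI
# ---------------------------------------------------------------------------


class TestStepNoCI:
    def test_absorbing_at_zero(self, strain_a_params):
        assert step_single_noCI(0.0, strain_a_params) == 0.0

    def test_neutral_identity(self):
        assert step_single_noCI(0.3, SingleStrainParams(F=1.0, mu=0.0)) == 0.3

    def test_paper_trajectory_with_exactly_inverted_F(self):
        # the printed endpoint 0.529 corresponds to the unrounded inversion
        # of the equilibrium expression, F = 0.4/0.377
        F = invert_equilibrium_for_F(0.6, 0.023)
        p = iterate_single(0.054, SingleStrainParams(F=F, mu=0.023), 120)[-1]
        assert round_half_away(p, 3) == 0.529

    def test_trajectory_sensitivity_to_rounded_F(self, strain_a_params):
        # with F rounded to 1.061 the endpoint lands one print-unit lower
        p = iterate_single(0.054, strain_a_params, 120)[-1]
        assert round_half_away(p, 3) == 0.528

    def test_out_of_range_p(self, strain_a_params):
        with pytest.raises(ValueError):
            step_single_noCI(1.5, strain_a_params)


class TestEquilibriumNoCI:
    def test_point_estimate_equilibrium(self, strain_a_params):
        res = equilibrium_single_noCI(strain_a_params)
        assert res.regime == "fisherian"
        assert round_half_away(res.p_s, 3) == 0.600

    def test_perfect_transmission_fixes(self):
        res = equilibrium_single_noCI(SingleStrainParams(F=1.05, mu=0.0))
        assert res.p_s == 1.0

    def test_no_invasion_when_growth_below_one(self):
        res = equilibrium_single_noCI(SingleStrainParams(F=1.02, mu=0.05))
        assert res.regime == "no_invasion"
        assert res.p_s is None

    def test_F_equal_one_with_leakage_is_no_invasion(self):
        res = equilibrium_single_noCI(SingleStrainParams(F=1.0, mu=0.01))
        assert res.regime == "no_invasion"


class TestInvertEquilibrium:
    @pytest.mark.parametrize(
        "mu,expected",
        [(0.023, 1.061), (0.003, 1.008), (0.049, 1.140)],
    )
    def test_printed_values(self, mu, expected):
        assert round_half_away(invert_equilibrium_for_F(0.6, mu), 3) == expected

    def test_neutral_limit(self):
        assert invert_equilibrium_for_F(0.6, 0.0) == 1.0

    def test_roundtrip(self):
        # mu = 0 gives the neutral F = 1 which sustains no equilibrium,
        # so the roundtrip is only defined for mu > 0
        for p_hat in (0.1, 0.5, 0.9):
            for mu in (0.001, 0.01, 0.05):
                if mu >= 1 - p_hat:
                    continue
                F = invert_equilibrium_for_F(p_hat, mu)
                res = equilibrium_single_noCI(SingleStrainParams(F=F, mu=mu))
                assert res.p_s == pytest.approx(p_hat, abs=1e-10)

    def test_unreachable_equilibrium(self):
        with pytest.raises(ValueError):
            invert_equilibrium_for_F(0.6, 0.4)


# ---------------------------------------------------------------------------
# single strain, CI
# ---------------------------------------------------------------------------


class TestStepCI:
    def test_fixation_absorbing_when_transmission_perfect(self):
        params = SingleStrainParams(F=0.95, mu=0.0, H=0.55)
        assert step_single_CI(1.0, params) == 1.0

    @pytest.mark.parametrize("p", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_no_ci_reduction(self, p):
        params = SingleStrainParams(F=1.05, mu=0.02, H=1.0)
        assert step_single_CI(p, params) == pytest.approx(
            step_single_noCI(p, params), abs=1e-14
        )

    def test_brute_force_oracle(self):
        expected = brute_force_ci_step(0.5, 0.95, 0.045, 0.55)
        got = step_single_CI(0.5, SingleStrainParams(F=0.95, mu=0.045, H=0.55))
        assert got == pytest.approx(expected, abs=1e-14)


class TestEquilibriaCI:
    def test_bistable_printed_stable(self, strain_r_params):
        res = equilibria_single_CI(strain_r_params)
        assert res.regime == "bistable"
        assert round_half_away(res.p_s, 2) == 0.93

    def test_bistable_unstable_differs_from_printed(self, strain_r_params):
        # direct solution gives ~0.232 where the printed figure is 0.22
        res = equilibria_single_CI(strain_r_params)
        assert res.p_u == pytest.approx(0.2318, abs=5e-4)

    def test_fisherian_at_high_F(self):
        res = equilibria_single_CI(SingleStrainParams(F=1.1, mu=0.045, H=0.55))
        assert res.regime == "fisherian"
        assert res.p_u == 0.0
        assert round_half_away(res.p_s, 2) == 0.94

    def test_equilibria_are_fixed_points(self, strain_r_params):
        res = equilibria_single_CI(strain_r_params)
        for p in (res.p_u, res.p_s):
            assert abs(step_single_CI(p, strain_r_params) - p) < 1e-10

    def test_stability_classification_by_slope(self, strain_r_params):
        res = equilibria_single_CI(strain_r_params)
        assert abs(recursion_slope(res.p_u, strain_r_params)) > 1
        assert abs(recursion_slope(res.p_s, strain_r_params)) < 1

    def test_no_ci_delegates(self):
        params = SingleStrainParams(F=1.061, mu=0.023, H=1.0)
        assert equilibria_single_CI(params) == equilibrium_single_noCI(params)

    def test_ci_only_maintenance_vanishes_as_H_to_one(self):
        # with weak CI and F(1-mu) < 1 the infection cannot persist
        res = equilibria_single_CI(SingleStrainParams(F=0.95, mu=0.045, H=0.999))
        assert res.regime == "no_invasion"

    def test_perfect_transmission_fisherian_fixes(self):
        res = equilibria_single_CI(SingleStrainParams(F=1.05, mu=0.0, H=0.55))
        assert res.regime == "fisherian"
        assert res.p_s == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_quadratic_handled(self):
        # leading coefficient s_h (1 - F mu) == 0
        res = equilibria_single_CI(SingleStrainParams(F=2.0, mu=0.5, H=0.5))
        assert res.regime == "no_invasion"

    def test_oracle_equivalence_random_parameters(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(120):
            F = rng.uniform(0.7, 1.3)
            mu = rng.uniform(0.0, 0.2)
            H = rng.uniform(0.0, 0.999)
            res = equilibria_single_CI(SingleStrainParams(F=F, mu=mu, H=H))
            expected = scan_fixed_points(F, mu, H)
            got = []
            if res.regime == "bistable":
                got = [res.p_u, res.p_s]
            elif res.regime == "fisherian" and 0 < res.p_s < 1:
                got = [res.p_s]
            assert len(got) == len(expected)
            for g, e in zip(sorted(got), sorted(expected)):
                assert g == pytest.approx(e, abs=1e-6)
            checked += 1
        assert checked >= 100

    def test_unstable_equilibrium_monotone_in_F(self):
        mu, H = 0.045, 0.55
        previous = None
        for F in np.linspace(0.9, 1.2, 61):
            res = equilibria_single_CI(SingleStrainParams(F=F, mu=mu, H=H))
            if res.regime == "no_invasion":
                continue
            p_u = res.p_u
            if F * (1 - mu) > 1:
                assert p_u == 0.0
            if previous is not None:
                assert p_u <= previous + 1e-12
            previous = p_u


# ---------------------------------------------------------------------------
# two strains
# ---------------------------------------------------------------------------


class TestStepTwoStrain:
    def test_single_strain_reduction_A(self, two_strain_params):
        state = PopState(p_A=0.3, p_R=0.0, p_O=0.7)
        nxt = step_two_strain(state, two_strain_params)
        expected = step_single_noCI(0.3, two_strain_params.strain_a)
        assert nxt.p_A == pytest.approx(expected, abs=1e-14)
        assert nxt.p_R == 0.0

    def test_uninfected_fixation_absorbing(self, two_strain_params):
        state = PopState(p_A=0.0, p_R=0.0, p_O=1.0)
        nxt = step_two_strain(state, two_strain_params)
        assert (nxt.p_A, nxt.p_R, nxt.p_O) == (0.0, 0.0, 1.0)

    def test_displacement_within_40_generations(
        self, two_strain_params, displacement_start
    ):
        traj = iterate(displacement_start, two_strain_params, 60)
        first = traj.first_below(0.01, "p_A")
        assert first is not None and first <= 40

    def test_ci_strain_near_stable_equilibrium_at_45(
        self, two_strain_params, displacement_start
    ):
        traj = iterate(displacement_start, two_strain_params, 45)
        assert round_half_away(traj.p_R[-1], 2) == 0.94


class TestInvasionWhenRare:
    def test_strain_a_invades_uninfected(self):
        p = TwoStrainParams(F_A=1.061, mu_A=0.023, F_R=1.0, mu_R=0.0, H=1.0)
        assert invasion_when_rare(p, invader="A") is True

    def test_boundary_equality_is_no_increase(self):
        p = TwoStrainParams(F_A=1.061, mu_A=0.023, F_R=1.061, mu_R=0.023, H=0.55)
        assert invasion_when_rare(p, invader="R", resident="A") is False

    def test_point_estimates_fail_rare_condition_yet_displace(
        self, two_strain_params, displacement_start
    ):
        # F_R(1-mu_R) = 1.0314 < F_A(1-mu_A) = 1.0366: the rare-invasion
        # condition fails, but displacement from p_R = 0.09 (where CI
        # already operates) still occurs
        assert invasion_when_rare(two_strain_params, "R", resident="A") is False
        traj = iterate(displacement_start, two_strain_params, 60)
        assert traj.p_A[-1] < 0.01 and traj.p_R[-1] > 0.9

    def test_resident_must_persist(self):
        p = TwoStrainParams(F_A=1.0, mu_A=0.05, F_R=1.1, mu_R=0.0, H=0.55)
        with pytest.raises(ValueError, match="persist"):
            invasion_when_rare(p, "R", resident="A")

    @pytest.mark.parametrize(
        "invader,resident",
        [("A", None), ("R", None), ("R", "A"), ("A", "R")],
    )
    def test_consistent_with_numerical_derivative(self, invader, resident):
        rng = np.random.default_rng(7)
        eps = 1e-8
        for _ in range(20):
            params = TwoStrainParams(
                F_A=rng.uniform(1.0, 1.2),
                mu_A=rng.uniform(0.0, 0.05),
                F_R=rng.uniform(0.9, 1.2),
                mu_R=rng.uniform(0.0, 0.08),
                H=rng.uniform(0.3, 0.9),
            )
            try:
                predicted = invasion_when_rare(params, invader, resident)
            except ValueError:
                continue
            if resident is None:
                resident_state = PopState(p_A=0.0, p_R=0.0, p_O=1.0)
            elif resident == "A":
                eq = equilibrium_single_noCI(params.strain_a)
                resident_state = PopState(p_A=eq.p_s, p_R=0.0)
            else:
                eq = equilibria_single_CI(params.strain_r)
                if eq.p_s is None:
                    continue
                resident_state = PopState(p_A=0.0, p_R=eq.p_s)
            scale = 1.0 - eps
            if invader == "A":
                state = PopState(
                    p_A=eps,
                    p_R=resident_state.p_R * scale,
                    p_O=1.0 - eps - resident_state.p_R * scale,
                )
                growth = step_two_strain(state, params).p_A / eps
            else:
                state = PopState(
                    p_A=resident_state.p_A * scale,
                    p_R=eps,
                    p_O=1.0 - eps - resident_state.p_A * scale,
                )
                growth = step_two_strain(state, params).p_R / eps
            if abs(growth - 1.0) < 1e-6:  # too close to neutral to resolve
                continue
            assert (growth > 1.0) == predicted

    def test_invalid_labels(self, two_strain_params):
        with pytest.raises(ValueError):
            invasion_when_rare(two_strain_params, "X")
        with pytest.raises(ValueError):
            invasion_when_rare(two_strain_params, "A", resident="A")


# ---------------------------------------------------------------------------
# invariants (property-based)
# ---------------------------------------------------------------------------


class TestInvariants:
    @settings(max_examples=200, deadline=None)
    @given(state=pop_states(), params=two_strain_params_st())
    def test_frequency_conservation(self, state, params):
        nxt = step_two_strain(state, params)
        assert abs(nxt.p_A + nxt.p_R + nxt.p_O - 1.0) < 1e-12

    @settings(max_examples=200, deadline=None)
    @given(p=unit, params=two_strain_params_st())
    def test_reduction_to_noCI_strain(self, p, params):
        nxt = step_two_strain(PopState(p_A=p, p_R=0.0, p_O=1.0 - p), params)
        assert nxt.p_A == pytest.approx(
            step_single_noCI(p, params.strain_a), abs=1e-14
        )

    @settings(max_examples=200, deadline=None)
    @given(p=unit, params=two_strain_params_st())
    def test_reduction_to_CI_strain(self, p, params):
        nxt = step_two_strain(PopState(p_A=0.0, p_R=p, p_O=1.0 - p), params)
        assert nxt.p_R == pytest.approx(
            step_single_CI(p, params.strain_r), abs=1e-14
        )

    @settings(max_examples=150, deadline=None)
    @given(F=valid_F, mu=valid_mu, H=valid_H)
    def test_equilibria_are_fixed_points_and_classified(self, F, mu, H):
        params = SingleStrainParams(F=F, mu=mu, H=H)
        res = equilibria_single_CI(params)
        step = step_single_CI if params.s_h > 0 else step_single_noCI
        for p, expect_stable in ((res.p_u, False), (res.p_s, True)):
            if p is None or p in (0.0, 1.0):
                continue
            assert abs(step(p, params) - p) < 1e-10
            slope = recursion_slope(p, params)
            if abs(abs(slope) - 1.0) > 1e-4:  # skip marginal cases
                assert (abs(slope) < 1.0) == expect_stable
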