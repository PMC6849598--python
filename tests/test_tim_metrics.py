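import math

import numpy as np
import pytest

from timweb import (
    CommunityModel,
    SpeciesSpec,
    State,
    TIMSpec,
    Trajectory,
    TrophicLink,
    compute_all_metrics,
    find_equilibrium,
    simulate,
)
from timweb.exceptions import DomainError, UsageError
from timweb.experiments import build_demo, generate_random_chain
from timweb.tim_metrics import (
    metric_bcr_change,
    metric_cv,
    metric_flux_change,
    metric_jacobian_sensitivity,
    metric_net_sensitivity,
    metric_tmii,
)

from conftest import make_lv_cue


class TestFluxChange:
    def test_null_tim_gives_unit_ratio_zero_difference(self):
        model = build_demo("chain_linear", {"tims.T1.strength": 0.0})
        ratio, diff = metric_flux_change(model, "T1", np.array([2.0, 1.0, 3.0]))
        assert ratio == 1.0
        assert diff == 0.0

    def test_linear_fr_ratio_is_inverse_exponential(self):
        """With a linear functional response densities cancel: ratio = exp(-c K)."""
        model = make_lv_cue(0.5, 2.0)
        for R, C in [(1.0, 1.0), (3.7, 0.2)]:
            ratio, _ = metric_flux_change(model, "T1", np.array([R, C]))
            assert ratio == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_holling2_difference_hand_value(self):
        """a R/(1+a h R) vs doubled attack: 0.5 - 2/3 = -1/6 at unit densities."""
        species = [
            SpeciesSpec("R", "producer", 1.0, 0.1),
            SpeciesSpec("C", "consumer", 0.1, 0.0),
        ]
        links = [TrophicLink("R", "C", 1.0, 0.5, fr_form="holling2", handling_time=1.0)]
        tims = [
            TIMSpec("T1", modifier_id="", target=("R", "C"), strength=math.log(2.0),
                    mode="forced", forced_density=1.0)
        ]
        model = CommunityModel(species, links, tims)
        _, diff = metric_flux_change(model, "T1", np.array([1.0, 1.0]))
        assert diff == pytest.approx(0.5 - 2.0 / 3.0, abs=1e-12)

    def test_ratio_orientation_tracks_term(self):
        """Strengthened interaction (term > 1) means ratio < 1 for positive flux."""
        model = make_lv_cue(0.5, 2.0)  # term e > 1
        ratio, _ = metric_flux_change(model, "T1", np.array([1.0, 1.0]))
        assert ratio < 1.0
        weak = make_lv_cue(-0.5, 2.0)  # term 1/e < 1
        ratio, _ = metric_flux_change(weak, "T1", np.array([1.0, 1.0]))
        assert ratio > 1.0


class TestBcrChange:
    def test_null_tim_is_unity(self):
        model = build_demo("chain_linear", {"tims.T1.strength": 0.0})
        assert metric_bcr_change(model, "T1", guess=np.ones(3)) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("c", [-1.0, -0.5, 0.5, 1.0])
    @pytest.mark.parametrize("K", [0.5, 2.0])
    def test_lv_cue_closed_form(self, c, K):
        """I*(c)/I*(0) = exp(-c K) on the analytically solvable cue model."""
        model = make_lv_cue(c, K)
        ratio = metric_bcr_change(model, "T1", guess=np.array([1.0, 1.0]))
        assert ratio == pytest.approx(math.exp(-c * K), rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_ratio_of_independent_solves(self, seed):
        model = generate_random_chain(seed).model
        ratio = metric_bcr_change(model, "T1", guess=np.ones(3), seed=seed)
        r1 = find_equilibrium(model, np.ones(3), seed=seed)
        r0 = find_equilibrium(model.with_tim_strength("T1", 0.0), np.ones(3), seed=seed)
        i = model.index("S0")
        expected = r1.state.densities[i] / r0.state.densities[i]
        assert ratio == pytest.approx(expected, abs=1e-8)


class TestTmii:
    def test_zero_when_modifier_absent_from_interactor_rate(self):
        """dI'/dK = 0 when c = 0 and K has no trophic link to the resource."""
        model = build_demo("chain_linear", {"tims.T1.strength": 0.0})
        res = find_equilibrium(model, np.ones(3))
        di_dk, dj_dk = metric_tmii(model, "T1", res.state)
        assert di_dk == 0.0
        # K preys on J: dJ'/dK = -(attack of C on H) * H at the state
        a2 = model.link_by_key("H", "C").attack_rate
        H = res.state.densities[model.index("H")]
        assert dj_dk == pytest.approx(-a2 * H, rel=1e-10)

    def test_matches_jacobian_entries(self):
        model = build_demo("chain_nonlinear")
        st = State(np.array([2.0, 1.0, 0.5]))
        from timweb import jacobian

        A = jacobian(model, st)
        pair = metric_tmii(model, "T1", st)
        assert pair[0] == A.entry("P", "C")
        assert pair[1] == A.entry("H", "C")

    def test_forced_mode_rejected(self):
        model = make_lv_cue(0.5, 1.0)
        with pytest.raises(UsageError, match="state coordinate"):
            metric_tmii(model, "T1", np.array([1.0, 1.0]))


class TestJacobianSensitivity:
    def test_null_tim_without_other_entanglement_is_zero(self):
        model = make_lv_cue(0.0, 1.0)
        pair = metric_jacobian_sensitivity(model, "T1", np.array([0.8, 2.0]))
        assert pair == (0.0, 0.0)

    def test_lv_cue_closed_form(self):
        """A_IJ = -a exp(cK) I so dA_IJ/dK = -a c exp(cK) I = -0.25 at K=0, I=1."""
        model = make_lv_cue(0.5, 0.0)
        pair = metric_jacobian_sensitivity(model, "T1", np.array([1.0, 1.0]))
        assert pair[0] == pytest.approx(-0.25, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_symbolic_matches_nested_finite_differences(self, seed):
        model = generate_random_chain(seed, {"fr_form": "holling2", "handling": (0.05, 0.3)}).model
        res = find_equilibrium(model, np.ones(3), seed=seed)
        sym = metric_jacobian_sensitivity(model, "T1", res.state, method="symbolic")
        fd = metric_jacobian_sensitivity(model, "T1", res.state, method="finite_difference")
        scale = max(abs(sym[0]), abs(sym[1]), 1e-2)
        assert max(abs(sym[0] - fd[0]), abs(sym[1] - fd[1])) / scale < 1e-4


class TestNetSensitivity:
    def test_k_independent_system_has_zero_derivative(self):
        model = make_lv_cue(0.0, 1.0)
        pair = metric_net_sensitivity(model, "T1", np.array([1.0, 1.5]))
        assert pair == pytest.approx((0.0, 0.0), abs=1e-14)

    @pytest.mark.parametrize("seed", range(8))
    def test_identity_matches_finite_difference_of_net_effects(self, seed):
        model = generate_random_chain(seed, {"fr_form": "holling2", "handling": (0.05, 0.3)}).model
        res = find_equilibrium(model, np.ones(3), seed=seed)
        sym = metric_net_sensitivity(model, "T1", res.state, method="symbolic")
        fd = metric_net_sensitivity(model, "T1", res.state, method="finite_difference")
        scale = max(abs(sym[0]), abs(sym[1]), 1e-2)
        assert max(abs(sym[0] - fd[0]), abs(sym[1] - fd[1])) / scale < 1e-4

    def test_density_mediated_effect_survives_zero_strength(self):
        """c = 0 with a trophically connected modifier: direct sensitivity is
        exactly zero but the net (press-perturbation) sensitivity is not."""
        model = build_demo(
            "chain_nonlinear",
            {"tims.T1.strength": 0.0, "species.C.self_limitation": 0.05},
        )
        res = find_equilibrium(model, np.ones(3))
        assert res.converged and res.feasible
        direct = metric_jacobian_sensitivity(model, "T1", res.state)
        total = metric_net_sensitivity(model, "T1", res.state)
        assert direct == (0.0, 0.0)
        assert max(abs(total[0]), abs(total[1])) > 1e-6


class TestCv:
    def _sinusoid_setup(self, n_points):
        species = [
            SpeciesSpec("R", "producer", 1.0, 0.1),
            SpeciesSpec("C", "consumer", 0.1, 0.0),
            SpeciesSpec("M", "producer", 1.0, 0.1),
        ]
        model = CommunityModel(
            species,
            [TrophicLink("R", "C", 0.5, 0.5)],
            [TIMSpec("T1", modifier_id="M", target=("R", "C"), strength=1.0,
                     form="linear_clipped")],
        )
        t = np.linspace(0.0, 4 * np.pi, n_points)
        states = np.column_stack([np.ones_like(t), np.ones_like(t), 1.0 + np.sin(t)])
        return model, Trajectory(t, states, ["R", "C", "M"])

    def test_constant_series_gives_zero(self):
        model = build_demo("chain_linear")
        res = find_equilibrium(model, np.ones(3))
        traj = simulate(model, res.state, (0.0, 50.0), t_eval=np.linspace(0, 50, 200))
        assert metric_cv(model, "T1", traj) == pytest.approx(0.0, abs=1e-6)

    def test_sinusoidal_modifier_closed_form(self):
        """Term 2 + sin t over whole periods: CV = (1/sqrt 2)/2 = 0.353553."""
        model, traj = self._sinusoid_setup(2001)
        assert metric_cv(model, "T1", traj, window=(0.0, 4 * np.pi)) == pytest.approx(
            0.3535534, abs=1e-4
        )

    def test_quadrature_convergence_under_halved_step(self):
        model, coarse = self._sinusoid_setup(1001)
        _, fine = self._sinusoid_setup(2001)
        cv_coarse = metric_cv(model, "T1", coarse, window=(0.0, 4 * np.pi))
        cv_fine = metric_cv(model, "T1", fine, window=(0.0, 4 * np.pi))
        assert abs(cv_coarse - cv_fine) < 1e-3

    def test_zero_mean_series_rejected(self):
        model, traj = self._sinusoid_setup(501)
        zero_tim_model = model.with_tim_strength("T1", -1.0)
        # term max(0, 1 - (1 + sin t)) is zero on half the window: mean near 0
        # over a window centred on sin t > 0
        with pytest.raises(DomainError):
            metric_cv(zero_tim_model, "T1", traj, window=(0.1, 2.0))


class TestComputeAllMetrics:
    def test_equilibrium_context_fills_applicable_fields(self):
        model = build_demo("chain_nonlinear")
        report = compute_all_metrics(model, "T1", at="equilibrium")
        assert report.cv_modification is None  # needs a trajectory
        assert report.modification_term is not None
        assert report.flux_ratio is not None
        assert report.bcr_change is not None
        assert report.tmii_pair is not None
        assert report.net_sensitivity_pair is not None
        assert report.errors == {}

    def test_null_tim_invariant_row(self):
        model = build_demo(
            "chain_nonlinear",
            {"tims.T1.strength": 0.0, "species.C.self_limitation": 0.05},
        )
        report = compute_all_metrics(model, "T1", at="equilibrium")
        assert report.modification_term == 1.0
        assert report.flux_ratio == 1.0
        assert report.flux_difference == 0.0
        assert report.bcr_change == pytest.approx(1.0, abs=1e-8)
        assert report.jacobian_sensitivity_pair == (0.0, 0.0)
        # density-mediated route stays visible in the net sensitivity
        assert max(abs(v) for v in report.net_sensitivity_pair) > 1e-6

    def test_matches_individually_computed_metrics(self):
        model = build_demo("chain_nonlinear")
        res = find_equilibrium(model, np.ones(3))
        report = compute_all_metrics(model, "T1", at="state", state=res.state)
        assert (report.flux_ratio, report.flux_difference) == metric_flux_change(
            model, "T1", res.state
        )
        assert report.tmii_pair == metric_tmii(model, "T1", res.state)
        assert report.jacobian_sensitivity_pair == metric_jacobian_sensitivity(
            model, "T1", res.state
        )
        assert report.net_sensitivity_pair == metric_net_sensitivity(model, "T1", res.state)

    def test_forced_tim_records_tmii_error_without_aborting(self):
        model = make_lv_cue(0.5, 1.0)
        report = compute_all_metrics(model, "T1", at="equilibrium")
        assert report.tmii_pair is None
        assert "tmii_pair" in report.errors
        assert report.modification_term is not None

    def test_flat_row_serialisation(self):
        model = build_demo("chain_linear")
        report = compute_all_metrics(model, "T1", at="equilibrium")
        row = report.to_row()
        assert row["modification_parameter"] == model.tims[0].strength
        assert {"tmii_i", "tmii_j", "net_sensitivity_i", "net_sensitivity_j"} <= set(row)
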