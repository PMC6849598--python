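import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timweb import (
    CommunityModel,
    SpeciesSpec,
    State,
    TIMSpec,
    TrophicLink,
    combined_modification,
    link_flux,
    modification_term,
    rhs,
)
from timweb.exceptions import DomainError, ModelValidationError, UsageError
from timweb.model_core import tim_modifier_density

from conftest import make_lv_cue


def tim(form="exponential", strength=0.5, **kw):
    params = {"midpoint": 1.0, "steepness": 2.0} if form == "sigmoid" else {}
    params.update(kw.pop("form_params", {}))
    return TIMSpec("T", modifier_id="K", target=("R", "C"), strength=strength,
                   form=form, form_params=params, **kw)


class TestModificationTerm:
    @pytest.mark.parametrize(
        "form,strength,k,expected",
        [
            ("exponential", 0.0, 5.0, 1.0),
            ("exponential", 0.5, 2.0, math.e),
            ("linear_clipped", -0.4, 5.0, 0.0),  # clipping floor max(0, 1 - 2)
            ("linear_clipped", 0.25, 2.0, 1.5),
            ("hyperbolic", 0.5, 2.0, 2.0),  # amplification branch 1 + c k
            ("hyperbolic", -0.5, 2.0, 0.5),  # decay branch 1 / (1 + |c| k)
            ("sigmoid", 0.8, 1.0, 1.4),  # midpoint: half the asymptotic change
            ("sigmoid", 0.8, 0.0, 1.0),
        ],
    )
    def test_closed_form_values(self, form, strength, k, expected):
        assert modification_term(tim(form, strength), k) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("form", ["exponential", "linear_clipped", "hyperbolic", "sigmoid"])
    @pytest.mark.parametrize("k", [0.0, 0.3, 1.0, 7.5])
    def test_zero_strength_is_exact_identity(self, form, k):
        assert modification_term(tim(form, 0.0), k) == 1.0

    @given(c=st.floats(-3, 3), k=st.floats(0, 50))
    @settings(deadline=None, max_examples=60)
    def test_positive_forms_stay_positive(self, c, k):
        for form in ("exponential", "hyperbolic"):
            assert modification_term(tim(form, c), k) > 0.0
        assert modification_term(tim("linear_clipped", c), k) >= 0.0
        if c > -1:
            assert modification_term(tim("sigmoid", c), k) > 0.0

    def test_negative_modifier_density_rejected(self):
        with pytest.raises(DomainError):
            modification_term(tim(), -0.1)

    def test_forced_matches_dynamic_at_same_density(self):
        """A forced cue at density x modifies exactly like a dynamic modifier at x."""
        model = make_lv_cue(0.7, 1.3)
        forced = model.tims[0]
        dynamic = TIMSpec("T2", modifier_id="J", target=("I", "J"), strength=0.7)
        st_ = State(np.array([0.5, 1.3]))
        k_forced = tim_modifier_density(model, forced, st_)
        k_dyn = tim_modifier_density(model, dynamic, st_)
        assert modification_term(forced, k_forced) == modification_term(dynamic, k_dyn)


class TestCombinedModification:
    def _two_tim_model(self, c1, c2):
        species = [
            SpeciesSpec("R", "producer", 1.0, 0.1),
            SpeciesSpec("C", "consumer", 0.1, 0.0),
            SpeciesSpec("K1", "producer", 1.0, 0.1),
            SpeciesSpec("K2", "producer", 1.0, 0.1),
        ]
        links = [TrophicLink("R", "C", 0.5, 0.5)]
        tims = [
            TIMSpec("A", modifier_id="K1", target=("R", "C"), strength=c1),
            TIMSpec("B", modifier_id="K2", target=("R", "C"), strength=c2),
        ]
        return CommunityModel(species, links, tims)

    def test_empty_product_is_one(self):
        model = self._two_tim_model(0.3, 0.3)
        assert combined_modification(model, [], State(np.ones(4))) == 1.0

    def test_opposing_exponentials_cancel(self):
        model = self._two_tim_model(0.3, -0.3)
        st_ = State(np.array([1.0, 1.0, 1.0, 1.0]))
        assert combined_modification(model, model.tims, st_) == pytest.approx(1.0, abs=1e-14)

    def test_equal_exponentials_compound(self):
        model = self._two_tim_model(0.5, 0.5)
        st_ = State(np.array([1.0, 1.0, 1.0, 1.0]))
        assert combined_modification(model, model.tims, st_) == pytest.approx(math.e, rel=1e-12)

    @given(st.permutations([0, 1]))
    @settings(deadline=None)
    def test_order_invariance(self, order):
        model = self._two_tim_model(0.4, -0.7)
        st_ = State(np.array([1.0, 2.0, 0.5, 1.5]))
        tims = [model.tims[i] for i in order]
        assert combined_modification(model, tims, st_) == combined_modification(
            model, model.tims, st_
        )

    def test_mixed_affected_parameters_rejected(self):
        model = self._two_tim_model(0.3, 0.3)
        from dataclasses import replace

        mixed = [model.tims[0], replace(model.tims[1], affected_parameter="handling_time")]
        with pytest.raises(UsageError):
            combined_modification(model, mixed, State(np.ones(4)))


class TestLinkFlux:
    def _model(self, fr_form="linear", h=0.0, strength=0.0, affected="attack_rate"):
        species = [
            SpeciesSpec("R", "producer", 1.0, 0.1),
            SpeciesSpec("C", "consumer", 0.1, 0.0),
            SpeciesSpec("K", "producer", 1.0, 0.1),
        ]
        links = [TrophicLink("R", "C", 0.5 if fr_form == "linear" else 1.0, 0.5,
                             fr_form=fr_form, handling_time=h)]
        tims = [TIMSpec("T", modifier_id="K", target=("R", "C"), strength=strength,
                        affected_parameter=affected)]
        return CommunityModel(species, links, tims)

    def test_linear_flux_hand_value(self):
        model = self._model()
        assert link_flux(model, model.links[0], np.array([2.0, 3.0, 0.0])) == pytest.approx(3.0)

    def test_no_resource_no_flux(self):
        for form, h in [("linear", 0.0), ("holling2", 1.0)]:
            model = self._model(form, h)
            assert link_flux(model, model.links[0], np.array([0.0, 3.0, 1.0])) == 0.0

    def test_holling2_hand_value(self):
        model = self._model("holling2", 1.0)
        assert link_flux(model, model.links[0], np.array([1.0, 1.0, 0.0])) == pytest.approx(0.5)

    def test_attack_modification_enters_denominator(self):
        # a m R C / (1 + a m h R) with m = 2: 2 / (1 + 2) = 2/3
        model = self._model("holling2", 1.0, strength=math.log(2.0))
        flux = link_flux(model, model.links[0], np.array([1.0, 1.0, 1.0]))
        assert flux == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_handling_modification_placement(self):
        # handling h m with m = 2: a R C / (1 + a h m R) = 1/3
        model = self._model("holling2", 1.0, strength=math.log(2.0), affected="handling_time")
        flux = link_flux(model, model.links[0], np.array([1.0, 1.0, 1.0]))
        assert flux == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_foreign_link_rejected(self):
        model = self._model()
        other = TrophicLink("K", "C", 0.5, 0.5)
        with pytest.raises(UsageError):
            link_flux(model, other, np.zeros(3))


class TestRhs:
    def test_lv_cue_hand_arithmetic(self):
        model = make_lv_cue(0.7, 0.0)  # forced K = 0: any c is inert
        rates = rhs(model, np.array([1.0, 1.0]))
        assert rates == pytest.approx([0.5, 0.05], abs=1e-14)

    def test_all_absent_is_absorbing(self):
        model = make_lv_cue(0.3, 1.0)
        assert np.all(rhs(model, np.zeros(2)) == 0.0)

    def test_vanishes_at_solved_equilibrium(self):
        from timweb import find_equilibrium
        from timweb.experiments import build_demo

        model = build_demo("chain_nonlinear")
        res = find_equilibrium(model, np.ones(3))
        assert res.converged
        assert np.max(np.abs(rhs(model, res.state))) < 1e-8

    def test_absent_species_cannot_be_consumed(self):
        """No flux from a zero-density resource; producers still grow."""
        from timweb.experiments import build_demo

        model = build_demo("chain_linear")
        rates = rhs(model, np.array([1.0, 0.0, 5.0]))
        assert rates[model.index("P")] > 0  # plant grows, nothing eats it via H = 0
        assert rates[model.index("H")] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_null_tim_equals_stripped_model_exactly(self, seed):
        """Zero-strength TIMs leave the vector field bit-for-bit unchanged."""
        from timweb.experiments import generate_random_chain

        model = generate_random_chain(seed).model
        zeroed = model.with_tim_strength("T1", 0.0)
        stripped = model.without_tims()
        rng = np.random.default_rng(seed)
        for _ in range(5):
            x = rng.uniform(0, 10, size=3)
            assert np.array_equal(rhs(zeroed, x), rhs(stripped, x))


class TestValidation:
    def test_all_violations_reported_together(self):
        species = [
            SpeciesSpec("A", "producer", 1.0, 0.0),
            SpeciesSpec("A", "wizard", 1.0, -0.5),
        ]
        links = [TrophicLink("A", "B", -1.0, 0.5)]
        tims = [TIMSpec("T", modifier_id="Z", target=("X", "Y"), strength=0.1)]
        with pytest.raises(ModelValidationError) as exc:
            CommunityModel(species, links, tims)
        messages = "\n".join(exc.value.errors)
        assert "duplicated species ids" in messages
        assert "wizard" in messages
        assert "attack_rate" in messages
        assert "missing link" in messages
        assert len(exc.value.errors) >= 4

    def test_linear_link_with_handling_time_rejected(self):
        species = [SpeciesSpec("A", "producer", 1.0, 0.0), SpeciesSpec("B", "consumer", 0.1, 0.0)]
        with pytest.raises(ModelValidationError, match="handling_time"):
            CommunityModel(species, [TrophicLink("A", "B", 0.5, 0.5, handling_time=0.3)], [])

    def test_state_rejects_negative_and_nonfinite(self):
        with pytest.raises(DomainError):
            State(np.array([1.0, -0.1]))
        with pytest.raises(DomainError):
            State(np.array([np.nan, 1.0]))
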