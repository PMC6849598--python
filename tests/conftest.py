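import numpy as np
import pytest

from timweb import CommunityModel, SpeciesSpec, TIMSpec, TrophicLink


def make_lv_cue(strength: float, cue_density: float) -> CommunityModel:
    """Lotka-Volterra prey-predator pair with a forced (cue) TIM.

    Prey I grows at r = 1, predator J dies at d = 0.2, attack 0.5 with
    conversion 0.5; the cue multiplies the attack rate by exp(c * K).
    Closed forms: interior equilibrium I* = d / (eps * a * exp(c*K)),
    J* = r / (a * exp(c*K)).
    """
    species = [
        SpeciesSpec("I", "producer", 1.0, 0.0),
        SpeciesSpec("J", "consumer", 0.2, 0.0),
    ]
    links = [TrophicLink("I", "J", 0.5, 0.5)]
    tims = [
        TIMSpec(
            "T1", modifier_id="", target=("I", "J"), strength=strength,
            mode="forced", forced_density=cue_density,
        )
    ]
    return CommunityModel(species, links, tims)


@pytest.fixture
def lv_cue():
    return make_lv_cue


@pytest.fixture
def neutral_lv():
    """Classic neutrally stable Lotka-Volterra pair (no TIM, no self-limitation)."""
    species = [
        SpeciesSpec("I", "producer", 1.0, 0.0),
        SpeciesSpec("J", "consumer", 0.2, 0.0),
    ]
    return CommunityModel(species, [TrophicLink("I", "J", 0.5, 0.5)], [])


def monotone(values) -> bool:
    """True when the finite entries of a series never change direction."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        return True
    d = np.diff(x)
    return bool(np.all(d >= -1e-10) or np.all(d <= 1e-10))
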