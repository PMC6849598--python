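"""Community dynamics models with trophic interaction modifications (TIMs).

A :class:`CommunityModel` is a set of coupled ODEs for species biomass
densities.  Producers grow logistically; consumers gain biomass through
trophic links (linear or Holling type II functional responses) and lose it
to density-independent mortality.  A TIM is a third species ("modifier",
index k) whose density multiplicatively rescales one parameter of one
consumer-resource functional response, via a modification term
``f(c_ijk, k)`` where ``c_ijk`` is the signed TIM strength.

Modification term forms
-----------------------
exponential
    ``f = exp(c * k)`` — sign-symmetric, strictly positive, unbounded.
linear_clipped
    ``f = max(0, 1 + c * k)`` — linear with a floor at zero.
hyperbolic
    piecewise one-parameter saturating family::

        f = 1 + c * k          (c >= 0, linear amplification)
        f = 1 / (1 + |c| * k)  (c < 0, hyperbolic decay)

    chosen so that a single signed parameter covers amplification and
    attenuation while staying strictly positive for every ``k >= 0``.
sigmoid
    ``f = 1 + c * k**s / (k**s + m**s)`` with midpoint ``m > 0`` and
    steepness ``s > 0`` taken from ``form_params``; requires ``c > -1``
    so the term stays strictly positive.

Every form satisfies ``f(0, k) == 1`` exactly: a zero-strength TIM is the
identity and the model collapses to its TIM-free counterpart bit for bit.

A TIM is either *dynamic* (the modifier is a state variable, with full
dynamical feedback) or *forced* (a cue held at a fixed density, mimicking
experiments that impose a modification without the modifier being part of
the food web).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .exceptions import DomainError, ModelValidationError, NumericError, UsageError

__all__ = [
    "SpeciesSpec",
    "TrophicLink",
    "TIMSpec",
    "CommunityModel",
    "State",
    "modification_term",
    "combined_modification",
    "link_flux",
    "rhs",
    "symbolic_system",
    "FR_FORMS",
    "TIM_FORMS",
    "AFFECTED_PARAMETERS",
]

FR_FORMS = ("linear", "holling2", "holling2_interference")
TIM_FORMS = ("exponential", "linear_clipped", "hyperbolic", "sigmoid")
AFFECTED_PARAMETERS = ("attack_rate", "handling_time", "interference")
ROLES = ("producer", "consumer")


@dataclass(frozen=True)
class SpeciesSpec:
    """One species.

    ``intrinsic_rate`` is the per-capita growth rate for producers and the
    per-capita death rate (entered as a positive number) for consumers.
    ``self_limitation`` is the intraspecific density-dependence coefficient
    (per density per time, >= 0); producers use it as logistic
    self-limitation, consumers may carry it as extra quadratic mortality.
    """

    id: str
    role: str
    intrinsic_rate: float
    self_limitation: float = 0.0
    name: str = ""

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "role": self.role,
            "intrinsic_rate": float(self.intrinsic_rate),
            "self_limitation": float(self.self_limitation),
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesSpec":
        return cls(
            id=str(d["id"]),
            role=str(d["role"]),
            intrinsic_rate=float(d["intrinsic_rate"]),
            self_limitation=float(d.get("self_limitation", 0.0)),
            name=str(d.get("name", "")),
        )


@dataclass(frozen=True)
class TrophicLink:
    """A consumer-resource link with its functional response parameters.

    Per-consumer consumption rate of resource R by consumer C:

    * ``linear``: ``a * R``
    * ``holling2``: ``a * R / (1 + a * h * R)``
    * ``holling2_interference``: ``a * R / (1 + a * h * R + w * C)``
      (Beddington-DeAngelis interference coefficient ``w``)

    Total biomass flux is the per-consumer rate times consumer density; the
    consumer converts a fraction ``conversion_efficiency`` of it to growth.
    """

    resource_id: str
    consumer_id: str
    attack_rate: float
    conversion_efficiency: float
    fr_form: str = "linear"
    handling_time: float = 0.0
    interference: float = 0.0

    def to_dict(self) -> dict:
        return {
            "resource_id": self.resource_id,
            "consumer_id": self.consumer_id,
            "fr_form": self.fr_form,
            "attack_rate": float(self.attack_rate),
            "handling_time": float(self.handling_time),
            "interference": float(self.interference),
            "conversion_efficiency": float(self.conversion_efficiency),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrophicLink":
        return cls(
            resource_id=str(d["resource_id"]),
            consumer_id=str(d["consumer_id"]),
            fr_form=str(d.get("fr_form", "linear")),
            attack_rate=float(d["attack_rate"]),
            handling_time=float(d.get("handling_time", 0.0)),
            interference=float(d.get("interference", 0.0)),
            conversion_efficiency=float(d["conversion_efficiency"]),
        )

    @property
    def key(self) -> tuple[str, str]:
        return (self.resource_id, self.consumer_id)


@dataclass(frozen=True)
class TIMSpec:
    """A trophic interaction modification.

    Species ``modifier_id`` (index k) rescales ``affected_parameter`` of the
    link ``target = (resource i, consumer j)`` by the modification term
    ``f(strength, k)``.  ``strength`` is the signed TIM parameter c_ijk (per
    modifier-density).  In ``forced`` mode the modifier density is held at
    ``forced_density`` regardless of the system state (a cue).
    """

    tim_id: str
    modifier_id: str
    target: tuple[str, str]
    strength: float
    affected_parameter: str = "attack_rate"
    form: str = "exponential"
    form_params: dict = field(default_factory=dict)
    mode: str = "dynamic"
    forced_density: float = 0.0

    def to_dict(self) -> dict:
        return {
            "tim_id": self.tim_id,
            "modifier_id": self.modifier_id,
            "target": [self.target[0], self.target[1]],
            "affected_parameter": self.affected_parameter,
            "form": self.form,
            "strength": float(self.strength),
            "form_params": {k: float(v) for k, v in self.form_params.items()},
            "mode": self.mode,
            "forced_density": float(self.forced_density),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TIMSpec":
        return cls(
            tim_id=str(d["tim_id"]),
            modifier_id=str(d.get("modifier_id", "")),
            target=(str(d["target"][0]), str(d["target"][1])),
            affected_parameter=str(d.get("affected_parameter", "attack_rate")),
            form=str(d.get("form", "exponential")),
            strength=float(d["strength"]),
            form_params={k: float(v) for k, v in dict(d.get("form_params", {})).items()},
            mode=str(d.get("mode", "dynamic")),
            forced_density=float(d.get("forced_density", 0.0)),
        )


@dataclass
class State:
    """Densities aligned with a model's ``species_order`` plus optional time."""

    densities: np.ndarray
    time: float | None = None

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.ndim != 1:
            raise UsageError("State densities must be a 1-D vector")
        if not np.all(np.isfinite(self.densities)):
            raise DomainError("State densities must be finite")
        if np.any(self.densities < 0):
            raise DomainError("State densities must be non-negative")

    def copy(self) -> "State":
        return State(self.densities.copy(), self.time)


def _as_densities(model: "CommunityModel", state) -> np.ndarray:
    x = state.densities if isinstance(state, State) else np.asarray(state, dtype=float)
    if x.shape != (model.n_species,):
        raise UsageError(
            f"state has {x.shape} densities but the model orders {model.n_species} species"
        )
    return x


@dataclass
class CommunityModel:
    """Species + trophic links + TIMs; evaluable as an ODE right-hand side."""

    species: list[SpeciesSpec]
    links: list[TrophicLink]
    tims: list[TIMSpec] = field(default_factory=list)
    species_order: list[str] | None = None

    def __post_init__(self):
        if self.species_order is None:
            self.species_order = [s.id for s in self.species]
        self.check()

    # -- lookups ---------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_order)

    def index(self, species_id: str) -> int:
        try:
            return self.species_order.index(species_id)
        except ValueError:
            raise UsageError(f"unknown species id {species_id!r}") from None

    def species_by_id(self, species_id: str) -> SpeciesSpec:
        for s in self.species:
            if s.id == species_id:
                return s
        raise UsageError(f"unknown species id {species_id!r}")

    def link_by_key(self, resource_id: str, consumer_id: str) -> TrophicLink:
        for l in self.links:
            if l.key == (resource_id, consumer_id):
                return l
        raise UsageError(f"no trophic link {resource_id!r} -> {consumer_id!r} in model")

    def tim_by_id(self, tim_id: str) -> TIMSpec:
        for t in self.tims:
            if t.tim_id == tim_id:
                return t
        raise UsageError(f"no TIM with id {tim_id!r} in model")

    def tims_on_link(self, link: TrophicLink) -> list[TIMSpec]:
        return [t for t in self.tims if t.target == link.key]

    # -- structural edits (return new models; specs are frozen) ----------
    def with_tim_strength(self, tim_id: str, strength: float) -> "CommunityModel":
        """A copy of the model with one TIM's strength replaced."""
        self.tim_by_id(tim_id)
        tims = [replace(t, strength=float(strength)) if t.tim_id == tim_id else t for t in self.tims]
        return CommunityModel(list(self.species), list(self.links), tims, list(self.species_order))

    def without_tim(self, tim_id: str) -> "CommunityModel":
        self.tim_by_id(tim_id)
        tims = [t for t in self.tims if t.tim_id != tim_id]
        return CommunityModel(list(self.species), list(self.links), tims, list(self.species_order))

    def without_tims(self) -> "CommunityModel":
        return CommunityModel(list(self.species), list(self.links), [], list(self.species_order))

    # -- validation ------------------------------------------------------
    def validate(self) -> list[str]:
        """Collect every structural violation (empty list = valid)."""
        errors: list[str] = []
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            errors.append(f"duplicated species ids: {dupes}")
        if sorted(self.species_order) != sorted(ids):
            errors.append("species_order is not a permutation of the species ids")
        for s in self.species:
            if s.role not in ROLES:
                errors.append(f"species {s.id!r}: unknown role {s.role!r} (expected one of {ROLES})")
            if not math.isfinite(s.intrinsic_rate):
                errors.append(f"species {s.id!r}: intrinsic_rate must be finite")
            if not (s.self_limitation >= 0):
                errors.append(f"species {s.id!r}: self_limitation must be >= 0")
        keys = [l.key for l in self.links]
        if len(set(keys)) != len(keys):
            errors.append("duplicated (resource, consumer) trophic link")
        for l in self.links:
            tag = f"link {l.resource_id!r}->{l.consumer_id!r}"
            if l.resource_id == l.consumer_id:
                errors.append(f"{tag}: resource and consumer must differ")
            for sid in l.key:
                if sid not in ids:
                    errors.append(f"{tag}: references unknown species {sid!r}")
            if l.fr_form not in FR_FORMS:
                errors.append(f"{tag}: unknown fr_form {l.fr_form!r} (implemented: {FR_FORMS})")
            if not (l.attack_rate > 0):
                errors.append(f"{tag}: attack_rate must be > 0")
            if not (l.handling_time >= 0):
                errors.append(f"{tag}: handling_time must be >= 0")
            if l.fr_form == "linear" and l.handling_time != 0:
                errors.append(f"{tag}: linear functional response requires handling_time = 0")
            if not (l.interference >= 0):
                errors.append(f"{tag}: interference must be >= 0")
            if not (0 < l.conversion_efficiency <= 1):
                errors.append(f"{tag}: conversion_efficiency must lie in (0, 1]")
        tim_ids = [t.tim_id for t in self.tims]
        if len(set(tim_ids)) != len(tim_ids):
            errors.append("duplicated TIM ids")
        for t in self.tims:
            tag = f"TIM {t.tim_id!r}"
            if t.target not in keys:
                errors.append(f"{tag}: targets missing link {t.target[0]!r}->{t.target[1]!r}")
            if t.mode not in ("dynamic", "forced"):
                errors.append(f"{tag}: unknown mode {t.mode!r}")
            if t.mode == "dynamic" and t.modifier_id not in ids:
                errors.append(f"{tag}: dynamic modifier {t.modifier_id!r} is not a model species")
            if t.mode == "forced" and not (t.forced_density >= 0):
                errors.append(f"{tag}: forced_density must be >= 0")
            if t.affected_parameter not in AFFECTED_PARAMETERS:
                errors.append(
                    f"{tag}: unknown affected_parameter {t.affected_parameter!r} "
                    f"(implemented: {AFFECTED_PARAMETERS})"
                )
            if t.form not in TIM_FORMS:
                errors.append(f"{tag}: unknown form {t.form!r} (implemented: {TIM_FORMS})")
            if t.form == "sigmoid":
                m = t.form_params.get("midpoint")
                s = t.form_params.get("steepness")
                if m is None or s is None:
                    errors.append(f"{tag}: sigmoid form needs form_params midpoint and steepness")
                elif not (m > 0 and s > 0):
                    errors.append(f"{tag}: sigmoid midpoint and steepness must be > 0")
                if t.strength <= -1:
                    errors.append(f"{tag}: sigmoid strength must be > -1 for positivity")
            if not math.isfinite(t.strength):
                errors.append(f"{tag}: strength must be finite")
        return errors

    def check(self) -> None:
        errors = self.validate()
        if errors:
            raise ModelValidationError(errors)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": [s.to_dict() for s in self.species],
            "links": [l.to_dict() for l in self.links],
            "tims": [t.to_dict() for t in self.tims],
            "species_order": list(self.species_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityModel":
        return cls(
            species=[SpeciesSpec.from_dict(s) for s in d["species"]],
            links=[TrophicLink.from_dict(l) for l in d["links"]],
            tims=[TIMSpec.from_dict(t) for t in d.get("tims", [])],
            species_order=[str(s) for s in d["species_order"]] if "species_order" in d else None,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunityModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# Modification terms
# ---------------------------------------------------------------------------

def modification_term(tim: TIMSpec, modifier_density: float) -> float:
    """Evaluate the modification term f(c_ijk, k) at modifier density k.

    Returns the positive multiplier applied to the TIM's affected
    functional-response parameter.  Exactly 1 when ``tim.strength == 0``.
    """
    k = float(modifier_density)
    if k < 0:
        raise DomainError(f"modifier density must be >= 0, got {k}")
    c = tim.strength
    if tim.form == "exponential":
        try:
            value = math.exp(c * k)
        except OverflowError:
            raise NumericError(f"exponential modification term overflowed at c={c}, k={k}") from None
    elif tim.form == "linear_clipped":
        value = max(0.0, 1.0 + c * k)
    elif tim.form == "hyperbolic":
        value = 1.0 + c * k if c >= 0 else 1.0 / (1.0 + abs(c) * k)
    elif tim.form == "sigmoid":
        m = tim.form_params["midpoint"]
        s = tim.form_params["steepness"]
        value = 1.0 + c * (k ** s / (k ** s + m ** s)) if k > 0 else 1.0
    else:  # pragma: no cover - caught at validation
        raise UsageError(f"unknown TIM form {tim.form!r}")
    if not math.isfinite(value):
        raise NumericError(f"modification term is non-finite for TIM {tim.tim_id!r} at k={k}")
    return value


def tim_modifier_density(model: CommunityModel, tim: TIMSpec, state) -> float:
    """The modifier density a TIM sees: the state coordinate (dynamic) or the forced cue."""
    if tim.mode == "forced":
        return float(tim.forced_density)
    x = _as_densities(model, state)
    return float(x[model.index(tim.modifier_id)])


def multiplicative_combiner(terms: Iterable[float]) -> float:
    """Default combination rule for simultaneous TIMs: the product of terms."""
    return float(math.prod(terms))


def combined_modification(
    model: CommunityModel,
    tims_on_link: Sequence[TIMSpec],
    state,
    combiner: Callable[[Iterable[float]], float] = multiplicative_combiner,
) -> float:
    """Combined multiplier of several TIMs acting on one link and parameter.

    All TIMs must target the same link and the same affected parameter;
    an empty list yields 1.  The combination rule is replaceable: pass any
    reduction over the individual terms (multiplicative by default).
    """
    tims = list(tims_on_link)
    if not tims:
        return 1.0
    targets = {t.target for t in tims}
    params = {t.affected_parameter for t in tims}
    if len(targets) > 1:
        raise UsageError(f"TIMs target different links: {sorted(targets)}")
    if len(params) > 1:
        raise UsageError(f"TIMs affect different parameters: {sorted(params)}")
    return combiner(modification_term(t, tim_modifier_density(model, t, state)) for t in tims)


# ---------------------------------------------------------------------------
# Fluxes and the right-hand side
# ---------------------------------------------------------------------------

def _effective_parameters(
    model: CommunityModel, link: TrophicLink, state, neutralize: frozenset[str]
) -> tuple[float, float, float]:
    """Link parameters after applying all TIM multipliers.

    TIMs whose id is in ``neutralize`` contribute a factor of exactly 1
    (their modifier is treated as absent from the term only).
    """
    a, h, w = link.attack_rate, link.handling_time, link.interference
    mult = {"attack_rate": 1.0, "handling_time": 1.0, "interference": 1.0}
    for tim in model.tims_on_link(link):
        if tim.tim_id in neutralize:
            continue
        term = modification_term(tim, tim_modifier_density(model, tim, state))
        mult[tim.affected_parameter] *= term
    return a * mult["attack_rate"], h * mult["handling_time"], w * mult["interference"]


def link_flux(model: CommunityModel, link: TrophicLink, state, neutralize: Iterable[str] = ()) -> float:
    """Total biomass flux through one trophic link at a state.

    ``neutralize`` names TIMs whose modification term is forced to 1 for
    this evaluation (used by the flux-change metric to switch one
    modification off while leaving every other TIM active).
    """
    if link not in model.links:
        raise UsageError("link is not part of the model")
    x = _as_densities(model, state)
    R = x[model.index(link.resource_id)]
    C = x[model.index(link.consumer_id)]
    a, h, w = _effective_parameters(model, link, state, frozenset(neutralize))
    if link.fr_form == "linear":
        return a * R * C
    if link.fr_form == "holling2":
        return a * R * C / (1.0 + a * h * R)
    if link.fr_form == "holling2_interference":
        return a * R * C / (1.0 + a * h * R + w * C)
    raise UsageError(f"unknown fr_form {link.fr_form!r}")  # pragma: no cover


def rhs(model: CommunityModel, state) -> np.ndarray:
    """Per-species rate of density change dN/dt at a state.

    Producers: ``N_i * (r_i - s_i * N_i) - sum(outgoing fluxes)``.
    Consumers: ``sum(eps * incoming fluxes) - sum(outgoing fluxes)
    - d_j * N_j - s_j * N_j**2``.
    """
    x = _as_densities(model, state)
    rates = np.zeros(model.n_species)
    for s in model.species:
        i = model.index(s.id)
        if s.role == "producer":
            rates[i] = x[i] * (s.intrinsic_rate - s.self_limitation * x[i])
        else:
            rates[i] = -s.intrinsic_rate * x[i] - s.self_limitation * x[i] ** 2
    for link in model.links:
        flux = link_flux(model, link, state)
        rates[model.index(link.resource_id)] -= flux
        rates[model.index(link.consumer_id)] += link.conversion_efficiency * flux
    return rates


# ---------------------------------------------------------------------------
# Symbolic mirror (used for exact Jacobians and TIM-sensitivity metrics)
# ---------------------------------------------------------------------------

def symbolic_system(model: CommunityModel, forced_tim_ids: Iterable[str] = ()):
    """Build a sympy mirror of the model's right-hand side.

    Returns ``(density_syms, rate_exprs, forced_syms)`` where
    ``density_syms`` align with ``species_order`` and ``forced_syms`` maps
    each id in ``forced_tim_ids`` to the symbol standing in for that
    forced TIM's cue density (so metrics can differentiate with respect to
    a forced modifier).  TIM strengths are baked in as numeric constants.
    """
    import sympy as sp

    syms = [sp.Symbol(f"N_{sid}", nonnegative=True) for sid in model.species_order]
    forced_syms = {tid: sp.Symbol(f"K_{tid}", nonnegative=True) for tid in forced_tim_ids}

    def term_expr(tim: TIMSpec):
        if tim.mode == "forced":
            if tim.tim_id in forced_syms:
                k = forced_syms[tim.tim_id]
            else:
                k = sp.Float(tim.forced_density)
        else:
            k = syms[model.index(tim.modifier_id)]
        c = tim.strength
        if tim.form == "exponential":
            return sp.exp(c * k)
        if tim.form == "linear_clipped":
            return sp.Max(0, 1 + c * k)
        if tim.form == "hyperbolic":
            return 1 + c * k if c >= 0 else 1 / (1 + abs(c) * k)
        if tim.form == "sigmoid":
            m = tim.form_params["midpoint"]
            s = tim.form_params["steepness"]
            return 1 + c * k ** s / (k ** s + sp.Float(m) ** s)
        raise UsageError(f"unknown TIM form {tim.form!r}")  # pragma: no cover

    rates = [sp.Integer(0) for _ in syms]
    for s in model.species:
        i = model.index(s.id)
        N = syms[i]
        if s.role == "producer":
            rates[i] += N * (s.intrinsic_rate - s.self_limitation * N)
        else:
            rates[i] += -s.intrinsic_rate * N - s.self_limitation * N ** 2
    for link in model.links:
        R = syms[model.index(link.resource_id)]
        C = syms[model.index(link.consumer_id)]
        a, h, w = sp.Float(link.attack_rate), sp.Float(link.handling_time), sp.Float(link.interference)
        for tim in model.tims_on_link(link):
            t = term_expr(tim)
            if tim.affected_parameter == "attack_rate":
                a = a * t
            elif tim.affected_parameter == "handling_time":
                h = h * t
            else:
                w = w * t
        if link.fr_form == "linear":
            flux = a * R * C
        elif link.fr_form == "holling2":
            flux = a * R * C / (1 + a * h * R)
        else:
            flux = a * R * C / (1 + a * h * R + w * C)
        rates[model.index(link.resource_id)] -= flux
        rates[model.index(link.consumer_id)] += link.conversion_efficiency * flux
    return syms, rates, forced_syms
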