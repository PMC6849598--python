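"""Metrics of trophic interaction modification strength.

One TIM can be scored at several levels of contextual information, from
the bare modification parameter up to press-perturbation sensitivities:

* ``modification parameter`` — the signed strength c_ijk itself.
* ``modification term`` — f(c_ijk, k) at the evaluation state.
* ``flux change`` — the target link's biomass flux with the focal TIM
  switched off over (ratio) or minus (difference) the flux with it on,
  both at the same state.
* ``change in B_CR`` — ratio of the resource's equilibrium density with
  the TIM to its equilibrium density with c_ijk = 0 (the biomass
  conversion ratio change reduces to this density ratio).
* ``coefficient of variation`` — sd/mean of the modification term along a
  trajectory window (for non-stationary systems).
* ``TMII pair`` — Jacobian entries (dI'/dK, dJ'/dK): the modifier's direct
  effect on each interactor's growth rate (the pairwise framing).
* ``Jacobian sensitivity`` — d(A_ij)/dK, d(A_ji)/dK: how the modifier
  density changes the *direct* interaction strengths.
* ``net-effects sensitivity`` — the same derivatives of the net-effects
  matrix -A^-1, capturing direct plus indirect (density-mediated) routes.

All derivative metrics are *direct* partials: the modifier density K is
perturbed with every other coordinate held fixed, with no re-equilibration
(equilibrium-shift responses are captured by sweeping the TIM parameter in
:mod:`timweb.experiments`).  This cleanly separates the direct TIM effect
from density-mediated pathways: with c_ijk = 0 the Jacobian sensitivity is
identically zero, while the net-effects sensitivity is generically nonzero
whenever the modifier is trophically connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import equilibria as eq
from .exceptions import DomainError, EquilibriumError, UsageError
from .model_core import (
    CommunityModel,
    State,
    TIMSpec,
    link_flux,
    modification_term,
    symbolic_system,
    tim_modifier_density,
)

__all__ = [
    "MetricReport",
    "metric_flux_change",
    "metric_bcr_change",
    "metric_tmii",
    "metric_jacobian_sensitivity",
    "metric_net_sensitivity",
    "metric_cv",
    "jacobian_sensitivity_matrix",
    "compute_all_metrics",
]


def _resolve(model: CommunityModel, tim) -> TIMSpec:
    return model.tim_by_id(tim) if isinstance(tim, str) else tim


# ---------------------------------------------------------------------------
# Flux change
# ---------------------------------------------------------------------------

def metric_flux_change(model: CommunityModel, tim, state) -> tuple[float, float]:
    """(flux ratio, flux difference) of the target link at one state.

    Both fluxes are evaluated at the *same* densities: once with the focal
    TIM's modification term forced to 1 (as if its modifier were absent
    from the term only) and once as-is.  Other TIMs on the link, and the
    modifier's trophic role, stay active.  The ratio is oriented
    unmodified/modified; a zero modified flux with nonzero unmodified flux
    yields ``inf`` (check with :func:`math.isinf`).
    """
    tim = _resolve(model, tim)
    link = model.link_by_key(*tim.target)
    f_off = link_flux(model, link, state, neutralize=(tim.tim_id,))
    f_on = link_flux(model, link, state)
    diff = f_off - f_on
    if f_on == 0.0:
        ratio = 1.0 if f_off == 0.0 else math.inf
    else:
        ratio = f_off / f_on
    return ratio, diff


# ---------------------------------------------------------------------------
# Change in B_CR (equilibrium resource-density ratio)
# ---------------------------------------------------------------------------

def metric_bcr_change(
    model: CommunityModel,
    tim,
    *,
    guess=None,
    seed: int = 0,
    tol: float = 1e-10,
) -> float:
    """Ratio I*/I*(c_ijk=0) of the resource's equilibrium densities.

    Solves the interior equilibrium twice with the same initial guess and
    restart policy: once with the TIM as specified, once with its strength
    set to zero.  Both solves must converge to feasible interior points.
    """
    tim = _resolve(model, tim)
    resource = tim.target[0]
    null_model = model.with_tim_strength(tim.tim_id, 0.0)
    sides = {"with TIM": model, "without TIM (c=0)": null_model}
    densities = {}
    for label, m in sides.items():
        res = eq.find_equilibrium(m, guess, seed=seed, tol=tol)
        if not res.converged:
            raise EquilibriumError(
                f"B_CR change: equilibrium solve {label} did not converge "
                f"(residual {res.residual_norm:.3g})"
            )
        if not res.feasible:
            raise EquilibriumError(f"B_CR change: equilibrium {label} is not interior-feasible")
        densities[label] = res.state.densities[m.index(resource)]
    return float(densities["with TIM"] / densities["without TIM (c=0)"])


# ---------------------------------------------------------------------------
# TMII pair (Jacobian entries)
# ---------------------------------------------------------------------------

def metric_tmii(model: CommunityModel, tim, state, method: str = "symbolic") -> tuple[float, float]:
    """Direct effect of the modifier on each interactor: (dI'/dK, dJ'/dK).

    These are the Jacobian entries (row i, column k) and (row j, column k)
    — the pairwise TMII framing of a modification.  Requires a dynamic
    TIM: the modifier must be a state coordinate.
    """
    tim = _resolve(model, tim)
    if tim.mode != "dynamic":
        raise UsageError(
            "TMII metric needs the modifier as a state coordinate; "
            f"TIM {tim.tim_id!r} is forced-mode (a cue, not a species axis)"
        )
    A = eq.jacobian(model, state, method=method)
    k = model.index(tim.modifier_id)
    i = model.index(tim.target[0])
    j = model.index(tim.target[1])
    return float(A.entries[i, k]), float(A.entries[j, k])


# ---------------------------------------------------------------------------
# Jacobian and net-effects sensitivities (mixed partials w.r.t. K)
# ---------------------------------------------------------------------------

def jacobian_sensitivity_matrix(
    model: CommunityModel, tim, state, method: str = "symbolic"
) -> np.ndarray:
    """Elementwise direct partial dA/dK of the community matrix.

    K is the focal TIM's modifier density — a state coordinate for dynamic
    TIMs, the forced cue value for forced TIMs.  All other coordinates are
    held fixed (no re-equilibration).
    """
    tim = _resolve(model, tim)
    st = state if isinstance(state, State) else State(np.asarray(state, dtype=float))
    x = st.densities
    if method == "symbolic":
        return _symbolic_dA_dK(model, tim)(x)
    if method == "finite_difference":
        return _fd_dA_dK(model, tim, x)
    raise UsageError(f"unknown method {method!r}")


def _symbolic_dA_dK(model: CommunityModel, tim: TIMSpec):
    import sympy as sp

    cache = getattr(model, "_dAdK_cache", {})
    if tim.tim_id not in cache:
        if tim.mode == "forced":
            syms, rates, forced = symbolic_system(model, forced_tim_ids=[tim.tim_id])
            Ksym = forced[tim.tim_id]
            A_expr = sp.Matrix(rates).jacobian(sp.Matrix(syms))
            dA = A_expr.diff(Ksym).subs(Ksym, sp.Float(tim.forced_density))
            fn = sp.lambdify(syms, dA, modules="numpy")
        else:
            syms, rates, _ = symbolic_system(model)
            Ksym = syms[model.index(tim.modifier_id)]
            A_expr = sp.Matrix(rates).jacobian(sp.Matrix(syms))
            dA = A_expr.diff(Ksym)
            fn = sp.lambdify(syms, dA, modules="numpy")
        cache[tim.tim_id] = lambda x, fn=fn: np.asarray(fn(*x), dtype=float)
        setattr(model, "_dAdK_cache", cache)
    return cache[tim.tim_id]


def _fd_dA_dK(model: CommunityModel, tim: TIMSpec, x: np.ndarray) -> np.ndarray:
    eps3 = np.finfo(float).eps ** 0.25  # nested differentiation: milder step
    if tim.mode == "dynamic":
        k = model.index(tim.modifier_id)
        h = eps3 * max(abs(x[k]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        if x[k] - h < 0:
            A0 = eq.jacobian(model, np.maximum(x, 0.0), method="finite_difference").entries
            Ap = eq.jacobian(model, xp, method="finite_difference").entries
            return (Ap - A0) / h
        xm[k] -= h
        Ap = eq.jacobian(model, xp, method="finite_difference").entries
        Am = eq.jacobian(model, xm, method="finite_difference").entries
        return (Ap - Am) / (2 * h)
    K = tim.forced_density
    h = eps3 * max(abs(K), 1.0)
    models = {}
    for sgn in (+1, -1):
        tims = [
            replace(t, forced_density=K + sgn * h) if t.tim_id == tim.tim_id else t
            for t in model.tims
        ]
        models[sgn] = CommunityModel(
            list(model.species), list(model.links), tims, list(model.species_order)
        )
    Ap = eq.jacobian(models[+1], x, method="finite_difference").entries
    Am = eq.jacobian(models[-1], x, method="finite_difference").entries
    return (Ap - Am) / (2 * h)


def metric_jacobian_sensitivity(
    model: CommunityModel, tim, state, method: str = "symbolic"
) -> tuple[float, float]:
    """(dA_ij/dK, dA_ji/dK): modifier sensitivity of the direct interaction.

    Mixed second partials of the growth-rate functions: how the direct
    interaction strengths between resource i and consumer j respond to the
    modifier density.  Exactly (0, 0) when c_ijk = 0 and the modifier does
    not otherwise enter the target link.
    """
    tim = _resolve(model, tim)
    dA = jacobian_sensitivity_matrix(model, tim, state, method=method)
    i = model.index(tim.target[0])
    j = model.index(tim.target[1])
    return float(dA[i, j]), float(dA[j, i])


def metric_net_sensitivity(
    model: CommunityModel, tim, state, method: str = "symbolic"
) -> tuple[float, float]:
    """(d(-A^-1)_ij/dK, d(-A^-1)_ji/dK): modifier sensitivity of net effects.

    Uses the matrix identity d(-A^-1)/dK = A^-1 (dA/dK) A^-1 with dA/dK the
    elementwise direct partial.  Because -A^-1 folds in indirect pathways,
    these entries are generically nonzero even at c_ijk = 0 whenever the
    modifier is trophically connected (density-mediated modification).
    """
    tim = _resolve(model, tim)
    A = eq.jacobian(model, state, method="symbolic" if method == "symbolic" else "finite_difference")
    # raises SingularMatrixError on ill-conditioned A
    eq.net_effects(A)
    Ainv = np.linalg.inv(A.entries)
    dA = jacobian_sensitivity_matrix(model, tim, state, method=method)
    dN = Ainv @ dA @ Ainv
    i = model.index(tim.target[0])
    j = model.index(tim.target[1])
    return float(dN[i, j]), float(dN[j, i])


# ---------------------------------------------------------------------------
# Coefficient of variation along a trajectory
# ---------------------------------------------------------------------------

def metric_cv(
    model: CommunityModel,
    tim,
    trajectory,
    window: tuple[float, float] | None = None,
    of: str = "modification",
    mean_tol: float = 1e-12,
) -> float:
    """sd/mean of the modification term (or link flux) over a time window.

    The series is evaluated along the trajectory and integrated with the
    trapezoid rule, so the estimate converges with sampling density.  By
    default the window drops the first half of the trajectory span as
    transient.  A constant series (e.g. at a stable fixed point) gives 0.
    """
    tim = _resolve(model, tim)
    times = np.asarray(trajectory.times, dtype=float)
    states = np.asarray(trajectory.states, dtype=float)
    if window is None:
        t0 = times[0] + 0.5 * (times[-1] - times[0])
        window = (t0, times[-1])
    lo, hi = window
    mask = (times >= lo - 1e-12) & (times <= hi + 1e-12)
    if mask.sum() < 3:
        raise UsageError("trajectory does not cover the requested window densely enough")
    t = times[mask]
    if of == "modification":
        series = np.array(
            [modification_term(tim, tim_modifier_density(model, tim, row)) for row in states[mask]]
        )
    elif of == "flux":
        link = model.link_by_key(*tim.target)
        series = np.array([link_flux(model, link, row) for row in states[mask]])
    else:
        raise UsageError(f"unknown series kind {of!r} (use 'modification' or 'flux')")
    span = t[-1] - t[0]
    mean = float(np.trapezoid(series, t) / span)
    if abs(mean) < mean_tol:
        raise DomainError("CV undefined: mean modification is (numerically) zero")
    var = float(np.trapezoid((series - mean) ** 2, t) / span)
    return math.sqrt(max(var, 0.0)) / mean


# ---------------------------------------------------------------------------
# The full report
# ---------------------------------------------------------------------------

_REPORT_FIELDS = (
    "modification_term",
    "flux_ratio",
    "flux_difference",
    "bcr_change",
    "cv_modification",
    "tmii_pair",
    "jacobian_sensitivity_pair",
    "net_sensitivity_pair",
)


@dataclass
class MetricReport:
    """One evaluation of the full metric suite for one TIM at one state.

    Inapplicable or failed metrics are ``None``; failures carry their
    reason in :attr:`errors` keyed by field name.  Scalar pairs are
    ``(toward-resource, toward-consumer)`` oriented as (i, j)/(j, i).
    """

    tim_id: str
    evaluation_state: State | None
    modification_parameter: float
    modification_term: float | None = None
    flux_ratio: float | None = None
    flux_difference: float | None = None
    bcr_change: float | None = None
    cv_modification: float | None = None
    tmii_pair: tuple[float, float] | None = None
    jacobian_sensitivity_pair: tuple[float, float] | None = None
    net_sensitivity_pair: tuple[float, float] | None = None
    settings: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat record (CSV-friendly); pairs split into _i/_j columns."""
        row = {
            "tim_id": self.tim_id,
            "modification_parameter": self.modification_parameter,
            "modification_term": self.modification_term,
            "flux_ratio": self.flux_ratio,
            "flux_difference": self.flux_difference,
            "bcr_change": self.bcr_change,
            "cv_modification": self.cv_modification,
        }
        for name, pair in (
            ("tmii", self.tmii_pair),
            ("jacobian_sensitivity", self.jacobian_sensitivity_pair),
            ("net_sensitivity", self.net_sensitivity_pair),
        ):
            row[f"{name}_i"] = None if pair is None else pair[0]
            row[f"{name}_j"] = None if pair is None else pair[1]
        return row

    def to_json_dict(self) -> dict:
        d = {
            "tim_id": self.tim_id,
            "modification_parameter": self.modification_parameter,
            "evaluation_state": None
            if self.evaluation_state is None
            else list(map(float, self.evaluation_state.densities)),
            "settings": self.settings,
            "errors": self.errors,
        }
        for f in _REPORT_FIELDS:
            v = getattr(self, f)
            d[f] = list(v) if isinstance(v, tuple) else v
        return d


def compute_all_metrics(
    model: CommunityModel,
    tim,
    at: str = "equilibrium",
    state=None,
    trajectory=None,
    window: tuple[float, float] | None = None,
    *,
    seed: int = 0,
    method: str = "symbolic",
) -> MetricReport:
    """Fill a :class:`MetricReport` in one of three evaluation contexts.

    ``at="equilibrium"`` solves the interior equilibrium and evaluates the
    state metrics there, plus the B_CR change (two further solves);
    ``at="state"`` evaluates at the given state (no B_CR, no CV);
    ``at="trajectory"`` adds the CV over ``window`` and evaluates the
    pointwise metrics at the trajectory's final state.

    Per-metric failures are recorded in ``report.errors`` instead of
    aborting the whole report.
    """
    tim = _resolve(model, tim)
    report = MetricReport(
        tim_id=tim.tim_id,
        evaluation_state=None,
        modification_parameter=float(tim.strength),
        settings={"at": at, "method": method, "seed": seed},
    )

    if at == "equilibrium":
        res = eq.find_equilibrium(model, state, seed=seed)
        if not (res.converged and res.feasible):
            report.errors["evaluation_state"] = (
                "no feasible interior equilibrium "
                f"(converged={res.converged}, feasible={res.feasible})"
            )
            return report
        st = res.state
    elif at == "state":
        if state is None:
            raise UsageError("at='state' requires a state")
        st = state if isinstance(state, State) else State(np.asarray(state, dtype=float))
    elif at == "trajectory":
        if trajectory is None:
            raise UsageError("at='trajectory' requires a trajectory")
        st = State(np.asarray(trajectory.states[-1], dtype=float), time=float(trajectory.times[-1]))
    else:
        raise UsageError(f"unknown evaluation context {at!r}")
    report.evaluation_state = st

    def attempt(name, fn):
        try:
            setattr(report, name, fn())
        except Exception as e:  # noqa: BLE001 - per-field error record by contract
            report.errors[name] = f"{type(e).__name__}: {e}"

    attempt(
        "modification_term",
        lambda: modification_term(tim, tim_modifier_density(model, tim, st)),
    )

    def flux():
        r, d = metric_flux_change(model, tim, st)
        report.flux_difference = d
        return r

    attempt("flux_ratio", flux)
    if at == "equilibrium":
        attempt("bcr_change", lambda: metric_bcr_change(model, tim, guess=st, seed=seed))
    if at == "trajectory":
        attempt("cv_modification", lambda: metric_cv(model, tim, trajectory, window))
    attempt("tmii_pair", lambda: metric_tmii(model, tim, st, method=method))
    attempt(
        "jacobian_sensitivity_pair",
        lambda: metric_jacobian_sensitivity(model, tim, st, method=method),
    )
    attempt("net_sensitivity_pair", lambda: metric_net_sensitivity(model, tim, st, method=method))
    return report
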