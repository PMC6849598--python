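"""Trajectory integration, asymptotic classification, and two experiments.

* :func:`simulate` — stiff-capable integration with densities clamped at
  zero (biomass cannot go negative).
* :func:`classify_dynamics` — integrate past a transient and label the
  asymptotic behaviour as a stable point, a cycle, marginal (e.g. the
  neutrally stable Lotka-Volterra centre), extinction, or divergence.
* :func:`static_replacement` — replace a dynamic TIM by a fixed parameter
  change: the affected functional-response parameter is multiplied by the
  modification term evaluated at a reference state.  The two vector fields
  agree exactly at that state, so a shared equilibrium is preserved, but
  their Jacobians differ — the dynamic feedback through the modifier
  column is lost.
* :func:`stabilization_scan` — sweep a TIM strength across a grid and
  record where a cycling system becomes a stable point, cross-checked
  against the leading eigenvalue at the interior equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.integrate

from . import equilibria as eqmod
from .exceptions import IntegrationError, UsageError
from .model_core import (
    CommunityModel,
    State,
    modification_term,
    rhs,
    tim_modifier_density,
)

__all__ = [
    "Trajectory",
    "simulate",
    "classify_dynamics",
    "static_replacement",
    "stabilization_scan",
    "AMPLITUDE_THRESHOLD",
    "DIVERGENCE_CAP",
]

AMPLITUDE_THRESHOLD = 0.01  # late-window relative peak-to-trough amplitude
DIVERGENCE_CAP = 1e8  # density units


@dataclass
class Trajectory:
    """Integrated densities over time, aligned to a model's species order."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species_order: list[str]
    solver_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.species_order)):
            raise UsageError("trajectory states must be (n_times, n_species)")
        if np.any(np.diff(self.times) <= 0):
            raise UsageError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise UsageError("trajectory contains non-finite densities")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species_order)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def final_state(self) -> State:
        return State(self.states[-1], time=float(self.times[-1]))


def simulate(
    model: CommunityModel,
    initial,
    t_span: tuple[float, float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t_eval=None,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the model's ODEs over ``t_span``.

    Densities are clamped at zero: the right-hand side is evaluated at
    ``max(N, 0)`` and any negative excursions in the solver output (bounded
    by the tolerances) are clipped, with the number of clipped entries
    recorded in ``solver_info["clamp_events"]``.
    """
    x0 = np.asarray(initial.densities if isinstance(initial, State) else initial, dtype=float)
    if x0.shape != (model.n_species,):
        raise UsageError("initial state has wrong dimension")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise UsageError("t_span must have positive length")

    def f(t, y):
        return rhs(model, np.maximum(y, 0.0))

    sol = scipy.integrate.solve_ivp(
        f, (t0, t1), np.maximum(x0, 0.0), method=method, rtol=rtol, atol=atol,
        t_eval=t_eval, max_step=max_step, dense_output=False,
    )
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else t0
        last_y = sol.y[:, -1] if sol.t.size else x0
        raise IntegrationError(
            f"integration failed at t={last_t:.6g}: {sol.message}",
            last_time=last_t,
            last_state=np.maximum(last_y, 0.0),
        )
    states = sol.y.T
    clamp_events = int(np.sum(states < 0))
    states = np.maximum(states, 0.0)
    return Trajectory(
        times=sol.t,
        states=states,
        species_order=list(model.species_order),
        solver_info={
            "method": method,
            "rtol": rtol,
            "atol": atol,
            "clamp_events": clamp_events,
            "nfev": int(sol.nfev),
        },
    )


def classify_dynamics(
    model: CommunityModel,
    initial,
    *,
    t_max: float = 1000.0,
    transient_fraction: float = 0.5,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    divergence_cap: float = DIVERGENCE_CAP,
    extinction_tol: float = eqmod.FEASIBILITY_TOL,
    n_window_points: int = 600,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    seed: int = 0,
) -> str:
    """Label the asymptotic behaviour from one initial condition.

    Integrates to ``t_max``, discards the leading ``transient_fraction`` of
    the span, and inspects the late window: divergence past the density
    cap, extinction of any species, a near-constant window (stable point,
    confirmed against a converged stable equilibrium near the endpoint),
    or sustained oscillation.  Oscillation around an *unstable* interior
    equilibrium is a limit cycle (``cycling``); oscillation around a
    marginal equilibrium — the neutral Lotka-Volterra centre — or any
    undecidable case is ``marginal``.
    """
    t_trans = transient_fraction * t_max
    t_eval = np.linspace(t_trans, t_max, n_window_points)
    try:
        traj = simulate(model, initial, (0.0, t_max), rtol=rtol, atol=atol, t_eval=t_eval)
    except IntegrationError as e:
        if e.last_state is not None and np.max(e.last_state) > divergence_cap:
            return "divergent"
        raise
    w = traj.states
    if np.max(w) > divergence_cap:
        return "divergent"
    if np.any(w[-1] < extinction_tol):
        return "extinction"
    means = w.mean(axis=0)
    amps = w.max(axis=0) - w.min(axis=0)
    rel = amps / np.maximum(means, extinction_tol)
    if np.all(rel < amplitude_threshold):
        res = eqmod.find_equilibrium(model, w[-1], seed=seed)
        if res.converged and np.max(np.abs(res.state.densities - w[-1])) < max(
            1e-3, amplitude_threshold * float(np.max(means))
        ):
            if res.stability == "stable":
                return "stable_point"
            if res.stability == "marginal":
                return "marginal"
        return "marginal"
    res = eqmod.find_equilibrium(model, means, seed=seed)
    if res.converged and res.feasible and res.stability == "unstable":
        return "cycling"
    if res.converged and res.stability == "marginal":
        return "marginal"
    if res.converged and res.feasible and res.stability == "stable":
        # oscillation persisting around a stable point: unresolved transient
        return "marginal"
    return "cycling"


def static_replacement(model: CommunityModel, tim, reference_state) -> CommunityModel:
    """Replace a TIM by a fixed change to the parameter it modifies.

    The focal TIM is removed and the affected functional-response
    parameter of its target link is multiplied by the modification term
    evaluated at the reference state's modifier density.  By construction
    the replaced model's vector field equals the original's at the
    reference state, so a reference equilibrium is preserved exactly; away
    from it the dynamic feedback through the modifier is absent.
    """
    tim = model.tim_by_id(tim) if isinstance(tim, str) else tim
    if tim not in model.tims:
        raise UsageError(f"TIM {tim.tim_id!r} is not part of the model")
    term = modification_term(tim, tim_modifier_density(model, tim, reference_state))
    link = model.link_by_key(*tim.target)
    new_link = replace(link, **{tim.affected_parameter: getattr(link, tim.affected_parameter) * term})
    links = [new_link if l is link else l for l in model.links]
    tims = [t for t in model.tims if t.tim_id != tim.tim_id]
    return CommunityModel(list(model.species), links, tims, list(model.species_order))


def stabilization_scan(
    model: CommunityModel,
    tim,
    c_grid,
    initial,
    *,
    seed: int = 0,
    t_max: float = 1000.0,
    classify_opts: dict | None = None,
) -> pd.DataFrame:
    """Classify dynamics and equilibrium stability across a TIM-strength grid.

    For each strength c in the grid the model's focal TIM is set to c, the
    dynamics are classified from ``initial``, and — where an interior
    equilibrium is found — the leading (largest) eigenvalue real part of
    its Jacobian is recorded.  A warning is issued if the system does not
    cycle at c = 0 (the scan is about stabilisation of cycles).

    Returns a DataFrame with columns ``c``, ``classification``,
    ``leading_eigenvalue_re``, ``eq_converged``, ``eq_feasible``.
    """
    tim = model.tim_by_id(tim) if isinstance(tim, str) else tim
    opts = dict(t_max=t_max, seed=seed)
    opts.update(classify_opts or {})
    base = classify_dynamics(model.with_tim_strength(tim.tim_id, 0.0), initial, **opts)
    if base != "cycling":
        warnings.warn(
            f"system is classified {base!r} (not cycling) at c = 0; "
            "the stabilisation scan expects a cycling baseline",
            stacklevel=2,
        )
    rows = []
    guess = np.asarray(initial.densities if isinstance(initial, State) else initial, dtype=float)
    for c in np.asarray(c_grid, dtype=float):
        m_c = model.with_tim_strength(tim.tim_id, float(c))
        classification = classify_dynamics(m_c, initial, **opts)
        res = eqmod.find_equilibrium(m_c, guess, seed=seed)
        leading = float(np.max(res.eigenvalues.real)) if res.converged else np.nan
        if res.converged and res.feasible:
            guess = res.state.densities  # continuation along the grid
        rows.append(
            {
                "c": float(c),
                "classification": classification,
                "leading_eigenvalue_re": leading,
                "eq_converged": bool(res.converged),
                "eq_feasible": bool(res.feasible),
            }
        )
    return pd.DataFrame(rows)
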