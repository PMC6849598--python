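"""Fixed points, community (Jacobian) matrices and net-effects matrices.

The community matrix A collects the partial derivatives of each species'
rate of density change with respect to each species' density, evaluated at
a system state (normally an equilibrium).  The net-effects matrix -A^-1
gives the combined direct and indirect (press-perturbation) effect of each
species on every other.

Numerical notes
---------------
Finite-difference Jacobians use central differences with per-coordinate
step ``h = eps**(1/3) * max(|x|, 1)`` (the standard optimal scaling for a
first derivative).  Coordinates sitting on the zero-density clamp boundary
fall back to a one-sided forward difference with a warning.  Eigenvalues
whose real part lies within ``1e-7`` of zero are classified marginal,
which keeps the neutrally stable Lotka-Volterra centre out of the
stable/unstable bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .exceptions import NumericError, SingularMatrixError, UsageError
from .model_core import CommunityModel, State, rhs, symbolic_system

__all__ = [
    "EquilibriumResult",
    "CommunityMatrix",
    "find_equilibrium",
    "jacobian",
    "net_effects",
    "classify_stability",
    "STABILITY_MARGIN",
    "FEASIBILITY_TOL",
]

STABILITY_MARGIN = 1e-7
FEASIBILITY_TOL = 1e-8
CONDITION_LIMIT = 1e12


@dataclass
class CommunityMatrix:
    """A square species-by-species matrix tied to an evaluation state.

    ``kind`` is ``"jacobian"`` (entry (x, y) = d rate_x / d density_y) or
    ``"net_effects"`` (the inverse negative Jacobian).
    """

    species_order: list[str]
    entries: np.ndarray
    evaluation_state: State
    kind: str = "jacobian"

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.species_order)
        if self.entries.shape != (n, n):
            raise UsageError(f"matrix shape {self.entries.shape} does not match {n} species")

    def entry(self, row_id: str, col_id: str) -> float:
        i = self.species_order.index(row_id)
        j = self.species_order.index(col_id)
        return float(self.entries[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.species_order, columns=self.species_order)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")


@dataclass
class EquilibriumResult:
    """A root of the model's right-hand side with its local diagnosis."""

    state: State
    residual_norm: float
    eigenvalues: np.ndarray
    stability: str
    feasible: bool
    converged: bool
    jacobian: CommunityMatrix | None = None
    attempts: int = 1

    @property
    def densities(self) -> np.ndarray:
        return self.state.densities

    def to_dataframe(self, species_order: Sequence[str] | None = None) -> pd.DataFrame:
        order = list(species_order) if species_order else self.jacobian.species_order
        return pd.DataFrame(
            {
                "species": order,
                "density": self.state.densities,
                "residual_norm": self.residual_norm,
                "stability": self.stability,
                "feasible": self.feasible,
                "converged": self.converged,
            }
        )


def classify_stability(eigenvalues, margin: float = STABILITY_MARGIN) -> str:
    """Classify a Jacobian spectrum as stable, unstable, or marginal.

    Stable requires every real part below ``-margin``; unstable requires
    some real part above ``+margin``; anything else (leading real part
    within the margin of zero) is marginal.
    """
    ev = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    if ev.size == 0:
        raise UsageError("empty eigenvalue spectrum")
    if not np.all(np.isfinite(ev)):
        raise NumericError("non-finite eigenvalue in spectrum")
    reals = ev.real
    if np.all(reals < -margin):
        return "stable"
    if np.any(reals > margin):
        return "unstable"
    return "marginal"


def _clipped_rhs(model: CommunityModel, x: np.ndarray) -> np.ndarray:
    return rhs(model, np.maximum(x, 0.0))


def jacobian(model: CommunityModel, state, method: str = "symbolic") -> CommunityMatrix:
    """Community (Jacobian) matrix of the model at a state.

    ``method="symbolic"`` differentiates the closed-form right-hand side
    with sympy; ``method="finite_difference"`` uses central differences.
    """
    st = state if isinstance(state, State) else State(np.asarray(state, dtype=float))
    x = st.densities
    if method == "symbolic":
        entries = _symbolic_jacobian(model)(x)
    elif method == "finite_difference":
        entries = _fd_jacobian(model, x)
    else:
        raise UsageError(f"unknown jacobian method {method!r}")
    if not np.all(np.isfinite(entries)):
        raise NumericError("Jacobian contains non-finite entries")
    return CommunityMatrix(list(model.species_order), entries, st, kind="jacobian")


def _symbolic_jacobian(model: CommunityModel):
    """Lambdified symbolic Jacobian, cached on the model instance."""
    cache = getattr(model, "_sym_jac_cache", None)
    if cache is None:
        import sympy as sp

        syms, rates, _ = symbolic_system(model)
        jac = sp.Matrix(rates).jacobian(sp.Matrix(syms))
        fn = sp.lambdify(syms, jac, modules="numpy")
        cache = lambda x: np.asarray(fn(*x), dtype=float)
        object.__setattr__(model, "_sym_jac_cache", cache)
    return cache


def _fd_jacobian(model: CommunityModel, x: np.ndarray) -> np.ndarray:
    n = x.size
    J = np.empty((n, n))
    eps3 = np.finfo(float).eps ** (1.0 / 3.0)
    for j in range(n):
        h = eps3 * max(abs(x[j]), 1.0)
        if x[j] - h < 0:
            warnings.warn(
                f"density of {model.species_order[j]!r} is on the clamp boundary; "
                "using one-sided differences",
                stacklevel=3,
            )
            f0 = _clipped_rhs(model, x)
            xp = x.copy()
            xp[j] += h
            J[:, j] = (_clipped_rhs(model, xp) - f0) / h
        else:
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (_clipped_rhs(model, xp) - _clipped_rhs(model, xm)) / (2 * h)
    return J


def net_effects(A: CommunityMatrix) -> CommunityMatrix:
    """Net-effects matrix -A^-1 from a community (Jacobian) matrix."""
    if A.kind != "jacobian":
        raise UsageError(f"net_effects needs a jacobian-kind matrix, got {A.kind!r}")
    cond = np.linalg.cond(A.entries)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularMatrixError(
            f"Jacobian at state {A.evaluation_state.densities} is singular or "
            f"ill-conditioned (cond={cond:.3g})"
        )
    N = -np.linalg.inv(A.entries)
    return CommunityMatrix(list(A.species_order), N, A.evaluation_state, kind="net_effects")


def find_equilibrium(
    model: CommunityModel,
    guess=None,
    *,
    tol: float = 1e-10,
    restarts: int = 20,
    seed: int = 0,
    jacobian_method: str = "symbolic",
) -> EquilibriumResult:
    """Locate a fixed point of the model by Newton-type root finding.

    Starts from ``guess`` (all-ones by default) and retries from up to
    ``restarts`` log-uniform random positive states drawn from a generator
    seeded with ``seed``.  The *interior* (feasible) root is the target:
    restarting continues past boundary (extinction) roots until a feasible
    converged root is found; the best root seen is returned otherwise.  As
    the one exception, a guess that is already a root to tolerance (e.g.
    the origin) is returned as-is.  Never raises on non-convergence: the
    returned result carries ``converged=False`` and the best residual seen.

    The returned equilibrium reports feasibility (every density above
    ``FEASIBILITY_TOL``) and local stability from the Jacobian spectrum.
    """
    n = model.n_species
    if guess is None:
        x0 = np.ones(n)
    else:
        x0 = np.asarray(guess.densities if isinstance(guess, State) else guess, dtype=float)

    jac_fn = _symbolic_jacobian(model)
    fun = lambda x: _clipped_rhs(model, x)
    jac = lambda x: jac_fn(np.maximum(x, 0.0))

    # Interior roots are sought in log-density space: z = log N keeps every
    # iterate strictly positive and well away from spurious clipped roots.
    _ZCAP = 50.0

    def fun_log(z):
        return rhs(model, np.exp(np.clip(z, -_ZCAP, _ZCAP)))

    def jac_log(z):
        x = np.exp(np.clip(z, -_ZCAP, _ZCAP))
        return jac_fn(x) * x[np.newaxis, :]

    def residual(x):
        return float(np.max(np.abs(rhs(model, x))))

    def rank(x, res):
        # prefer converged roots, then feasible ones, then small residuals
        return (res < tol, bool(np.all(x > FEASIBILITY_TOL)), -res)

    best = (np.maximum(x0, 0.0), residual(np.maximum(x0, 0.0)))
    attempts = 0
    if best[1] >= tol:  # guess is not already a fixed point
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(0, restarts)):
            starts.append(10.0 ** rng.uniform(-2, 2, size=n))
        def log_solve(start):
            z0 = np.log(np.maximum(start, 1e-12))
            sol = scipy.optimize.root(fun_log, z0, jac=jac_log, method="hybr", tol=1e-13)
            return np.exp(np.clip(sol.x, -_ZCAP, _ZCAP))

        def warm_start(start):
            # ride the flow briefly: for attracting interior states this
            # lands inside the Newton basin of the interior root
            import scipy.integrate

            sol = scipy.integrate.solve_ivp(
                lambda t, y: fun(y), (0.0, 50.0), np.maximum(start, 0.0),
                method="LSODA", rtol=1e-6, atol=1e-9,
            )
            if not sol.success:
                raise NumericError("warm-start integration failed")
            return np.maximum(sol.y[:, -1], 0.0)

        def found_interior():
            return best[1] < tol and bool(np.all(best[0] > FEASIBILITY_TOL))

        for start in starts:
            attempts += 1
            candidates = []
            for maker in (
                lambda: log_solve(start),
                lambda: np.maximum(
                    scipy.optimize.root(fun, start, jac=jac, method="hybr", tol=1e-13).x, 0.0
                ),
            ):
                try:
                    candidates.append(maker())
                except (FloatingPointError, NumericError, ValueError):
                    pass
            for x in candidates:
                try:
                    res = residual(x)
                except NumericError:
                    continue
                if rank(x, res) > rank(*best):
                    best = (x, res)
            if not found_interior():
                try:
                    x = log_solve(warm_start(start))
                    res = residual(x)
                    if rank(x, res) > rank(*best):
                        best = (x, res)
                except (FloatingPointError, NumericError, ValueError):
                    pass
            if found_interior():
                break
    x, res = best
    converged = res < tol
    st = State(x)
    A = jacobian(model, st, method=jacobian_method)
    ev = np.linalg.eigvals(A.entries)
    return EquilibriumResult(
        state=st,
        residual_norm=res,
        eigenvalues=ev,
        stability=classify_stability(ev),
        feasible=bool(np.all(x > FEASIBILITY_TOL)),
        converged=converged,
        jacobian=A,
        attempts=attempts,
    )
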