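"""Demonstration systems, TIM-parameter sweeps, and synthetic experiments.

Three demonstration systems mirror the classic settings in which TIM
metrics are compared:

``chain_linear``
    plant-herbivore-predator chain, linear (type I) consumption, with an
    exponential TIM from the predator onto the plant-herbivore attack rate
    (predation risk suppressing herbivore foraging).
``chain_nonlinear``
    the same topology with Holling type II functional responses.
``aphid_parasitoid``
    two hosts sharing one parasitoid, with a TIM from host 1's density
    onto the parasitoid's attack on host 2.  Which functional-response
    parameter the TIM targets is configuration, not doctrine: override
    ``tims.T1.affected_parameter`` to explore alternatives.

All demo parameters are package defaults chosen so that every demo has a
feasible, locally stable interior equilibrium at c = 0 (verified in the
test suite).  They are illustrative communities, not fits to any dataset.

The module also provides the sweep engine (vary one TIM's strength over a
grid, re-solve the equilibrium by continuation, and recompute the whole
metric suite at each point), a seeded random-chain generator for property
tests, and a synthetic multi-level functional-response experiment
(prey density x modifier density design) with a lognormal observation
model plus the matching nonlinear least-squares fitter.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.optimize

from . import equilibria as eqmod
from . import tim_metrics as metrics
from .exceptions import FitError, UsageError
from .model_core import (
    CommunityModel,
    SpeciesSpec,
    State,
    TIMSpec,
    TrophicLink,
    modification_term,
)

__all__ = [
    "SweepTable",
    "ExperimentData",
    "FitResult",
    "GeneratedChain",
    "build_demo",
    "build_stabilization_demo",
    "sweep_tim_parameter",
    "generate_random_chain",
    "generate_fr_experiment",
    "fit_tim_model",
    "DEMO_NAMES",
    "model_hash",
]

DEMO_NAMES = ("chain_linear", "chain_nonlinear", "aphid_parasitoid")

# Frozen demo defaults (interior equilibrium feasible and stable at c = 0;
# re-verified by the test suite).
_CHAIN_DEFAULTS = dict(
    r=1.0, plant_self_limitation=0.05,
    a1=0.5, a2=0.4, eps1=0.5, eps2=0.5, d1=0.1, d2=0.1, h1=0.0, h2=0.0,
    tim_strength=-0.1,
)
_CHAIN_NONLINEAR_DEFAULTS = dict(
    r=1.0, plant_self_limitation=0.13,
    a1=0.3, a2=0.6, eps1=0.5, eps2=0.5, d1=0.25, d2=0.13, h1=0.2, h2=0.2,
    tim_strength=-0.1,
)
_APHID_DEFAULTS = dict(
    r1=1.0, r2=1.0, host_self_limitation=0.1,
    a1=0.1, a2=0.12, eps=0.5, d=0.1,
    tim_strength=-0.2,
)
# Rosenzweig-MacArthur chain enriched past its Hopf point (cycles at c = 0)
# with an exponential TIM: the consumer's own density reduces its attack
# rate (risk-averse foraging at crowding), stabilising within the grid.
_RM_DEFAULTS = dict(
    r=1.0, self_limitation=0.05, a=1.0, h=0.5, eps=0.5, d=0.4,
)
STABILIZATION_C_GRID = tuple(np.round(np.linspace(-0.8, 0.0, 9), 10))
STABILIZATION_INITIAL = (2.0, 1.0)


def model_hash(model: CommunityModel) -> str:
    """Stable content hash of a model's canonical JSON form."""
    payload = json.dumps(model.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Demo constructors
# ---------------------------------------------------------------------------

def _chain_model(nonlinear: bool) -> CommunityModel:
    p = _CHAIN_NONLINEAR_DEFAULTS if nonlinear else _CHAIN_DEFAULTS
    form = "holling2" if nonlinear else "linear"
    species = [
        SpeciesSpec("P", "producer", p["r"], p["plant_self_limitation"], name="plant"),
        SpeciesSpec("H", "consumer", p["d1"], 0.0, name="herbivore"),
        SpeciesSpec("C", "consumer", p["d2"], 0.0, name="predator"),
    ]
    links = [
        TrophicLink("P", "H", p["a1"], p["eps1"], fr_form=form, handling_time=p["h1"]),
        TrophicLink("H", "C", p["a2"], p["eps2"], fr_form=form, handling_time=p["h2"]),
    ]
    tims = [
        TIMSpec(
            "T1", modifier_id="C", target=("P", "H"), strength=p["tim_strength"],
            affected_parameter="attack_rate", form="exponential",
        )
    ]
    return CommunityModel(species, links, tims)


def _aphid_parasitoid_model() -> CommunityModel:
    p = _APHID_DEFAULTS
    species = [
        SpeciesSpec("H1", "producer", p["r1"], p["host_self_limitation"], name="host 1"),
        SpeciesSpec("H2", "producer", p["r2"], p["host_self_limitation"], name="host 2"),
        SpeciesSpec("P", "consumer", p["d"], 0.0, name="parasitoid"),
    ]
    links = [
        TrophicLink("H1", "P", p["a1"], p["eps"], fr_form="linear"),
        TrophicLink("H2", "P", p["a2"], p["eps"], fr_form="linear"),
    ]
    tims = [
        TIMSpec(
            "T1", modifier_id="H1", target=("H2", "P"), strength=p["tim_strength"],
            affected_parameter="attack_rate", form="exponential",
        )
    ]
    return CommunityModel(species, links, tims)


def _apply_overrides(model: CommunityModel, overrides: dict) -> CommunityModel:
    """Apply dotted-path overrides, e.g. ``{"tims.T1.strength": 0.3}``.

    Paths: ``species.<id>.<field>``, ``links.<resource>-><consumer>.<field>``,
    ``tims.<tim_id>.<field>``.  Unknown targets raise a usage error.
    """
    from dataclasses import replace as _replace

    species = list(model.species)
    links = list(model.links)
    tims = list(model.tims)
    for path, value in overrides.items():
        parts = path.split(".")
        if len(parts) != 3:
            raise UsageError(f"override path {path!r} must be section.target.field")
        section, target, fld = parts
        if section == "species":
            idx = next((n for n, s in enumerate(species) if s.id == target), None)
            if idx is None:
                raise UsageError(f"override {path!r}: no species {target!r}")
            if fld not in species[idx].__dataclass_fields__:
                raise UsageError(f"override {path!r}: species have no field {fld!r}")
            species[idx] = _replace(species[idx], **{fld: value})
        elif section == "links":
            if "->" not in target:
                raise UsageError(f"override {path!r}: link target must be 'resource->consumer'")
            rid, cid = target.split("->", 1)
            idx = next((n for n, l in enumerate(links) if l.key == (rid, cid)), None)
            if idx is None:
                raise UsageError(f"override {path!r}: no link {rid!r}->{cid!r}")
            if fld not in links[idx].__dataclass_fields__:
                raise UsageError(f"override {path!r}: links have no field {fld!r}")
            links[idx] = _replace(links[idx], **{fld: value})
        elif section == "tims":
            idx = next((n for n, t in enumerate(tims) if t.tim_id == target), None)
            if idx is None:
                raise UsageError(f"override {path!r}: no TIM {target!r}")
            if fld == "target":
                value = (str(value[0]), str(value[1]))
            if fld not in tims[idx].__dataclass_fields__:
                raise UsageError(f"override {path!r}: TIMs have no field {fld!r}")
            tims[idx] = _replace(tims[idx], **{fld: value})
        else:
            raise UsageError(f"override {path!r}: unknown section {section!r}")
    return CommunityModel(species, links, tims, list(model.species_order))


def build_demo(name: str, overrides: dict | None = None) -> CommunityModel:
    """Construct one of the named demonstration systems.

    ``overrides`` is a dotted-path dict (see :func:`_apply_overrides`)
    changing exactly the named parameters, e.g.
    ``build_demo("chain_linear", {"tims.T1.strength": 0.4})``.
    """
    if name == "chain_linear":
        model = _chain_model(nonlinear=False)
    elif name == "chain_nonlinear":
        model = _chain_model(nonlinear=True)
    elif name == "aphid_parasitoid":
        model = _aphid_parasitoid_model()
    else:
        raise UsageError(f"unknown demo {name!r}; available: {', '.join(DEMO_NAMES)}")
    if overrides:
        model = _apply_overrides(model, overrides)
    return model


def build_stabilization_demo() -> tuple[CommunityModel, str, np.ndarray, State]:
    """Enriched consumer-resource system that cycles at c = 0.

    Returns ``(model, tim_id, c_grid, initial_state)`` for
    :func:`timweb.dynamics.stabilization_scan`: a Rosenzweig-MacArthur
    pair past its Hopf point with an exponential TIM in which the
    consumer's own density depresses its attack rate.  The shipped grid
    contains strengths at which the cycle collapses to a stable point.
    """
    p = _RM_DEFAULTS
    species = [
        SpeciesSpec("R", "producer", p["r"], p["self_limitation"], name="resource"),
        SpeciesSpec("C", "consumer", p["d"], 0.0, name="consumer"),
    ]
    links = [
        TrophicLink("R", "C", p["a"], p["eps"], fr_form="holling2", handling_time=p["h"]),
    ]
    tims = [
        TIMSpec(
            "T1", modifier_id="C", target=("R", "C"), strength=0.0,
            affected_parameter="attack_rate", form="exponential",
        )
    ]
    model = CommunityModel(species, links, tims)
    return model, "T1", np.asarray(STABILIZATION_C_GRID), State(np.asarray(STABILIZATION_INITIAL))


# ---------------------------------------------------------------------------
# TIM-parameter sweep (the metric-comparison engine)
# ---------------------------------------------------------------------------

@dataclass
class SweepTable:
    """Metric suite across a grid of TIM strengths.

    One row per grid value of c: equilibrium densities, convergence /
    feasibility / stability flags, and the full metric report where the
    equilibrium exists.  Non-converged or infeasible points are flagged
    and their metric fields left absent, never extrapolated.
    """

    tim_id: str
    c_grid: np.ndarray
    rows: list[dict]
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {
                "c": row["c"],
                "converged": row["converged"],
                "feasible": row["feasible"],
                "stability": row["stability"],
            }
            for sid, dens in zip(self.provenance["species_order"], row["densities"]):
                rec[f"N_{sid}"] = dens
            report = row.get("report")
            if report is not None:
                rec.update({k: v for k, v in report.to_row().items() if k != "tim_id"})
            records.append(rec)
        return pd.DataFrame(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _continuation_order(c_grid: np.ndarray) -> list[int]:
    """Grid indices ordered from the value nearest zero outward, per sign."""
    order = []
    idx = np.argsort(np.asarray(c_grid))
    nonneg = [i for i in idx if c_grid[i] >= 0]
    neg = [i for i in reversed(idx) if c_grid[i] < 0]
    return nonneg + neg


def sweep_tim_parameter(
    model: CommunityModel,
    tim,
    c_grid,
    *,
    seed: int = 0,
    guess=None,
    metric_method: str = "symbolic",
) -> SweepTable:
    """Vary one TIM's strength over a grid and recompute the metric suite.

    The equilibrium is tracked by continuation: grid points are visited
    from c = 0 outward in each direction and each solve starts from the
    previous feasible equilibrium.  At every feasible point the full
    metric report (including the B_CR change against the c = 0 model) is
    evaluated at the resultant equilibrium densities.
    """
    tim = model.tim_by_id(tim) if isinstance(tim, str) else tim
    c_grid = np.asarray(c_grid, dtype=float)
    if c_grid.ndim != 1 or c_grid.size == 0 or not np.all(np.isfinite(c_grid)):
        raise UsageError("c_grid must be a finite non-empty 1-D grid")
    base_guess = None if guess is None else np.asarray(
        guess.densities if isinstance(guess, State) else guess, dtype=float
    )
    rows_by_index: dict[int, dict] = {}
    order = _continuation_order(c_grid)
    last_good = {1: base_guess, -1: base_guess}
    for i in order:
        c = float(c_grid[i])
        branch = 1 if c >= 0 else -1
        m_c = model.with_tim_strength(tim.tim_id, c)
        res = eqmod.find_equilibrium(m_c, last_good[branch], seed=seed)
        ok = res.converged and res.feasible
        row = {
            "c": c,
            "converged": bool(res.converged),
            "feasible": bool(res.feasible),
            "stability": res.stability,
            "densities": res.state.densities.copy(),
            "report": None,
        }
        if ok:
            last_good[branch] = res.state.densities
            if c == 0.0:
                last_good[-1] = res.state.densities
            report = metrics.compute_all_metrics(
                m_c, tim.tim_id, at="state", state=res.state, seed=seed, method=metric_method
            )
            try:
                report.bcr_change = metrics.metric_bcr_change(
                    m_c, tim.tim_id, guess=res.state, seed=seed
                )
            except Exception as e:  # noqa: BLE001 - flagged, not fatal, per row
                report.errors["bcr_change"] = f"{type(e).__name__}: {e}"
            row["report"] = report
        rows_by_index[i] = row
    return SweepTable(
        tim_id=tim.tim_id,
        c_grid=c_grid,
        rows=[rows_by_index[i] for i in range(c_grid.size)],
        provenance={
            "model_hash": model_hash(model),
            "seed": seed,
            "species_order": list(model.species_order),
            "metric_method": metric_method,
        },
    )


# ---------------------------------------------------------------------------
# Random chain fixtures
# ---------------------------------------------------------------------------

class GeneratedChain(NamedTuple):
    model: CommunityModel
    attempts: int


_CHAIN_CONFIG_DEFAULTS = dict(
    length=3,
    r=(0.5, 1.5),
    self_limitation=(0.02, 0.1),
    attack=(0.2, 0.8),
    efficiency=(0.3, 0.7),
    death=(0.05, 0.15),
    tim_strength=(-0.5, 0.5),
    fr_form="linear",
    handling=(0.0, 0.0),
    max_attempts=200,
)


def generate_random_chain(seed: int, config: dict | None = None) -> GeneratedChain:
    """Seeded random food chain with a TIM, rejection-sampled for stability.

    Draws chain parameters uniformly from the configured ranges and keeps
    the first draw whose c = 0 counterpart has a feasible, locally stable
    interior equilibrium.  The top species modifies the basal link's
    attack rate (exponential form).  Reproducible: the same seed and
    config give the same model.
    """
    cfg = dict(_CHAIN_CONFIG_DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise UsageError(f"unknown random-chain config keys: {sorted(unknown)}")
        cfg.update(config)
    L = int(cfg["length"])
    if L < 3:
        raise UsageError("chain length must be >= 3 (needs a modifier above the modified link)")
    rng = np.random.default_rng(seed)
    for attempt in range(1, int(cfg["max_attempts"]) + 1):
        species = [SpeciesSpec("S0", "producer", rng.uniform(*cfg["r"]), rng.uniform(*cfg["self_limitation"]))]
        links = []
        for lvl in range(1, L):
            species.append(SpeciesSpec(f"S{lvl}", "consumer", rng.uniform(*cfg["death"]), 0.0))
            links.append(
                TrophicLink(
                    f"S{lvl-1}", f"S{lvl}",
                    attack_rate=rng.uniform(*cfg["attack"]),
                    conversion_efficiency=rng.uniform(*cfg["efficiency"]),
                    fr_form=cfg["fr_form"],
                    handling_time=rng.uniform(*cfg["handling"]) if cfg["fr_form"] != "linear" else 0.0,
                )
            )
        tims = [
            TIMSpec(
                "T1", modifier_id=f"S{L-1}", target=("S0", "S1"),
                strength=rng.uniform(*cfg["tim_strength"]),
                affected_parameter="attack_rate", form="exponential",
            )
        ]
        model = CommunityModel(species, links, tims)
        null = model.with_tim_strength("T1", 0.0)
        res = eqmod.find_equilibrium(null, np.ones(L), seed=int(rng.integers(2**31 - 1)))
        if res.converged and res.feasible and res.stability == "stable":
            return GeneratedChain(model, attempt)
    raise UsageError(
        f"no feasible stable chain found in {cfg['max_attempts']} attempts for config {cfg!r}"
    )


# ---------------------------------------------------------------------------
# Multi-level functional-response experiments (generate + fit)
# ---------------------------------------------------------------------------

@dataclass
class ExperimentData:
    """Synthetic consumption-rate table over a prey x modifier design.

    ``table`` columns: ``prey_density``, ``modifier_density``,
    ``consumption_rate`` (per consumer per time).  ``true_spec`` records
    the generating surface; ``noise_cv`` the lognormal coefficient of
    variation of the multiplicative observation noise.
    """

    table: pd.DataFrame
    design: dict
    true_spec: dict
    noise_cv: float
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_FIT_FR_FORMS = ("linear", "holling2")
_FIT_AFFECTED = ("attack_rate", "handling_time")


def _surface(
    R: np.ndarray,
    K: np.ndarray,
    a: float,
    h: float,
    c: float,
    fr_form: str,
    tim_form: str,
    affected_parameter: str,
    form_params: dict,
) -> np.ndarray:
    """Per-consumer consumption rate over prey density R and modifier density K."""
    tim = TIMSpec("fit", modifier_id="K", target=("R", "C"), strength=c,
                  form=tim_form, form_params=form_params)
    m = np.array([modification_term(tim, k) for k in np.atleast_1d(K)], dtype=float)
    a_eff = a * m if affected_parameter == "attack_rate" else a
    h_eff = h * m if affected_parameter == "handling_time" else h
    if fr_form == "linear":
        return a_eff * R
    return a_eff * R / (1.0 + a_eff * h_eff * R)


def generate_fr_experiment(
    true_model_spec: dict,
    design: dict,
    noise: float,
    seed: int,
) -> ExperimentData:
    """Simulate a short-term functional-response experiment with a TIM.

    ``true_model_spec`` keys: ``fr_form`` (linear | holling2),
    ``attack_rate``, ``handling_time``, ``tim_form``, ``strength``,
    ``affected_parameter``, optional ``form_params``.  ``design`` keys:
    ``prey_levels``, ``modifier_levels`` (each a list of densities, at
    least two modifier levels) and ``replicates``.  Observed rates are the
    true surface times mean-one lognormal noise with coefficient of
    variation ``noise`` (so the expected observation equals the truth).
    """
    spec = dict(true_model_spec)
    fr_form = spec.get("fr_form", "holling2")
    if fr_form not in _FIT_FR_FORMS:
        raise UsageError(f"experiment fr_form must be one of {_FIT_FR_FORMS}")
    affected = spec.get("affected_parameter", "attack_rate")
    if affected not in _FIT_AFFECTED:
        raise UsageError(f"experiment affected_parameter must be one of {_FIT_AFFECTED}")
    prey = np.asarray(design["prey_levels"], dtype=float)
    mods = np.asarray(design["modifier_levels"], dtype=float)
    reps = int(design["replicates"])
    if mods.size < 2:
        raise UsageError("design needs at least 2 distinct modifier levels to identify a TIM")
    if np.any(prey < 0) or np.any(mods < 0):
        raise UsageError("densities in the design must be >= 0")
    if reps < 1:
        raise UsageError("replicates must be >= 1")
    cv = float(noise)
    if cv < 0:
        raise UsageError("noise CV must be >= 0")
    Rg, Kg = np.meshgrid(prey, mods, indexing="ij")
    R = np.repeat(Rg.ravel(), reps)
    K = np.repeat(Kg.ravel(), reps)
    truth = _surface(
        R, K, spec["attack_rate"], spec.get("handling_time", 0.0), spec["strength"],
        fr_form, spec.get("tim_form", "exponential"), affected, spec.get("form_params", {}),
    )
    rng = np.random.default_rng(seed)
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv**2))
        factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=R.size))
    else:
        factors = np.ones(R.size)
    table = pd.DataFrame(
        {
            "prey_density": R,
            "modifier_density": K,
            "consumption_rate": truth * factors,
        }
    )
    return ExperimentData(
        table=table,
        design={"prey_levels": prey.tolist(), "modifier_levels": mods.tolist(), "replicates": reps},
        true_spec=spec,
        noise_cv=cv,
        seed=int(seed),
    )


@dataclass
class FitResult:
    """Best nonlinear least-squares fit of a TIM functional-response surface."""

    params: dict
    rss: float
    converged: bool
    start_records: list[dict]
    stderr: dict = field(default_factory=dict)
    n_obs: int = 0

    def __getitem__(self, key):
        return self.params[key]


def fit_tim_model(
    data: ExperimentData,
    spec: dict,
    *,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit (attack rate, handling time, TIM strength) to experiment data.

    ``spec`` names the surface to fit: ``fr_form`` (linear | holling2),
    ``tim_form``, ``affected_parameter``, optional fixed ``form_params``.
    Multi-start nonlinear least squares with box bounds (a > 0, h >= 0, c
    unbounded); all start outcomes are reported alongside the best fit.
    Linear functional responses have no handling time to estimate.
    """
    fr_form = spec.get("fr_form", "holling2")
    tim_form = spec.get("tim_form", "exponential")
    affected = spec.get("affected_parameter", "attack_rate")
    form_params = spec.get("form_params", {})
    if fr_form not in _FIT_FR_FORMS:
        raise UsageError(f"fit fr_form must be one of {_FIT_FR_FORMS}")
    if affected not in _FIT_AFFECTED:
        raise UsageError(f"fit affected_parameter must be one of {_FIT_AFFECTED}")
    if fr_form == "linear" and affected == "handling_time":
        raise UsageError("a linear functional response has no handling time to modify")

    tab = data.table if isinstance(data, ExperimentData) else data
    R = tab["prey_density"].to_numpy(dtype=float)
    K = tab["modifier_density"].to_numpy(dtype=float)
    y = tab["consumption_rate"].to_numpy(dtype=float)
    fit_h = fr_form == "holling2"
    names = ["attack_rate"] + (["handling_time"] if fit_h else []) + ["strength"]

    def unpack(theta):
        if fit_h:
            return theta[0], theta[1], theta[2]
        return theta[0], 0.0, theta[1]

    def residuals(theta):
        a, h, c = unpack(theta)
        return _surface(R, K, a, h, c, fr_form, tim_form, affected, form_params) - y

    c_lo = -1.0 + 1e-9 if tim_form == "sigmoid" else -np.inf
    lo = [1e-10] + ([0.0] if fit_h else []) + [c_lo]
    hi = [np.inf] * (2 + fit_h)

    rate_scale = max(np.max(y) / max(np.max(R), 1e-12), 1e-6)
    rng = np.random.default_rng(seed)
    starts = [np.array([rate_scale] + ([0.1] if fit_h else []) + [0.0])]
    for _ in range(max(0, n_starts - 1)):
        a0 = rate_scale * 10.0 ** rng.uniform(-1, 1)
        h0 = 10.0 ** rng.uniform(-2, 0.5)
        c0 = rng.uniform(max(c_lo, -2.0), 2.0)
        starts.append(np.array([a0] + ([h0] if fit_h else []) + [c0]))

    best = None
    records = []
    for x0 in starts:
        try:
            res = scipy.optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception as e:  # noqa: BLE001 - recorded per start
            records.append({"start": x0.tolist(), "success": False, "error": str(e)})
            continue
        rss = float(2 * res.cost)
        records.append({"start": x0.tolist(), "success": bool(res.success), "rss": rss})
        if res.success and (best is None or rss < best[1]):
            best = (res, rss)
    if best is None:
        raise FitError(f"no start converged out of {len(starts)}; records: {records}")
    res, rss = best
    params = {name: float(v) for name, v in zip(names, res.x)}
    stderr = {}
    dof = y.size - res.x.size
    if dof > 0 and rss > 0:
        try:
            JtJ = res.jac.T @ res.jac
            cov = rss / dof * np.linalg.inv(JtJ)
            stderr = {
                name: float(math.sqrt(max(cov[i, i], 0.0))) for i, name in enumerate(names)
            }
        except np.linalg.LinAlgError:
            stderr = {}
    return FitResult(
        params=params,
        rss=rss,
        converged=True,
        start_records=records,
        stderr=stderr,
        n_obs=int(y.size),
    )
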