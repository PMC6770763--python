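"""Initial-concentration assignment from expression data and kinetic
parameter estimation against observed time courses.

Two distinct mappings live here.  First, relative expression levels (e.g.
an RNA-seq cohort summary) seed the *inactive* species' initial
concentrations through a single linear scale factor, with each active
counterpart pinned to zero.  Second, unknown rate constants are estimated
by bounded nonlinear least squares on simulated-vs-observed concentrations
— the kinetic laws are nonlinear in Km, so a literal linear regression
cannot produce them; trust-region-reflective least squares with a numeric
Jacobian is the workhorse, optionally multistarted for multimodal losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.optimize

from .network import NetworkModel
from .ode import SimulationError, SimulationSettings, build_ode_system, simulate

__all__ = [
    "FreeParameter",
    "FitProblem",
    "FitResult",
    "initial_concentrations_from_expression",
    "apply_initial_concentrations",
    "fit_parameters",
]

_HUGE_RESIDUAL = 1e6  # assigned when a candidate's simulation fails


def initial_concentrations_from_expression(
    expression: Mapping[str, float] | pd.Series,
    scale: float,
    mapping: Mapping[str, str],
    model: NetworkModel,
) -> dict[str, float]:
    """Translate relative expression into an initial-concentration assignment.

    ``mapping`` sends gene names to *inactive-state* species ids; each mapped
    species gets ``scale · expression[gene]`` and its active counterpart (if
    any) is assigned zero.  Unmapped species are untouched.  Returns the
    assignment as a dict; apply it with
    :func:`apply_initial_concentrations`.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    expr = dict(expression)
    assignment: dict[str, float] = {}
    for gene, sid in mapping.items():
        if sid not in model.species:
            raise KeyError(f"mapping targets unknown species {sid!r}")
        sp = model.species[sid]
        if sp.activation_state == "active":
            raise ValueError(
                f"mapping may only target inactive-state species, but {sid!r} "
                "is an active form"
            )
        value = expr.get(gene)
        if value is None:
            raise KeyError(f"no expression value for gene {gene!r}")
        if value < 0:
            raise ValueError(f"negative expression for gene {gene!r}")
        assignment[sid] = scale * value
        if sp.counterpart is not None:
            assignment[sp.counterpart] = 0.0
    return assignment


def apply_initial_concentrations(
    model: NetworkModel, assignment: Mapping[str, float]
) -> NetworkModel:
    """Return a copy of the model with the given initial concentrations."""
    out = model.copy()
    for sid, conc in assignment.items():
        out.species[sid].initial_concentration = conc
    return out


@dataclass(frozen=True)
class FreeParameter:
    reaction_id: str
    parameter: str  # k1, k2, Kcat or Km
    lower: float
    upper: float
    guess: float

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ValueError("bounds must satisfy 0 <= lower < upper")
        if not self.lower <= self.guess <= self.upper:
            raise ValueError("initial guess must lie within the bounds")


@dataclass
class FitProblem:
    """Bundle of model, free parameters, observations and solver settings.

    ``observations`` is a tidy table with columns ``species``, ``time``,
    ``value`` and optionally ``weight`` (default 1).  Observation times not
    on the settings grid are matched to the nearest sampled time.
    """

    model: NetworkModel
    free_parameters: list[FreeParameter]
    observations: pd.DataFrame
    settings: SimulationSettings

    def __post_init__(self) -> None:
        required = {"species", "time", "value"}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations lack columns: {sorted(missing)}")
        if "weight" not in self.observations.columns:
            self.observations = self.observations.assign(weight=1.0)
        if not self.free_parameters:
            raise ValueError("no free parameters")
        for fp in self.free_parameters:
            if fp.reaction_id not in self.model.reactions:
                raise KeyError(f"unknown reaction {fp.reaction_id!r}")
        if len(self.observations) < len(self.free_parameters):
            warnings.warn(
                "fewer observations than free parameters; the fit is "
                "under-determined",
                stacklevel=2,
            )


@dataclass
class FitResult:
    estimates: dict[tuple[str, str], float]  # (reaction, parameter) -> value
    rss: float
    success: bool
    n_evaluations: int
    residuals: np.ndarray
    message: str = ""


def _with_parameters(
    model: NetworkModel, free: list[FreeParameter], theta: np.ndarray
) -> NetworkModel:
    out = model.copy()
    for fp, value in zip(free, theta):
        rxn = out.reactions[fp.reaction_id]
        rxn.law = rxn.law.with_parameter(fp.parameter, float(value))
    return out


def fit_parameters(
    problem: FitProblem, multistart: int = 0, seed: int = 0
) -> FitResult:
    """Bounded least-squares estimation of the free kinetic constants.

    Minimizes Σ wᵢ·(simᵢ − obsᵢ)² with scipy's trust-region-reflective
    solver.  A candidate whose simulation fails contributes a huge constant
    residual instead of crashing the optimizer, and non-convergence is
    reported in the result flag rather than raised.  ``multistart > 0`` adds
    that many seeded random restarts within the bounds and keeps the best
    fit.  Deterministic given guess and seed; invariant to observation
    order.
    """
    free = problem.free_parameters
    obs = problem.observations.sort_values(
        ["species", "time"], kind="stable"
    ).reset_index(drop=True)
    times = problem.settings.times()
    time_index = np.abs(
        times[None, :] - obs["time"].to_numpy()[:, None]
    ).argmin(axis=1)
    sqrt_w = np.sqrt(obs["weight"].to_numpy(dtype=float))
    observed = obs["value"].to_numpy(dtype=float)
    species = obs["species"].tolist()

    # fail early on unknown observed species
    _, index = build_ode_system(problem.model)
    for sid in set(species):
        if sid not in index:
            raise KeyError(f"observed species {sid!r} not in model")
    species_rows = [index[s] for s in species]

    def residuals(theta: np.ndarray) -> np.ndarray:
        candidate = _with_parameters(problem.model, free, theta)
        try:
            traj = simulate(candidate, problem.settings)
        except SimulationError:
            return np.full(len(observed), _HUGE_RESIDUAL)
        sim = traj.values[species_rows, time_index]
        return sqrt_w * (sim - observed)

    lower = np.array([fp.lower for fp in free])
    upper = np.array([fp.upper for fp in free])
    starts = [np.array([fp.guess for fp in free])]
    if multistart > 0:
        rng = np.random.default_rng(seed)
        starts += [rng.uniform(lower, upper) for _ in range(multistart)]

    best = None
    n_evaluations = 0
    for x0 in starts:
        sol = scipy.optimize.least_squares(
            residuals, x0, bounds=(lower, upper), method="trf"
        )
        n_evaluations += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    # never return a worse point than the initial guess
    guess_res = residuals(starts[0])
    guess_cost = 0.5 * float(guess_res @ guess_res)
    if best.cost > guess_cost:
        estimates = starts[0]
        final_res, success, message = guess_res, False, "optimizer failed to improve"
    else:
        estimates = best.x
        final_res = best.fun
        success = bool(best.success)
        message = best.message
    return FitResult(
        estimates={
            (fp.reaction_id, fp.parameter): float(v)
            for fp, v in zip(free, estimates)
        },
        rss=float(final_res @ final_res),
        success=success,
        n_evaluations=n_evaluations,
        residuals=final_res,
        message=message,
    )
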