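"""ODE assembly, LSODA time-course simulation, and trajectory summaries.

Each reaction contributes ``±stoichiometry × rate`` to the concentration
derivative of its substrates and products.  Because compartment volumes are
constant, the volume factor on both sides of ``d([X]·V)/dt = ±V·rate``
cancels and the engine integrates concentrations directly — simulations are
therefore invariant to compartment volume.

Integration uses LSODA (via :func:`scipy.integrate.odeint`), the classic
stiff/non-stiff switching solver, with user-controlled relative/absolute
tolerances and a maximum-internal-steps guard.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.optimize

from .network import (
    HMM,
    MASS_ACTION,
    MODIFIED_HMM,
    OPAQUE,
    InvalidModelError,
    NetworkModel,
    validate_network,
)

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "SimulationError",
    "build_ode_system",
    "simulate",
    "auc",
    "find_plateau",
    "steady_state",
    "SteadyStateResult",
]


class SimulationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g} s)")
        self.last_time = last_time


@dataclass
class SimulationSettings:
    """Time-course settings in the solver's vocabulary.

    ``duration`` is in seconds.  Either ``interval_size`` or ``n_intervals``
    may be given; the other is derived as ``duration/interval_size`` rounded
    to the nearest integer.  If all three are supplied and disagree by more
    than 1% a warning is emitted and the count derived from
    ``duration/interval_size`` wins (stated interval counts in published
    settings blocks are occasionally typos).

    ``max_internal_steps`` caps LSODA's internal steps per output interval;
    values this small (≤ 10) virtually guarantee truncated integrations, so
    requesting one triggers a warning.  ``integrate_reduced_model`` is
    accepted for configuration fidelity with COPASI-style settings blocks but
    is a no-op: the full state is always integrated.
    """

    duration: float
    interval_size: float | None = None
    n_intervals: int | None = None
    relative_tolerance: float = 1e-6
    absolute_tolerance: float = 1e-12
    max_internal_steps: int = 100_000
    integrate_reduced_model: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.interval_size is None and self.n_intervals is None:
            self.n_intervals = 100
        if self.interval_size is not None:
            if self.interval_size <= 0:
                raise ValueError("interval_size must be > 0")
            derived = max(1, round(self.duration / self.interval_size))
            if self.n_intervals is not None and self.n_intervals != derived:
                stated = self.interval_size * self.n_intervals
                if abs(stated - self.duration) / self.duration >= 0.01:
                    warnings.warn(
                        f"inconsistent settings: duration {self.duration:g} != "
                        f"interval_size × n_intervals = {stated:g}; using "
                        f"n_intervals = round(duration/interval_size) = {derived}",
                        stacklevel=2,
                    )
                self.n_intervals = derived
            elif self.n_intervals is None:
                self.n_intervals = derived
        if self.n_intervals is not None and self.n_intervals < 1:
            raise ValueError("n_intervals must be a positive integer")
        if self.interval_size is None:
            self.interval_size = self.duration / self.n_intervals
        if self.relative_tolerance <= 0 or self.absolute_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_internal_steps <= 0:
            raise ValueError("max_internal_steps must be positive")
        if self.max_internal_steps <= 10:
            warnings.warn(
                f"max_internal_steps={self.max_internal_steps} is far too small "
                "for LSODA and will likely truncate the integration",
                stacklevel=2,
            )

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_intervals + 1)


@dataclass
class Trajectory:
    """Sampled time course: ``values[i, j]`` is species ``species_order[i]``
    at ``times[j]``.  Concentrations are clipped at zero for reporting;
    pre-clip minima are kept in ``diagnostics['min_value']``."""

    times: np.ndarray
    values: np.ndarray
    species_order: list[str]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.species_order)}

    def concentration(self, species_id: str) -> np.ndarray:
        try:
            return self.values[self._index[species_id]]
        except KeyError:
            raise KeyError(f"species {species_id!r} not in trajectory") from None

    def endpoint(self, species_id: str) -> float:
        return float(self.concentration(species_id)[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide table: one ``time`` column plus one column per species."""
        df = pd.DataFrame(self.values.T, columns=self.species_order)
        df.insert(0, "time", self.times)
        return df


def build_ode_system(
    model: NetworkModel,
) -> tuple[Callable[[float, np.ndarray], np.ndarray], dict[str, int]]:
    """Compile the model into a derivative function and a species index map.

    The returned ``rhs(t, y)`` evaluates every reaction rate at the clamped
    state ``max(y, 0)`` (guarding Michaelis–Menten denominators against
    integrator undershoot) and accumulates signed stoichiometric
    contributions per species.
    """
    violations = validate_network(model)
    if violations:
        raise InvalidModelError(violations)

    index = {sid: i for i, sid in enumerate(model.species)}
    n = len(index)

    # Per reaction: (rate closure over clamped state, [(species index, ±stoich)])
    compiled: list[tuple[Callable[[np.ndarray], float], list[tuple[int, float]]]] = []
    for rxn in model.reactions.values():
        law = rxn.law
        sub_ix = [(index[s], st) for s, st in rxn.substrates]
        prod_ix = [(index[p], st) for p, st in rxn.products]

        if law.variant == MASS_ACTION:
            k1, k2 = law.k1, law.k2

            def rate(y, _sub=sub_ix, _prod=prod_ix, _k1=k1, _k2=k2):
                fwd = _k1 * math.prod(y[i] ** st for i, st in _sub)
                if _k2 is None:
                    return fwd
                return fwd - _k2 * math.prod(y[i] ** st for i, st in _prod)

        elif law.variant == HMM:
            s_ix = sub_ix[0][0]
            e_ix = index[law.enzyme] if law.enzyme else None

            def rate(y, _s=s_ix, _e=e_ix, _kcat=law.Kcat, _km=law.Km):
                e = 1.0 if _e is None else y[_e]
                return _kcat * e * y[_s] / (_km + y[_s])

        elif law.variant == MODIFIED_HMM:
            s_ix = sub_ix[0][0]
            m_ix = index[law.modifier]

            def rate(y, _s=s_ix, _m=m_ix, _kcat=law.Kcat, _km=law.Km):
                return _kcat * y[_m] * y[_s] / (_km + y[_s])

        else:  # OPAQUE: lambdify the stored expression over all species ids
            rate = _compile_opaque(law.expression, law.parameters, index)

        deltas: dict[int, float] = {}
        for i, st in sub_ix:
            deltas[i] = deltas.get(i, 0.0) - st
        for i, st in prod_ix:
            deltas[i] = deltas.get(i, 0.0) + st
        compiled.append((rate, [(i, d) for i, d in deltas.items() if d != 0.0]))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        dy = np.zeros(n)
        for rate, deltas in compiled:
            r = rate(yc)
            for i, d in deltas:
                dy[i] += d * r
        return dy

    return rhs, index


def _compile_opaque(
    expression: str, parameters: dict[str, float], index: dict[str, int]
) -> Callable[[np.ndarray], float]:
    import sympy

    local = {sid: sympy.Symbol(sid) for sid in index}
    local.update({name: sympy.Float(val) for name, val in parameters.items()})
    expr = sympy.sympify(expression, locals=local)
    free = sorted(expr.free_symbols, key=lambda s: s.name)
    unknown = [s.name for s in free if s.name not in index]
    if unknown:
        raise ValueError(
            f"opaque rate expression references unknown symbols: {unknown}"
        )
    fn = sympy.lambdify([local[s.name] for s in free], expr, modules="math")
    ixs = [index[s.name] for s in free]

    def rate(y, _fn=fn, _ixs=ixs):
        return _fn(*(y[i] for i in _ixs))

    return rate


def simulate(model: NetworkModel, settings: SimulationSettings) -> Trajectory:
    """Integrate the model with LSODA and sample at the requested times.

    Deterministic for fixed inputs on one platform.  On integrator failure a
    :class:`SimulationError` is raised carrying the last successful time.
    """
    rhs, index = build_ode_system(model)
    y0 = np.array([model.species[sid].initial_concentration for sid in index])
    times = settings.times()

    with warnings.catch_warnings():
        # failures are converted to SimulationError below; the solver's own
        # warning is redundant noise
        warnings.simplefilter("ignore", scipy.integrate.ODEintWarning)
        y, info = scipy.integrate.odeint(
            rhs,
            y0,
            times,
            rtol=settings.relative_tolerance,
            atol=settings.absolute_tolerance,
            mxstep=settings.max_internal_steps,
            tfirst=True,
            full_output=True,
            printmessg=False,
        )
    message = info.get("message", "")
    if message != "Integration successful.":
        tcur = info.get("tcur")
        last = float(tcur[-1]) if tcur is not None and len(tcur) else 0.0
        raise SimulationError(f"LSODA failed: {message}", last_time=last)

    values = y.T
    diagnostics = {
        "solver": "LSODA",
        "min_value": float(values.min()),
        "n_steps": int(info["nst"][-1]),
        "n_rhs_evaluations": int(info["nfe"][-1]),
    }
    floor = -settings.absolute_tolerance * 10
    if values.min() < floor:
        warnings.warn(
            f"trajectory dipped to {values.min():g}, below the tolerance floor "
            f"{floor:g}; results may be inaccurate",
            stacklevel=2,
        )
    return Trajectory(
        times=times,
        values=np.clip(values, 0.0, None),
        species_order=list(index),
        diagnostics=diagnostics,
    )


def auc(traj: Trajectory, species_id: str) -> float:
    """Trapezoidal area under a species' concentration curve (conc·time)."""
    return float(np.trapezoid(traj.concentration(species_id), traj.times))


def find_plateau(
    traj: Trajectory, species_id: str, rel_slope_threshold: float = 0.01
) -> float | None:
    """Earliest sampled time after which the curve stays flat.

    Flat means every subsequent finite-difference slope has magnitude at most
    ``rel_slope_threshold`` times the trajectory's maximum slope magnitude.
    Returns ``None`` when the curve never settles (e.g. sustained linear
    growth).  Requires at least three time points.
    """
    if len(traj.times) < 3:
        raise ValueError("plateau detection requires at least 3 time points")
    c = traj.concentration(species_id)
    slopes = np.diff(c) / np.diff(traj.times)
    max_slope = float(np.abs(slopes).max())
    if max_slope == 0.0:
        return float(traj.times[0])
    ok = np.abs(slopes) <= rel_slope_threshold * max_slope
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return float(traj.times[0])
    last_bad = int(bad[-1])
    if last_bad == len(slopes) - 1:
        return None
    return float(traj.times[last_bad + 1])


@dataclass
class SteadyStateResult:
    """Outcome of a steady-state search.  Failure is a first-class result —
    sufficiently complex networks may simply not settle within the horizon."""

    success: bool
    state: dict[str, float] | None
    residual: float
    method: str
    message: str = ""


def steady_state(
    model: NetworkModel, max_time: float = 1e6, tolerance: float = 1e-9
) -> SteadyStateResult:
    """Find a state where every derivative magnitude is ≤ ``tolerance``.

    Strategy: damped-Newton root search applied as a *polish* step — first on
    the initial state when it is already near a fixed point, otherwise on the
    endpoint of an integration out to ``max_time``.  Polishing rather than
    searching from scratch keeps the answer on the steady-state branch that
    is actually reachable from the initial condition: conservation relations
    make the root set a continuum, and a free Newton search may land on a
    member the dynamics never visit.  Failure is a first-class outcome.
    """
    rhs, index = build_ode_system(model)
    y0 = np.array([model.species[sid].initial_concentration for sid in index])
    # sink species are pure accumulators: their inflow never vanishes and
    # does not disqualify a steady state of the live species
    live = np.array([model.species[sid].role != "sink" for sid in index])

    def residual_vector(y: np.ndarray) -> np.ndarray:
        return rhs(0.0, y)[live]

    def as_result(y: np.ndarray, method: str) -> SteadyStateResult | None:
        res = float(np.abs(residual_vector(y)).max())
        if res <= tolerance and (y >= -tolerance).all():
            state = {sid: max(float(y[i]), 0.0) for sid, i in index.items()}
            return SteadyStateResult(True, state, res, method)
        return None

    def polish(y: np.ndarray, method: str) -> SteadyStateResult | None:
        # damped Gauss-Newton on ||rhs||²; tolerant of the singular Jacobians
        # that conservation relations produce
        sol = scipy.optimize.least_squares(
            lambda v: residual_vector(v), np.maximum(y, 0.0),
            bounds=(0.0, np.inf), xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        return as_result(sol.x, method)

    found = as_result(y0, "initial-state") or (
        polish(y0, "newton")
        if float(np.abs(residual_vector(y0)).max()) <= 1e3 * tolerance
        else None
    )
    if found:
        return found

    settings = SimulationSettings(
        duration=max_time, n_intervals=200, absolute_tolerance=min(tolerance, 1e-12)
    )
    try:
        traj = simulate(model, settings)
    except SimulationError as exc:
        return SteadyStateResult(
            False, None, math.inf, "integration", f"integration failed: {exc}"
        )
    y_end = traj.values[:, -1]
    found = as_result(y_end, "integration") or polish(y_end, "integration+newton")
    if found:
        return found
    res = float(np.abs(residual_vector(y_end)).max())
    return SteadyStateResult(
        False,
        None,
        res,
        "integration",
        f"no steady state within t={max_time:g} s (max |dC/dt| = {res:g})",
    )
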