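"""Stiff ODE integration of a network under a stimulation protocol.

The system is autonomous within each protocol segment (the MHC input is
piecewise constant), so a trajectory is assembled by integrating segment by
segment with LSODA, which avoids stepping over pulse edges. All simulations
start from the model's pre-stimulus steady state (baseline), found by
integrating the zero-input system to quiescence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from ._codegen import compile_jac, compile_rhs
from .network import NetworkModel
from .parameters import ParameterSet
from .stimulation import StimulusProtocol

RTOL_DEFAULT = 1e-6
ATOL_DEFAULT = 1e-9
_MIN_PER_H = 60.0
_MXSTEP = 50_000  # hard cap on internal LSODA steps per segment


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_time_h: float | None = None, last_state=None):
        super().__init__(message)
        self.last_time_h = last_time_h
        self.last_state = last_state


class _EvalBudgetExceeded(Exception):
    """Internal: integration exceeded its right-hand-side evaluation budget."""


def _with_budget(rhs, jac, max_work_units, n_state):
    """Wrap the RHS (1 unit/call) and Jacobian (n_state units/call) with a
    shared hard work budget.

    Randomly sampled parameter sets can make the system so stiff that the
    integrator grinds indefinitely; the budget turns such runs into ordinary
    failures the sampling analyses count and move past. Charging Jacobian
    updates at the cost of their internal differencing keeps jac-heavy
    grinding under the same cap.
    """
    if max_work_units is None:
        return rhs, jac
    counter = {"n": 0}

    def guarded(t, y, p, u):
        counter["n"] += 1
        if counter["n"] > max_work_units:
            raise _EvalBudgetExceeded
        return rhs(t, y, p, u)

    if jac is None:
        return guarded, None

    def guarded_jac(t, y, p, u):
        counter["n"] += n_state
        if counter["n"] > max_work_units:
            raise _EvalBudgetExceeded
        return jac(t, y, p, u)

    return guarded, guarded_jac


class BaselineError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class Trajectory:
    """Simulated time courses for all species on a time grid (hours, nM)."""

    time_h: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species_names: tuple[str, ...]
    protocol: StimulusProtocol
    params: ParameterSet
    baseline: np.ndarray  # pre-stimulus steady state

    def series(self, species: str) -> np.ndarray:
        try:
            i = self.species_names.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None
        return self.states[:, i]

    def baseline_of(self, species: str) -> float:
        return float(self.baseline[self.species_names.index(species)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with columns time_h, species, value."""
        n_t = len(self.time_h)
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.time_h, len(self.species_names)),
                "species": list(self.species_names) * n_t,
                "value": self.states.ravel(),
            }
        )


def default_grid(protocol: StimulusProtocol) -> np.ndarray:
    """Output grid: 1-min spacing for 2 h after each pulse, 10-min elsewhere."""
    pts = [np.array([0.0, protocol.horizon])]
    pts.append(np.arange(0.0, protocol.horizon + 1e-9, 10.0 / 60.0))
    for p in protocol.pulses:
        hi = min(p.start + 2.0, protocol.horizon)
        pts.append(np.arange(p.start, hi + 1e-9, 1.0 / 60.0))
    grid = np.unique(np.concatenate(pts))
    return grid[(grid >= 0) & (grid <= protocol.horizon + 1e-9)]


def find_baseline(
    model: NetworkModel,
    params: ParameterSet,
    t_settle_h: float = 4000.0,
    tol: float = 1e-7,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    max_rhs_evals: int | None = None,
) -> np.ndarray:
    """Pre-stimulus steady state of the zero-input system.

    Integrates from the declared initial values until the right-hand side
    norm falls below ``tol`` (nM/min); raises :class:`BaselineError` with the
    residual if the zero-input system is not stationary.
    """
    rhs = compile_rhs(model)
    guarded, gjac = _with_budget(rhs, compile_jac(model), max_rhs_evals,
                                 len(model.species))
    p = params.as_array(model.parameter_names)
    y = model.initial_state()
    t_end = t_settle_h * _MIN_PER_H
    for t_stop in (t_end, 4 * t_end):
        try:
            out, info = odeint(guarded, y, [0.0, t_stop], args=(p, 0.0), tfirst=True,
                               Dfun=gjac, rtol=rtol, atol=atol, mxstep=_MXSTEP,
                               full_output=True)
        except _EvalBudgetExceeded:
            raise BaselineError("zero-input integration exceeded its work budget", np.inf)
        if info["message"] != "Integration successful.":
            raise BaselineError(f"zero-input integration failed: {info['message']}", np.inf)
        y = out[-1]
        if not np.all(np.isfinite(y)):
            raise BaselineError("zero-input integration diverged", np.inf)
        resid = float(np.max(np.abs(rhs(0.0, y, p, 0.0))))
        if resid < tol:
            return np.maximum(y, 0.0)
    raise BaselineError(
        f"no steady state within iteration cap (residual {resid:.3g} nM/min)", resid
    )


def simulate(
    model: NetworkModel,
    params: ParameterSet,
    protocol: StimulusProtocol,
    grid: np.ndarray | None = None,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    baseline: np.ndarray | None = None,
    max_rhs_evals: int | None = None,
) -> Trajectory:
    """Integrate the model under ``protocol`` and sample on ``grid`` (hours).

    Deterministic given inputs. Raises :class:`SimulationError` carrying the
    last successful time and state if the integrator fails.
    """
    missing = [n for n in model.parameter_names if n not in params]
    if missing:
        raise KeyError(f"parameter set incomplete for {model.name!r}: missing {missing}")
    if grid is None:
        grid = default_grid(protocol)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 0 or grid[-1] > protocol.horizon + 1e-9 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing within [0, horizon]")

    rhs, jac = _with_budget(compile_rhs(model), compile_jac(model), max_rhs_evals,
                            len(model.species))
    p = params.as_array(model.parameter_names)
    if baseline is None:
        baseline = find_baseline(
            model, params, rtol=rtol, atol=atol,
            # the settling run is much cheaper than the driven one; give it
            # a third of the work budget so pathological draws fail fast
            max_rhs_evals=None if max_rhs_evals is None else max(max_rhs_evals // 3, 1),
        )
    y = baseline.copy()
    if protocol.cni_dose > 0:
        if "CnI" not in model.species_names:
            raise KeyError(f"model {model.name!r} has no CnI species")
        y[model.species_index("CnI")] = protocol.cni_dose

    edges = protocol.segment_edges()
    out = np.empty((len(grid), len(y)))
    if grid[0] == 0.0:
        out[0] = y
        filled = 1
    else:
        filled = 0
    for lo, hi in zip(edges, edges[1:]):
        u = protocol.amplitude_at(lo)
        mask = (grid > lo + 1e-12) & (grid <= hi + 1e-12)
        pts = grid[mask] * _MIN_PER_H
        need_hi = len(pts) == 0 or abs(pts[-1] - hi * _MIN_PER_H) > 1e-9
        ts = np.concatenate([[lo * _MIN_PER_H], pts,
                             [hi * _MIN_PER_H] if need_hi else []])
        try:
            seg, info = odeint(rhs, y, ts, args=(p, u), tfirst=True, Dfun=jac,
                               rtol=rtol, atol=atol, mxstep=_MXSTEP, full_output=True)
        except _EvalBudgetExceeded:
            raise SimulationError(
                f"integration exceeded its work budget in segment [{lo}, {hi}] h",
                last_time_h=lo, last_state=y,
            ) from None
        if info["message"] != "Integration successful.":
            raise SimulationError(
                f"integration failed in segment [{lo}, {hi}] h: {info['message']}",
                last_time_h=lo,
                last_state=y,
            )
        if len(pts):
            out[filled : filled + len(pts)] = seg[1 : 1 + len(pts)]
            filled += len(pts)
        y = seg[-1]
    assert filled == len(grid)
    return Trajectory(
        time_h=grid,
        states=out,
        species_names=model.species_names,
        protocol=protocol,
        params=params,
        baseline=baseline,
    )
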