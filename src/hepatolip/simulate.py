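"""Integration of the model through dose events and steady-state analysis.

Time is expressed in hours at every public interface (matching figure axes)
and in seconds internally (matching rate-constant units); the conversion is
centralized in :data:`SECONDS_PER_HOUR`.

The integrator is restarted at every event boundary so discontinuities never
cross a solver step: boluses are applied between segments, influx windows
change the constant source vector per segment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import DoseEvent, active_sources, apply_bolus, event_boundaries
from .model import (
    Sources,
    dimensionalize,  # noqa: F401  (re-exported convenience)
    nondimensionalize,
    rhs_dimensionless,
    state_scales,
)
from .params import DimensionalParameters
from .states import (
    DRUG_NAMES,
    N_STATES,
    PCSK9_NAMES,
    SHARED_WITH_REDUCED,
    STATE_INDEX,
    STATE_NAMES,
    state_from_dict,
    validate_state,
)

__all__ = [
    "SECONDS_PER_HOUR",
    "Scenario",
    "SimulationResult",
    "SteadyState",
    "SimulationError",
    "integrate",
    "integrate_fixed_step",
    "find_steady_state",
    "compare_with_reduced_model",
]

SECONDS_PER_HOUR = 3600.0

#: Negative excursions larger than this multiple of atol are hard errors;
#: smaller ones are round-off and are clipped to zero.
_NEG_TOL_FACTOR = 1e3


class SimulationError(RuntimeError):
    """Solver failure, negative excursion beyond tolerance, or bad scenario."""


@dataclass(frozen=True)
class Scenario:
    """Parameters + initial state + events + horizon: the unit of simulation.

    ``y0`` is the dimensionless initial state (before any t = 0 boluses).
    Use :meth:`from_concentrations` to build it from dimensional
    concentrations in molec./mL.
    """

    params: DimensionalParameters
    y0: np.ndarray
    events: tuple[DoseEvent, ...] = ()
    horizon_h: float = 200.0
    output_step_h: float = 0.5
    output_times_h: tuple[float, ...] | None = None
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    max_step_s: float = np.inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "y0", validate_state(self.y0))
        object.__setattr__(self, "events", tuple(self.events))
        if not (self.horizon_h > 0):
            raise SimulationError(f"horizon must be positive, got {self.horizon_h!r}")
        for e in self.events:
            if e.time_h > self.horizon_h:
                raise SimulationError(
                    f"event at {e.time_h} h lies beyond the {self.horizon_h} h horizon"
                )
        if self.output_times_h is None and not (self.output_step_h > 0):
            raise SimulationError("output_step_h must be positive")

    @classmethod
    def from_concentrations(
        cls,
        params: DimensionalParameters,
        concentrations: Mapping[str, float] | None = None,
        **kwargs,
    ) -> "Scenario":
        """Build a scenario from dimensional initial concentrations (molec./mL).

        Unlisted components start at zero (the in vitro default: fresh medium
        plus whatever the protocol adds).
        """
        y_bar = state_from_dict(concentrations or {})
        y0 = y_bar / state_scales(params.scales)
        return cls(params=params, y0=y0, **kwargs)

    def replace(self, **kwargs) -> "Scenario":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)

    def output_grid_h(self) -> np.ndarray:
        if self.output_times_h is not None:
            grid = np.asarray(self.output_times_h, dtype=float)
            if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
                raise SimulationError("output_times_h must be strictly increasing")
            if grid[0] < 0 or grid[-1] > self.horizon_h:
                raise SimulationError("output_times_h must lie within [0, horizon]")
            return grid
        n = int(round(self.horizon_h / self.output_step_h))
        return np.linspace(0.0, n * self.output_step_h, n + 1)

    def config_hash(self) -> str:
        """Stable hash of everything that determines the trajectory."""
        payload = repr((self.params, tuple(self.y0), self.events, self.horizon_h,
                        self.output_step_h, self.output_times_h, self.method,
                        self.rtol, self.atol, self.max_step_s))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Trajectory on the output grid plus event log and solver diagnostics."""

    time_h: np.ndarray
    y: np.ndarray  # (n_times, 21), dimensionless
    scenario: Scenario
    event_log: list[dict] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def component(self, name: str) -> np.ndarray:
        return self.y[:, STATE_INDEX[name]]

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1].copy()

    def to_frame(self, dimensional: bool = False) -> pd.DataFrame:
        data = self.y * state_scales(self.scenario.params.scales) if dimensional else self.y
        df = pd.DataFrame(data, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.time_h)
        return df

    def write_csv(self, path) -> None:
        self.to_frame(dimensional=True).to_csv(path, index=False, float_format="%.12g")


@dataclass
class SteadyState:
    """A fixed point of the system with residual and stability information.

    ``stable`` reports whether every Jacobian eigenvalue outside the neutral
    subspace spanned by the drug conservation laws (total antibody, total
    statin are conserved when their sources are off, giving structurally zero
    eigenvalues) has negative real part.
    """

    state: np.ndarray
    residual: float
    stable: bool
    n_neutral_modes: int = 0
    basin_checked: int = 0
    t_reached_h: float = float("nan")
    method: str = "long_run"

    def component(self, name: str) -> float:
        return float(self.state[STATE_INDEX[name]])


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _check_negatives(y: np.ndarray, atol: float, where: str) -> np.ndarray:
    floor = -_NEG_TOL_FACTOR * atol
    if np.any(y < floor):
        idx = int(np.argmin(y))
        name = STATE_NAMES[idx % N_STATES] if y.ndim == 1 else STATE_NAMES[
            int(np.unravel_index(np.argmin(y), y.shape)[1])
        ]
        raise SimulationError(
            f"negative excursion beyond tolerance in component {name!r} ({where}): "
            f"min value {y.min():.3e}"
        )
    return np.maximum(y, 0.0)


def integrate(s: Scenario) -> SimulationResult:
    """Integrate the scenario over [0, horizon] with event handling.

    Returns the trajectory on the output grid; the first row is the initial
    state after application of any t = 0 boluses.  Deterministic for a fixed
    scenario.
    """
    p = nondimensionalize(s.params)
    scales = s.params.scales
    grid_h = s.output_grid_h()
    boundaries_h = [0.0] + event_boundaries(list(s.events), s.horizon_h) + [s.horizon_h]

    y = s.y0.copy()
    event_log: list[dict] = []
    nfev = 0
    n_segments = 0
    out = np.empty((len(grid_h), N_STATES))
    filled = np.zeros(len(grid_h), dtype=bool)

    for seg_i in range(len(boundaries_h) - 1):
        t0_h, t1_h = boundaries_h[seg_i], boundaries_h[seg_i + 1]
        # apply boluses scheduled at the segment start
        for e in s.events:
            if e.mode == "bolus" and e.time_h == t0_h:
                pre = y.copy()
                y = apply_bolus(y, e, scales)
                event_log.append({
                    "time_h": t0_h, "species": e.species, "mode": "bolus",
                    "amount": e.amount,
                    "pre": pre.copy(), "post": y.copy(),
                })
        src = active_sources(t0_h, list(s.events), scales)
        if src != Sources() and seg_i < len(boundaries_h) - 1:
            event_log.append({
                "time_h": t0_h, "mode": "influx_window",
                "sources": src, "until_h": t1_h,
            })

        # output points inside [t0, t1); t1 itself belongs to the next
        # segment (post-event state), except at the final horizon
        last = seg_i == len(boundaries_h) - 2
        mask = (grid_h >= t0_h) & ((grid_h < t1_h) | (last & np.isclose(grid_h, t1_h)))
        pts_h = grid_h[mask]

        t_eval_s = np.unique(np.concatenate([pts_h, [t1_h]])) * SECONDS_PER_HOUR

        def fun(t, yv, _p=p, _src=src):
            return rhs_dimensionless(t, np.maximum(yv, 0.0), _p, _src, validate=False)

        sol = solve_ivp(
            fun,
            (t0_h * SECONDS_PER_HOUR, t1_h * SECONDS_PER_HOUR),
            y,
            method=s.method,
            rtol=s.rtol,
            atol=s.atol,
            max_step=s.max_step_s,
            t_eval=t_eval_s,
        )
        nfev += sol.nfev
        n_segments += 1
        if not sol.success:
            raise SimulationError(
                f"solver failed in segment [{t0_h}, {t1_h}] h: {sol.message}; "
                f"last state at t = {sol.t[-1] / SECONDS_PER_HOUR:.4g} h"
            )
        seg_y = _check_negatives(sol.y.T, s.atol, f"segment [{t0_h}, {t1_h}] h")
        # distribute output rows
        for t_s, row in zip(sol.t, seg_y):
            t_h = t_s / SECONDS_PER_HOUR
            hit = mask & np.isclose(grid_h, t_h, rtol=0, atol=1e-9)
            if hit.any():
                out[hit] = row
                filled |= hit
        y = seg_y[-1]

    if not filled.all():
        missing = grid_h[~filled]
        raise SimulationError(f"output grid points not produced: {missing[:5]}")

    return SimulationResult(
        time_h=grid_h,
        y=out,
        scenario=s,
        event_log=event_log,
        diagnostics={
            "nfev": int(nfev),
            "n_segments": n_segments,
            "method": s.method,
            "rtol": s.rtol,
            "atol": s.atol,
            "config_hash": s.config_hash(),
        },
    )


def integrate_fixed_step(s: Scenario, step_h: float = 1e-3) -> SimulationResult:
    """Explicit fixed-step RK4 integration (dual-integrator oracle).

    Slow and non-stiff-safe by design; used to cross-check the adaptive
    integrator on drug-free scenarios.
    """
    p = nondimensionalize(s.params)
    scales = s.params.scales
    grid_h = s.output_grid_h()
    boundaries_h = [0.0] + event_boundaries(list(s.events), s.horizon_h) + [s.horizon_h]
    dt = step_h * SECONDS_PER_HOUR

    y = s.y0.copy()
    out = np.empty((len(grid_h), N_STATES))
    out_i = 0
    nfev = 0

    def push(t_h: float, yv: np.ndarray) -> None:
        nonlocal out_i
        while out_i < len(grid_h) and grid_h[out_i] <= t_h + 1e-12:
            out[out_i] = np.maximum(yv, 0.0)
            out_i += 1

    for seg_i in range(len(boundaries_h) - 1):
        t0_h, t1_h = boundaries_h[seg_i], boundaries_h[seg_i + 1]
        for e in s.events:
            if e.mode == "bolus" and e.time_h == t0_h:
                y = apply_bolus(y, e, scales)
        src = active_sources(t0_h, list(s.events), scales)
        n_steps = max(1, int(np.ceil((t1_h - t0_h) * SECONDS_PER_HOUR / dt)))
        h_s = (t1_h - t0_h) * SECONDS_PER_HOUR / n_steps
        t_s = t0_h * SECONDS_PER_HOUR
        push(t0_h, y)
        for _ in range(n_steps):
            k1 = rhs_dimensionless(t_s, np.maximum(y, 0), p, src, validate=False)
            k2 = rhs_dimensionless(t_s + h_s / 2, np.maximum(y + h_s / 2 * k1, 0), p, src, validate=False)
            k3 = rhs_dimensionless(t_s + h_s / 2, np.maximum(y + h_s / 2 * k2, 0), p, src, validate=False)
            k4 = rhs_dimensionless(t_s + h_s, np.maximum(y + h_s * k3, 0), p, src, validate=False)
            y = y + h_s / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t_s += h_s
            nfev += 4
            push(t_s / SECONDS_PER_HOUR, y)

    push(s.horizon_h + 1.0, y)  # flush any trailing grid point
    return SimulationResult(
        time_h=grid_h,
        y=_check_negatives(out, s.atol, "fixed-step trajectory"),
        scenario=s,
        diagnostics={"nfev": nfev, "method": "RK4-fixed", "step_h": step_h},
    )


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _constant_sources(s: Scenario) -> Sources:
    pending = [e for e in s.events if e.mode == "influx"]
    if pending:
        raise SimulationError(
            "steady-state analysis requires constant sources; scenario has "
            f"{len(pending)} finite-duration influx event(s)"
        )
    return Sources()


def _initial_with_boluses(s: Scenario) -> np.ndarray:
    y = s.y0.copy()
    for e in s.events:
        if e.mode == "bolus":
            if e.time_h != 0.0:
                raise SimulationError(
                    "steady-state analysis only supports t = 0 boluses"
                )
            y = apply_bolus(y, e, s.params.scales)
    return y


def numerical_jacobian(fun, y: np.ndarray, rel_step: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` at ``y``."""
    n = len(y)
    jac = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), 1e-3)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] = max(ym[j] - h, 0.0)
        denom = yp[j] - ym[j]
        jac[:, j] = (fun(yp) - fun(ym)) / denom
    return jac


def _stability(fun, y: np.ndarray, zero_tol: float = 1e-12) -> tuple[bool, int]:
    jac = numerical_jacobian(fun, y)
    eig = np.linalg.eigvals(jac)
    neutral = np.abs(eig) < zero_tol
    stable = bool(np.all(eig.real[~neutral] < 0))
    return stable, int(neutral.sum())


def find_steady_state(
    s: Scenario,
    method: Literal["long_run", "root"] = "long_run",
    *,
    residual_tol: float = 1e-10,
    window_h: float = 250.0,
    max_horizon_h: float = 30000.0,
) -> SteadyState:
    """Locate the fixed point reached from the scenario's initial state.

    ``long_run`` integrates in windows until the RHS max-norm falls below
    ``residual_tol``; ``root`` polishes the long-run endpoint with a damped
    Newton/hybrid root finder (rejecting any polish that drifts the conserved
    drug totals, which would leave the dynamically reachable manifold).
    """
    p = nondimensionalize(s.params)
    src = _constant_sources(s)
    y = _initial_with_boluses(s)

    def f(yv: np.ndarray) -> np.ndarray:
        return rhs_dimensionless(0.0, np.maximum(yv, 0.0), p, src, validate=False)

    coarse_tol = residual_tol if method == "long_run" else max(residual_tol, 1e-8)
    t_h = 0.0
    residual = float(np.max(np.abs(f(y))))
    while residual > coarse_tol:
        if t_h >= max_horizon_h:
            raise SimulationError(
                f"steady state not reached within {max_horizon_h} h; "
                f"last residual {residual:.3e}"
            )
        sol = solve_ivp(
            lambda t, yv: f(yv),
            (0.0, window_h * SECONDS_PER_HOUR),
            y,
            method=s.method,
            rtol=s.rtol,
            atol=s.atol,
        )
        if not sol.success:
            raise SimulationError(f"solver failure during long run: {sol.message}")
        y = np.maximum(sol.y[:, -1], 0.0)
        t_h += window_h
        residual = float(np.max(np.abs(f(y))))

    if method == "root":
        from scipy.optimize import root

        conserved_before = _drug_totals(y, p.W)
        sol_root = root(f, y, method="hybr", tol=1e-14)
        y_pol = np.maximum(sol_root.x, 0.0)
        pol_res = float(np.max(np.abs(f(y_pol))))
        drift = np.abs(_drug_totals(y_pol, p.W) - conserved_before)
        ok_drift = np.all(drift <= 1e-8 * (1.0 + np.abs(conserved_before)))
        if sol_root.success and pol_res < residual and ok_drift:
            y, residual = y_pol, pol_res
        # the conserved drug totals make the Jacobian singular, which can
        # stall the hybrid solver; finish by integration in that case
        while residual > residual_tol:
            if t_h >= max_horizon_h:
                raise SimulationError(
                    f"root polish did not reach residual tolerance: {residual:.3e}"
                )
            sol = solve_ivp(
                lambda t, yv: f(yv),
                (0.0, window_h * SECONDS_PER_HOUR),
                y,
                method=s.method, rtol=s.rtol, atol=s.atol,
            )
            if not sol.success:
                raise SimulationError(f"solver failure during polish: {sol.message}")
            y = np.maximum(sol.y[:, -1], 0.0)
            t_h += window_h
            residual = float(np.max(np.abs(f(y))))

    stable, n_neutral = _stability(f, y)
    return SteadyState(
        state=y,
        residual=residual,
        stable=stable,
        n_neutral_modes=n_neutral,
        t_reached_h=t_h,
        method=method,
    )


def _drug_totals(y: np.ndarray, W: float) -> np.ndarray:
    """Conserved totals: W*A_E + p_AB and W*S_E + S_i + S_ih."""
    i = STATE_INDEX
    return np.array([
        W * y[i["A_E"]] + y[i["p_AB"]],
        W * y[i["S_E"]] + y[i["S_i"]] + y[i["S_ih"]],
    ])


def quasi_steady_state(
    s: Scenario,
    *,
    settle_h: float = 500.0,
    residual_tol: float = 1e-10,
) -> SteadyState:
    """Readout state for therapy metrics: a true steady state if one is
    detected before ``settle_h``, otherwise the state at ``settle_h``."""
    only_t0_boluses = all(e.mode == "bolus" and e.time_h == 0.0 for e in s.events)
    if only_t0_boluses:
        try:
            return find_steady_state(
                s, residual_tol=residual_tol, max_horizon_h=settle_h
            )
        except SimulationError:
            pass
    run = integrate(s.replace(horizon_h=settle_h, output_times_h=(0.0, settle_h)))
    y = run.final_state
    p = nondimensionalize(s.params)
    residual = float(np.max(np.abs(
        rhs_dimensionless(0.0, y, p, Sources(), validate=False)
    )))
    return SteadyState(state=y, residual=residual, stable=False,
                       t_reached_h=settle_h, method="settle_h")


def multistart_convergence(
    s: Scenario,
    n_starts: int = 20,
    *,
    seed: int = 0,
    spread: float = 10.0,
    rtol_match: float = 1e-4,
) -> tuple[SteadyState, int]:
    """Basin check: perturb the reference fixed point by random factors in
    [1/spread, spread] on the non-drug components and count how many starts
    converge back to it within ``rtol_match`` relative."""
    ref = find_steady_state(s, residual_tol=1e-10)
    rng = np.random.default_rng(seed)
    drug_idx = [STATE_INDEX[n] for n in DRUG_NAMES]
    n_conv = 0
    for _ in range(n_starts):
        factors = spread ** rng.uniform(-1.0, 1.0, N_STATES)
        y0 = ref.state * factors
        y0[drug_idx] = s.y0[drug_idx]
        ss = find_steady_state(s.replace(y0=y0), residual_tol=1e-10)
        denom = np.maximum(np.abs(ref.state), 1e-30)
        rel = np.abs(ss.state - ref.state) / denom
        mask = np.abs(ref.state) > 1e-20  # compare only meaningfully nonzero
        if np.max(rel[mask]) < rtol_match:
            n_conv += 1
    ref.basin_checked = n_conv
    return ref, n_conv


# ---------------------------------------------------------------------------
# reduced-model comparison
# ---------------------------------------------------------------------------

def reduced_scenario(s: Scenario) -> Scenario:
    """The PCSK9-disabled variant: transcription, binding and initial pools of
    the PCSK9 pathway are all switched off."""
    params = s.params.with_overrides(mu_mp_star=0.0, omega_P=0.0, alpha_p=0.0)
    y0 = s.y0.copy()
    for name in PCSK9_NAMES:
        y0[STATE_INDEX[name]] = 0.0
    events = tuple(e for e in s.events if e.species != "PCSK9_E")
    return s.replace(params=params, y0=y0, events=events)


def compare_with_reduced_model(s: Scenario) -> dict[str, float]:
    """Per-component max relative deviation between the full model and the
    PCSK9-disabled reduction on the shared (non-PCSK9, non-drug) variables.

    Deviation for a component is max_t |full - reduced| normalised by the
    reduced trajectory's max magnitude (0 for identically-zero components).
    """
    full = integrate(s)
    red = integrate(reduced_scenario(s))
    devs: dict[str, float] = {}
    for name in SHARED_WITH_REDUCED:
        a = full.component(name)
        b = red.component(name)
        scale = float(np.max(np.abs(b)))
        devs[name] = float(np.max(np.abs(a - b)) / scale) if scale > 0 else (
            float(np.max(np.abs(a)))
        )
    return devs
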