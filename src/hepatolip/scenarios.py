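"""Preset in-silico experiments and therapy-comparison analyses.

Each builder reproduces one of the published qualitative experiments:
baseline kinetics with extracellular PCSK9, the PCSK9 concentration sweep and
timed pulse, single-dose statin therapy, anti-PCSK9 antibody / small-molecule
therapy at high PCSK9, and combined therapy.  All quantities reported by the
metric helpers are dimensional (molec./mL, hours).

"Steady-state" readouts for therapy metrics are taken at a settle horizon
(500 h by default, the state there being numerically stationary for every
preset); time-resolved metrics are computed from paired treated/untreated
trajectories on a shared output grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dosing import DoseEvent
from .model import state_scales
from .params import DimensionalParameters, default_parameters
from .simulate import (
    Scenario,
    SimulationError,
    SimulationResult,
    integrate,
)
from .states import STATE_INDEX

__all__ = [
    "TherapyMetrics",
    "SweepSpec",
    "ThresholdScan",
    "MatchedRecyclingPair",
    "baseline_scenario",
    "pcsk9_pulse_scenario",
    "pcsk9_threshold_scan",
    "statin_scenario",
    "anti_pcsk9_scenario",
    "combined_therapy_scenario",
    "recycling_fraction_comparison",
    "run_sweep",
    "DEFAULT_STATIN_DOSE",
    "DEFAULT_ANTIBODY_DOSE",
    "DEFAULT_SETTLE_H",
]

#: Assumed default doses (molec./mL); the printed protocols do not state
#: magnitudes, so these are exposed and overridable everywhere.
DEFAULT_STATIN_DOSE = 5e15
DEFAULT_ANTIBODY_DOSE = 3e14

DEFAULT_SETTLE_H = 500.0

#: Small-molecule kinetics relative to antibody defaults: larger association
#: rate and smaller dissociation rate.
SMALL_MOLECULE_ON_FACTOR = 10.0
SMALL_MOLECULE_OFF_FACTOR = 10.0


@dataclass(frozen=True)
class TherapyMetrics:
    """Steady-state lipoprotein readouts of one treatment arm vs baseline."""

    ldl_ss: float               # molec./mL, extracellular LDL at readout
    vldl_ss: float              # molec./mL, extracellular VLDL at readout
    pct_ldl_reduction: float    # 100 * (1 - treated/untreated), <= 100
    pct_vldl_reduction: float
    t_half_ldl_h: float         # first time the LDL deficit reaches half its max


@dataclass(frozen=True)
class SweepSpec:
    """A one-dimensional sweep of a parameter or initial concentration."""

    name: str
    values: tuple[float, ...]
    kind: str = "initial"       # "initial" (state name) or "parameter"
    metric: str = "l_E"
    settle_h: float = DEFAULT_SETTLE_H

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("sweep values must be finite and non-negative")
        if self.kind not in ("initial", "parameter"):
            raise ValueError(f"unknown sweep kind {self.kind!r}")


@dataclass(frozen=True)
class ThresholdScan:
    """Result of the PCSK9 concentration scan."""

    threshold: float | None          # smallest qualifying concentration, or None
    curve: tuple[tuple[float, float], ...]  # (p_E0, steady LDL) pairs, molec./mL
    baseline_ldl: float              # PCSK9-free steady LDL, molec./mL
    elevation_frac: float


@dataclass(frozen=True)
class MatchedRecyclingPair:
    """A PCSK9 concentration and the recycling fraction mimicking it."""

    p_E0: float
    f_matched: float
    discrepancy: float   # relative LDL mismatch of the best match
    matched: bool


# ---------------------------------------------------------------------------
# preset builders
# ---------------------------------------------------------------------------

def baseline_scenario(
    params: DimensionalParameters | None = None,
    p_E0: float = 1e12,
    horizon_h: float = 200.0,
    **kwargs,
) -> Scenario:
    """The reference kinetics experiment: fresh medium, constant VLDL source,
    extracellular PCSK9 preset to ``p_E0`` (1e12 molec./mL by default)."""
    params = params if params is not None else default_parameters()
    init = {"p_E": p_E0} if p_E0 > 0 else {}
    return Scenario.from_concentrations(params, init, horizon_h=horizon_h, **kwargs)


def pcsk9_pulse_scenario(
    params: DimensionalParameters | None = None,
    pulse_total: float = 1e12,
    t_pulse_h: float = 100.0,
    duration_min: float = 10.0,
    horizon_h: float = 300.0,
    **kwargs,
) -> Scenario:
    """Timed external PCSK9 influx: ``pulse_total`` molec./mL delivered over
    ``duration_min`` minutes starting at ``t_pulse_h`` (default: 1e12 at
    100 h for 10 min)."""
    params = params if params is not None else default_parameters()
    duration_h = duration_min / 60.0
    rate = pulse_total / (duration_min * 60.0)  # molec./(mL s)
    event = DoseEvent(
        time_h=t_pulse_h, species="PCSK9_E", mode="influx",
        amount=rate, duration_h=duration_h,
    )
    return Scenario.from_concentrations(
        params, {}, events=(event,), horizon_h=horizon_h, **kwargs
    )


# ---------------------------------------------------------------------------
# readout helpers
# ---------------------------------------------------------------------------

def _settle_run(s: Scenario, settle_h: float, step_h: float = 1.0) -> SimulationResult:
    return integrate(s.replace(horizon_h=settle_h, output_step_h=step_h,
                               output_times_h=None))


def _dimensional(run: SimulationResult, name: str) -> np.ndarray:
    scale = state_scales(run.scenario.params.scales)[STATE_INDEX[name]]
    return run.component(name) * scale


def _metrics_from_runs(
    treated: SimulationResult, untreated: SimulationResult
) -> TherapyMetrics:
    l_t, l_u = _dimensional(treated, "l_E"), _dimensional(untreated, "l_E")
    v_t, v_u = _dimensional(treated, "v_E"), _dimensional(untreated, "v_E")
    pct_l = 100.0 * (1.0 - l_t[-1] / l_u[-1]) if l_u[-1] > 0 else 0.0
    pct_v = 100.0 * (1.0 - v_t[-1] / v_u[-1]) if v_u[-1] > 0 else 0.0
    deficit = l_u - l_t
    d_max = float(np.max(deficit))
    if d_max > 0:
        idx = int(np.argmax(deficit >= 0.5 * d_max))
        t_half = float(treated.time_h[idx])
    else:
        t_half = float("nan")
    return TherapyMetrics(
        ldl_ss=float(l_t[-1]),
        vldl_ss=float(v_t[-1]),
        pct_ldl_reduction=pct_l,
        pct_vldl_reduction=pct_v,
        t_half_ldl_h=t_half,
    )


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def pcsk9_threshold_scan(
    params: DimensionalParameters | None = None,
    decades: tuple[float, ...] = (1e10, 1e11, 1e12, 1e13, 1e14, 1e15),
    elevation_frac: float = 0.10,
    settle_h: float = DEFAULT_SETTLE_H,
) -> ThresholdScan:
    """Scan initial extracellular PCSK9 and find the smallest concentration
    whose steady-state LDL exceeds the PCSK9-free baseline by
    ``elevation_frac`` (default 10%)."""
    if elevation_frac <= 0:
        raise ValueError("elevation_frac must be positive")
    decades = tuple(sorted(decades))
    params = params if params is not None else default_parameters()

    def steady_ldl(p_e0: float) -> float:
        s = baseline_scenario(params, p_E0=p_e0)
        try:
            return float(_dimensional(_settle_run(s, settle_h), "l_E")[-1])
        except SimulationError as err:
            raise SimulationError(
                f"steady readout failed at PCSK9 = {p_e0:.3g} molec./mL: {err}"
            ) from err

    baseline_ldl = steady_ldl(0.0)
    curve = tuple((d, steady_ldl(d)) for d in decades)
    threshold = next(
        (d for d, ldl in curve if ldl >= (1.0 + elevation_frac) * baseline_ldl),
        None,
    )
    return ThresholdScan(
        threshold=threshold, curve=curve,
        baseline_ldl=baseline_ldl, elevation_frac=elevation_frac,
    )


def statin_scenario(
    dose: float = DEFAULT_STATIN_DOSE,
    t_dose_h: float = 10.0,
    params: DimensionalParameters | None = None,
    p_E0: float = 1e12,
    mode: str = "bolus",
    influx_duration_min: float = 10.0,
    settle_h: float = DEFAULT_SETTLE_H,
) -> tuple[SimulationResult, TherapyMetrics]:
    """Single statin dose applied at ``t_dose_h`` (10 h by default).

    The published protocol does not state whether the dose is a bolus or a
    brief influx; both are exposed (``mode``), bolus being the default.
    """
    if dose < 0:
        raise ValueError("statin dose must be >= 0")
    params = params if params is not None else default_parameters()
    if mode == "bolus":
        events = (DoseEvent(time_h=t_dose_h, species="statin_E", amount=dose),)
    elif mode == "influx":
        events = (DoseEvent(
            time_h=t_dose_h, species="statin_E", mode="influx",
            amount=dose / (influx_duration_min * 60.0),
            duration_h=influx_duration_min / 60.0,
        ),)
    else:
        raise ValueError(f"unknown statin dose mode {mode!r}")
    if dose == 0:
        events = ()
    base = baseline_scenario(params, p_E0=p_E0)
    treated = base.replace(events=events)
    run_t = _settle_run(treated, settle_h)
    run_u = _settle_run(base, settle_h)
    return run_t, _metrics_from_runs(run_t, run_u)


def agent_parameters(
    params: DimensionalParameters,
    agent: str,
    on_factor: float = SMALL_MOLECULE_ON_FACTOR,
    off_factor: float = SMALL_MOLECULE_OFF_FACTOR,
) -> DimensionalParameters:
    """Anti-PCSK9 agent kinetics: antibody uses the defaults; the small
    molecule scales the association rate up and dissociation rate down."""
    if agent == "antibody":
        return params
    if agent == "small_molecule":
        return params.with_overrides(
            eps_p=params.eps_p * on_factor,
            eps_minus_p=params.eps_minus_p / off_factor,
        )
    raise ValueError(f"unknown anti-PCSK9 agent {agent!r}")


def anti_pcsk9_scenario(
    agent: str = "antibody",
    dose: float = DEFAULT_ANTIBODY_DOSE,
    pcsk9_init: float = 1e14,
    params: DimensionalParameters | None = None,
    settle_h: float = DEFAULT_SETTLE_H,
    **agent_kwargs,
) -> tuple[SimulationResult, TherapyMetrics]:
    """Anti-PCSK9 agent and PCSK9 both present from t = 0 (high-PCSK9
    protocol: PCSK9 at 1e14 molec./mL, agent at ``dose``)."""
    if dose < 0:
        raise ValueError("agent dose must be >= 0")
    params = params if params is not None else default_parameters()
    params_t = agent_parameters(params, agent, **agent_kwargs)
    treated = Scenario.from_concentrations(
        params_t, {"p_E": pcsk9_init, "A_E": dose}
    )
    untreated = Scenario.from_concentrations(params, {"p_E": pcsk9_init})
    run_t = _settle_run(treated, settle_h)
    run_u = _settle_run(untreated, settle_h)
    return run_t, _metrics_from_runs(run_t, run_u)


def combined_therapy_scenario(
    statin_dose: float = DEFAULT_STATIN_DOSE,
    antibody_dose: float = DEFAULT_ANTIBODY_DOSE,
    pcsk9_init: float = 1e14,
    params: DimensionalParameters | None = None,
    settle_h: float = DEFAULT_SETTLE_H,
) -> dict[str, TherapyMetrics]:
    """Monotherapies and simultaneous combination, all dosed at t = 0 against
    the high-PCSK9 background; returns metrics per arm."""
    params = params if params is not None else default_parameters()

    def arm(statin: float, antibody: float) -> SimulationResult:
        init = {"p_E": pcsk9_init}
        if statin > 0:
            init["S_E"] = statin
        if antibody > 0:
            init["A_E"] = antibody
        return _settle_run(Scenario.from_concentrations(params, init), settle_h)

    run_u = arm(0.0, 0.0)
    runs = {
        "statin": arm(statin_dose, 0.0),
        "antibody": arm(0.0, antibody_dose),
        "combined": arm(statin_dose, antibody_dose),
    }
    return {name: _metrics_from_runs(r, run_u) for name, r in runs.items()}


def recycling_fraction_comparison(
    pcsk9_values: tuple[float, ...],
    params: DimensionalParameters | None = None,
    f_min: float = 0.01,
    settle_h: float = DEFAULT_SETTLE_H,
    xtol: float = 1e-4,
) -> list[MatchedRecyclingPair]:
    """For each PCSK9 concentration, find the recycling fraction ``f`` whose
    PCSK9-free steady-state LDL best matches the PCSK9-loaded run.

    PCSK9 degradation of receptors mimics a reduced recycling efficiency, so
    the matched ``f`` decreases as the PCSK9 load grows.
    """
    from scipy.optimize import brentq

    params = params if params is not None else default_parameters()
    f_default = params.f
    pcsk9_free = params.with_overrides(mu_mp_star=0.0, alpha_p=0.0, omega_P=0.0)

    def ldl_with_pcsk9(p_e0: float) -> float:
        s = baseline_scenario(params, p_E0=p_e0)
        return float(_dimensional(_settle_run(s, settle_h), "l_E")[-1])

    def ldl_with_f(f_val: float) -> float:
        s = baseline_scenario(pcsk9_free.with_overrides(f=f_val), p_E0=0.0)
        return float(_dimensional(_settle_run(s, settle_h), "l_E")[-1])

    pairs: list[MatchedRecyclingPair] = []
    for p_e0 in pcsk9_values:
        target = ldl_with_pcsk9(p_e0)

        def mismatch(f_val: float) -> float:
            return ldl_with_f(f_val) - target

        lo, hi = mismatch(f_min), mismatch(f_default)
        if p_e0 == 0.0 or abs(hi) <= xtol * max(target, 1e-300):
            pairs.append(MatchedRecyclingPair(p_e0, f_default,
                                              abs(hi) / max(target, 1e-300), True))
            continue
        if lo * hi > 0:  # target outside the reachable LDL range
            best_f = f_min if abs(lo) < abs(hi) else f_default
            best = min(abs(lo), abs(hi)) / max(target, 1e-300)
            pairs.append(MatchedRecyclingPair(p_e0, best_f, best, False))
            continue
        f_star = brentq(mismatch, f_min, f_default, xtol=xtol)
        disc = abs(mismatch(f_star)) / max(target, 1e-300)
        pairs.append(MatchedRecyclingPair(p_e0, float(f_star), disc, True))
    return pairs


def run_sweep(
    spec: SweepSpec, params: DimensionalParameters | None = None
) -> list[tuple[float, float]]:
    """Evaluate a steady-readout metric along a one-dimensional sweep."""
    params = params if params is not None else default_parameters()
    curve = []
    for v in spec.values:
        if spec.kind == "parameter":
            s = baseline_scenario(params.with_overrides(**{spec.name: v}))
        else:
            s = Scenario.from_concentrations(params, {spec.name: v})
        run = _settle_run(s, spec.settle_h)
        curve.append((float(v), float(_dimensional(run, spec.metric)[-1])))
    return curve
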