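"""Local sensitivity of steady-state outputs to model parameters.

Implemented as central finite differences of relative (log-log) sensitivity
coefficients ``d ln Y / d ln theta`` on steady-readout outputs.  This is a
stand-in design: the published analysis names its parameter groups (PCSK9
pathway; anti-PCSK9 agents and statins) but not its numerical method, so the
perturbation scheme here is documented rather than inherited.

Parameters whose default value is zero (intracellular PCSK9 degradation) are
perturbed additively by ``h_frac`` times a documented reference scale, since
a multiplicative perturbation of zero is degenerate; such coefficients are
semi-relative (``dY/dtheta * ref / Y``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DimensionalParameters, ParameterError, default_parameters
from .scenarios import DEFAULT_SETTLE_H, _dimensional, _settle_run, baseline_scenario
from .simulate import Scenario, SimulationError

__all__ = [
    "SensitivityReport",
    "local_sensitivity",
    "PCSK9_TARGETS",
    "THERAPY_TARGETS",
    "DEFAULT_OUTPUTS",
]

#: Newly-introduced PCSK9 pathway parameters.
PCSK9_TARGETS = (
    "mu_mp_star", "mu_p", "delta_mp", "kappa_mp", "gamma_p", "delta_p",
    "alpha_p", "alpha_minus_p", "M_p", "beta_p",
)

#: Drug-interaction parameters (anti-PCSK9 agents and statins).
THERAPY_TARGETS = ("eps_S", "eps_minus_S", "CL_S", "eps_p", "eps_minus_p")

DEFAULT_OUTPUTS = ("c", "l_E", "v_E", "r_f")

#: Additive perturbation reference scales for zero-valued parameters.
ZERO_REFERENCE_SCALE = {
    "delta_p": 4.48e-5,   # matches the PCSK9 mRNA degradation rate scale, 1/s
    "omega_P": 1e6,
    "omega_A": 1e6,
    "omega_S": 1e6,
}


@dataclass
class SensitivityReport:
    outputs: tuple[str, ...]
    parameters: tuple[str, ...]
    matrix: np.ndarray            # (n_parameters, n_outputs)
    valid: np.ndarray             # bool mask, same shape
    h_frac: float
    method: str = "central-fd-loglog"

    def coefficient(self, parameter: str, output: str) -> float:
        i = self.parameters.index(parameter)
        j = self.outputs.index(output)
        return float(self.matrix[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.parameters),
                            columns=list(self.outputs))


def _steady_outputs(
    s: Scenario, outputs: tuple[str, ...], settle_h: float
) -> np.ndarray:
    run = _settle_run(s, settle_h)
    return np.array([_dimensional(run, name)[-1] for name in outputs])


def local_sensitivity(
    params: DimensionalParameters | None = None,
    targets: tuple[str, ...] = PCSK9_TARGETS,
    outputs: tuple[str, ...] = DEFAULT_OUTPUTS,
    h_frac: float = 0.01,
    scenario_builder=None,
    settle_h: float = DEFAULT_SETTLE_H,
) -> SensitivityReport:
    """Relative sensitivity coefficients of steady outputs to ``targets``.

    ``scenario_builder`` maps a parameter set to the scenario whose steady
    readout is differentiated; the default is the baseline experiment with
    1e12 molec./mL extracellular PCSK9.  A steady-state failure under a
    perturbed parameter marks the affected coefficients invalid (NaN) rather
    than dropping them silently.
    """
    if not (0 < h_frac <= 0.5):
        raise ValueError(f"h_frac must lie in (0, 0.5], got {h_frac!r}")
    params = params if params is not None else default_parameters()
    build = scenario_builder or (lambda p: baseline_scenario(p, p_E0=1e12))

    y0 = _steady_outputs(build(params), outputs, settle_h)
    if np.any(y0 <= 0):
        bad = [outputs[i] for i in np.flatnonzero(y0 <= 0)]
        raise SimulationError(f"baseline steady output(s) not positive: {bad}")

    matrix = np.full((len(targets), len(outputs)), np.nan)
    valid = np.zeros_like(matrix, dtype=bool)
    for i, name in enumerate(targets):
        theta = getattr(params, name)
        try:
            if theta > 0:
                hi = params.with_overrides(**{name: theta * (1 + h_frac)})
                lo = params.with_overrides(**{name: theta * (1 - h_frac)})
                denom = 2.0 * h_frac * y0
            else:
                ref = ZERO_REFERENCE_SCALE.get(name, 1.0)
                step = h_frac * ref
                hi = params.with_overrides(**{name: theta + step})
                lo = params  # cannot go below zero; forward difference
                denom = step * y0 / ref
            y_hi = _steady_outputs(build(hi), outputs, settle_h)
            y_lo = (
                _steady_outputs(build(lo), outputs, settle_h)
                if lo is not params else y0
            )
        except (SimulationError, ParameterError):
            continue  # row stays NaN/invalid
        matrix[i] = (y_hi - y_lo) / denom
        valid[i] = np.isfinite(matrix[i])
    return SensitivityReport(
        outputs=tuple(outputs), parameters=tuple(targets),
        matrix=matrix, valid=valid, h_frac=h_frac,
    )
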