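"""Timed perturbations of the extracellular medium.

Two event modes mirror the in vitro protocol: an instantaneous ``bolus``
(concentration added to the medium at one time point) and a finite-duration
``influx`` (a constant source active over a half-open window
``[time_h, time_h + duration_h)``).  The half-open convention avoids double
counting at integrator restart boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Sources
from .params import Scales
from .states import DOSEABLE_SPECIES, STATE_INDEX

__all__ = ["DoseEvent", "DoseError", "apply_bolus", "active_sources", "event_boundaries"]

_MODES = ("bolus", "influx")

#: dose species -> Sources field carrying its influx strength
_SOURCE_FIELD = {
    "LDL_E": "omega_L",
    "VLDL_E": "omega_V",
    "PCSK9_E": "omega_P",
    "antibody_E": "omega_A",
    "statin_E": "omega_S",
}

#: dose species -> Scales attribute of the corresponding state component
_SCALE_FIELD = {
    "LDL_E": "l0",
    "VLDL_E": "v0",
    "PCSK9_E": "pE0_ref",
    "antibody_E": "pE0_ref",
    "statin_E": "sE0",
}


class DoseError(ValueError):
    """Malformed dose event."""


@dataclass(frozen=True)
class DoseEvent:
    """A timed perturbation of one extracellular species.

    ``amount`` is a concentration (molec./mL) for a bolus and a source rate
    (molec./(mL s)) for an influx.  ``duration_h`` must be 0 for a bolus.
    """

    time_h: float
    species: str
    mode: str = "bolus"
    amount: float = 0.0
    duration_h: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in DOSEABLE_SPECIES:
            raise DoseError(
                f"unknown dose species {self.species!r}; "
                f"expected one of {sorted(DOSEABLE_SPECIES)}"
            )
        if self.mode not in _MODES:
            raise DoseError(f"unknown dose mode {self.mode!r}; expected {_MODES}")
        if not (self.time_h >= 0):
            raise DoseError(f"event time must be >= 0 h, got {self.time_h!r}")
        if not (self.amount >= 0):
            raise DoseError(f"dose amount must be >= 0, got {self.amount!r}")
        if not (self.duration_h >= 0):
            raise DoseError(f"influx duration must be >= 0 h, got {self.duration_h!r}")
        if self.mode == "bolus" and self.duration_h != 0:
            raise DoseError("a bolus event must have duration_h = 0")
        if self.mode == "influx" and self.duration_h == 0:
            raise DoseError("an influx event must have duration_h > 0")

    @property
    def end_h(self) -> float:
        return self.time_h + self.duration_h


def apply_bolus(y: np.ndarray, event: DoseEvent, scales: Scales) -> np.ndarray:
    """Return ``y`` with the event's species incremented by its amount.

    The dimensional amount (molec./mL) is converted to the dimensionless
    scale of the targeted component; all other components are untouched.
    """
    if event.mode != "bolus":
        raise DoseError(f"apply_bolus called with mode {event.mode!r}")
    y = np.array(y, dtype=float, copy=True)
    idx = STATE_INDEX[DOSEABLE_SPECIES[event.species]]
    y[idx] += event.amount / getattr(scales, _SCALE_FIELD[event.species])
    return y


def active_sources(
    t_h: float, events: list[DoseEvent], scales: Scales | None = None
) -> Sources:
    """Summed influx strengths active at time ``t_h`` (hours).

    Windows are half-open: an influx contributes on ``[time_h, end_h)``.
    Overlapping influxes on the same species add.  Returns dimensional rates
    (molec./(mL s)) unless ``scales`` is given, in which case the strengths
    are converted to the dimensionless scale.
    """
    strengths = dict.fromkeys(_SOURCE_FIELD.values(), 0.0)
    for e in events:
        if e.mode == "influx" and e.time_h <= t_h < e.end_h:
            strengths[_SOURCE_FIELD[e.species]] += e.amount
    src = Sources(**strengths)
    return src.scaled(scales) if scales is not None else src


def event_boundaries(events: list[DoseEvent], horizon_h: float) -> list[float]:
    """Sorted distinct times in (0, horizon) where the RHS changes: bolus
    instants, influx starts and influx ends."""
    times: set[float] = set()
    for e in events:
        for t in (e.time_h, e.end_h) if e.mode == "influx" else (e.time_h,):
            if 0.0 < t < horizon_h:
                times.add(float(t))
    return sorted(times)
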