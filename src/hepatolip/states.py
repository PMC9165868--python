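"""Canonical state vector of the 21-component hepatocyte lipoprotein model.

The ordering below is frozen: every array-valued interface in this package
(right-hand sides, trajectories, CSV columns) uses it.  All user-facing I/O
refers to components by name, never by index.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

#: Canonical component names, in the fixed integration order.
STATE_NAMES: tuple[str, ...] = (
    "m_h",   # HMGCR mRNA
    "m_r",   # LDLR mRNA
    "m_p",   # PCSK9 mRNA
    "h",     # HMGCR enzyme (free)
    "p_I",   # intracellular PCSK9
    "r_I",   # internal LDLR pool
    "r_f",   # free surface LDLR
    "l_E",   # extracellular LDL
    "l_RB",  # receptor-bound LDL
    "l_I",   # internalised LDL
    "v_E",   # extracellular VLDL
    "v_RB",  # receptor-bound VLDL
    "v_I",   # internalised VLDL
    "c",     # intracellular cholesterol
    "p_E",   # extracellular PCSK9 (free)
    "p_RB",  # receptor-bound PCSK9
    "A_E",   # free anti-PCSK9 agent (antibody or small molecule)
    "p_AB",  # agent-PCSK9 complex
    "S_E",   # extracellular statin
    "S_i",   # intracellular free statin
    "S_ih",  # statin-HMGCR complex
)

N_STATES: int = len(STATE_NAMES)

#: name -> index lookup (total and stable).
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

#: mRNA components (transcription targets).
MRNA_NAMES: tuple[str, ...] = ("m_h", "m_r", "m_p")

#: Components that vanish identically when the PCSK9 pathway is disabled.
PCSK9_NAMES: tuple[str, ...] = ("m_p", "p_I", "p_E", "p_RB", "p_AB")

#: Drug-related components (zero in drug-free scenarios).
DRUG_NAMES: tuple[str, ...] = ("A_E", "p_AB", "S_E", "S_i", "S_ih")

#: Variables shared with the PCSK9-free, drug-free parent reduction.
SHARED_WITH_REDUCED: tuple[str, ...] = tuple(
    n for n in STATE_NAMES if n not in PCSK9_NAMES and n not in DRUG_NAMES
)

#: Extracellular species that dose events may target, mapped to state names.
DOSEABLE_SPECIES: dict[str, str] = {
    "PCSK9_E": "p_E",
    "antibody_E": "A_E",
    "statin_E": "S_E",
    "LDL_E": "l_E",
    "VLDL_E": "v_E",
}


class StateError(ValueError):
    """Raised for malformed state vectors (wrong length, negative, NaN)."""


def state_from_dict(values: Mapping[str, float], *, default: float = 0.0) -> np.ndarray:
    """Build a state vector from a name -> value mapping.

    Unlisted components get ``default``; unknown names are rejected.
    """
    unknown = set(values) - set(STATE_NAMES)
    if unknown:
        raise StateError(f"unknown state component(s): {sorted(unknown)}")
    y = np.full(N_STATES, float(default))
    for name, val in values.items():
        y[STATE_INDEX[name]] = float(val)
    return y


def state_to_dict(y: np.ndarray) -> dict[str, float]:
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise StateError(f"state vector must have shape ({N_STATES},), got {y.shape}")
    return {name: float(y[i]) for i, name in enumerate(STATE_NAMES)}


def validate_state(y: np.ndarray, *, neg_tol: float = 0.0) -> np.ndarray:
    """Check shape, finiteness and non-negativity (to ``neg_tol``).

    Returns the validated array (negatives within tolerance clipped to zero).
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise StateError(f"state vector must have shape ({N_STATES},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise StateError(f"non-finite state component(s): {bad}")
    if np.any(y < -abs(neg_tol)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(y < -abs(neg_tol))]
        raise StateError(f"negative state component(s): {bad}")
    return np.maximum(y, 0.0)
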