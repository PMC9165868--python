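"""Right-hand sides of the hepatocyte cholesterol/lipoprotein ODE system.

Two equivalent formulations are implemented:

* :func:`rhs_dimensional` — the barred system in (molecules, mL, seconds)
  units, kept as a cross-check oracle;
* :func:`rhs_dimensionless` — the rescaled system actually used for
  integration throughout the package.

The two are linked by :func:`nondimensionalize` / :func:`dimensionalize`;
their defining contract (enforced by the test suite) is that trajectories of
the dimensional system, mapped through the state rescalings of
:class:`~hepatolip.params.Scales`, coincide with trajectories of the
dimensionless system.

Model structure
---------------
Transcription of HMGCR, LDLR and PCSK9 mRNA is activated by a shared SREBP-2
pool and repressed by intracellular cholesterol through a Hill-type term (see
:func:`transcription_rate`).  Translated LDLR transits an internal pool to the
cell surface where free receptors bind LDL, VLDL and PCSK9; bound particles
are internalised and a fraction ``f`` of the receptors carried by LDL/VLDL
vesicles is recycled, while receptors internalised with PCSK9 are degraded.
Cholesterol is produced by HMGCR activity and extracted from internalised
lipoproteins, closing the negative feedback on transcription.  Statins enter
the cell with clearance ``CL_S`` and sequester HMGCR; anti-PCSK9 agents bind
extracellular PCSK9 1:1.

Receptor occupancy terms
------------------------
The internalisation of receptor-bound particles also carries along free
receptors sharing the coated pit.  With surface occupancy measured against
the capacity scale (``r_f`` dimensionless, free fraction), the co-internalised
free-receptor flux for species ``x`` is ``M_x nu_x beta_x r_f x_RB/(1-r_f)``
and the total receptor flux is ``M_x nu_x beta_x x_RB/(1-r_f)`` (bound plus
co-internalised; a fraction ``f`` of the LDL/VLDL part is recycled).  The
``1 - r_f`` divisor is guarded: it is evaluated only when bound material is
present, and a vanishing divisor with bound material present raises
:class:`SingularityError`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .params import (
    DimensionalParameters,
    DimensionlessParameters,
    ParameterError,
    Scales,
)
from .states import N_STATES, validate_state

__all__ = [
    "GENES",
    "Sources",
    "ModelError",
    "SingularityError",
    "transcription_rate",
    "rhs_dimensionless",
    "rhs_dimensional",
    "nondimensionalize",
    "dimensionalize",
]

GENES = ("HMGCR", "LDLR", "PCSK9")

#: Minimum admissible value of the free-receptor occupancy divisor.
_OCC_GUARD = 1e-12


class ModelError(ValueError):
    """Domain error in a model evaluation (negative/NaN input, bad gene)."""


class SingularityError(ModelError):
    """Receptor-occupancy divisor vanished while bound material is present."""


@dataclass(frozen=True)
class Sources:
    """Source strengths for the five extracellular species.

    Units follow the system being evaluated: molec./(mL s) for the
    dimensional form, scale-relative per second for the dimensionless form.
    These are *additional* influxes (dose events); the constant sources held
    in the parameter set (``omega_V`` etc.) are always applied on top.
    """

    omega_L: float = 0.0
    omega_V: float = 0.0
    omega_P: float = 0.0
    omega_A: float = 0.0
    omega_S: float = 0.0

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not np.isfinite(v) or v < 0:
                raise ModelError(f"source {f_.name!r} must be finite and >= 0, got {v!r}")

    def scaled(self, scales: Scales) -> "Sources":
        """Convert dimensional source strengths to the dimensionless scale."""
        return Sources(
            omega_L=self.omega_L / scales.l0,
            omega_V=self.omega_V / scales.v0,
            omega_P=self.omega_P / scales.pE0_ref,
            omega_A=self.omega_A / scales.pE0_ref,
            omega_S=self.omega_S / scales.sE0,
        )

    def __add__(self, other: "Sources") -> "Sources":
        return Sources(
            self.omega_L + other.omega_L,
            self.omega_V + other.omega_V,
            self.omega_P + other.omega_P,
            self.omega_A + other.omega_A,
            self.omega_S + other.omega_S,
        )


_NO_SOURCES = Sources()


def transcription_rate(c: float, gene: str, p: DimensionlessParameters) -> float:
    """SREBP-2-activated, cholesterol-repressed transcription rate.

    Returns ``mu* / (1 + (kappa (1 + (c/kc)^xc))^x_gene)`` for the requested
    gene.  The rate is strictly decreasing in the cholesterol level ``c`` and
    bounded above by its value at ``c = 0``.
    """
    if not np.isfinite(c) or c < 0:
        raise ModelError(f"cholesterol level must be finite and >= 0, got {c!r}")
    if p.kc <= 0:
        raise ModelError("SREBP-2-cholesterol dissociation scale kc must be positive")
    try:
        mu, kappa, x = {
            "HMGCR": (p.mu_mh, p.kappa_mh, p.xh),
            "LDLR": (p.mu_mr, p.kappa_mr, p.xr),
            "PCSK9": (p.mu_mp, p.kappa_mp, p.xp),
        }[gene]
    except KeyError:
        raise ModelError(f"unknown gene {gene!r}; expected one of {GENES}") from None
    return mu / (1.0 + (kappa * (1.0 + (c / p.kc) ** p.xc)) ** x)


def _occupancy_fluxes(r_f: float, bound: float, beta: float) -> tuple[float, float]:
    """(total, co-internalised-free) receptor fluxes for one bound species.

    Both are per unit ``M nu``; the divisor ``1 - r_f`` is only touched when
    bound material is present.
    """
    if bound == 0.0:
        return 0.0, 0.0
    occ = 1.0 - r_f
    if occ <= _OCC_GUARD:
        raise SingularityError(
            "free-receptor occupancy reached capacity (r_f -> 1) with bound "
            "receptors present; occupancy divisor 1 - r_f is singular"
        )
    return beta * bound / occ, beta * r_f * bound / occ


def rhs_dimensionless(
    t: float,
    y: np.ndarray,
    p: DimensionlessParameters,
    sources: Sources | None = None,
    *,
    validate: bool = True,
) -> np.ndarray:
    """Time derivative of the 21-component dimensionless state.

    ``sources`` holds event-driven influx strengths on the dimensionless
    scale; constant parameter sources are added internally.  With
    ``validate=True`` (the default for direct calls) the state is checked for
    NaN and negativity; the integrator disables validation and handles
    round-off negatives itself.
    """
    if validate:
        y = validate_state(y)
    src = sources if sources is not None else _NO_SOURCES

    (m_h, m_r, m_p, h, p_I, r_I, r_f, l_E, l_RB, l_I, v_E, v_RB, v_I, c,
     p_E, p_RB, A_E, p_AB, S_E, S_i, S_ih) = y

    dy = np.empty(N_STATES)

    # transcription / mRNA turnover (nuclear compartment, scaled by J)
    dy[0] = (transcription_rate(c, "HMGCR", p) - p.delta_mh * m_h) / p.J
    dy[1] = (transcription_rate(c, "LDLR", p) - p.delta_mr * m_r) / p.J
    dy[2] = (transcription_rate(c, "PCSK9", p) - p.delta_mp * m_p) / p.J

    # HMGCR: translation, degradation, statin sequestration
    dy[3] = p.mu_h * m_h - p.delta_h * h - p.eps_S_h * S_i * h + p.eps_minus_S_h * S_ih

    # intracellular PCSK9: translation, secretion, degradation
    dy[4] = p.mu_p * m_p - p.gamma_p * p_I - p.delta_p * p_I

    # receptor internalisation fluxes (total, free part) per species
    tot_l, free_l = _occupancy_fluxes(r_f, l_RB, p.beta_l)
    tot_v, free_v = _occupancy_fluxes(r_f, v_RB, p.beta_v)
    tot_p, free_p = _occupancy_fluxes(r_f, p_RB, p.beta_p)

    # internal receptor pool: synthesis, export, recycling of empty-pit and
    # LDL/VLDL vesicle receptors (none from PCSK9-bound vesicles)
    dy[5] = (
        p.mu_r * m_r
        - p.gamma_r * r_I
        + p.f * p.beta_0 * p.P * r_f
        + p.f * p.M_l * p.nu_l * tot_l
        + p.f * p.M_v * p.nu_v * tot_v
    )

    # free surface receptors
    dy[6] = (
        p.gamma_r * r_I
        - p.beta_0 * p.P * r_f
        - p.M_l * p.nu_l * (free_l + p.alpha_l * r_f * l_E - p.alpha_minus_l * l_RB)
        - p.M_v * p.nu_v * (free_v + p.alpha_v * r_f * v_E - p.alpha_minus_v * v_RB)
        - p.M_p * p.nu_p * (free_p + p.alpha_p * r_f * p_E - p.alpha_minus_p * p_RB)
    )

    # LDL: extracellular (fed by VLDL delipidation), bound, internalised
    dy[7] = (
        (-p.alpha_l * r_f * l_E + p.alpha_minus_l * l_RB) / p.W
        + p.chi_v * p.rho_v * v_E
        + src.omega_L
    )
    dy[8] = p.alpha_l * r_f * l_E - p.alpha_minus_l * l_RB - p.beta_l * l_RB
    dy[9] = p.beta_l * l_RB - p.gamma_l * l_I

    # VLDL: extracellular (constant source, delipidation), bound, internalised
    dy[10] = (
        (-p.alpha_v * r_f * v_E + p.alpha_minus_v * v_RB) / p.W
        - p.chi_v * v_E
        + p.omega_V
        + src.omega_V
    )
    dy[11] = p.alpha_v * r_f * v_E - p.alpha_minus_v * v_RB - p.beta_v * v_RB
    dy[12] = p.beta_v * v_RB - p.gamma_v * v_I

    # cholesterol: lipoprotein extraction, HMGCR synthesis, degradation
    dy[13] = (
        p.R_l_chol * p.sigma_l * p.gamma_l * l_I
        + p.R_v_chol * p.sigma_v * p.gamma_v * v_I
        + p.mu_c * h
        - p.delta_c * c
    )

    # extracellular and receptor-bound PCSK9
    dy[14] = (
        (
            -p.alpha_p * r_f * p_E
            + p.alpha_minus_p * p_RB
            + p.gamma_p * p_I
            - p.eps_p * A_E * p_E
            + p.eps_minus_p * p_AB
        )
        / p.W
        + p.omega_P
        + src.omega_P
    )
    dy[15] = p.alpha_p * r_f * p_E - p.alpha_minus_p * p_RB - p.beta_p * p_RB

    # anti-PCSK9 agent and its complex (1:1 binding)
    dy[16] = (-p.eps_p * A_E * p_E + p.eps_minus_p * p_AB) / p.W + p.omega_A + src.omega_A
    dy[17] = p.eps_p * A_E * p_E - p.eps_minus_p * p_AB

    # statin: uptake, HMGCR sequestration
    dy[18] = -p.CL_S * S_E / p.W + p.omega_S + src.omega_S
    dy[19] = p.CL_S * S_E - p.eps_S * S_i * h + p.eps_minus_S * S_ih
    dy[20] = p.eps_S * S_i * h - p.eps_minus_S * S_ih

    return dy


def rhs_dimensional(
    t: float,
    y_bar: np.ndarray,
    p: DimensionalParameters,
    sources: Sources | None = None,
    *,
    validate: bool = True,
) -> np.ndarray:
    """Time derivative of the barred (dimensional) system.

    Exists as a cross-check oracle for the rescaling map; the simulator
    integrates the dimensionless form.
    """
    if validate:
        y_bar = validate_state(y_bar)
    src = sources if sources is not None else _NO_SOURCES
    rf0 = p.scales.rf0

    (m_h, m_r, m_p, h, p_I, r_I, r_f, l_E, l_RB, l_I, v_E, v_RB, v_I, c,
     p_E, p_RB, A_E, p_AB, S_E, S_i, S_ih) = y_bar

    if c < 0 or not np.isfinite(c):
        raise ModelError(f"cholesterol level must be finite and >= 0, got {c!r}")
    srebp_block = 1.0 + (c / p.kc) ** p.xc

    def act(mu_star: float, kappa: float, x: int) -> float:
        return mu_star / (1.0 + (kappa * srebp_block / p.s0) ** x)

    def occ_fluxes(bound: float, beta: float) -> tuple[float, float]:
        if bound == 0.0:
            return 0.0, 0.0
        denom = rf0 - r_f
        if denom <= _OCC_GUARD * rf0:
            raise SingularityError(
                "free surface receptors reached the capacity scale rf0 with "
                "bound receptors present; divisor rf0 - r_f is singular"
            )
        return beta * rf0 * bound / denom, beta * r_f * bound / denom

    dy = np.empty(N_STATES)

    dy[0] = (act(p.mu_mh_star, p.kappa_mh, p.xh) - p.delta_mh * m_h) / p.J
    dy[1] = (act(p.mu_mr_star, p.kappa_mr, p.xr) - p.delta_mr * m_r) / p.J
    dy[2] = (act(p.mu_mp_star, p.kappa_mp, p.xp) - p.delta_mp * m_p) / p.J

    dy[3] = p.mu_h * m_h - p.delta_h * h - p.eps_S * S_i * h + p.eps_minus_S * S_ih
    dy[4] = p.mu_p * m_p - p.gamma_p * p_I - p.delta_p * p_I

    tot_l, free_l = occ_fluxes(l_RB, p.beta_l)
    tot_v, free_v = occ_fluxes(v_RB, p.beta_v)
    tot_p, free_p = occ_fluxes(p_RB, p.beta_p)

    dy[5] = (
        p.mu_r * m_r
        - p.gamma_r * r_I
        + p.f * p.beta_0 * p.P * r_f
        + p.f * p.M_l * tot_l
        + p.f * p.M_v * tot_v
    )
    dy[6] = (
        p.gamma_r * r_I
        - p.beta_0 * p.P * r_f
        - p.M_l * (free_l + p.alpha_l * r_f * l_E - p.alpha_minus_l * l_RB)
        - p.M_v * (free_v + p.alpha_v * r_f * v_E - p.alpha_minus_v * v_RB)
        - p.M_p * (free_p + p.alpha_p * r_f * p_E - p.alpha_minus_p * p_RB)
    )

    dy[7] = (
        (-p.alpha_l * r_f * l_E + p.alpha_minus_l * l_RB) / p.W
        + p.chi_v * v_E
        + src.omega_L
    )
    dy[8] = p.alpha_l * r_f * l_E - p.alpha_minus_l * l_RB - p.beta_l * l_RB
    dy[9] = p.beta_l * l_RB - p.gamma_l * l_I

    dy[10] = (
        (-p.alpha_v * r_f * v_E + p.alpha_minus_v * v_RB) / p.W
        - p.chi_v * v_E
        + p.omega_V
        + src.omega_V
    )
    dy[11] = p.alpha_v * r_f * v_E - p.alpha_minus_v * v_RB - p.beta_v * v_RB
    dy[12] = p.beta_v * v_RB - p.gamma_v * v_I

    dy[13] = (
        p.R_l_chol * p.gamma_l * l_I
        + p.R_v_chol * p.gamma_v * v_I
        + p.mu_c * h
        - p.delta_c * c
    )

    dy[14] = (
        (
            -p.alpha_p * r_f * p_E
            + p.alpha_minus_p * p_RB
            + p.gamma_p * p_I
            - p.eps_p * A_E * p_E
            + p.eps_minus_p * p_AB
        )
        / p.W
        + p.omega_P
        + src.omega_P
    )
    dy[15] = p.alpha_p * r_f * p_E - p.alpha_minus_p * p_RB - p.beta_p * p_RB

    dy[16] = (-p.eps_p * A_E * p_E + p.eps_minus_p * p_AB) / p.W + p.omega_A + src.omega_A
    dy[17] = p.eps_p * A_E * p_E - p.eps_minus_p * p_AB

    dy[18] = -p.CL_S * S_E / p.W + p.omega_S + src.omega_S
    dy[19] = p.CL_S * S_E - p.eps_S * S_i * h + p.eps_minus_S * S_ih
    dy[20] = p.eps_S * S_i * h - p.eps_minus_S * S_ih

    return dy


# ---------------------------------------------------------------------------
# dimensional <-> dimensionless parameter maps
# ---------------------------------------------------------------------------

def state_scales(scales: Scales) -> np.ndarray:
    """Per-component rescaling vector: ``y_dimless = y_bar / state_scales``."""
    s = scales
    return np.array([
        s.m0, s.m0, s.m0,            # mRNAs
        s.s0,                        # h
        s.pE0_ref,                   # p_I
        s.rf0, s.rf0,                # r_I, r_f
        s.l0, s.l0, s.l0,            # LDL
        s.v0, s.v0, s.v0,            # VLDL
        s.s0,                        # c
        s.pE0_ref, s.pE0_ref,        # p_E, p_RB
        s.pE0_ref, s.pE0_ref,        # A_E, p_AB
        s.sE0, s.sE0, s.sE0,         # statin
    ])


def nondimensionalize(p: DimensionalParameters) -> DimensionlessParameters:
    """Fold the reference scales into the rate constants.

    The returned set makes :func:`rhs_dimensionless` the exact pushforward of
    :func:`rhs_dimensional` under ``y = y_bar / state_scales(p.scales)``; the
    test suite verifies this by integrating both systems.
    """
    s = p.scales
    for name in ("rf0", "sE0", "pE0_ref", "l0", "v0", "m0", "s0"):
        if getattr(s, name) <= 0:
            raise ParameterError(f"zero or negative reference scale {name!r}")
    return DimensionlessParameters(
        mu_mh=p.mu_mh_star / s.m0,
        mu_mr=p.mu_mr_star / s.m0,
        mu_mp=p.mu_mp_star / s.m0,
        delta_mh=p.delta_mh,
        delta_mr=p.delta_mr,
        delta_mp=p.delta_mp,
        kappa_mh=p.kappa_mh / p.s0,
        kappa_mr=p.kappa_mr / p.s0,
        kappa_mp=p.kappa_mp / p.s0,
        kc=p.kc / s.s0,
        xc=p.xc, xh=p.xh, xr=p.xr, xp=p.xp,
        mu_h=p.mu_h * s.m0 / s.s0,
        mu_r=p.mu_r * s.m0 / s.rf0,
        mu_p=p.mu_p * s.m0 / s.pE0_ref,
        delta_h=p.delta_h,
        delta_p=p.delta_p,
        delta_c=p.delta_c,
        gamma_r=p.gamma_r,
        gamma_p=p.gamma_p,
        gamma_l=p.gamma_l,
        gamma_v=p.gamma_v,
        f=p.f, P=p.P, beta_0=p.beta_0,
        M_l=p.M_l, M_v=p.M_v, M_p=p.M_p,
        nu_l=s.l0 / s.rf0,
        nu_v=s.v0 / s.rf0,
        nu_p=s.pE0_ref / s.rf0,
        rho_v=s.v0 / s.l0,
        sigma_l=s.l0 / s.s0,
        sigma_v=s.v0 / s.s0,
        alpha_l=p.alpha_l * s.rf0,
        alpha_minus_l=p.alpha_minus_l,
        alpha_v=p.alpha_v * s.rf0,
        alpha_minus_v=p.alpha_minus_v,
        alpha_p=p.alpha_p * s.rf0,
        alpha_minus_p=p.alpha_minus_p,
        beta_l=p.beta_l, beta_v=p.beta_v, beta_p=p.beta_p,
        chi_v=p.chi_v,
        omega_V=p.omega_V / s.v0,
        omega_P=p.omega_P / s.pE0_ref,
        omega_A=p.omega_A / s.pE0_ref,
        omega_S=p.omega_S / s.sE0,
        R_l_chol=p.R_l_chol,
        R_v_chol=p.R_v_chol,
        mu_c=p.mu_c,
        eps_S_h=p.eps_S * s.sE0,
        eps_minus_S_h=p.eps_minus_S * s.sE0 / s.s0,
        eps_S=p.eps_S * s.s0,
        eps_minus_S=p.eps_minus_S,
        CL_S=p.CL_S,
        eps_p=p.eps_p * s.pE0_ref,
        eps_minus_p=p.eps_minus_p,
        W=p.W, J=p.J,
        scales=s,
    )


def dimensionalize(
    q: DimensionlessParameters, scales: Scales | None = None
) -> DimensionalParameters:
    """Inverse of :func:`nondimensionalize` (exact round trip)."""
    s = scales if scales is not None else q.scales
    return DimensionalParameters(
        mu_mh_star=q.mu_mh * s.m0,
        mu_mr_star=q.mu_mr * s.m0,
        mu_mp_star=q.mu_mp * s.m0,
        delta_mh=q.delta_mh,
        delta_mr=q.delta_mr,
        delta_mp=q.delta_mp,
        kappa_mh=q.kappa_mh * s.s0,
        kappa_mr=q.kappa_mr * s.s0,
        kappa_mp=q.kappa_mp * s.s0,
        s0=s.s0,
        kc=q.kc * s.s0,
        xc=q.xc, xh=q.xh, xr=q.xr, xp=q.xp,
        mu_h=q.mu_h * s.s0 / s.m0,
        mu_r=q.mu_r * s.rf0 / s.m0,
        mu_p=q.mu_p * s.pE0_ref / s.m0,
        delta_h=q.delta_h,
        delta_p=q.delta_p,
        delta_c=q.delta_c,
        gamma_r=q.gamma_r,
        gamma_p=q.gamma_p,
        gamma_l=q.gamma_l,
        gamma_v=q.gamma_v,
        f=q.f, P=q.P, beta_0=q.beta_0,
        M_l=q.M_l, M_v=q.M_v, M_p=q.M_p,
        alpha_l=q.alpha_l / s.rf0,
        alpha_minus_l=q.alpha_minus_l,
        alpha_v=q.alpha_v / s.rf0,
        alpha_minus_v=q.alpha_minus_v,
        alpha_p=q.alpha_p / s.rf0,
        alpha_minus_p=q.alpha_minus_p,
        beta_l=q.beta_l, beta_v=q.beta_v, beta_p=q.beta_p,
        chi_v=q.chi_v,
        omega_V=q.omega_V * s.v0,
        omega_P=q.omega_P * s.pE0_ref,
        omega_A=q.omega_A * s.pE0_ref,
        omega_S=q.omega_S * s.sE0,
        R_l_chol=q.R_l_chol,
        R_v_chol=q.R_v_chol,
        mu_c=q.mu_c,
        eps_S=q.eps_S_h / s.sE0,
        eps_minus_S=q.eps_minus_S,
        CL_S=q.CL_S,
        eps_p=q.eps_p / s.pE0_ref,
        eps_minus_p=q.eps_minus_p,
        W=q.W, J=q.J,
        scales=s,
    )
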