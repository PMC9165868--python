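"""Parameter containers for the dimensional and dimensionless model forms.

Dimensional parameters carry the barred rate constants in (molecules, mL,
seconds) units.  The dimensionless set is produced from them by
:func:`hepatolip.model.nondimensionalize` using the reference scales stored in
:class:`Scales`; the defining contract between the two forms is trajectory
equivalence, which the test suite enforces.

Defaults ship in ``hepatolip/data/parameters.tsv`` with one provenance tag per
parameter: ``table1`` (printed, fixed), ``parent_model`` (inherited from the
parent endocytosis model), or ``assumed`` (chosen here to keep every
steady-state concentration positive and finite; freely overridable).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = [
    "Scales",
    "DimensionalParameters",
    "DimensionlessParameters",
    "ParameterError",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "PROVENANCE_TAGS",
]

PROVENANCE_TAGS = ("table1", "s1_appendix", "parent_model", "assumed")

#: Parameters constrained to be positive integers (Hill exponents / site counts).
_INTEGER_FIELDS = ("xc", "xh", "xr", "xp")


class ParameterError(ValueError):
    """Invalid, missing, or out-of-range parameter value."""


@dataclass(frozen=True)
class Scales:
    """Reference scales of the non-dimensionalization.

    State components are rescaled as ``y = y_bar / scale``:

    ====================  =================
    component             scale
    ====================  =================
    m_h, m_r, m_p         ``m0``
    h, c                  ``s0`` (SREBP-2 pool)
    r_I, r_f              ``rf0`` (surface receptor capacity)
    l_E, l_RB, l_I        ``l0``
    v_E, v_RB, v_I        ``v0``
    p_I, p_E, p_RB        ``pE0_ref``
    A_E, p_AB             ``pE0_ref``
    S_E, S_i, S_ih        ``sE0``
    ====================  =================

    Time is kept in seconds in both forms.
    """

    rf0: float = 1.0e14
    sE0: float = 1.0e12
    pE0_ref: float = 1.0e12
    l0: float = 1.0e12
    v0: float = 1.0e12
    m0: float = 1.0e10
    s0: float = 8.21e16

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not (v > 0):
                raise ParameterError(
                    f"reference scale {f_.name!r} must be positive, got {v!r}"
                )

    @classmethod
    def identity(cls) -> "Scales":
        return cls(rf0=1, sE0=1, pE0_ref=1, l0=1, v0=1, m0=1, s0=1)


@dataclass(frozen=True)
class DimensionalParameters:
    """Barred (dimensional) parameter set; units molecules / mL / s."""

    # transcription (maximal rates, molec./(mL s))
    mu_mh_star: float
    mu_mr_star: float
    mu_mp_star: float
    # mRNA degradation (1/s)
    delta_mh: float
    delta_mr: float
    delta_mp: float
    # gene-SREBP-2 binding affinities (molec./mL)
    kappa_mh: float
    kappa_mr: float
    kappa_mp: float
    # SREBP-2 pool and cholesterol feedback
    s0: float
    kc: float
    xc: int
    xh: int
    xr: int
    xp: int
    # translation (1/s)
    mu_h: float
    mu_r: float
    mu_p: float
    # intracellular degradation (1/s)
    delta_h: float
    delta_p: float
    delta_c: float
    # transport (1/s)
    gamma_r: float
    gamma_p: float
    # cholesterol extraction from internalised lipoproteins (1/s)
    gamma_l: float
    gamma_v: float
    # receptor recycling
    f: float
    P: float
    beta_0: float
    # receptors covered per bound particle
    M_l: float
    M_v: float
    M_p: float
    # binding / unbinding (mL/(molec. s)) / (1/s)
    alpha_l: float
    alpha_minus_l: float
    alpha_v: float
    alpha_minus_v: float
    alpha_p: float
    alpha_minus_p: float
    # internalisation (1/s)
    beta_l: float
    beta_v: float
    beta_p: float
    # VLDL -> LDL delipidation (1/s)
    chi_v: float
    # constant sources (molec./(mL s))
    omega_V: float
    omega_P: float
    omega_A: float
    omega_S: float
    # cholesterol yield and synthesis
    R_l_chol: float
    R_v_chol: float
    mu_c: float
    # statin kinetics
    eps_S: float
    eps_minus_S: float
    CL_S: float
    # anti-PCSK9 agent kinetics
    eps_p: float
    eps_minus_p: float
    # compartment scaling constants
    W: float
    J: float
    # reference scales for the non-dimensionalization
    scales: Scales = field(default_factory=Scales)

    def __post_init__(self) -> None:
        for f_ in fields(self):
            if f_.name == "scales":
                continue
            v = getattr(self, f_.name)
            if not (v >= 0):
                raise ParameterError(f"parameter {f_.name!r} must be >= 0, got {v!r}")
        for name in _INTEGER_FIELDS:
            v = getattr(self, name)
            if v < 1 or int(v) != v:
                raise ParameterError(
                    f"Hill exponent {name!r} must be a positive integer, got {v!r}"
                )
        if not (0.0 <= self.f <= 1.0):
            raise ParameterError(f"recycled fraction f must lie in [0, 1], got {self.f!r}")
        for name in ("M_l", "M_v", "M_p"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name!r} must be >= 1")
        if self.kc <= 0:
            raise ParameterError("kc must be positive")
        if self.s0 <= 0:
            raise ParameterError("s0 must be positive")
        if self.W <= 0 or self.J <= 0:
            raise ParameterError("compartment constants W and J must be positive")

    def with_overrides(self, **overrides: float) -> "DimensionalParameters":
        """Return a copy with named parameters replaced (names validated)."""
        known = {f_.name for f_ in fields(self)} - {"scales"}
        scale_names = {f_.name for f_ in fields(Scales)}
        plain = {k: v for k, v in overrides.items() if k in known}
        unknown = set(overrides) - known - scale_names
        # s0 is both a model parameter and the h/c reference scale; keep in sync.
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        scale_over = {k: v for k, v in overrides.items() if k in scale_names and k != "s0"}
        if "s0" in overrides:
            scale_over["s0"] = overrides["s0"]
        new_scales = replace(self.scales, **scale_over) if scale_over else self.scales
        for name in _INTEGER_FIELDS:
            if name in plain:
                if float(plain[name]) != int(plain[name]):
                    raise ParameterError(
                        f"Hill exponent {name!r} must be a positive integer, "
                        f"got {plain[name]!r}"
                    )
                plain[name] = int(plain[name])
        return replace(self, scales=new_scales, **plain)


@dataclass(frozen=True)
class DimensionlessParameters:
    """Unbarred parameter set of the final dimensionless system.

    Produced by :func:`hepatolip.model.nondimensionalize`; carries the scale
    ratios (``nu_l``, ``nu_v``, ``nu_p``, ``rho_v``, ``sigma_l``, ``sigma_v``)
    that appear only in the dimensionless receptor/cholesterol balances, plus
    the :class:`Scales` record needed to invert the map.
    """

    mu_mh: float
    mu_mr: float
    mu_mp: float
    delta_mh: float
    delta_mr: float
    delta_mp: float
    kappa_mh: float
    kappa_mr: float
    kappa_mp: float
    kc: float
    xc: int
    xh: int
    xr: int
    xp: int
    mu_h: float
    mu_r: float
    mu_p: float
    delta_h: float
    delta_p: float
    delta_c: float
    gamma_r: float
    gamma_p: float
    gamma_l: float
    gamma_v: float
    f: float
    P: float
    beta_0: float
    M_l: float
    M_v: float
    M_p: float
    nu_l: float
    nu_v: float
    nu_p: float
    rho_v: float
    sigma_l: float
    sigma_v: float
    alpha_l: float
    alpha_minus_l: float
    alpha_v: float
    alpha_minus_v: float
    alpha_p: float
    alpha_minus_p: float
    beta_l: float
    beta_v: float
    beta_p: float
    chi_v: float
    omega_V: float
    omega_P: float
    omega_A: float
    omega_S: float
    R_l_chol: float
    R_v_chol: float
    mu_c: float
    eps_S_h: float
    eps_minus_S_h: float
    eps_S: float
    eps_minus_S: float
    CL_S: float
    eps_p: float
    eps_minus_p: float
    W: float
    J: float
    scales: Scales = field(default_factory=Scales)

    def __post_init__(self) -> None:
        for f_ in fields(self):
            if f_.name == "scales":
                continue
            v = getattr(self, f_.name)
            if not (v >= 0):
                raise ParameterError(f"parameter {f_.name!r} must be >= 0, got {v!r}")


# ---------------------------------------------------------------------------
# parameter file I/O (flat name/value/units/provenance TSV)
# ---------------------------------------------------------------------------

_SCALE_FIELDS = tuple(f_.name for f_ in fields(Scales))


def _param_field_names() -> list[str]:
    return [f_.name for f_ in fields(DimensionalParameters) if f_.name != "scales"]


def load_parameters(path: str | Path) -> DimensionalParameters:
    """Load a dimensional parameter set from a name/value/units/provenance TSV."""
    path = Path(path)
    values: dict[str, float] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "value", "units", "provenance"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParameterError(
                f"parameter file {path} must have columns {sorted(required)}"
            )
        for row in reader:
            name = row["name"].strip()
            if not name or name.startswith("#"):
                continue
            if name in values:
                raise ParameterError(f"duplicate parameter {name!r} in {path}")
            tag = row["provenance"].strip()
            if tag not in PROVENANCE_TAGS:
                raise ParameterError(
                    f"unknown provenance tag {tag!r} for {name!r}; "
                    f"expected one of {PROVENANCE_TAGS}"
                )
            values[name] = float(row["value"])
    return parameters_from_mapping(values)


def parameters_from_mapping(values: dict[str, float]) -> DimensionalParameters:
    param_names = _param_field_names()
    unknown = set(values) - set(param_names) - set(_SCALE_FIELDS)
    if unknown:
        raise ParameterError(f"unknown parameter name(s): {sorted(unknown)}")
    missing = set(param_names) - set(values)
    if missing:
        raise ParameterError(f"missing parameter(s): {sorted(missing)}")
    scale_kwargs = {k: values[k] for k in _SCALE_FIELDS if k in values and k != "s0"}
    scale_kwargs["s0"] = values["s0"]
    kwargs: dict = {k: values[k] for k in param_names}
    for name in _INTEGER_FIELDS:
        if float(kwargs[name]) != int(kwargs[name]):
            raise ParameterError(
                f"Hill exponent {name!r} must be a positive integer, got "
                f"{kwargs[name]!r}"
            )
        kwargs[name] = int(kwargs[name])
    return DimensionalParameters(scales=Scales(**scale_kwargs), **kwargs)


def _load_metadata() -> dict[str, dict[str, str]]:
    """units/provenance per parameter, read from the packaged defaults file."""
    meta: dict[str, dict[str, str]] = {}
    ref = importlib.resources.files("hepatolip") / "data" / "parameters.tsv"
    with ref.open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["name"].strip()] = {
                "units": row["units"].strip(),
                "provenance": row["provenance"].strip(),
            }
    return meta


def save_parameters(p: DimensionalParameters, path: str | Path) -> None:
    """Write a parameter set back to TSV, preserving packaged units/provenance.

    Values are written with :func:`repr` so a load/save cycle is bit-exact.
    """
    meta = _load_metadata()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", "value", "units", "provenance"])
        for name in _param_field_names():
            m = meta.get(name, {"units": "-", "provenance": "assumed"})
            writer.writerow([name, repr(getattr(p, name)), m["units"], m["provenance"]])
        for name in _SCALE_FIELDS:
            if name == "s0":
                continue
            m = meta.get(name, {"units": "molec./mL", "provenance": "assumed"})
            writer.writerow(
                [name, repr(getattr(p.scales, name)), m["units"], m["provenance"]]
            )


def default_parameters(**overrides: float) -> DimensionalParameters:
    """The packaged default parameter set, optionally with overrides."""
    ref = importlib.resources.files("hepatolip") / "data" / "parameters.tsv"
    with importlib.resources.as_file(ref) as path:
        p = load_parameters(path)
    return p.with_overrides(**overrides) if overrides else p


def provenance_table() -> dict[str, str]:
    """name -> provenance tag for the packaged defaults."""
    return {k: v["provenance"] for k, v in _load_metadata().items()}
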