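"""Model parameters, unit conventions and nondimensionalization.

Internal unit system: **hours** and **centimetres**.  The motility
coefficient ``K`` is stored in cm^2/h; literature values quoted in cm^2/s
are converted once on input (x3600).  Concentrations are dimensionless and
stored normalized so that the initial concentration ``Ci = 1`` by
convention; only the ratio ``C0/Ci`` affects the radius dynamics (scaling
both by a common factor leaves every trajectory unchanged, which is tested
as a package invariant).

Reference scales used for dimensionless reporting:

* ``K0 = 1e-10 cm^2/s = 3.6e-7 cm^2/h`` -- typical cell motility scale,
* ``eta0 = 1e-2 1/h`` -- order of magnitude of proliferation for highly
  proliferative cancer cells,
* ``t_max`` -- the observation horizon (default 210 h, the span over which
  spheroid formation is imaged).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import yaml

#: Reference motility, cm^2/s.
K0_CM2_PER_S = 1e-10
#: Reference motility converted once to internal units, cm^2/h.
K0_CM2_PER_H = K0_CM2_PER_S * 3600.0
#: Reference proliferation rate, 1/h.
ETA0_PER_H = 1e-2

#: Default observation horizon, hours.
DEFAULT_T_MAX_H = 210.0

_REL_TOL = 1e-12


class ParameterError(ValueError):
    """Raised for invalid or inconsistent model parameters."""


@dataclass(frozen=True)
class ModelParameters:
    """Physical parameters of the PDE-ODE spheroid-formation model.

    Parameters
    ----------
    K : float
        Cell motility coefficient in cm^2/h (response of the cell flux to
        the concentration gradient, reduced by adhesion).  Use
        :meth:`from_units` or ``K_units="cm2/s"`` in file input to convert
        from cm^2/s.
    eta : float
        Proliferation rate in 1/h.
    C0 : float
        Relaxed (boundary) concentration, dimensionless.
    Ci : float
        Initial uniform concentration, dimensionless.  Stored normalized to
        1 by convention; construct with any positive pair (C0, Ci) and call
        :meth:`normalized`.
    R0 : float
        Initial spheroid radius, cm.
    t_max : float
        Horizon used for time normalization, h.
    D : float, optional
        Bare cell diffusivity, cm^2/h.  Documentation field: the model
        posits K = epsilon*D with 0 < epsilon < 1 (adhesion reduces
        motility) but the dynamics use K directly.
    epsilon : float, optional
        Adhesion reduction factor in K = epsilon*D; see ``D``.
    """

    K: float
    eta: float
    C0: float
    Ci: float = 1.0
    R0: float = 0.01
    t_max: float = DEFAULT_T_MAX_H
    D: Optional[float] = None
    epsilon: Optional[float] = None

    def check(self) -> "ModelParameters":
        """Raise :class:`ParameterError` if any invariant is violated.

        Construction itself does not throw, so that :func:`validate` can
        report every violation of a bad parameter set at once; solvers call
        this before using the parameters.
        """
        violations = validate(self)
        if violations:
            raise ParameterError("; ".join(violations))
        return self

    @classmethod
    def from_units(
        cls,
        K: float,
        K_units: str = "cm2/h",
        **kwargs,
    ) -> "ModelParameters":
        """Build parameters accepting ``K`` in either cm^2/s or cm^2/h."""
        if K_units == "cm2/s":
            K = K * 3600.0
        elif K_units != "cm2/h":
            raise ParameterError(f"K_units must be 'cm2/s' or 'cm2/h', got {K_units!r}")
        return cls(K=K, **kwargs)

    @classmethod
    def from_dimensionless(
        cls,
        K_star: float,
        eta_star: float,
        C0_over_Ci: float,
        R0: float = 0.01,
        t_max: float = DEFAULT_T_MAX_H,
    ) -> "ModelParameters":
        """Build parameters from the dimensionless figures-of-merit
        ``K* = K/K0``, ``eta* = eta/eta0`` and the concentration ratio."""
        return cls(
            K=K_star * K0_CM2_PER_H,
            eta=eta_star * ETA0_PER_H,
            C0=C0_over_Ci,
            Ci=1.0,
            R0=R0,
            t_max=t_max,
        )

    @property
    def C_ratio(self) -> float:
        """Concentration ratio C0/Ci, the only way concentration scale
        enters the dynamics."""
        return self.C0 / self.Ci

    def normalized(self) -> "ModelParameters":
        """Return an equivalent parameter set with Ci rescaled to 1."""
        if self.Ci == 1.0:
            return self
        return replace(self, C0=self.C0 / self.Ci, Ci=1.0)

    # -- file IO -----------------------------------------------------------

    # "analytic" carries the eigen-series configuration block, parsed by
    # spheroidsim.analytic.load_series_config from the same file
    _FILE_KEYS = {"K", "K_units", "eta", "C0", "Ci", "R0_cm", "t_max_h", "seed",
                  "analytic"}

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ModelParameters":
        """Read a flat YAML/JSON parameter file.

        Recognized keys: ``K, K_units ('cm2/s'|'cm2/h'), eta, C0, Ci,
        R0_cm, t_max_h, seed``.  Unknown keys are rejected.  ``seed`` is
        accepted (for reproducibility sidecars) but not stored here.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"parameter file {path} must contain a mapping")
        unknown = set(data) - cls._FILE_KEYS
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = {"K", "eta", "C0"} - set(data)
        if missing:
            raise ParameterError(f"missing required parameter keys: {sorted(missing)}")
        return cls.from_units(
            K=float(data["K"]),
            K_units=data.get("K_units", "cm2/h"),
            eta=float(data["eta"]),
            C0=float(data["C0"]),
            Ci=float(data.get("Ci", 1.0)),
            R0=float(data.get("R0_cm", 0.01)),
            t_max=float(data.get("t_max_h", DEFAULT_T_MAX_H)),
        )

    def to_dict(self) -> dict:
        d = {
            "K": self.K,
            "K_units": "cm2/h",
            "eta": self.eta,
            "C0": self.C0,
            "Ci": self.Ci,
            "R0_cm": self.R0,
            "t_max_h": self.t_max,
        }
        return d


def validate(params: ModelParameters) -> list[str]:
    """Check every parameter invariant; return a list of violations.

    Returns an empty list iff the parameter set is valid.  Each violation
    message names the offending field and the rule it breaks.  This
    function reports rather than throws so callers can collect all
    problems at once.
    """
    v: list[str] = []

    def _finite_positive(name: str, value: float, allow_zero: bool = False) -> None:
        if not math.isfinite(value):
            v.append(f"{name} must be finite, got {value}")
        elif value < 0 or (value == 0 and not allow_zero):
            rule = ">= 0" if allow_zero else "> 0"
            v.append(f"{name} must be {rule}, got {value}")

    _finite_positive("K", params.K)
    _finite_positive("eta", params.eta, allow_zero=True)
    _finite_positive("C0", params.C0)
    _finite_positive("Ci", params.Ci)
    _finite_positive("R0", params.R0)
    _finite_positive("t_max", params.t_max)

    if params.epsilon is not None:
        if not (0.0 < params.epsilon < 1.0):
            v.append(f"epsilon must satisfy 0 < epsilon < 1, got {params.epsilon}")
    if params.D is not None:
        _finite_positive("D", params.D)
    if params.D is not None and params.epsilon is not None:
        expected = params.epsilon * params.D
        if expected > 0 and abs(params.K - expected) > _REL_TOL * abs(expected):
            v.append(
                f"K must equal epsilon*D to relative {_REL_TOL:g}: "
                f"K={params.K!r}, epsilon*D={expected!r}"
            )
    return v


@dataclass(frozen=True)
class DimensionlessView:
    """Dimensionless report of a parameter set.

    ``K_star = K/K0`` with K0 = 1e-10 cm^2/s, ``eta_star = eta/eta0`` with
    eta0 = 1e-2 1/h, and ``C_ratio = C0/Ci``.  ``R0_cm`` and ``t_max_h``
    are carried so the view is invertible (:meth:`to_parameters`), and the
    normalized coordinates of any trajectory point are exposed through
    :meth:`t_star` (t/t_max in [0, 1]) and :meth:`r_star`
    ((R - R0)/R0, zero at t = 0).
    """

    K_star: float
    eta_star: float
    C_ratio: float
    R0_cm: float
    t_max_h: float

    def t_star(self, t_hours):
        """Normalized time t/t_max."""
        return t_hours / self.t_max_h

    def r_star(self, radius_cm):
        """Normalized radius (R - R0)/R0; exactly 0 at R = R0."""
        return (radius_cm - self.R0_cm) / self.R0_cm

    def to_parameters(self) -> ModelParameters:
        """Invert the nondimensionalization (Ci = 1 convention)."""
        return ModelParameters(
            K=self.K_star * K0_CM2_PER_H,
            eta=self.eta_star * ETA0_PER_H,
            C0=self.C_ratio,
            Ci=1.0,
            R0=self.R0_cm,
            t_max=self.t_max_h,
        )


def nondimensionalize(params: ModelParameters) -> DimensionlessView:
    """Express a parameter set in the reference scales (K0, eta0, t_max).

    Raises
    ------
    ParameterError
        If any field is non-finite or violates positivity; the message
        names the field.
    """
    violations = validate(params)
    if violations:
        raise ParameterError("; ".join(violations))
    return DimensionlessView(
        K_star=params.K / K0_CM2_PER_H,
        eta_star=params.eta / ETA0_PER_H,
        C_ratio=params.C0 / params.Ci,
        R0_cm=params.R0,
        t_max_h=params.t_max,
    )


@dataclass(frozen=True)
class CountPair:
    """Viable cell counts at 24 h (N1) and 48 h (N2) for proliferation-rate
    estimation from a Trypan-blue assay."""

    N1: float
    N2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.N1) and self.N1 > 0):
            raise ParameterError(f"N1 must be > 0, got {self.N1}")
        if not (math.isfinite(self.N2) and self.N2 >= 0):
            raise ParameterError(f"N2 must be >= 0, got {self.N2}")
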