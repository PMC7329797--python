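"""Population layer: fixed effects, covariate laws, log-normal IIV, residual error.

An individual's kinetic parameter is

    P_i = theta_P * prod(covariate factors) * exp(eta_P,i),   eta ~ N(0, omega_P^2)

with covariate factors of linear (1 + beta*(COV - ref)), power ((COV/ref)^beta)
or indicator (1 + beta*IND) form.  Observed concentrations carry combined
additive + proportional residual error

    C_obs = C1 + C1*eps_prop + eps_add,   eps ~ N(0, sigma^2) each.

Inter-individual variability is reported as %CV of the log-normal
distribution, %CV = 100*sqrt(exp(omega^2) - 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .dataset import CovariateSet
from .structural import InfusionSchedule, StructuralParams, concentration_profile

__all__ = [
    "PARAM_NAMES",
    "FixedEffects",
    "IIVSpec",
    "ResidualSpec",
    "CovariateLaw",
    "PopulationModel",
    "CovariateError",
    "residual_variance",
    "cv_to_omega2",
    "omega2_to_cv",
    "simulate_subject",
    "meropenem_crrt_model",
]

#: canonical kinetic-parameter order; also the eta-vector order
PARAM_NAMES = ("V1", "CL", "Q", "V2")

_STRUCT_FIELD = {"V1": "v1", "CL": "cl_crrt", "Q": "q", "V2": "v2"}


class CovariateError(KeyError):
    """A covariate required by an active law is missing."""


@dataclass(frozen=True)
class FixedEffects:
    """Typical values (theta) of the kinetic constants."""

    v1: float
    v2: float
    cl_crrt: float
    q: float

    def __post_init__(self):
        for name in ("v1", "v2", "cl_crrt", "q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"theta {name} must be positive")

    def as_dict(self) -> dict:
        return {"V1": self.v1, "CL": self.cl_crrt, "Q": self.q, "V2": self.v2}


@dataclass(frozen=True)
class IIVSpec:
    """Variances omega^2 of the log-scale random effects.

    A parameter absent from ``omega2`` carries no random effect at all
    (its eta is structurally zero), mirroring variances fixed to zero
    during model building.
    """

    omega2: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.omega2.items():
            if k not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r}")
            if v < 0:
                raise ValueError(f"omega2[{k}] must be >= 0")

    @property
    def eta_names(self) -> tuple[str, ...]:
        return tuple(p for p in PARAM_NAMES if self.omega2.get(p, 0.0) > 0.0)

    def omega2_vector(self) -> np.ndarray:
        return np.array([self.omega2[p] for p in self.eta_names])


@dataclass(frozen=True)
class ResidualSpec:
    """Residual-error magnitudes: sigma_add in mg/l, sigma_prop dimensionless (SD)."""

    sigma_add: float
    sigma_prop: float

    def __post_init__(self):
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual SDs must be >= 0")
        if self.sigma_add == 0 and self.sigma_prop == 0:
            raise ValueError("at least one residual component must be positive")


@dataclass(frozen=True)
class CovariateLaw:
    """One covariate-parameter relationship.

    form "linear":    factor = 1 + coefficient * (COV - reference)
    form "power":     factor = (COV / reference) ** coefficient
    form "indicator": factor = 1 + coefficient * IND,  IND in {0, 1}
    """

    parameter: str
    covariate: str
    form: str
    coefficient: float
    reference: float = 1.0

    def __post_init__(self):
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("linear", "power", "indicator"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "power" and self.reference <= 0:
            raise ValueError("power law needs a positive reference value")

    def factor(self, value: float) -> float:
        if self.form == "linear":
            return 1.0 + self.coefficient * (value - self.reference)
        if self.form == "power":
            return (value / self.reference) ** self.coefficient
        if value not in (0, 1, 0.0, 1.0, False, True):
            raise ValueError(f"indicator covariate {self.covariate} must be 0/1, got {value}")
        return 1.0 + self.coefficient * value


def _cov_value(cov, name: str) -> float:
    if isinstance(cov, CovariateSet):
        v = cov.get(name)
    else:
        v = cov.get(name)
    if v is None:
        raise CovariateError(f"covariate {name!r} required by a covariate law is missing")
    return float(v)


@dataclass(frozen=True)
class PopulationModel:
    fixed: FixedEffects
    iiv: IIVSpec
    residual: ResidualSpec
    laws: tuple[CovariateLaw, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "laws", tuple(self.laws))

    # -- parameter mapping ---------------------------------------------------

    def covariate_factors(self, cov) -> dict:
        """Multiplicative covariate factor per parameter."""
        factors = {p: 1.0 for p in PARAM_NAMES}
        for law in self.laws:
            factors[law.parameter] *= law.factor(_cov_value(cov, law.covariate))
        return factors

    def typical_values(self, cov=None) -> dict:
        theta = self.fixed.as_dict()
        if cov is None:
            return theta
        f = self.covariate_factors(cov)
        return {p: theta[p] * f[p] for p in PARAM_NAMES}

    def individual_params(self, eta=None, cov=None) -> StructuralParams:
        """Apply covariate laws and random effects: P = theta * factor * exp(eta).

        ``eta`` maps parameter name to value (missing entries are 0); an eta
        supplied for a parameter with no IIV is rejected.
        """
        eta = dict(eta or {})
        for name in eta:
            if name not in self.iiv.eta_names:
                raise ValueError(f"parameter {name!r} carries no random effect")
        vals = self.typical_values(cov)
        out = {}
        for p in PARAM_NAMES:
            v = vals[p] * float(np.exp(eta.get(p, 0.0)))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"individual {p} is not positive/finite: {v}")
            out[_STRUCT_FIELD[p]] = v
        return StructuralParams(**out)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed.as_dict(),
            "covariate_laws": [
                {
                    "parameter": l.parameter,
                    "covariate": l.covariate,
                    "form": l.form,
                    "coefficient": l.coefficient,
                    "reference": l.reference,
                }
                for l in self.laws
            ],
            "iiv_omega2": dict(self.iiv.omega2),
            "iiv_cv_percent": {k: omega2_to_cv(v) for k, v in self.iiv.omega2.items()},
            "residual": {
                "sigma_add_mg_per_l": self.residual.sigma_add,
                "sigma_prop": self.residual.sigma_prop,
                "sigma_prop_cv_percent": 100.0 * self.residual.sigma_prop,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        fe = d["fixed_effects"]
        return cls(
            fixed=FixedEffects(v1=fe["V1"], v2=fe["V2"], cl_crrt=fe["CL"], q=fe["Q"]),
            iiv=IIVSpec(omega2=dict(d.get("iiv_omega2", {}))),
            residual=ResidualSpec(
                sigma_add=d["residual"]["sigma_add_mg_per_l"],
                sigma_prop=d["residual"]["sigma_prop"],
            ),
            laws=tuple(CovariateLaw(**law) for law in d.get("covariate_laws", [])),
        )

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PopulationModel":
        path = str(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_dict(d)


def residual_variance(pred, res: ResidualSpec):
    """Variance of an observation around prediction ``pred`` (mg^2/l^2)."""
    pred = np.asarray(pred, float)
    if np.any(pred < 0):
        raise ValueError("prediction must be >= 0")
    out = res.sigma_add**2 + (pred * res.sigma_prop) ** 2
    return out if out.ndim else float(out)


def cv_to_omega2(cv_percent: float) -> float:
    """Log-normal %CV -> variance on the log scale: omega2 = ln(1 + (cv/100)^2)."""
    if cv_percent < 0:
        raise ValueError("cv must be >= 0")
    return float(np.log1p((cv_percent / 100.0) ** 2))

def omega2_to_cv(omega2: float) -> float:
    """Inverse of :func:`cv_to_omega2`: cv% = 100*sqrt(exp(omega2) - 1)."""
    if omega2 < 0:
        raise ValueError("omega2 must be >= 0")
    return float(100.0 * np.sqrt(np.expm1(omega2)))


def draw_etas(model: PopulationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """n x d matrix of random effects for the model's free eta entries."""
    om = model.iiv.omega2_vector()
    return rng.normal(0.0, np.sqrt(om), size=(n, om.size))


def simulate_subject(
    model: PopulationModel,
    cov,
    schedule: InfusionSchedule,
    times,
    rng: np.random.Generator,
    with_residual: bool = True,
):
    """Simulate one subject: draw eta, build parameters, evaluate the profile.

    Returns ``(observations, eta_dict)``; residual error per the combined
    additive + proportional model when ``with_residual``.  Simulated values
    may be negative through the additive component; they are returned as-is
    (the generative model is faithful, downstream consumers decide).
    """
    names = model.iiv.eta_names
    eta_vec = draw_etas(model, 1, rng)[0]
    eta = dict(zip(names, eta_vec))
    params = model.individual_params(eta=eta, cov=cov)
    conc = concentration_profile(params, schedule, times)
    if with_residual:
        sd = np.sqrt(residual_variance(conc, model.residual))
        conc = conc + rng.normal(0.0, 1.0, size=conc.shape) * sd
    return np.asarray(conc), eta


def meropenem_crrt_model() -> PopulationModel:
    """The final published population model for meropenem during CRRT.

    Typical values for a patient with serum albumin 24.6 g/l:
    V1 = 27.9 l with a power-law albumin effect of exponent -2.87,
    V2 = 33.7 l, Cl_CRRT = 15.1 l/h, Q = 21.1 l/h.  IIV: 53.1 / 43.7 /
    85.6 %CV on V1 / Cl / V2 (none on Q).  Residual error: 0.881 mg/l
    additive SD, 24.1% proportional SD.
    """
    return PopulationModel(
        fixed=FixedEffects(v1=27.9, v2=33.7, cl_crrt=15.1, q=21.1),
        iiv=IIVSpec(
            omega2={
                "V1": cv_to_omega2(53.1),
                "CL": cv_to_omega2(43.7),
                "V2": cv_to_omega2(85.6),
            }
        ),
        residual=ResidualSpec(sigma_add=0.881, sigma_prop=0.241),
        laws=(
            CovariateLaw(
                parameter="V1",
                covariate="albumin",
                form="power",
                coefficient=-2.87,
                reference=24.6,
            ),
        ),
    )
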