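"""Population layer: fixed effects, covariate effects, interindividual random
effects and the residual-error model.

Individual parameters follow a log-normal model: for subject *i* and
parameter *P*,

    P_i = exp( theta_P + sum_e k_e * x_e,i + eta_P,i )

where ``theta_P`` is the log of the typical value, each covariate effect *e*
contributes ``k_e * ln(Cov_i / Cov_ref)`` (power model, continuous) or
``k_e * 1[subject in category]`` (categorical), and ``eta_P,i ~ N(0, Omega)``.
Observations are log-normally distributed around the model prediction:
``ln(y) = ln(yhat) + eps``, ``eps ~ N(0, sigma^2)``.

Interindividual variability (IIV) is reported as CV% using the ``100*omega``
convention (the SD of the log-scale random effect, in percent); the
log-normal convention ``100*sqrt(exp(omega^2)-1)`` is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .structural import StructuralParams

__all__ = [
    "CovariateRecord",
    "CovariateEffect",
    "OmegaSpec",
    "PopulationModel",
    "covariate_factor",
    "individual_params",
    "sample_etas",
    "observe",
    "log_likelihood_term",
    "iiv_cv_percent",
    "final_model",
    "base_model",
]

logger = logging.getLogger(__name__)

STRUCTURAL_PARAMS = ("Vmax", "Km", "CL", "Vc", "Q", "Vp")


@dataclass(frozen=True)
class CovariateRecord:
    """Baseline covariates of one subject.

    ``wt`` kg, ``alb`` g/L; ``sex`` in {"M", "F"}; ``therapy`` in
    {"mono", "combo"}.  Additional screening covariates (AGE, AST, LDH, ...)
    live in ``extra`` keyed by their canonical column name.
    """

    wt: float
    alb: float = 38.0
    sex: str = "M"
    therapy: str = "mono"
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wt <= 0 or self.alb <= 0:
            raise ValueError("WT and ALB must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.therapy not in ("mono", "combo"):
            raise ValueError(f"therapy must be 'mono' or 'combo', got {self.therapy!r}")

    def get(self, name: str):
        mapping = {"WT": self.wt, "ALB": self.alb, "SEX": self.sex, "THERAPY": self.therapy}
        if name in mapping:
            return mapping[name]
        return self.extra.get(name)


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    ``kind="power"``: multiplies the parameter by ``(cov/reference)**coefficient``.
    ``kind="categorical"``: multiplies by ``exp(coefficient)`` when the subject
    is in ``category`` (the non-reference level), else by 1.
    """

    parameter: str
    covariate: str
    coefficient: float
    kind: str = "power"
    reference: float | None = None  # Cov_pop, continuous effects only
    category: str | None = None  # non-reference level, categorical only

    def __post_init__(self) -> None:
        if self.kind not in ("power", "categorical"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "power" and (self.reference is None or self.reference <= 0):
            raise ValueError("power effects need a positive reference value")
        if self.kind == "categorical" and self.category is None:
            raise ValueError("categorical effects need a category level")

    @property
    def name(self) -> str:
        return f"{self.covariate}->{self.parameter}"

    def design_value(self, cov: CovariateRecord) -> float:
        """x such that the log-parameter contribution is coefficient * x."""
        value = cov.get(self.covariate)
        if self.kind == "power":
            if value is None:
                logger.warning(
                    "missing %s for a subject; imputing reference %s",
                    self.covariate,
                    self.reference,
                )
                return 0.0
            return math.log(float(value) / self.reference)
        if value is None:
            logger.warning(
                "missing %s for a subject; assuming reference category", self.covariate
            )
            return 0.0
        return 1.0 if str(value) == self.category else 0.0


def covariate_factor(effect: CovariateEffect, cov: CovariateRecord) -> float:
    """Multiplicative factor this effect contributes for this subject."""
    return math.exp(effect.coefficient * effect.design_value(cov))


@dataclass(frozen=True)
class OmegaSpec:
    """IIV covariance: the set of parameters carrying an eta, and Omega itself."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("Omega shape does not match the IIV parameter set")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("Omega must be symmetric")
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -1e-10:
            raise ValueError("Omega must be positive semi-definite")
        object.__setattr__(self, "matrix", m)

    def variance(self, name: str) -> float:
        return float(self.matrix[self.names.index(name), self.names.index(name)])

    @classmethod
    def from_variances(
        cls,
        variances: Mapping[str, float],
        covariances: Mapping[tuple[str, str], float] | None = None,
    ) -> "OmegaSpec":
        names = tuple(variances)
        m = np.diag([float(variances[n]) for n in names])
        for (a, b), v in (covariances or {}).items():
            i, j = names.index(a), names.index(b)
            m[i, j] = m[j, i] = float(v)
        return cls(names, m)


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects (log-scale), covariate effects, Omega and sigma."""

    theta: Mapping[str, float]  # log typical values, keys subset of STRUCTURAL_PARAMS
    omega: OmegaSpec
    sigma: float  # residual SD on the log-concentration scale
    covariate_effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        missing = set(STRUCTURAL_PARAMS) - set(self.theta)
        if missing:
            raise ValueError(f"theta missing parameters: {sorted(missing)}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        unknown = {e.parameter for e in self.covariate_effects} - set(STRUCTURAL_PARAMS)
        if unknown:
            raise ValueError(f"covariate effects on unknown parameters: {sorted(unknown)}")
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    @classmethod
    def from_typical(
        cls,
        typical: Mapping[str, float],
        omega: OmegaSpec,
        sigma: float,
        covariate_effects: Iterable[CovariateEffect] = (),
    ) -> "PopulationModel":
        theta = {k: math.log(v) for k, v in typical.items()}
        return cls(theta, omega, sigma, tuple(covariate_effects))

    def typical_values(self) -> dict[str, float]:
        return {k: math.exp(v) for k, v in self.theta.items()}

    def effects_on(self, parameter: str) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.covariate_effects if e.parameter == parameter)

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        return replace(self, covariate_effects=self.covariate_effects + (effect,))

    def without_effect(self, name: str) -> "PopulationModel":
        kept = tuple(e for e in self.covariate_effects if e.name != name)
        if len(kept) == len(self.covariate_effects):
            raise KeyError(f"no covariate effect named {name!r}")
        return replace(self, covariate_effects=kept)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "typical": self.typical_values(),
            "omega": {
                "names": list(self.omega.names),
                "matrix": self.omega.matrix.tolist(),
            },
            "sigma": self.sigma,
            "covariate_effects": [
                {
                    "parameter": e.parameter,
                    "covariate": e.covariate,
                    "coefficient": e.coefficient,
                    "kind": e.kind,
                    "reference": e.reference,
                    "category": e.category,
                }
                for e in self.covariate_effects
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationModel":
        omega = OmegaSpec(tuple(d["omega"]["names"]), np.asarray(d["omega"]["matrix"]))
        effects = tuple(CovariateEffect(**e) for e in d.get("covariate_effects", []))
        return cls.from_typical(d["typical"], omega, float(d["sigma"]), effects)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def individual_params(
    pop: PopulationModel,
    cov: CovariateRecord,
    eta: Mapping[str, float] | None = None,
) -> StructuralParams:
    """Structural parameters for one subject (covariates and etas applied)."""
    eta = eta or {}
    values: dict[str, float] = {}
    for name in STRUCTURAL_PARAMS:
        log_val = pop.theta[name] + float(eta.get(name, 0.0))
        for effect in pop.effects_on(name):
            log_val += effect.coefficient * effect.design_value(cov)
        values[name] = math.exp(log_val)
        if not math.isfinite(values[name]):
            raise FloatingPointError(f"non-finite individual {name}")
    return StructuralParams(**values)


def sample_etas(omega: OmegaSpec, n: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` multivariate-normal eta vectors; columns = IIV parameters."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # eigen-based factor handles singular (including zero) Omega exactly
    w, v = np.linalg.eigh(omega.matrix)
    factor = v * np.sqrt(np.maximum(w, 0.0))
    draws = rng.standard_normal((n, len(omega.names))) @ factor.T
    return pd.DataFrame(draws, columns=list(omega.names))


def observe(pred, sigma: float, seed: int | np.random.Generator):
    """Simulate observed concentrations: ln(y) = ln(pred) + N(0, sigma^2)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pred = np.asarray(pred, dtype=float)
    if np.any(pred <= 0):
        raise ValueError("predictions must be positive to observe on the log scale")
    if sigma == 0:
        return pred.copy()
    return pred * np.exp(rng.normal(0.0, sigma, size=pred.shape))


def log_likelihood_term(obs: float, pred: float, sigma: float) -> float:
    """Normal log-density of ln(obs) around ln(pred) with SD sigma.

    The Jacobian of the log transform is omitted consistently package-wide, so
    objective-function differences between models remain comparable.
    """
    if pred <= 0 or obs <= 0:
        raise ValueError("obs and pred must be positive")
    z = (math.log(obs) - math.log(pred)) / sigma
    return -0.5 * (z * z + math.log(2.0 * math.pi * sigma * sigma))


def iiv_cv_percent(omega_sq: float, convention: str = "sd") -> float:
    """IIV as CV%.  ``"sd"`` returns 100*sqrt(omega^2) (the reporting
    convention used for this model); ``"lognormal"`` returns
    100*sqrt(exp(omega^2)-1)."""
    if omega_sq < 0:
        raise ValueError("variance must be non-negative")
    if convention == "sd":
        return 100.0 * math.sqrt(omega_sq)
    if convention == "lognormal":
        return 100.0 * math.sqrt(math.expm1(omega_sq))
    raise ValueError(f"unknown convention {convention!r}")


# --------------------------------------------------------------------------
# Published model factories
# --------------------------------------------------------------------------

#: final-model covariate effects: weight and albumin (power, reference = the
#: population median), combination therapy on CL, female sex on Vc.
FINAL_EFFECTS = (
    CovariateEffect("CL", "WT", 0.695, "power", reference=64.0),
    CovariateEffect("CL", "ALB", -0.657, "power", reference=38.0),
    CovariateEffect("CL", "THERAPY", -0.200, "categorical", category="combo"),
    CovariateEffect("Vc", "WT", 0.369, "power", reference=64.0),
    CovariateEffect("Vc", "SEX", -0.164, "categorical", category="F"),
)


def final_model() -> PopulationModel:
    """The final covariate model with its reported estimates.

    Typical values: CL 0.311 L/day, Vc 3.58 L, Q 0.952 L/day, Vp 2.71 L,
    Vmax 2.80 ug/day, Km 4.45 ug/mL.  IIV on Vmax/CL/Vc/Vp with a CL-Vc
    covariance of 0.0128; residual log-SD 0.146.
    """
    omega = OmegaSpec.from_variances(
        {"Vmax": 0.974**2, "CL": 0.0854, "Vc": 0.0221, "Vp": 0.604**2},
        {("CL", "Vc"): 0.0128},
    )
    return PopulationModel.from_typical(
        {"Vmax": 2.80, "Km": 4.45, "CL": 0.311, "Vc": 3.58, "Q": 0.952, "Vp": 2.71},
        omega,
        sigma=0.146,
        covariate_effects=FINAL_EFFECTS,
    )


def base_model() -> PopulationModel:
    """The weight-only base model (weight on CL and Vc, no other covariates)."""
    omega = OmegaSpec.from_variances(
        {"Vmax": 0.899**2, "CL": 0.111, "Vc": 0.0270, "Vp": 0.595**2},
        {("CL", "Vc"): 0.0172},
    )
    return PopulationModel.from_typical(
        {"Vmax": 4.03, "Km": 5.63, "CL": 0.275, "Vc": 3.38, "Q": 0.953, "Vp": 2.78},
        omega,
        sigma=0.145,
        covariate_effects=(
            CovariateEffect("CL", "WT", 0.703, "power", reference=64.0),
            CovariateEffect("Vc", "WT", 0.499, "power", reference=64.0),
        ),
    )
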