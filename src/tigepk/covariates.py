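"""Covariate models and the published tigecycline final model.

Covariate-parameter relations come in four continuous families plus one
categorical family, each normalized by the cohort median of the covariate:

    linear       theta_i = theta_pop + theta_cov * (cov / median)
    exponential  theta_i = theta_pop * exp(theta_cov * cov / median)
    power        theta_i = theta_pop * (cov / median) ** theta_cov
    categorical  theta_i = theta_pop * theta_cov ** cov       (cov in {0, 1})

The published final model (critically ill adults, 98 subjects):

    CL (L/h) = 3.09 + (CCr / 77) * 3.28
    V1 (L)   = 32.1 * (BW / 61) ** 1.95
    Q (L/h)  = 39.7 * (log10 GGT / 1.7) ** 0.956 * (log10 TBIL / 1.2) ** -0.912
    V2 (L)   = 113  * (BW / 61) ** 1.61 * (log10 ALB / 1.4) ** 4.52

with exponential (lognormal) interindividual variability on CL, V1 and Q
(omegas 27.0%, 72.5%, 18.8%, reported as 100*sqrt(variance)) and a 2.02%
proportional residual error.  The "log" in the liver-function terms is
base-10: the printed normalization constants 1.7, 1.2 and 1.4 are the
base-10 logs of the cohort median GGT, TBIL and ALB.  Normalization
constants are stored with the model, never recomputed from data, so
simulation from the published model is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from tigepk.structural import PKParameters

__all__ = [
    "CovariateRecord",
    "CovariateEffect",
    "VarianceModel",
    "cockcroft_gault",
    "apply_covariate",
    "final_model_typicals",
    "individualize",
    "omega_percent_to_sd",
    "omega_sd_to_percent",
    "FINAL_MODEL_THETAS",
    "FINAL_MODEL_OMEGAS",
    "FINAL_MODEL_SIGMA",
    "FINAL_MODEL_MEDIANS",
]

_FORMS = ("linear", "exponential", "power", "power_categorical")


@dataclass
class CovariateRecord:
    """Per-subject covariates measured on the day of concentration monitoring.

    Units: age years; BW kg; BMI kg/m^2; SCr, TBIL umol/L; CCr mL/min;
    ALB g/L; BUN mmol/L; ALT/AST/ALP/GGT U/L; WBC, PLT 1e9/L; RBC 1e12/L;
    daily_dose mg/day.  ``sex`` is "male"/"female".
    """

    age: float
    sex: str
    BW: float
    SCr: float
    ALB: float
    GGT: float
    TBIL: float
    CCr: float | None = None
    BMI: float | None = None
    BUN: float | None = None
    ALT: float | None = None
    AST: float | None = None
    ALP: float | None = None
    WBC: float | None = None
    RBC: float | None = None
    PLT: float | None = None
    daily_dose: float = 100.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "BW", "SCr", "ALB", "GGT", "TBIL"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"covariate {name} must be > 0, got {v}")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation.

    ``parameter`` is one of CL, V1, Q, V2; ``covariate`` names a dataset
    column (or CovariateRecord field); ``log10`` applies a base-10 log to
    the covariate before normalization (liver-function terms of the final
    model).  ``cov_median`` is the stored normalization constant.
    """

    parameter: str
    covariate: str
    form: str
    theta_cov: float
    cov_median: float = 1.0
    log10: bool = False

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}; one of {_FORMS}")
        if self.form != "power_categorical" and not self.cov_median > 0:
            raise ValueError("cov_median must be > 0 for continuous covariates")
        if self.parameter not in ("CL", "V1", "Q", "V2"):
            raise ValueError(f"unknown parameter {self.parameter!r}")


@dataclass
class VarianceModel:
    """Random-effect structure.

    ``omega`` maps parameter name -> interindividual SD on the log scale,
    reported in percent (100 * sqrt(variance), an approximate %CV);
    parameters without IIV carry 0 (V2 in the final model).  ``sigma`` is
    the residual SD, in percent of the prediction for proportional error,
    in mg/L for additive; the combined form carries both.
    """

    omega: dict[str, float] = field(default_factory=dict)
    sigma: float = 2.02
    residual_form: str = "proportional"
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_form not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual form {self.residual_form!r}")
        for k, v in self.omega.items():
            if v < 0:
                raise ValueError(f"omega[{k}] must be >= 0")
        if self.sigma < 0 or self.sigma_add < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def iiv_parameters(self) -> list[str]:
        """Parameters carrying nonzero interindividual variability, in order."""
        return [p for p in ("CL", "V1", "Q", "V2") if self.omega.get(p, 0.0) > 0]


def omega_percent_to_sd(pct: float) -> float:
    """Reported percent (100*sqrt(variance)) -> SD on the log scale."""
    return pct / 100.0


def omega_sd_to_percent(sd: float) -> float:
    return sd * 100.0


def cockcroft_gault(
    age: float,
    BW: float,
    SCr: float,
    sex: str,
    minimum: float = 1.0,
) -> float:
    """Cockcroft-Gault creatinine clearance, mL/min.

    ``SCr`` in umol/L (converted internally to mg/dL by /88.4).  Females
    get the 0.85 factor.  Ages at or beyond 140 years would make the
    formula non-positive; a warning is issued and the result floored at
    ``minimum``.
    """
    if not (age > 0 and BW > 0 and SCr > 0):
        raise ValueError("age, BW and SCr must be > 0")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    scr_mgdl = SCr / 88.4
    ccr = (140.0 - age) * BW / (72.0 * scr_mgdl)
    if sex == "female":
        ccr *= 0.85
    if age >= 140 or ccr < minimum:
        warnings.warn(
            f"Cockcroft-Gault gave {ccr:.3g} mL/min (age {age}); floored at {minimum}",
            stacklevel=2,
        )
        ccr = minimum
    return ccr


def apply_covariate(
    form: str,
    theta_pop: float,
    theta_cov: float,
    cov_value: float,
    cov_median: float = 1.0,
) -> float:
    """Individual typical parameter under one covariate relation.

    See module docstring for the four families.  For the categorical form,
    ``cov_value`` must be 0 or 1 and ``cov_median`` is ignored.
    """
    if form == "linear":
        return theta_pop + theta_cov * (cov_value / cov_median)
    if form == "exponential":
        return theta_pop * math.exp(theta_cov * cov_value / cov_median)
    if form == "power":
        return theta_pop * (cov_value / cov_median) ** theta_cov
    if form == "power_categorical":
        if cov_value not in (0, 1):
            raise ValueError(f"categorical covariate must be 0 or 1, got {cov_value}")
        return theta_pop * theta_cov**cov_value
    raise ValueError(f"unknown covariate form {form!r}; one of {_FORMS}")


# Published final-model constants (typical values, covariate effects,
# normalization medians, variance components).
FINAL_MODEL_THETAS: dict[str, float] = {
    "CL": 3.09,
    "V1": 32.1,
    "Q": 39.7,
    "V2": 113.0,
    "CCR_CL": 3.28,
    "BW_V1": 1.95,
    "GGT_Q": 0.956,
    "TBIL_Q": -0.912,
    "BW_V2": 1.61,
    "ALB_V2": 4.52,
}
FINAL_MODEL_MEDIANS: dict[str, float] = {
    "CCR": 77.0,
    "BW": 61.0,
    "log10GGT": 1.7,
    "log10TBIL": 1.2,
    "log10ALB": 1.4,
}
FINAL_MODEL_OMEGAS: dict[str, float] = {"CL": 27.0, "V1": 72.5, "Q": 18.8, "V2": 0.0}
FINAL_MODEL_SIGMA: float = 2.02  # % proportional


def _log10_checked(value: float, name: str) -> float:
    lg = math.log10(value) if value > 0 else float("-inf")
    if not lg > 0:
        raise ValueError(
            f"covariate {name}={value} has log10 <= 0; the final model's "
            "power terms require log10 of the covariate to be positive"
        )
    return lg


def final_model_typicals(cov: CovariateRecord) -> PKParameters:
    """Typical (population-predicted) parameters for one subject.

    Evaluates the published final-model equations at the subject's CCr, BW,
    GGT, TBIL and ALB.  CCr must be present on the record (derive it with
    :func:`cockcroft_gault` if needed).
    """
    if cov.CCr is None or not cov.CCr > 0:
        raise ValueError("CovariateRecord.CCr must be present and > 0")
    th = FINAL_MODEL_THETAS
    md = FINAL_MODEL_MEDIANS
    cl = apply_covariate("linear", th["CL"], th["CCR_CL"], cov.CCr, md["CCR"])
    v1 = apply_covariate("power", th["V1"], th["BW_V1"], cov.BW, md["BW"])
    q = apply_covariate(
        "power", th["Q"], th["GGT_Q"], _log10_checked(cov.GGT, "GGT"), md["log10GGT"]
    )
    q = apply_covariate(
        "power", q, th["TBIL_Q"], _log10_checked(cov.TBIL, "TBIL"), md["log10TBIL"]
    )
    v2 = apply_covariate("power", th["V2"], th["BW_V2"], cov.BW, md["BW"])
    v2 = apply_covariate(
        "power", v2, th["ALB_V2"], _log10_checked(cov.ALB, "ALB"), md["log10ALB"]
    )
    return PKParameters(CL=cl, V1=v1, Q=q, V2=v2)


def individualize(typicals: PKParameters, eta: dict[str, float]) -> PKParameters:
    """Apply exponential interindividual variability: param_i = typical * exp(eta).

    Parameters absent from ``eta`` get eta = 0.  Positivity is preserved for
    any finite eta.
    """
    vals = {}
    for name in ("CL", "V1", "Q", "V2"):
        e = eta.get(name, 0.0)
        if not math.isfinite(e):
            raise ValueError(f"eta[{name}] must be finite")
        vals[name] = getattr(typicals, name) * math.exp(e)
    return PKParameters(**vals)
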