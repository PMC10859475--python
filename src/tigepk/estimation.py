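"""Nonlinear mixed-effects estimation for the population PK model.

The marginal likelihood is approximated by a Laplace expansion at each
subject's conditional random-effect mode, with the residual variance
evaluated at individual predictions (the "interaction" convention) and the
curvature taken from the first-order (Gauss-Newton) linearization — the
closest re-implementable analogue of FOCE-I.  Exact numerical equality
with NONMEM is not claimed.

For subject i with random effects eta, the conditional -2 log-likelihood is

    g(eta) = sum_j [ ln 2pi + ln var_j + (y_j - f_j)^2 / var_j ]
             + eta' Omega^-1 eta + ln det(2 pi Omega)

with f_j the model prediction at the individualized parameters
(typical * exp(eta)) and var_j the residual variance (sigma^2 f^2 for the
proportional error of the final model).  The objective function value is

    OFV = sum_i [ g(eta_i^) - k ln 2pi + ln det(H_i / 2) ]

where eta_i^ minimizes g and H_i is the positive-definite FOCE curvature
2 J' W J + 2 Omega^-1 (J = df/deta at the mode, W = 1/var).  In the
Omega -> 0 limit this reduces exactly to the fixed-effects -2 log-likelihood.

Model comparison uses OFV differences against chi-square quantiles
(3.84 for p<0.05 in forward inclusion, 10.83 for p<0.001 in backward
elimination) and AIC = OFV + 2 * n_estimated_parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from tigepk.covariates import CovariateEffect, VarianceModel

__all__ = [
    "ModelSpec",
    "FitResult",
    "EstimationError",
    "final_model_spec",
    "base_model_spec",
    "neg2ll_subject",
    "ofv",
    "fit",
    "forward_inclusion",
    "backward_elimination",
    "correlation_screen",
]

_LN2PI = math.log(2.0 * math.pi)
_PRED_FLOOR = 1e-10  # mg/L floor under proportional error
_STRUCT_2CPT = ("CL", "V1", "Q", "V2")
_STRUCT_1CPT = ("CL", "V1")


class EstimationError(RuntimeError):
    """Estimation failure (inner mode search or dataset problem)."""


@dataclass
class ModelSpec:
    """Structural + covariate + variance model definition.

    ``fixed_initials`` holds starting typical values per structural
    parameter; covariate effects carry their own starting ``theta_cov``.
    Covariate names refer to dataset columns (WT, CCR, GGT, ...).
    """

    n_compartments: int = 2
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    variance: VarianceModel = field(default_factory=lambda: VarianceModel())
    fixed_initials: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        seen = set()
        for e in self.covariate_effects:
            if e.parameter not in self.structural_parameters:
                raise ValueError(
                    f"covariate effect on {e.parameter} not in a "
                    f"{self.n_compartments}-compartment model"
                )
            key = (e.parameter, e.covariate)
            if key in seen:
                raise ValueError(f"duplicated covariate effect {key}")
            seen.add(key)
        for p in self.variance.iiv_parameters:
            if p not in self.structural_parameters:
                raise ValueError(f"IIV on unknown parameter {p}")

    @property
    def structural_parameters(self) -> tuple[str, ...]:
        return _STRUCT_2CPT if self.n_compartments == 2 else _STRUCT_1CPT

    def effect_name(self, e: CovariateEffect) -> str:
        return f"{e.covariate}_{e.parameter}"

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + [effect])

    def without_effect(self, parameter: str, covariate: str) -> "ModelSpec":
        kept = [
            e
            for e in self.covariate_effects
            if not (e.parameter == parameter and e.covariate == covariate)
        ]
        if len(kept) == len(self.covariate_effects):
            raise ValueError(f"no effect ({parameter}, {covariate}) in model")
        return replace(self, covariate_effects=kept)

    def n_estimated(self) -> int:
        n = len(self.structural_parameters) + len(self.covariate_effects)
        n += len(self.variance.iiv_parameters)
        n += 2 if self.variance.residual_form == "combined" else 1
        return n


def final_model_spec() -> ModelSpec:
    """The published final model with Table-2 estimates as initial values."""
    from tigepk.covariates import (
        FINAL_MODEL_MEDIANS as MD,
        FINAL_MODEL_OMEGAS,
        FINAL_MODEL_SIGMA,
        FINAL_MODEL_THETAS as TH,
    )

    effects = [
        CovariateEffect("CL", "CCR", "linear", TH["CCR_CL"], MD["CCR"]),
        CovariateEffect("V1", "WT", "power", TH["BW_V1"], MD["BW"]),
        CovariateEffect("Q", "GGT", "power", TH["GGT_Q"], MD["log10GGT"], log10=True),
        CovariateEffect("Q", "TBIL", "power", TH["TBIL_Q"], MD["log10TBIL"], log10=True),
        CovariateEffect("V2", "WT", "power", TH["BW_V2"], MD["BW"]),
        CovariateEffect("V2", "ALB", "power", TH["ALB_V2"], MD["log10ALB"], log10=True),
    ]
    variance = VarianceModel(
        omega={p: FINAL_MODEL_OMEGAS[p] for p in ("CL", "V1", "Q") },
        sigma=FINAL_MODEL_SIGMA,
        residual_form="proportional",
    )
    return ModelSpec(
        n_compartments=2,
        covariate_effects=effects,
        variance=variance,
        fixed_initials={"CL": TH["CL"], "V1": TH["V1"], "Q": TH["Q"], "V2": TH["V2"]},
    )


def base_model_spec(n_compartments: int = 2) -> ModelSpec:
    """Covariate-free base model (starting point for covariate selection)."""
    omega = {"CL": 30.0, "V1": 50.0} if n_compartments == 1 else {
        "CL": 30.0,
        "V1": 50.0,
        "Q": 20.0,
    }
    init = {"CL": 6.0, "V1": 32.0}
    if n_compartments == 2:
        init.update({"Q": 40.0, "V2": 110.0})
    return ModelSpec(
        n_compartments=n_compartments,
        covariate_effects=[],
        variance=VarianceModel(omega=omega, sigma=2.0, residual_form="proportional"),
        fixed_initials=init,
    )


# ------------------------------------------------------------- internals --


class _Problem:
    """Dataset unpacked into padded per-subject arrays + parameter packing."""

    def __init__(self, df: pd.DataFrame, spec: ModelSpec):
        from tigepk.io import validate_dataset

        validate_dataset(df)
        self.spec = spec
        self.struct = spec.structural_parameters
        self.iiv = spec.variance.iiv_parameters
        self.k = len(self.iiv)
        self.iiv_idx = [self.struct.index(p) for p in self.iiv]

        ids, dose_t, dose_rate, dose_dur, obs_t, obs_y = [], [], [], [], [], []
        covs: dict[str, list[float]] = {e.covariate: [] for e in spec.covariate_effects}
        for sid, g in df.groupby("ID", sort=False):
            d = g[g["EVID"] == 1]
            o = g[g["EVID"] == 0]
            if len(d) == 0:
                raise EstimationError(f"subject {sid} has no dose events")
            ids.append(sid)
            dose_t.append(d["TIME"].to_numpy(float))
            dose_rate.append(d["RATE"].to_numpy(float))
            dose_dur.append((d["AMT"] / d["RATE"]).to_numpy(float))
            obs_t.append(o["TIME"].to_numpy(float))
            obs_y.append(o["DV"].to_numpy(float))
            for c in covs:
                if c not in g.columns:
                    raise EstimationError(f"dataset missing covariate column {c}")
                covs[c].append(float(g[c].iloc[0]))
        self.ids = ids
        self.n = len(ids)
        D = max(len(x) for x in dose_t)
        M = max(len(x) for x in obs_t)
        self.n_obs_total = sum(len(x) for x in obs_t)

        def pad(lst, width, fill):
            out = np.full((self.n, width), fill, float)
            for i, x in enumerate(lst):
                out[i, : len(x)] = x
            return out

        # padded dose slots get rate 0 -> contribute nothing
        self.dose_t = pad(dose_t, D, 0.0)
        self.dose_rate = pad(dose_rate, D, 0.0)
        self.dose_dur = pad(dose_dur, D, 1.0)
        self.obs_t = pad(obs_t, M, 0.0)
        self.y = pad(obs_y, M, 0.0)
        self.obs_mask = np.zeros((self.n, M), bool)
        for i, x in enumerate(obs_t):
            self.obs_mask[i, : len(x)] = True
        self.cov_values = {}
        for e in spec.covariate_effects:
            v = np.asarray(covs[e.covariate], float)
            if e.log10:
                if np.any(v <= 1.0):
                    raise EstimationError(
                        f"covariate {e.covariate} has log10 <= 0 for some subject"
                    )
                v = np.log10(v)
            self.cov_values[spec.effect_name(e)] = v
        self._eta = np.zeros((self.n, self.k))
        self.inner_flagged: list = []

    # -- parameter packing: [log tv..., theta_cov..., log omega_sd..., log sigma(s)]

    def pack_initial(self) -> np.ndarray:
        s = self.spec
        x = [math.log(s.fixed_initials[p]) for p in self.struct]
        x += [e.theta_cov for e in s.covariate_effects]
        x += [math.log(s.variance.omega[p] / 100.0) for p in self.iiv]
        if s.variance.residual_form in ("proportional", "combined"):
            x.append(math.log(max(s.variance.sigma / 100.0, 1e-12)))
        if s.variance.residual_form in ("additive", "combined"):
            x.append(math.log(max(s.variance.sigma_add, 1e-12)))
        return np.asarray(x, float)

    def unpack(self, x: np.ndarray):
        ns = len(self.struct)
        ne = len(self.spec.covariate_effects)
        tv = np.exp(x[:ns])
        thetas = x[ns : ns + ne]
        om = np.exp(x[ns + ne : ns + ne + self.k])
        i = ns + ne + self.k
        form = self.spec.variance.residual_form
        sig_p = sig_a = 0.0
        if form in ("proportional", "combined"):
            sig_p = math.exp(x[i])
            i += 1
        if form in ("additive", "combined"):
            sig_a = math.exp(x[i])
        return tv, thetas, om, sig_p, sig_a

    def param_names(self) -> list[str]:
        s = self.spec
        names = list(self.struct)
        names += [s.effect_name(e) for e in s.covariate_effects]
        names += [f"omega_{p}" for p in self.iiv]
        if s.variance.residual_form in ("proportional", "combined"):
            names.append("sigma")
        if s.variance.residual_form in ("additive", "combined"):
            names.append("sigma_add")
        return names

    def typicals(self, tv: np.ndarray, thetas: np.ndarray) -> np.ndarray:
        """Per-subject typical values, shape (n, n_struct)."""
        add = np.zeros((self.n, len(self.struct)))
        mult = np.ones((self.n, len(self.struct)))
        for e, th in zip(self.spec.covariate_effects, thetas):
            j = self.struct.index(e.parameter)
            z = self.cov_values[self.spec.effect_name(e)] / e.cov_median
            if e.form == "linear":
                add[:, j] += th * z
            elif e.form == "exponential":
                mult[:, j] *= np.exp(th * z)
            elif e.form == "power":
                mult[:, j] *= z**th
            elif e.form == "power_categorical":
                mult[:, j] *= th ** (z * e.cov_median)  # raw 0/1 value
        typ = (tv[None, :] + add) * mult
        return np.maximum(typ, 1e-6)

    def conc(self, params: np.ndarray) -> np.ndarray:
        """Batched concentration at obs times; params shape (n, n_struct).

        Extreme trial parameters may produce non-finite values; callers
        treat those as an infinite-objective penalty.
        """
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            return self._conc_impl(params)

    def _conc_impl(self, params: np.ndarray) -> np.ndarray:
        CL, V1 = params[:, 0], params[:, 1]
        tau = self.obs_t[:, :, None] - self.dose_t[:, None, :]
        dur = self.dose_dur[:, None, :]
        rate = self.dose_rate[:, None, :]
        if len(self.struct) == 4:
            Q, V2 = params[:, 2], params[:, 3]
            k10 = CL / V1
            k12 = Q / V1
            k21 = Q / V2
            s = k10 + k12 + k21
            disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
            al = 0.5 * (s + disc)
            be = 0.5 * (s - disc)
            A = (al - k21) / (al - be)
            B = (k21 - be) / (al - be)
            cA = (A / (al * V1))[:, None, None]
            cB = (B / (be * V1))[:, None, None]
            al = al[:, None, None]
            be = be[:, None, None]
            tpos = np.maximum(tau, 0.0)
            teff = np.minimum(tpos, dur)  # infusion time elapsed
            trem = tpos - teff  # time since end of infusion
            c = rate * (
                cA * (1.0 - np.exp(-al * teff)) * np.exp(-al * trem)
                + cB * (1.0 - np.exp(-be * teff)) * np.exp(-be * trem)
            )
        else:
            k = (CL / V1)[:, None, None]
            tpos = np.maximum(tau, 0.0)
            teff = np.minimum(tpos, dur)
            trem = tpos - teff
            c = rate / CL[:, None, None] * (1.0 - np.exp(-k * teff)) * np.exp(-k * trem)
        return c.sum(axis=2)

    def _resvar(self, f: np.ndarray, sig_p: float, sig_a: float) -> np.ndarray:
        v = self.spec.variance.residual_form
        if v == "proportional":
            return sig_p**2 * f**2
        if v == "additive":
            return np.full_like(f, sig_a**2)
        return sig_a**2 + sig_p**2 * f**2

    def g(self, etas, typ, om, sig_p, sig_a) -> np.ndarray:
        """Conditional -2 log-likelihood per subject (vector of length n)."""
        params = typ.copy()
        if self.k:
            params[:, self.iiv_idx] = params[:, self.iiv_idx] * np.exp(etas)
        f = np.maximum(self.conc(params), _PRED_FLOOR)
        var = self._resvar(f, sig_p, sig_a)
        r = self.y - f
        t = _LN2PI + np.log(var) + r * r / var
        data = np.where(self.obs_mask, t, 0.0).sum(axis=1)
        if self.k:
            prior = (etas**2 / om[None, :] ** 2).sum(axis=1)
            prior += self.k * _LN2PI + 2.0 * np.log(om).sum()
            data = data + prior
        return data

    def _inner(self, typ, om, sig_p, sig_a, tol=1e-7, max_iter=60):
        """Batched Newton search for the conditional eta modes.

        Returns (etas, g_at_mode, logdet(H/2)) with H the FOCE curvature.
        """
        n, k = self.n, self.k
        self.inner_flagged = []
        if k == 0:
            g0 = self.g(np.zeros((n, 0)), typ, om, sig_p, sig_a)
            return np.zeros((n, 0)), g0, np.zeros(n)
        etas = self._eta.copy()
        h = 1e-5
        inv_om2 = 1.0 / om**2

        def predict(e):
            params = typ.copy()
            params[:, self.iiv_idx] = params[:, self.iiv_idx] * np.exp(e)
            return np.maximum(self.conc(params), _PRED_FLOOR)

        gcur = self.g(etas, typ, om, sig_p, sig_a)
        H = None
        for _ in range(max_iter):
            f = predict(etas)
            var = self._resvar(f, sig_p, sig_a)
            r = self.y - f
            # J = df/deta via central differences, shape (n, M, k)
            J = np.empty(f.shape + (k,))
            for j in range(k):
                step = np.zeros((n, k))
                step[:, j] = h
                J[:, :, j] = (predict(etas + step) - predict(etas - step)) / (2 * h)
            dvar = (
                2.0 * sig_p**2 * f
                if self.spec.variance.residual_form != "additive"
                else np.zeros_like(f)
            )
            dt = dvar / var - 2.0 * r / var - r * r * dvar / var**2
            w = np.where(self.obs_mask, 1.0, 0.0)
            grad = np.einsum("nm,nmk->nk", dt * w, J) + 2.0 * etas * inv_om2[None, :]
            Jw = J * (w / var)[:, :, None]
            H = 2.0 * np.einsum("nmj,nmk->njk", Jw, J)
            H[:, np.arange(k), np.arange(k)] += 2.0 * inv_om2[None, :]
            gmax = np.abs(grad).max(axis=1)
            active = gmax > tol
            if not active.any():
                break
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            alpha = np.ones(n)
            for _ls in range(12):
                trial = etas - alpha[:, None] * step * active[:, None]
                gtrial = self.g(trial, typ, om, sig_p, sig_a)
                worse = active & (gtrial > gcur + 1e-12)
                if not worse.any():
                    etas, gcur = trial, gtrial
                    break
                alpha[worse] *= 0.5
            else:
                improved = active & (gtrial <= gcur)
                etas = np.where(improved[:, None], trial, etas)
                gcur = np.where(improved, gtrial, gcur)
                break
        else:
            bad = np.abs(grad).max(axis=1) > 1e-4
            self.inner_flagged = [self.ids[i] for i in np.nonzero(bad)[0]]
        self._eta = etas.copy()
        # FOCE curvature at the mode for the Laplace determinant term
        f = predict(etas)
        var = self._resvar(f, sig_p, sig_a)
        J = np.empty(f.shape + (k,))
        for j in range(k):
            step = np.zeros((n, k))
            step[:, j] = h
            J[:, :, j] = (predict(etas + step) - predict(etas - step)) / (2 * h)
        w = np.where(self.obs_mask, 1.0, 0.0)
        Jw = J * (w / var)[:, :, None]
        H = 2.0 * np.einsum("nmj,nmk->njk", Jw, J)
        H[:, np.arange(k), np.arange(k)] += 2.0 * inv_om2[None, :]
        sign, logdet = np.linalg.slogdet(H / 2.0)
        if np.any(sign <= 0):
            raise EstimationError("non-positive-definite conditional curvature")
        gmode = self.g(etas, typ, om, sig_p, sig_a)
        return etas, gmode, logdet

    def ofv_terms(self, x: np.ndarray) -> np.ndarray:
        tv, thetas, om, sig_p, sig_a = self.unpack(x)
        typ = self.typicals(tv, thetas)
        etas, gmode, logdet = self._inner(typ, om, sig_p, sig_a)
        return gmode - self.k * _LN2PI + logdet

    def ofv_x(self, x: np.ndarray) -> float:
        try:
            val = float(self.ofv_terms(x).sum())
        except (FloatingPointError, np.linalg.LinAlgError, EstimationError):
            return 1e12
        if not math.isfinite(val):
            return 1e12
        return val


# ----------------------------------------------------------- public API --


def _apply_overrides(prob: _Problem, x: np.ndarray, fixed_effects: dict[str, float]):
    """Override packed parameters by public name (omega/sigma given in %)."""
    names = prob.param_names()
    for name, val in fixed_effects.items():
        if name not in names:
            raise KeyError(f"unknown parameter {name}")
        i = names.index(name)
        if name in prob.struct:
            x[i] = math.log(val)
        elif name.startswith("omega_") or name == "sigma":
            x[i] = math.log(val / 100.0)
        elif name == "sigma_add":
            x[i] = math.log(val)
        else:
            x[i] = val
    return x


def neg2ll_subject(
    subject_df: pd.DataFrame,
    spec: ModelSpec,
    fixed_effects: dict[str, float] | None = None,
    eta: np.ndarray | dict[str, float] | None = None,
) -> float:
    """Conditional -2 log-likelihood contribution of one subject.

    ``fixed_effects`` overrides entries of the spec's initial values (by
    parameter/effect name); ``eta`` gives the random effects for the
    subject's IIV parameters (vector in IIV order, or dict by name;
    default 0).  Includes the eta prior term eta' Omega^-1 eta +
    ln det(2 pi Omega).
    """
    if (subject_df["EVID"] == 0).sum() < 1:
        raise EstimationError("subject has no observations")
    prob = _Problem(subject_df, spec)
    x = prob.pack_initial()
    if fixed_effects:
        x = _apply_overrides(prob, x, fixed_effects)
    tv, thetas, om, sig_p, sig_a = prob.unpack(x)
    typ = prob.typicals(tv, thetas)
    if eta is None:
        e = np.zeros((1, prob.k))
    elif isinstance(eta, dict):
        e = np.array([[eta.get(p, 0.0) for p in prob.iiv]])
    else:
        e = np.asarray(eta, float).reshape(1, prob.k)
    return float(prob.g(e, typ, om, sig_p, sig_a)[0])


def ofv(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    fixed_effects: dict[str, float] | None = None,
) -> float:
    """FOCE-type objective function value at given parameters.

    Deterministic given data and parameters: each subject's eta is taken at
    its conditional mode.  Raises EstimationError (with the flagged subject
    ids) if any inner mode search fails to converge.
    """
    prob = _Problem(dataset, spec)
    x = prob.pack_initial()
    if fixed_effects:
        x = _apply_overrides(prob, x, fixed_effects)
    val = float(prob.ofv_terms(x).sum())
    if prob.inner_flagged:
        raise EstimationError(
            f"inner eta search did not converge for subjects {prob.inner_flagged}"
        )
    return val


@dataclass
class FitResult:
    """Estimates and diagnostics from one mixed-effects fit.

    ``estimates`` maps parameter names (CL, V1, ..., CCR_CL, ...,
    omega_CL [%], sigma [%]) to values; ``rse`` holds relative standard
    errors in percent where computed.  AIC = OFV + 2 * n_parameters.
    """

    estimates: dict[str, float]
    rse: dict[str, float] | None
    ofv: float
    aic: float
    n_parameters: int
    ebes: pd.DataFrame
    converged: bool
    message: str
    spec: ModelSpec
    n_subjects: int
    n_observations: int

    def fitted_spec(self) -> ModelSpec:
        """The model spec with initial values replaced by the estimates."""
        s = self.spec
        initials = {p: self.estimates[p] for p in s.structural_parameters}
        effects = [
            replace(e, theta_cov=self.estimates[s.effect_name(e)])
            for e in s.covariate_effects
        ]
        omega = dict(s.variance.omega)
        for p in s.variance.iiv_parameters:
            omega[p] = self.estimates[f"omega_{p}"]
        variance = replace(
            s.variance,
            omega=omega,
            sigma=self.estimates.get("sigma", s.variance.sigma),
            sigma_add=self.estimates.get("sigma_add", s.variance.sigma_add),
        )
        return replace(
            s, covariate_effects=effects, variance=variance, fixed_initials=initials
        )


def _se_from_scores(prob: _Problem, xopt: np.ndarray, step: float = 1e-3):
    """Delta-method SEs from the cross-product of per-subject scores (BHHH).

    The observed information is approximated by sum_i s_i s_i' with
    s_i = d(log L_i)/d theta = -d(OFV_i)/d theta / 2, the per-subject score
    obtained by central differences of the subject-level OFV contributions.
    Positive-semidefinite by construction, hence robust to the small
    numerical noise of the inner mode search.
    """
    p = len(xopt)
    scores = np.zeros((prob.n, p))
    for j in range(p):
        xp = xopt.copy()
        xp[j] += step
        tp = prob.ofv_terms(xp)
        xm = xopt.copy()
        xm[j] -= step
        tm = prob.ofv_terms(xm)
        scores[:, j] = -(tp - tm) / (4.0 * step)  # d(logL_i)/dx_j
    info = scores.T @ scores
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def fit(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    compute_se: bool = True,
    maxiter: int = 400,
    gtol: float = 1e-4,
    ftol: float = 1e-8,
    eps: float = 1e-5,
) -> FitResult:
    """Estimate fixed effects and variance components by minimizing the OFV.

    Quasi-Newton (L-BFGS-B) on log-transformed positive parameters with
    numerical gradients; the inner eta modes are found by damped Newton
    iterations, warm-started across outer iterations.  Never raises on
    optimizer failure: a non-converged FitResult carries the diagnostics.
    """
    prob = _Problem(dataset, spec)
    x0 = prob.pack_initial()
    res = optimize.minimize(
        prob.ofv_x,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "eps": eps},
    )
    xopt = res.x
    final_ofv = prob.ofv_x(xopt)  # refresh eta cache at the optimum
    tv, thetas, om, sig_p, sig_a = prob.unpack(xopt)
    names = prob.param_names()
    values = list(tv) + list(thetas) + list(om * 100.0)
    if spec.variance.residual_form in ("proportional", "combined"):
        values.append(sig_p * 100.0)
    if spec.variance.residual_form in ("additive", "combined"):
        values.append(sig_a)
    estimates = dict(zip(names, [float(v) for v in values]))

    rse = None
    if compute_se:
        se_x = _se_from_scores(prob, xopt)
        if se_x is not None:
            rse = {}
            ns, ne = len(prob.struct), len(spec.covariate_effects)
            for i, name in enumerate(names):
                est = estimates[name]
                if ns <= i < ns + ne:  # untransformed covariate thetas
                    se_val = se_x[i]
                else:  # log-transformed: SE on value = value * SE on log
                    se_val = abs(est) * se_x[i]
                rse[name] = float(100.0 * se_val / abs(est)) if est != 0 else float("nan")

    npar = spec.n_estimated()
    ebes = pd.DataFrame(prob._eta, columns=[f"eta_{p}" for p in prob.iiv])
    ebes.insert(0, "ID", prob.ids)
    converged = bool(res.success) and not prob.inner_flagged and final_ofv < 1e11
    return FitResult(
        estimates=estimates,
        rse=rse,
        ofv=float(final_ofv),
        aic=float(final_ofv + 2 * npar),
        n_parameters=npar,
        ebes=ebes,
        converged=converged,
        message=str(res.message),
        spec=spec,
        n_subjects=prob.n,
        n_observations=prob.n_obs_total,
    )


# ------------------------------------------------- stepwise covariate search --


def correlation_screen(
    dataset: pd.DataFrame, covariates: list[str], cutoff: float = 0.5
) -> list[tuple[str, str, float]]:
    """Pairwise Spearman pre-screen over per-subject covariate values.

    Returns the pairs with |rho| > cutoff; both members of a flagged pair
    should not co-enter the candidate set.
    """
    per_subject = dataset.groupby("ID", sort=False)[covariates].first()
    flagged = []
    for i, a in enumerate(covariates):
        for b in covariates[i + 1 :]:
            rho = stats.spearmanr(per_subject[a], per_subject[b]).statistic
            if abs(rho) > cutoff:
                flagged.append((a, b, float(rho)))
    return flagged


def forward_inclusion(
    dataset: pd.DataFrame,
    base: ModelSpec,
    candidates: list[CovariateEffect],
    threshold: float = 3.84,
    fitter=None,
    fit_kwargs: dict | None = None,
):
    """Greedy forward covariate inclusion by OFV drop.

    At each step every remaining candidate is added to the current model and
    refit; the candidate with the largest OFV decrease among those with a
    decrease >= ``threshold`` (the chi-square 3.84 ~ p<0.05 convention) is
    kept.  Stops when no candidate qualifies.  Candidate fit failures are
    skipped and logged, never abort the search.  Ties go to the larger
    decrease, residual ties to candidate list order.

    Returns (selected ModelSpec with estimates, step log).
    """
    fitter = fitter or fit
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    log: list[dict] = []
    current = base
    current_fit = fitter(dataset, current, **fit_kwargs)
    current = current_fit.fitted_spec()
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        best = None
        for cand in remaining:
            trial = current.with_effect(cand)
            try:
                tf = fitter(dataset, trial, **fit_kwargs)
                delta = current_fit.ofv - tf.ofv
                ok = tf.converged
            except Exception as exc:  # candidate failure: skip, keep searching
                log.append(
                    {
                        "step": step,
                        "action": "forward",
                        "candidate": current.effect_name(cand),
                        "delta_ofv": None,
                        "included": False,
                        "error": str(exc),
                    }
                )
                continue
            log.append(
                {
                    "step": step,
                    "action": "forward",
                    "candidate": current.effect_name(cand),
                    "delta_ofv": float(delta),
                    "included": False,
                    "error": None if ok else tf.message,
                }
            )
            if delta >= threshold and (best is None or delta > best[0]):
                best = (delta, cand, tf)
        if best is None:
            break
        delta, cand, tf = best
        for entry in log:
            if entry["step"] == step and entry["candidate"] == current.effect_name(cand):
                entry["included"] = True
        current_fit = tf
        current = tf.fitted_spec()
        remaining = [c for c in remaining if c is not cand]
    return current, log


def backward_elimination(
    dataset: pd.DataFrame,
    full: ModelSpec,
    threshold: float = 10.83,
    fitter=None,
    fit_kwargs: dict | None = None,
):
    """Backward elimination: retain an effect only if its removal raises OFV
    by strictly more than ``threshold`` (chi-square 10.83 ~ p<0.001).

    Iteratively removes the effect whose removal costs least, whenever that
    cost is <= threshold.  Returns (final ModelSpec with estimates, step log).
    """
    fitter = fitter or fit
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    log: list[dict] = []
    current_fit = fitter(dataset, full, **fit_kwargs)
    current = current_fit.fitted_spec()
    step = 0
    while current.covariate_effects:
        step += 1
        worst = None
        for e in current.covariate_effects:
            reduced = current.without_effect(e.parameter, e.covariate)
            try:
                rf = fitter(dataset, reduced, **fit_kwargs)
                increase = rf.ofv - current_fit.ofv
            except Exception as exc:
                log.append(
                    {
                        "step": step,
                        "action": "backward",
                        "candidate": current.effect_name(e),
                        "delta_ofv": None,
                        "removed": False,
                        "error": str(exc),
                    }
                )
                continue
            log.append(
                {
                    "step": step,
                    "action": "backward",
                    "candidate": current.effect_name(e),
                    "delta_ofv": float(increase),
                    "removed": False,
                    "error": None,
                }
            )
            if increase <= threshold and (worst is None or increase < worst[0]):
                worst = (increase, e, rf)
        if worst is None:
            break
        increase, e, rf = worst
        for entry in log:
            if entry["step"] == step and entry["candidate"] == current.effect_name(e):
                entry["removed"] = True
        current_fit = rf
        current = rf.fitted_spec()
    return current, log
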