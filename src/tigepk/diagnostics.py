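"""Model evaluation: goodness-of-fit quantities, bootstrap, and VPC.

CWRES follows the FOCE linearization: with J = df/deta at the subject's
conditional mode eta^, the marginal mean is approximated by
f(eta^) - J eta^ and the marginal covariance by J Omega J' + diag(resvar),
the residual variance evaluated at the individual predictions
(interaction).  CWRES is the Cholesky-decorrelated residual, approximately
standard normal under a correctly specified model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tigepk.estimation import EstimationError, FitResult, ModelSpec, _Problem, fit

__all__ = ["gof_quantities", "bootstrap", "BootstrapSummary", "vpc", "VPCResult"]

NOMINAL_TAD_BINS = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 12.0)


def time_after_dose(dataset: pd.DataFrame) -> pd.Series:
    """TAD per observation row: time since the most recent dose event."""
    tad = pd.Series(np.nan, index=dataset.index)
    for sid, g in dataset.groupby("ID", sort=False):
        dose_times = g.loc[g["EVID"] == 1, "TIME"].to_numpy()
        for idx, t in g.loc[g["EVID"] == 0, "TIME"].items():
            prior = dose_times[dose_times <= t]
            if len(prior) == 0:
                raise EstimationError(
                    f"subject {sid}: observation at t={t} has no prior dose"
                )
            tad[idx] = t - prior.max()
    return tad[dataset["EVID"] == 0]


def _solve_modes(prob: _Problem, x: np.ndarray):
    tv, thetas, om, sig_p, sig_a = prob.unpack(x)
    typ = prob.typicals(tv, thetas)
    etas, _, _ = prob._inner(typ, om, sig_p, sig_a)
    return typ, om, sig_p, sig_a, etas


def gof_quantities(
    dataset: pd.DataFrame, result: FitResult | ModelSpec
) -> pd.DataFrame:
    """Per-observation PRED, IPRED, CWRES and TAD for a fitted model.

    PRED is the population prediction (eta = 0); IPRED the prediction at
    the subject's empirical Bayes eta; CWRES the FOCE-linearized,
    decorrelated residual.  ``result`` may be a converged FitResult or a
    ModelSpec evaluated at its stored parameter values.
    """
    if isinstance(result, ModelSpec):
        spec = result
    else:
        if not result.converged:
            raise EstimationError("goodness-of-fit requires a converged fit")
        spec = result.fitted_spec()
    prob = _Problem(dataset, spec)
    x = prob.pack_initial()
    typ, om, sig_p, sig_a, etas = _solve_modes(prob, x)

    def predict(e):
        params = typ.copy()
        if prob.k:
            params[:, prob.iiv_idx] = params[:, prob.iiv_idx] * np.exp(e)
        return np.maximum(prob.conc(params), 1e-10)

    pred = predict(np.zeros_like(etas))
    ipred = predict(etas)
    var = prob._resvar(ipred, sig_p, sig_a)

    k = prob.k
    cwres = np.zeros_like(pred)
    if k:
        h = 1e-5
        J = np.empty(ipred.shape + (k,))
        for j in range(k):
            step = np.zeros((prob.n, k))
            step[:, j] = h
            J[:, :, j] = (predict(etas + step) - predict(etas - step)) / (2 * h)
        Om = np.diag(om**2)
        for i in range(prob.n):
            m = prob.obs_mask[i]
            Ji = J[i][m]
            mean = ipred[i][m] - Ji @ etas[i]
            cov = Ji @ Om @ Ji.T + np.diag(var[i][m])
            L = np.linalg.cholesky(cov)
            cwres[i][m] = np.linalg.solve(L, prob.y[i][m] - mean)
    else:
        cwres = (prob.y - pred) / np.sqrt(var)

    rows = []
    tad = time_after_dose(dataset)
    obs = dataset[dataset["EVID"] == 0]
    by_id = {sid: 0 for sid in prob.ids}
    id_index = {sid: i for i, sid in enumerate(prob.ids)}
    for idx, row in obs.iterrows():
        i = id_index[row["ID"]]
        j = by_id[row["ID"]]
        by_id[row["ID"]] += 1
        rows.append(
            {
                "ID": row["ID"],
                "TIME": row["TIME"],
                "TAD": tad[idx],
                "DV": row["DV"],
                "PRED": pred[i, j],
                "IPRED": ipred[i, j],
                "CWRES": cwres[i, j],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BootstrapSummary:
    """Median and 2.5/97.5 percentiles of re-estimated parameters.

    ``reliable`` is False when more than 20% of the requested refits failed.
    """

    table: pd.DataFrame  # index: parameter; columns: median, p2.5, p97.5
    n_success: int
    n_requested: int
    reliable: bool
    samples: pd.DataFrame  # one row of estimates per successful resample


def bootstrap(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    n_resamples: int = 1000,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap: whole-subject resampling with replacement.

    Each resample draws the original number of subjects, reassigns
    sequential IDs, and refits ``spec``.  Failed refits are excluded and
    counted.  Bit-reproducible under ``seed``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    rng = np.random.default_rng(seed)
    subjects = {sid: g for sid, g in dataset.groupby("ID", sort=False)}
    ids = list(subjects)
    rows = []
    n_fail = 0
    for _ in range(n_resamples):
        draw = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(draw, start=1):
            g = subjects[sid].copy()
            g["ID"] = new_id
            parts.append(g)
        boot_df = pd.concat(parts, ignore_index=True)
        try:
            r = fit(boot_df, spec, **fit_kwargs)
            if not r.converged:
                raise EstimationError(r.message)
            rows.append(r.estimates)
        except Exception:
            n_fail += 1
    samples = pd.DataFrame(rows)
    if samples.empty:
        raise EstimationError("all bootstrap refits failed")
    table = pd.DataFrame(
        {
            "median": samples.median(),
            "p2.5": samples.quantile(0.025),
            "p97.5": samples.quantile(0.975),
        }
    )
    n_success = len(samples)
    return BootstrapSummary(
        table=table,
        n_success=n_success,
        n_requested=n_resamples,
        reliable=(n_fail <= 0.2 * n_resamples),
        samples=samples,
    )


@dataclass
class VPCResult:
    """Observed percentiles per time bin with simulation-based envelopes.

    ``table`` has one row per bin: bin midpoint (nominal TAD), number of
    observations, observed 5th/50th/95th percentiles, and the 2.5-97.5
    percentile envelope of each of those percentiles across simulated
    replicates.  Concentrations are computed on the raw scale; plot on a
    log axis.
    """

    table: pd.DataFrame
    n_replicates: int


def vpc(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    n_replicates: int = 1000,
    seed: int = 0,
    bins: tuple[float, ...] = NOMINAL_TAD_BINS,
) -> VPCResult:
    """Visual-predictive-check computation.

    Simulates ``n_replicates`` datasets under the study design (same
    subjects, doses, times and covariates), with eta ~ N(0, Omega) and the
    residual model of ``spec``; per replicate computes the 5th/50th/95th
    concentration percentile per bin, then the 2.5-97.5 envelope of each
    percentile across replicates.  Observations are assigned to the nearest
    nominal bin time (default: the eight nominal sampling times of the
    intensive design).  Empty bins are dropped with a warning.
    """
    prob = _Problem(dataset, spec)
    x = prob.pack_initial()
    tv, thetas, om, sig_p, sig_a = prob.unpack(x)
    typ = prob.typicals(tv, thetas)
    rng = np.random.default_rng(seed)

    tad = time_after_dose(dataset).to_numpy()
    obs_dv = dataset.loc[dataset["EVID"] == 0, "DV"].to_numpy()
    bin_arr = np.asarray(bins, float)
    assign = np.abs(tad[:, None] - bin_arr[None, :]).argmin(axis=1)

    flat_mask = prob.obs_mask.ravel()

    def percentiles(values: np.ndarray) -> np.ndarray:
        out = np.full((len(bin_arr), 3), np.nan)
        for b in range(len(bin_arr)):
            sel = values[assign == b]
            if len(sel):
                out[b] = np.percentile(sel, [5, 50, 95])
        return out

    obs_pct = percentiles(obs_dv)

    sim_pct = np.empty((n_replicates, len(bin_arr), 3))
    for r in range(n_replicates):
        etas = rng.standard_normal((prob.n, prob.k)) * om[None, :]
        params = typ.copy()
        if prob.k:
            params[:, prob.iiv_idx] = params[:, prob.iiv_idx] * np.exp(etas)
        f = np.maximum(prob.conc(params), 1e-10)
        var = prob._resvar(f, sig_p, sig_a)
        y = f + rng.standard_normal(f.shape) * np.sqrt(var)
        sim_pct[r] = percentiles(y.ravel()[flat_mask])

    rows = []
    for b, bt in enumerate(bin_arr):
        n_in_bin = int((assign == b).sum())
        if n_in_bin == 0:
            warnings.warn(f"VPC bin at TAD {bt} h is empty; dropped", stacklevel=2)
            continue
        row = {"bin_tad": bt, "n_obs": n_in_bin}
        for q, name in zip(range(3), ("p5", "p50", "p95")):
            row[f"obs_{name}"] = obs_pct[b, q]
            row[f"sim_{name}_lo"] = np.nanpercentile(sim_pct[:, b, q], 2.5)
            row[f"sim_{name}_med"] = np.nanpercentile(sim_pct[:, b, q], 50)
            row[f"sim_{name}_hi"] = np.nanpercentile(sim_pct[:, b, q], 97.5)
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_replicates=n_replicates)
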