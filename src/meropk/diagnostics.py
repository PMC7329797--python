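"""Model evaluation: visual predictive check, nonparametric bootstrap, residuals.

The VPC simulates replicate datasets under the fitted model using the
original design (each subject's own doses, sampling times and covariates),
bins observed and simulated concentrations at the nominal sampling times,
and compares the observed 5th/50th/95th percentiles with the simulation-
based 90% confidence band of each percentile.  The bootstrap resamples
whole subjects with replacement and refits; parameter uncertainty is
summarized as the median and the 5th-95th percentile interval.  Percentiles
everywhere use linear interpolation of order statistics (numpy's default).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .dataset import PKDataset, SubjectRecord
from .estimation import (
    EstimationError,
    FitResult,
    ModelSpec,
    _FitData,
    _make_inner,
    fit_population,
)
from .popmodel import PopulationModel, residual_variance

__all__ = ["VPCResult", "BootstrapResult", "vpc", "bootstrap", "gof_residuals"]


@dataclass(frozen=True)
class VPCResult:
    bin_times: np.ndarray
    observed: np.ndarray        # (3, n_bins): 5th / 50th / 95th observed percentile
    band_lo: np.ndarray         # (3, n_bins): lower edge of the simulated 90% CI
    band_hi: np.ndarray         # (3, n_bins)
    n_sim: int
    n_obs_per_bin: np.ndarray
    flags: np.ndarray           # (3, n_bins) True where observed leaves its band

    def n_outside(self) -> int:
        return int(self.flags.sum())

    def frame(self) -> pd.DataFrame:
        q = ["p5", "p50", "p95"]
        rows = []
        for j, t in enumerate(self.bin_times):
            for i, name in enumerate(q):
                rows.append(
                    {
                        "time": t,
                        "percentile": name,
                        "observed": self.observed[i, j],
                        "sim_lo": self.band_lo[i, j],
                        "sim_hi": self.band_hi[i, j],
                        "outside": bool(self.flags[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapResult:
    estimates: pd.DataFrame     # one row per successful resample
    median: pd.Series
    ci_lo: pd.Series            # 5th percentile
    ci_hi: pd.Series            # 95th percentile
    n_success: int
    n_fail: int

    @property
    def n_boot(self) -> int:
        return self.n_success + self.n_fail

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.median, "ci5": self.ci_lo, "ci95": self.ci_hi}
        )


def _time_after_dose(subject: SubjectRecord, t: float) -> float:
    prior = [d.start_time for d in subject.doses if d.start_time < t - 1e-9]
    if not prior:
        return t - (subject.first_dose_time or 0.0)
    return t - max(prior)


def _simulate_design(dataset: PKDataset, model: PopulationModel, n_sim: int, rng):
    """Replicate concentration arrays under the model for the original design.

    Returns (tads, obs_values, sims) where sims has shape (n_sim, n_obs_total)
    aligned with the flattened non-excluded observations.
    """
    fd = _FitData(dataset)
    spec = ModelSpec(
        n_compartments=2, iiv_params=model.iiv.eta_names or ("V1",), laws=model.laws
    )
    inner = _make_inner(fd, model, spec)
    om = inner.om
    d = len(om)
    S = fd.n_subjects
    sims = np.empty((n_sim, int(fd.mask.sum())))
    for k in range(n_sim):
        etas = rng.normal(0.0, np.sqrt(om), size=(S, d)) if d else np.zeros((S, 0))
        f = inner.predict(etas)
        sd = np.sqrt(residual_variance(np.maximum(f, 0.0), model.residual))
        y = f + rng.normal(size=f.shape) * sd
        sims[k] = y[fd.mask]
    return fd, sims


def vpc(
    dataset: PKDataset,
    model: PopulationModel,
    n_sim: int = 1000,
    rng=None,
    percentiles=(5.0, 50.0, 95.0),
    band: float = 90.0,
) -> VPCResult:
    """Visual predictive check binned at the nominal sampling times.

    Simulated replicate values keep residual error (including any negative
    draws) to stay faithful to the generative model.  Bins with no
    observation are dropped.  An observed percentile outside its simulated
    band flags possible model misspecification.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(rng)
    subjects = [s for s in dataset.subjects if s.active_observations()]
    tads = []
    for s in subjects:
        for o in s.active_observations():
            tads.append(_time_after_dose(s, o.time))
    tads = np.round(np.asarray(tads), 6)
    fd, sims = _simulate_design(dataset, model, n_sim, rng)
    obs = fd.y[fd.mask]

    bins = np.unique(tads)
    q = np.asarray(percentiles)
    lo_q, hi_q = 50.0 - band / 2.0, 50.0 + band / 2.0
    observed = np.empty((len(q), len(bins)))
    band_lo = np.empty_like(observed)
    band_hi = np.empty_like(observed)
    n_per = np.empty(len(bins), int)
    for j, b in enumerate(bins):
        m = tads == b
        n_per[j] = m.sum()
        observed[:, j] = np.percentile(obs[m], q)
        sim_stats = np.percentile(sims[:, m], q, axis=1)  # (3, n_sim)
        band_lo[:, j] = np.percentile(sim_stats, lo_q, axis=1)
        band_hi[:, j] = np.percentile(sim_stats, hi_q, axis=1)
    flags = (observed < band_lo) | (observed > band_hi)
    return VPCResult(
        bin_times=bins,
        observed=observed,
        band_lo=band_lo,
        band_hi=band_hi,
        n_sim=n_sim,
        n_obs_per_bin=n_per,
        flags=flags,
    )


def bootstrap(
    dataset: PKDataset,
    spec: ModelSpec,
    n_boot: int,
    rng=None,
    init: PopulationModel | None = None,
    max_fev: int = 1500,
    xatol: float = 1e-4,
    boundary_omega2: float = 1e-6,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit, summarize.

    Each replicate draws subjects with replacement up to the original
    subject count and refits the final model warm-started at the original
    estimates.  Replicates that do not converge, or that run a variance to
    the boundary, count as unsuccessful and are excluded from the
    percentile summary; more than 50% failures aborts.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng)
    if init is None:
        raise ValueError("bootstrap requires the original fit's model as init")
    subjects = dataset.subjects
    n = len(subjects)
    rows = []
    n_fail = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = tuple(
            dataclasses.replace(subjects[i], subject_id=f"B{b}_{k}")
            for k, i in enumerate(idx)
        )
        ds_b = dataclasses.replace(dataset, subjects=resampled)
        try:
            fit = fit_population(ds_b, spec, init, max_fev=max_fev, xatol=xatol)
        except (EstimationError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        boundary = any(v < boundary_omega2 for v in fit.model.iiv.omega2.values())
        if not fit.converged or boundary:
            n_fail += 1
            continue
        rows.append(_flatten_params(fit.model, spec))
        if n_fail > n_boot / 2:
            raise EstimationError(
                f"bootstrap aborted: {n_fail} of {b + 1} replicates unsuccessful"
            )
    est = pd.DataFrame(rows)
    if est.empty:
        raise EstimationError("bootstrap produced no successful fit")
    return BootstrapResult(
        estimates=est,
        median=est.median(),
        ci_lo=est.quantile(0.05),
        ci_hi=est.quantile(0.95),
        n_success=len(est),
        n_fail=n_fail,
    )


def _flatten_params(model: PopulationModel, spec: ModelSpec) -> dict:
    out = {}
    theta = model.fixed.as_dict()
    for p in spec.theta_names:
        out[f"theta_{p}"] = theta[p]
    for law in model.laws:
        out[f"beta_{law.parameter}_{law.covariate}_{law.form}"] = law.coefficient
    for p, v in model.iiv.omega2.items():
        out[f"omega2_{p}"] = v
    out["sigma_add"] = model.residual.sigma_add
    out["sigma_prop"] = model.residual.sigma_prop
    return out


def gof_residuals(dataset: PKDataset, fit: FitResult) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    PRED: population prediction (eta = 0).  IPRED: individual prediction at
    the empirical Bayes eta mode.  IWRES = (obs - IPRED)/sqrt(var(IPRED)).
    CWRES decorrelates each subject's residual vector with the covariance of
    the conditionally linearized model, V = J Omega J' + diag(var(IPRED)),
    around the expectation F(eta_hat) - J eta_hat, using the Cholesky factor
    of V (lower-triangular solve).  For a correctly specified model CWRES is
    approximately standard normal.
    """
    model = fit.model
    spec = fit.spec
    fd = _FitData(dataset)
    inner = _make_inner(fd, model, spec)
    d = inner.d
    S = fd.n_subjects
    etas = np.zeros((S, d))
    for i, sid in enumerate(fd.ids):
        e = fit.etas.get(sid)
        if e:
            for k, col in enumerate(inner.eta_cols):
                etas[i, k] = e.get(inner.theta_names[col], 0.0)
    pred = inner.predict(np.zeros((S, d)))
    ipred = inner.predict(etas)
    J = inner.jacobian(etas)
    om = np.diag(inner.om) if d else np.zeros((0, 0))
    rows = []
    for i, sid in enumerate(fd.ids):
        m = fd.mask[i]
        y = fd.y[i, m]
        f = ipred[i, m]
        Ji = J[i][m]
        g = residual_variance(np.maximum(f, 0.0), model.residual)
        iwres = (y - f) / np.sqrt(g)
        V = Ji @ om @ Ji.T + np.diag(np.atleast_1d(g))
        mean = f - Ji @ etas[i]
        L = np.linalg.cholesky(V)
        cwres = solve_triangular(L, y - mean, lower=True)
        for j, t in enumerate(fd.t[i, m]):
            rows.append(
                {
                    "subject_id": sid,
                    "time": t,
                    "observed": y[j],
                    "pred": pred[i, m][j],
                    "ipred": f[j],
                    "iwres": iwres[j],
                    "cwres": cwres[j],
                }
            )
    return pd.DataFrame(rows)
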