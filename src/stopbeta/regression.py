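"""Bayesian multiple regression of SSRT on beta-power and DAI regressors.

The outcome (per-subject SSRT) and all regressors are z-normalized; each
coefficient gets a Normal(0, 0.5) prior, the residual SD a half-Normal(1)
prior, and the likelihood is Normal around the linear predictor.  Because
the model is linear-Gaussian, the posterior is sampled exactly with a Gibbs
scheme: the coefficient block has a conjugate multivariate-Normal full
conditional, and the noise SD is drawn from its one-dimensional full
conditional by inverse-CDF on a fine grid.  Model comparison uses
PSIS-LOO (expected log pointwise predictive density) via arviz, with exact
leave-one-out refits for observations whose Pareto-k diagnostic is
unstable.

Model variants: model 1 = main effects plus all first-order interactions;
model 2 = main effects only; model 3 = main effects with the two pre-SMA
beta-power regressors (successful/failed) averaged, as they are strongly
correlated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

REGRESSORS = ["rifg_s", "rifg_f", "presma_s", "presma_f", "dai"]

PRIOR_COEF_SD = 0.5
PRIOR_NOISE_SD = 1.0


# ---------------------------------------------------------------------------
# regression table
# ---------------------------------------------------------------------------

@dataclass
class RegressionTable:
    data: pd.DataFrame            # z-scored regressors + 'ssrt'
    n_excluded_peak: int
    n_excluded_outlier: int
    audit: dict = field(default_factory=dict)


def build_regression_table(features: pd.DataFrame,
                           min_subjects: int = 10) -> RegressionTable:
    """Screen, z-normalize and audit the per-subject regression inputs.

    ``features`` needs one row per subject with columns
    ``rifg_s, rifg_f, presma_s, presma_f, dai, ssrt`` and optionally a
    boolean ``peak_ok`` (positive beta-power peak inside the tROI in both
    trial types and both regions); rows failing it are excluded, then all
    variables are z-normalized and rows with any |z| > 3 are excluded as
    outliers (and the remaining columns re-standardized).
    """
    cols = REGRESSORS + ["ssrt"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    df = features.copy()
    n0 = len(df)
    if "peak_ok" in df.columns:
        df = df[df["peak_ok"].astype(bool)]
    n_peak = n0 - len(df)
    df = df.dropna(subset=cols)

    def zscore(frame):
        sd = frame[cols].std(ddof=1)
        degenerate = sd <= 1e-10 * (1.0 + frame[cols].abs().mean())
        if degenerate.any():
            zero = list(sd.index[degenerate])
            raise ValueError(f"zero variance in columns {zero}")
        return (frame[cols] - frame[cols].mean()) / sd

    z = zscore(df)
    keep = (z.abs() <= 3).all(axis=1)
    n_out = int((~keep).sum())
    df = df[keep]
    if len(df) < min_subjects:
        raise ValueError(f"only {len(df)} subjects remain after screening "
                         f"(need >= {min_subjects})")
    z = zscore(df)
    z.insert(0, "subject", df["subject"].to_numpy()
             if "subject" in df.columns else np.arange(len(df)))
    return RegressionTable(data=z.reset_index(drop=True),
                           n_excluded_peak=n_peak,
                           n_excluded_outlier=n_out,
                           audit={"n_included": len(df)})


def design_matrix(table: RegressionTable, model_id: int):
    """Design matrix and regressor names for one model variant.

    Interaction terms in model 1 are products of the z-scored main effects,
    not re-standardized.
    """
    df = table.data
    if model_id == 1:
        names = list(REGRESSORS)
        cols = [df[c].to_numpy() for c in REGRESSORS]
        for a, b in itertools.combinations(REGRESSORS, 2):
            names.append(f"{a}:{b}")
            cols.append(df[a].to_numpy() * df[b].to_numpy())
    elif model_id == 2:
        names = list(REGRESSORS)
        cols = [df[c].to_numpy() for c in REGRESSORS]
    elif model_id == 3:
        names = ["rifg_s", "rifg_f", "presma_avg", "dai"]
        cols = [df["rifg_s"].to_numpy(), df["rifg_f"].to_numpy(),
                0.5 * (df["presma_s"].to_numpy() + df["presma_f"].to_numpy()),
                df["dai"].to_numpy()]
    else:
        raise ValueError("model_id must be 1, 2 or 3")
    X = np.column_stack(cols)
    y = df["ssrt"].to_numpy()
    return X, y, names


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    model_id: int
    names: list
    coef_draws: np.ndarray        # (draws, p)
    noise_sd_draws: np.ndarray    # (draws,)
    log_likelihood: np.ndarray    # (draws, n)
    X: np.ndarray
    y: np.ndarray
    elpd_loo: float | None = None
    elpd_loo_se: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def coef(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown regressor {name!r}; have {self.names}")
        return self.coef_draws[:, j]

    def to_inference_data(self) -> az.InferenceData:
        posterior = {f"beta_{n}": self.coef_draws[None, :, i]
                     for i, n in enumerate(self.names)}
        posterior["sigma"] = self.noise_sd_draws[None, :]
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"ssrt": self.log_likelihood[None, :, :]})


def _sample_sigma(rng, sse: float, n: int, grid: np.ndarray) -> float:
    """Inverse-CDF draw of the noise SD full conditional on a grid."""
    logp = (-n * np.log(grid) - sse / (2.0 * grid ** 2)
            - grid ** 2 / (2.0 * PRIOR_NOISE_SD ** 2))
    logp -= logp.max()
    cdf = np.cumsum(np.exp(logp))
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, grid))


def _gibbs(X, y, draws, tune, seed, likelihood: bool = True):
    n, p = X.shape
    rng = np.random.default_rng(seed)
    XtX = X.T @ X
    Xty = X.T @ y
    prior_prec = np.eye(p) / PRIOR_COEF_SD ** 2
    grid = np.linspace(1e-3, 6.0, 4000)
    sigma = 1.0
    betas = np.empty((tune + draws, p))
    sigmas = np.empty(tune + draws)
    for d in range(tune + draws):
        if likelihood:
            prec = XtX / sigma ** 2 + prior_prec
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Xty / sigma ** 2)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            sse = float(((y - X @ beta) ** 2).sum())
            sigma = _sample_sigma(rng, sse, n, grid)
        else:  # prior-only sampling (likelihood switched off)
            beta = rng.normal(0.0, PRIOR_COEF_SD, p)
            sigma = abs(rng.normal(0.0, PRIOR_NOISE_SD))
        betas[d] = beta
        sigmas[d] = sigma
    return betas[tune:], sigmas[tune:]


def fit_model(table: RegressionTable, model_id: int, draws: int = 20_000,
              tune: int = 2000, seed: int = 0,
              likelihood: bool = True) -> PosteriorFit:
    """Sample the posterior of one model variant.

    ``draws`` posterior samples are kept after ``tune`` warm-up sweeps of
    the Gibbs sampler.  ``likelihood=False`` reproduces the prior (a
    sampler sanity check).
    """
    X, y, names = design_matrix(table, model_id)
    betas, sigmas = _gibbs(X, y, draws, tune, seed, likelihood=likelihood)
    mu = betas @ X.T                          # (draws, n)
    loglik = (-0.5 * ((y[None, :] - mu) / sigmas[:, None]) ** 2
              - np.log(sigmas)[:, None] - 0.5 * np.log(2 * np.pi))
    fit = PosteriorFit(model_id=model_id, names=names, coef_draws=betas,
                       noise_sd_draws=sigmas, log_likelihood=loglik,
                       X=X, y=y)
    ess = az.ess(az.convert_to_dataset(betas[None, :, :]))
    fit.diagnostics = {"divergences": 0,
                       "min_ess": float(ess.to_array().min())}
    return fit


def coef_direction_prob(fit: PosteriorFit, regressor: str) -> float:
    """Marginal posterior probability that a coefficient is negative."""
    return float((fit.coef(regressor) < 0).mean())


# ---------------------------------------------------------------------------
# LOO model comparison
# ---------------------------------------------------------------------------

def _exact_elpd_i(table_X, y, i, seed, draws=4000, tune=500):
    """Exact leave-one-out elpd for observation i via refit."""
    mask = np.ones(y.size, dtype=bool)
    mask[i] = False
    betas, sigmas = _gibbs(table_X[mask], y[mask], draws, tune, seed)
    mu_i = betas @ table_X[i]
    ll = (-0.5 * ((y[i] - mu_i) / sigmas) ** 2
          - np.log(sigmas) - 0.5 * np.log(2 * np.pi))
    return float(logsumexp(ll) - np.log(ll.size))


def loo_compare(fits: list, k_threshold: float = 0.7, seed: int = 0):
    """Rank fitted models by elpd_loo (PSIS, exact refits as fallback).

    All fits must be on the same data.  Returns a DataFrame ranked by
    elpd_loo with standard errors; models within one SE of the best are
    flagged as ties.
    """
    y0 = fits[0].y
    for f in fits[1:]:
        if f.y.shape != y0.shape or not np.allclose(f.y, y0):
            raise ValueError("fits are not on identical data")
    rows = []
    for f in fits:
        idata = f.to_inference_data()
        loo = az.loo(idata, pointwise=True)
        elpd_i = np.asarray(loo.loo_i.values, dtype=float)
        khat = np.asarray(loo.pareto_k.values, dtype=float)
        bad = np.flatnonzero(khat > k_threshold)
        for i in bad:
            elpd_i[i] = _exact_elpd_i(f.X, f.y, int(i), seed=seed + int(i))
        elpd = float(elpd_i.sum())
        se = float(np.sqrt(elpd_i.size * np.var(elpd_i, ddof=0)))
        f.elpd_loo, f.elpd_loo_se = elpd, se
        rows.append({"model_id": f.model_id, "elpd_loo": elpd, "se": se,
                     "n_refit": int(bad.size)})
    out = pd.DataFrame(rows).sort_values("elpd_loo", ascending=False)
    best = out["elpd_loo"].iloc[0]
    best_se = out["se"].iloc[0]
    out["within_one_se"] = out["elpd_loo"] >= best - best_se
    return out.reset_index(drop=True)
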