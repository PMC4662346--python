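"""Bayesian mixed models for per-shoot count data.

The model is a GLMM with a Poisson log-link (counts) or Gaussian
(continuous traits) response, arbitrary identity- or covariance-
structured random effects, and an observation-level "unit" effect that
absorbs overdispersion in the Poisson case.  Fitting is by MCMC:

* fixed effects and random-effect levels have conjugate Gaussian
  updates given the latent log rates;
* for the Poisson family the latent residuals are updated one
  observation at a time with an adaptive random-walk Metropolis step
  (tuning frozen at the end of burn-in so runs are reproducible);
* the residual/unit variance has a conjugate inverse-gamma update;
* every other variance carries a scaled-F(1,1) prior (scale 1000),
  implemented by parameter expansion: the term enters the predictor as
  ``alpha * L xi`` with ``xi ~ N(0, V I)``, ``V ~ IG(1/2, 1/2)`` and
  ``alpha ~ N(0, 1000)``, so the implied prior on the variance
  ``alpha^2 V`` is 1000 * F(1,1) — a heavy-tailed half-t(1) on the
  standard deviation.

Structured terms supply a provenance covariance ``C`` through its
PSD-safe factor ``L`` (``L L' = C``), so no matrix inverses are needed
even for singular structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ContractError,
    DegenerateDataError,
    InvalidParameterError,
    ScheduleError,
    SchemaError,
    StructureError,
)
from .popgen import CovarianceStructure

FAMILIES = ("poisson_log", "gaussian")


@dataclass
class PriorSpec:
    """Priors: diffuse normal fixed effects, scaled-F(1,1) variances,
    inverse-gamma residual."""

    fixed_mean: float = 0.0
    fixed_variance: float = 1e8
    variance_scale: float = 1000.0  # alpha.V of the parameter expansion
    residual_shape: float = 0.001
    residual_scale: float = 0.001

    def __post_init__(self):
        for name in ("fixed_variance", "variance_scale", "residual_shape",
                     "residual_scale"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass
class MCMCSchedule:
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 15
    seed: int = 0

    def __post_init__(self):
        kept = self.n_iter - self.burn_in
        if kept <= 0 or kept % self.thin != 0:
            raise ScheduleError("thin must divide (n_iter - burn_in)")
        if self.n_retained < 100:
            raise ScheduleError("schedule retains fewer than 100 draws")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


#: Named schedules: ``desk`` for routine/test use, ``paper`` matching the
#: published analysis (500k iterations, 50k burn-in, sampling every 450).
SCHEDULE_PRESETS = {
    "desk": dict(n_iter=20_000, burn_in=5_000, thin=15),
    "paper": dict(n_iter=500_000, burn_in=50_000, thin=450),
    "smoke": dict(n_iter=3_100, burn_in=600, thin=25),
}


def schedule_preset(name: str, seed: int = 0) -> MCMCSchedule:
    if name not in SCHEDULE_PRESETS:
        raise ConfigurationError(f"unknown schedule preset {name!r}")
    return MCMCSchedule(seed=seed, **SCHEDULE_PRESETS[name])


@dataclass
class RandomTerm:
    """A random effect: ``group`` column, optionally a covariance structure."""

    name: str
    group: str
    structure: CovarianceStructure | None = None


@dataclass
class ModelSpec:
    family: str
    response: str
    fixed_terms: list = field(default_factory=list)  # besides the intercept
    random_terms: list = field(default_factory=list)
    include_unit: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSchedule = field(default_factory=MCMCSchedule)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus metadata.

    ``fixed`` has one column per fixed term (incl. intercept);
    ``variances`` one column per random term plus ``unit`` (Poisson) or
    ``residual`` (Gaussian).  ``fixed_predictor_variance`` is the
    per-draw variance of the fixed-effect linear predictor over the
    observations, used for marginal R^2.
    """

    fixed: pd.DataFrame
    variances: pd.DataFrame
    fixed_predictor_variance: np.ndarray
    family: str
    spec: ModelSpec
    seed: int
    acceptance_rate: float | None = None
    n_dropped_rows: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.fixed)

    @property
    def residual_name(self) -> str:
        return "unit" if self.family == "poisson_log" else "residual"


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(data: pd.DataFrame, fixed_terms) -> tuple[np.ndarray, list]:
    """Intercept + fixed terms as a dense design matrix.

    A term may be a data column (continuous), ``<col>_sq`` for its
    square, ``a:b`` for a product interaction, or a non-numeric column
    (e.g. ``year``) expanded to treatment contrasts with the first
    sorted level as reference.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]

    def _col(term):
        if term in data.columns:
            return data[term]
        if term.endswith("_sq") and term[:-3] in data.columns:
            return data[term[:-3]].astype(float) ** 2
        raise SchemaError(f"fixed term {term!r} not found in data")

    for term in fixed_terms:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(_col(a).to_numpy(float) * _col(b).to_numpy(float))
            names.append(term)
            continue
        series = _col(term)
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            cols.append(series.to_numpy(float))
            names.append(term)
        elif pd.api.types.is_numeric_dtype(series) and term.endswith("_sq"):
            cols.append(series.to_numpy(float))
            names.append(term)
        else:
            levels = sorted(series.unique())
            for lev in levels[1:]:  # first level = reference
                cols.append((series == lev).to_numpy(float))
                names.append(f"{term}_{lev}")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

class _Term:
    """Sampler state for one random term (parameter-expanded)."""

    def __init__(self, term: RandomTerm, data: pd.DataFrame):
        self.name = term.name
        series = data[term.group]
        if term.structure is not None:
            levels = list(term.structure.labels)
            present = set(series.unique())
            unknown = present - set(levels)
            if unknown:
                raise StructureError(
                    f"term {term.name!r}: groups {sorted(unknown)} not in structure"
                )
            self.L = term.structure.factor()
        else:
            levels = sorted(series.unique())
            self.L = None  # identity
        self.levels = levels
        self.q = len(levels)
        lut = {l: i for i, l in enumerate(levels)}
        self.gidx = series.map(lut).to_numpy(dtype=np.intp)
        self.counts = np.bincount(self.gidx, minlength=self.q).astype(float)
        self.xi = np.zeros(self.q)
        self.alpha = 1.0
        self.V = 1.0

    @property
    def u_level(self) -> np.ndarray:
        base = self.xi if self.L is None else self.L @ self.xi
        return self.alpha * base

    def contribution(self) -> np.ndarray:
        return self.u_level[self.gidx]

    @property
    def sigma2(self) -> float:
        return self.alpha**2 * self.V


def _sample_inv_gamma(rng, shape, scale):
    # guard against underflow of gamma draws at tiny shapes (e.g. 0.001)
    return scale / max(rng.gamma(shape), 1e-300)


def _poisson_mle(X, y, max_iter=100, tol=1e-10):
    """Newton-Raphson Poisson regression (log link), with ridge fallback."""
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        lam = np.exp(eta)
        grad = X.T @ (y - lam)
        H = (X * lam[:, None]).T @ X + 1e-10 * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    H = (X * np.exp(eta)[:, None]).T @ X + 1e-10 * np.eye(p)
    return beta, H


def _fit_poisson_glm_mh(X, y, names, spec, rng):
    """Poisson GLM posterior (no random terms, no unit effect).

    Independence Metropolis-Hastings with a Laplace proposal centred at
    the ML fit; acceptance is near one, so draws are effectively exact
    posterior samples under the diffuse normal prior.
    """
    beta_hat, H = _poisson_mle(X, y)
    Hc = np.linalg.cholesky(np.linalg.inv(H + np.eye(len(beta_hat)) / spec.priors.fixed_variance))

    def logpost(b):
        eta = np.clip(X @ b, -30, 30)
        return float(y @ eta - np.exp(eta).sum() - 0.5 * (b @ b) / spec.priors.fixed_variance)

    def logprop(b):
        z = np.linalg.solve(Hc, b - beta_hat)
        return -0.5 * float(z @ z)

    sched = spec.mcmc
    beta = beta_hat.copy()
    lp, lq = logpost(beta), logprop(beta)
    draws, fpv = [], []
    accepted = total = 0
    for it in range(1, sched.n_iter + 1):
        prop = beta_hat + Hc @ rng.standard_normal(len(beta_hat))
        lp_new, lq_new = logpost(prop), logprop(prop)
        total += 1
        if np.log(rng.random()) < (lp_new - lp) - (lq_new - lq):
            beta, lp, lq = prop, lp_new, lq_new
            accepted += 1
        if it > sched.burn_in and (it - sched.burn_in) % sched.thin == 0:
            draws.append(beta.copy())
            fpv.append(np.var(X @ beta))
    fixed = pd.DataFrame(np.array(draws), columns=names)
    variances = pd.DataFrame(index=fixed.index)
    return fixed, variances, np.array(fpv), accepted / total


# ---------------------------------------------------------------------------
# main fit
# ---------------------------------------------------------------------------

def fit_glmm(data: pd.DataFrame, spec: ModelSpec, prior_only: bool = False) -> PosteriorSamples:
    """Fit the GLMM by MCMC and return retained posterior draws.

    Rows with missing values in any model column are dropped (the count
    is reported on the result).  With ``prior_only=True`` the likelihood
    is switched off and the sampler explores the joint prior — used to
    validate the variance-prior implementation.
    """
    sched = spec.mcmc
    rng = np.random.default_rng(sched.seed)

    used_cols = {spec.response} | {t.group for t in spec.random_terms}
    for term in spec.fixed_terms:
        for part in term.split(":"):
            base = part[:-3] if part.endswith("_sq") else part
            if base in data.columns:
                used_cols.add(base)
    missing_cols = used_cols - set(data.columns)
    if missing_cols:
        raise SchemaError(f"model columns missing from data: {sorted(missing_cols)}")
    clean = data.dropna(subset=sorted(used_cols))
    n_dropped = len(data) - len(clean)
    clean = clean.reset_index(drop=True)

    y = clean[spec.response].to_numpy()
    if spec.family == "poisson_log":
        if np.any(y < 0) or not np.allclose(y, np.rint(y)):
            raise DegenerateDataError("poisson_log response must be nonnegative integers")
        y = y.astype(float)
    else:
        y = y.astype(float)
        if not prior_only and np.std(y) == 0.0:
            raise DegenerateDataError("gaussian response has zero variance")

    X, names = build_design_matrix(clean, spec.fixed_terms)
    n, p = X.shape

    if spec.family == "poisson_log" and not spec.include_unit:
        if spec.random_terms:
            raise ConfigurationError(
                "include_unit=False is only supported without random terms "
                "(sensitivity runs degenerate to a Poisson GLM)"
            )
        fixed, variances, fpv, acc = _fit_poisson_glm_mh(X, y, names, spec, rng)
        return PosteriorSamples(
            fixed=fixed, variances=variances, fixed_predictor_variance=fpv,
            family=spec.family, spec=spec, seed=sched.seed,
            acceptance_rate=acc, n_dropped_rows=n_dropped,
        )

    terms = [_Term(t, clean) for t in spec.random_terms]
    pri = spec.priors

    XtX = X.T @ X
    prior_prec_beta = np.eye(p) / pri.fixed_variance

    # state
    beta = np.zeros(p)
    if spec.family == "poisson_log":
        eta = np.log(y + 0.5)
        beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    else:
        eta = y.copy()
        beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    mu = X @ beta
    sigma2_e = max(float(np.var(eta - mu)), 1e-2)

    step = 0.5  # latent RW step, adapted during burn-in then frozen
    accepted = total = 0

    keep = sched.n_retained
    fixed_out = np.empty((keep, p))
    var_out = np.empty((keep, len(terms) + 1))
    fpv_out = np.empty(keep)
    ki = 0

    is_pois = spec.family == "poisson_log" and not prior_only
    latent = spec.family == "poisson_log"

    for it in range(1, sched.n_iter + 1):
        # --- latent log rates (Poisson only) -------------------------------
        if is_pois:
            prop = eta + step * rng.standard_normal(n)
            prop = np.clip(prop, -30.0, 30.0)
            logr = (
                y * (prop - eta)
                - (np.exp(prop) - np.exp(eta))
                - ((prop - mu) ** 2 - (eta - mu) ** 2) / (2.0 * sigma2_e)
            )
            acc = np.log(rng.random(n)) < logr
            eta[acc] = prop[acc]
            total += n
            accepted += int(acc.sum())
            if it <= sched.burn_in and it % 50 == 0:
                rate = acc.mean()
                step *= np.exp((rate - 0.44) * 0.5)
                step = float(np.clip(step, 1e-3, 10.0))
        elif latent and prior_only:
            eta = mu + np.sqrt(sigma2_e) * rng.standard_normal(n)

        # --- fixed effects -------------------------------------------------
        if prior_only:
            beta = pri.fixed_mean + np.sqrt(pri.fixed_variance) * rng.standard_normal(p)
            mu = X @ beta + sum((t.contribution() for t in terms), np.zeros(n))
        else:
            r = eta - (mu - X @ beta)
            prec = XtX / sigma2_e + prior_prec_beta
            cf = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, X.T @ r / sigma2_e)
            beta_new = mean + np.linalg.solve(cf.T, rng.standard_normal(p))
            mu = mu + X @ (beta_new - beta)
            beta = beta_new

        # --- random terms --------------------------------------------------
        for t in terms:
            contrib_old = t.contribution()
            if prior_only:
                t.xi = np.sqrt(t.V) * rng.standard_normal(t.q)
                t.alpha = float(rng.normal(0.0, np.sqrt(pri.variance_scale)))
            else:
                r = eta - (mu - contrib_old)
                sums = np.bincount(t.gidx, weights=r, minlength=t.q)
                if t.L is None:
                    prec = t.alpha**2 * t.counts / sigma2_e + 1.0 / t.V
                    mean = (t.alpha * sums / sigma2_e) / prec
                    t.xi = mean + rng.standard_normal(t.q) / np.sqrt(prec)
                else:
                    A = (t.alpha**2 / sigma2_e) * (t.L.T * t.counts) @ t.L + np.eye(t.q) / t.V
                    b = (t.alpha / sigma2_e) * (t.L.T @ sums)
                    cf = np.linalg.cholesky(A)
                    mean = np.linalg.solve(A, b)
                    t.xi = mean + np.linalg.solve(cf.T, rng.standard_normal(t.q))
                # expansion scalar alpha
                w_level = t.xi if t.L is None else t.L @ t.xi
                sw2 = float((t.counts * w_level**2).sum())
                swr = float((w_level * sums).sum())
                aprec = sw2 / sigma2_e + 1.0 / pri.variance_scale
                amean = (swr / sigma2_e) / aprec
                t.alpha = float(rng.normal(amean, 1.0 / np.sqrt(aprec)))
            # working variance of xi: IG(1/2, 1/2) prior
            t.V = _sample_inv_gamma(
                rng, 0.5 + 0.5 * t.q, 0.5 + 0.5 * float(t.xi @ t.xi)
            )
            if not prior_only:
                mu = mu + (t.contribution() - contrib_old)

        # --- residual / unit variance -------------------------------------
        if prior_only:
            sigma2_e = _sample_inv_gamma(rng, pri.residual_shape, pri.residual_scale)
            sigma2_e = float(np.clip(sigma2_e, 1e-12, 1e12))
        else:
            e = eta - mu if latent else y - mu
            sigma2_e = _sample_inv_gamma(
                rng, pri.residual_shape + 0.5 * n, pri.residual_scale + 0.5 * float(e @ e)
            )

        # --- retain --------------------------------------------------------
        if it > sched.burn_in and (it - sched.burn_in) % sched.thin == 0:
            fixed_out[ki] = beta
            for tj, t in enumerate(terms):
                var_out[ki, tj] = t.sigma2
            var_out[ki, -1] = sigma2_e
            fpv_out[ki] = np.var(X @ beta)
            ki += 1

    resid_name = "unit" if spec.family == "poisson_log" else "residual"
    fixed = pd.DataFrame(fixed_out, columns=names)
    variances = pd.DataFrame(
        var_out, columns=[t.name for t in terms] + [resid_name]
    )
    return PosteriorSamples(
        fixed=fixed,
        variances=variances,
        fixed_predictor_variance=fpv_out,
        family=spec.family,
        spec=spec,
        seed=sched.seed,
        acceptance_rate=(accepted / total) if total else None,
        n_dropped_rows=n_dropped,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _ess_autocorr(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.std(x) == 0.0:
        return float("nan")
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # sum consecutive pairs until a pair sum goes nonpositive
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair <= 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    a, b = x[: int(first * n)], x[int((1 - last) * n):]
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    se2 = np.var(a) / max(_ess_autocorr(a), 1.0) + np.var(b) / max(_ess_autocorr(b), 1.0)
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def diagnostics(samples: PosteriorSamples, ess_floor: float = 100.0, z_limit: float = 3.0) -> pd.DataFrame:
    """Per-parameter effective sample size and Geweke z, with flags.

    A parameter is flagged when ESS < ``ess_floor``, |z| > ``z_limit``,
    or either statistic is undefined (degenerate chain).
    """
    if samples.n_draws < 100:
        raise ContractError("diagnostics need at least 100 retained draws")
    rows = []
    chains = pd.concat([samples.fixed, samples.variances], axis=1)
    for name in chains.columns:
        x = chains[name].to_numpy()
        ess = _ess_autocorr(x)
        z = _geweke_z(x)
        flagged = (not np.isfinite(ess)) or (not np.isfinite(z)) or ess < ess_floor or abs(z) > z_limit
        rows.append((name, ess, z, flagged))
    out = pd.DataFrame(rows, columns=["parameter", "ess", "geweke_z", "flagged"])
    if samples.acceptance_rate is not None:
        out.attrs["acceptance_rate"] = samples.acceptance_rate
    return out
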