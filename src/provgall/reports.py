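"""Reported quantities derived from posterior samples and survey tables.

Variance components follow the convention of dividing each random-term
variance (including the observation-level UNIT term) by the summed
random variances and multiplying by the share of variance not explained
by the fixed effects (1 - RsqM), where RsqM is the marginal R^2 of
Nakagawa & Schielzeth.  For the log-link Poisson family the
distribution-specific variance uses the lognormal approximation
``ln(1/lambda + 1)`` with ``lambda = exp(beta0 + Sum(sigma^2)/2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import (
    AliasingError,
    ConfigurationError,
    ContractError,
    DegenerateDataError,
    ProvgallError,
)
from .glmm import (
    MCMCSchedule,
    ModelSpec,
    PosteriorSamples,
    RandomTerm,
    fit_glmm,
)
from .popgen import CovarianceStructure

#: Default pooling: a structured provenance term and its nugget are also
#: reported as a single pooled "provenance" component.
DEFAULT_POOL = {"provenance": ("provenance_structured", "provenance_nugget")}


# ---------------------------------------------------------------------------
# marginal R^2 and variance components
# ---------------------------------------------------------------------------

def _rsqm_draws(samples: PosteriorSamples, design: np.ndarray | None = None):
    """Per-draw (sigma2_fixed, sigma2_random_total, sigma2_dist, RsqM)."""
    if design is not None:
        betas = samples.fixed.to_numpy()
        eta = betas @ np.asarray(design, dtype=float).T
        s2f = eta.var(axis=1)
    else:
        s2f = np.asarray(samples.fixed_predictor_variance, dtype=float)
    s2r = samples.variances.to_numpy().sum(axis=1) if len(samples.variances.columns) else np.zeros_like(s2f)
    if samples.family == "poisson_log":
        b0 = samples.fixed["intercept"].to_numpy()
        lam = np.exp(b0 + 0.5 * s2r)
        s2d = np.log(1.0 / lam + 1.0)
    else:
        s2d = np.zeros_like(s2f)
    denom = s2f + s2r + s2d
    rsqm = np.where(denom > 0, s2f / np.where(denom > 0, denom, 1.0), 0.0)
    return s2f, s2r, s2d, rsqm


def marginal_r2(samples: PosteriorSamples, design: np.ndarray | None = None):
    """Marginal R^2 (fixed-effect share of latent-scale variance).

    Returns (per-draw array, summary dict with mean and central 95%
    interval).  ``design`` recomputes the fixed-predictor variance from
    an explicit design matrix; by default the variance stored during
    fitting is used.
    """
    *_, rsqm = _rsqm_draws(samples, design)
    summary = {
        "mean": float(rsqm.mean()),
        "ci_low": float(np.quantile(rsqm, 0.025)),
        "ci_high": float(np.quantile(rsqm, 0.975)),
    }
    return rsqm, summary


def variance_components(
    samples: PosteriorSamples,
    design: np.ndarray | None = None,
    pool: dict | None = None,
) -> pd.DataFrame:
    """Posterior variance components on the 0-1 scale.

    Per draw, each random-term variance (including UNIT/residual) is
    divided by the summed random variances and multiplied by
    ``1 - RsqM``; the per-draw components therefore sum to ``1 - RsqM``
    exactly.  Structured provenance terms and their nugget are reported
    separately and pooled (rows named by ``pool``).
    """
    vnames = list(samples.variances.columns)
    if not vnames or (len(vnames) == 1 and vnames[0] in ("unit", "residual")):
        if samples.family == "poisson_log" and "unit" not in vnames:
            raise ContractError("poisson_log samples must carry a UNIT variance")
        if not vnames:
            raise ContractError("need at least one random term plus UNIT/residual")
    if samples.family == "poisson_log" and "unit" not in vnames:
        raise ContractError("poisson_log samples must carry a UNIT variance")

    _, s2r, _, rsqm = _rsqm_draws(samples, design)
    V = samples.variances.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = V / s2r[:, None] * (1.0 - rsqm)[:, None]
    frame = pd.DataFrame(comp, columns=vnames)
    pool = DEFAULT_POOL if pool is None else pool
    for pooled_name, parts in pool.items():
        present = [t for t in parts if t in frame.columns]
        if len(present) >= 2:
            frame[pooled_name] = frame[present].sum(axis=1)
    rows = []
    for name in frame.columns:
        x = frame[name].to_numpy()
        rows.append(
            (name, float(x.mean()), float(np.quantile(x, 0.025)),
             float(np.quantile(x, 0.975)))
        )
    out = pd.DataFrame(rows, columns=["term", "mean", "ci_low", "ci_high"])
    out.attrs["rsqm_mean"] = float(rsqm.mean())
    out.attrs["per_draw"] = frame
    return out


# ---------------------------------------------------------------------------
# fixed-effect summaries
# ---------------------------------------------------------------------------

def pmcmc(samples: PosteriorSamples | np.ndarray, term: str | None = None) -> float:
    """Bayesian two-sided sign probability of a coefficient.

    ``pMCMC = max(2 * min(P(draw > 0), P(draw < 0)), 2 / n_draws)``.
    """
    if isinstance(samples, PosteriorSamples):
        if term not in samples.fixed.columns:
            raise ContractError(f"term {term!r} not among fixed effects")
        draws = samples.fixed[term].to_numpy()
    else:
        draws = np.asarray(samples, dtype=float)
    n = len(draws)
    if n < 100:
        raise ContractError("pMCMC needs at least 100 draws")
    if np.all(draws == 0.0):
        raise DegenerateDataError("all draws are exactly zero")
    frac_pos = float(np.mean(draws > 0))
    frac_neg = float(np.mean(draws < 0))
    return max(2.0 * min(frac_pos, frac_neg), 2.0 / n)


def vif(design: pd.DataFrame | np.ndarray, names=None) -> pd.Series:
    """Variance inflation factors, ``1 / (1 - R^2_j)`` per column.

    ``design`` excludes the intercept (one is added internally for the
    auxiliary regressions).  Perfectly collinear columns raise
    :class:`AliasingError` naming the aliased terms.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    ones = np.ones((n, 1))
    out = {}
    aliased = []
    for j in range(p):
        yj = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0.0:
            aliased.append(names[j])
            continue
        r2 = 1.0 - float(resid @ resid) / ss_tot
        if r2 > 1.0 - 1e-10:
            aliased.append(names[j])
        else:
            out[names[j]] = 1.0 / (1.0 - r2)
    if aliased:
        raise AliasingError(aliased)
    return pd.Series(out, name="vif")


def fdr_adjust(p_values, method: str = "BH", alpha: float = 0.05):
    """Step-up false-discovery-rate adjustment (BH or the more
    conservative BY), returning adjusted p-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ProvgallError("p-values must lie in (0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ConfigurationError(f"unknown FDR method {method!r}")
    reject, adj, *_ = multipletests(p, alpha=alpha, method=key)
    return adj, reject


def fixed_effect_table(
    samples: PosteriorSamples,
    design: pd.DataFrame | None = None,
    fdr_method: str = "BH",
) -> pd.DataFrame:
    """Posterior mean, 95% CI, pMCMC, sign and FDR flags per fixed term.

    The FDR family is the set of non-intercept terms of this model; when
    comparing one term across many gall types, adjust across types with
    :func:`fdr_adjust` instead.
    """
    rows = []
    for name in samples.fixed.columns:
        draws = samples.fixed[name].to_numpy()
        rows.append(
            dict(
                term=name,
                mean=float(draws.mean()),
                ci_low=float(np.quantile(draws, 0.025)),
                ci_high=float(np.quantile(draws, 0.975)),
                pmcmc=pmcmc(draws),
                sign="+" if draws.mean() > 0 else "-",
            )
        )
    out = pd.DataFrame(rows)
    mask = out["term"] != "intercept"
    out["significant_raw"] = out["pmcmc"] < 0.05
    adj = np.full(len(out), np.nan)
    flg = np.zeros(len(out), dtype=bool)
    if mask.any():
        adj_vals, rej = fdr_adjust(out.loc[mask, "pmcmc"].to_numpy(), fdr_method)
        adj[mask.to_numpy()] = adj_vals
        flg[mask.to_numpy()] = rej
    out["pmcmc_adjusted"] = adj
    out["significant_fdr"] = flg
    if design is not None:
        v = vif(design)
        out = out.merge(v.rename("vif"), left_on="term", right_index=True, how="left")
    return out


# ---------------------------------------------------------------------------
# prediction curves
# ---------------------------------------------------------------------------

def prediction_curve(
    samples: PosteriorSamples,
    x_grid,
    term: str,
    observed_range: tuple | None = None,
    literal_x_scaling: bool = False,
) -> pd.DataFrame:
    """Expected count along a trait gradient with credible bands.

    Per retained draw i the curve is
    ``y_i(x) = exp(intercept_i + x * coef_i [+ x^2 * coef_sq_i]
    + 0.5 * Sum(random-effect variances_i))`` — the lognormal mean
    correction over all random-effect variances.  With
    ``literal_x_scaling`` the correction is multiplied by x instead (a
    sensitivity variant).  Values outside ``observed_range`` trigger a
    warning, not an error.
    """
    if term not in samples.fixed.columns:
        raise ContractError(f"term {term!r} not among fixed effects")
    x = np.asarray(x_grid, dtype=float)
    if observed_range is not None:
        lo, hi = observed_range
        if x.min() < lo or x.max() > hi:
            warnings.warn("prediction grid extends beyond the observed trait range")
    b0 = samples.fixed["intercept"].to_numpy()[:, None]
    coef = samples.fixed[term].to_numpy()[:, None]
    eta = b0 + coef * x[None, :]
    sq = f"{term}_sq"
    if sq in samples.fixed.columns:
        eta = eta + samples.fixed[sq].to_numpy()[:, None] * x[None, :] ** 2
    s2 = samples.variances.to_numpy().sum(axis=1)[:, None] if len(samples.variances.columns) else 0.0
    corr = 0.5 * s2 * (x[None, :] if literal_x_scaling else 1.0)
    y = np.exp(eta + corr)
    return pd.DataFrame(
        {
            "x": x,
            "mean": y.mean(axis=0),
            "ci_low": np.quantile(y, 0.025, axis=0),
            "ci_high": np.quantile(y, 0.975, axis=0),
        }
    )


# ---------------------------------------------------------------------------
# survey summaries
# ---------------------------------------------------------------------------

@dataclass
class GallSurveyTable:
    """Per gall-type x year summaries and between-year abundance ratios."""

    per_year: pd.DataFrame  # gall_type, [season], year, total, mean_per_shoot, incidence
    ratios: pd.DataFrame    # gall_type, ratio_value, ratio_label


def _ratio_label(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Between-year ratio oriented larger:smaller, integer-rounded label.

    Returns (numeric ratio >= 1, label like '16:1' or '1:8'); undefined
    (a zero mean) renders as NaN and an en dash.
    """
    if mean_a == 0.0 or mean_b == 0.0:
        return float("nan"), "–"
    big, small = (mean_a, mean_b) if mean_a >= mean_b else (mean_b, mean_a)
    r = big / small
    if not np.isfinite(r):  # a denominator underflowed: effectively a zero mean
        return float("nan"), "–"
    label = f"{int(round(r))}:1" if mean_a >= mean_b else f"1:{int(round(r))}"
    return r, label


def summary_ratios(per_year: pd.DataFrame) -> pd.DataFrame:
    """Between-year ratios of mean galls per shoot from a per-year table.

    Works on any frame with ``gall_type``, ``year`` and
    ``mean_per_shoot`` columns (e.g. a published summary), so printed
    means can be re-expressed in the larger:smaller integer style.
    """
    rows = []
    for gt, sub in per_year.groupby("gall_type", sort=True):
        sub = sub.sort_values("year")
        if len(sub) >= 2:
            a, b = sub["mean_per_shoot"].iloc[0], sub["mean_per_shoot"].iloc[1]
            val, label = _ratio_label(float(a), float(b))
        else:
            val, label = float("nan"), "–"
        rows.append((gt, val, label))
    return pd.DataFrame(rows, columns=["gall_type", "ratio_value", "ratio_label"])


def survey_summary(records: pd.DataFrame) -> GallSurveyTable:
    """Summarise shoot-level counts per gall type and survey year.

    Totals, mean galls per shoot (total / number of shoot records),
    incidence (proportion of shoots bearing at least one gall) and the
    between-year ratio of means oriented larger:smaller.
    """
    keys = ["gall_type"]
    if "season" in records.columns:
        keys.append("season")
    grouped = records.groupby(keys + ["year"], sort=True)["count"]
    per_year = grouped.agg(
        total="sum",
        n_shoots="count",
        incidence=lambda c: float((c >= 1).mean()),
    ).reset_index()
    per_year["mean_per_shoot"] = per_year["total"] / per_year["n_shoots"]
    ratios = summary_ratios(per_year)
    cols = keys + ["year", "total", "n_shoots", "mean_per_shoot", "incidence"]
    return GallSurveyTable(per_year=per_year[cols], ratios=ratios)


def incidence_filter(summary: GallSurveyTable | pd.DataFrame, threshold: float = 0.01):
    """Split gall types by the rare-type rule.

    A type is excluded iff its incidence is below ``threshold`` in
    EVERY survey year; a single year at or above the threshold retains
    it.  Returns (retained, excluded) lists of gall types.
    """
    per_year = summary.per_year if isinstance(summary, GallSurveyTable) else summary
    retained, excluded = [], []
    for gt, sub in per_year.groupby("gall_type", sort=True):
        if (sub["incidence"] < threshold).all():
            excluded.append(gt)
        else:
            retained.append(gt)
    return retained, excluded


# ---------------------------------------------------------------------------
# covariance-structure comparison
# ---------------------------------------------------------------------------

def standard_gall_spec(
    structure: CovarianceStructure,
    fixed_terms=("year",),
    schedule: MCMCSchedule | None = None,
    include_zone: bool = True,
    include_tree: bool = True,
) -> ModelSpec:
    """Model of per-shoot counts with the trial's random-effect layout.

    Identity structures give a single unstructured provenance term; any
    other structure is entered as a structured term plus an identity
    nugget, alongside soil-zone, plot and tree terms and the UNIT
    effect.
    """
    if structure.mode == "identity":
        prov_terms = [RandomTerm("provenance", "provenance", None)]
    else:
        prov_terms = [
            RandomTerm("provenance_structured", "provenance", structure),
            RandomTerm("provenance_nugget", "provenance", None),
        ]
    terms = prov_terms[:]
    if include_zone:
        terms.append(RandomTerm("soil_zone", "soil_zone", None))
    terms.append(RandomTerm("plot", "plot", None))
    if include_tree:
        terms.append(RandomTerm("tree", "tree", None))
    return ModelSpec(
        family="poisson_log",
        response="count",
        fixed_terms=list(fixed_terms),
        random_terms=terms,
        mcmc=schedule or MCMCSchedule(),
    )


def compare_structures(
    records: pd.DataFrame,
    gall_type: str,
    structures: dict,
    fixed_terms=("year",),
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
    **spec_kwargs,
) -> pd.DataFrame:
    """Provenance variance component under alternative covariance modes.

    Fits the same data once per named structure (identity / 1-F_ST /
    1-GeoF_ST, possibly on different provenance subsets) and tabulates
    the pooled provenance component with its 95% credible interval.
    """
    if not structures:
        raise ConfigurationError("need at least one covariance structure")
    sub_all = records[records["gall_type"] == gall_type]
    if sub_all.empty:
        raise ConfigurationError(f"no records for gall type {gall_type!r}")
    rows = []
    for name, structure in structures.items():
        sub = sub_all[sub_all["provenance"].isin(structure.labels)]
        sched = schedule or MCMCSchedule()
        spec = standard_gall_spec(
            structure, fixed_terms=fixed_terms,
            schedule=MCMCSchedule(sched.n_iter, sched.burn_in, sched.thin, seed),
            **spec_kwargs,
        )
        fit = fit_glmm(sub, spec)
        comps = variance_components(fit)
        prov_row = comps[comps["term"] == "provenance"]
        if prov_row.empty:
            prov_row = comps[comps["term"] == "provenance_structured"]
        structured = comps.loc[comps["term"] == "provenance_structured", "mean"]
        nugget = comps.loc[comps["term"] == "provenance_nugget", "mean"]
        rows.append(
            dict(
                mode=name,
                covariance_mode=structure.mode,
                n_provenances=len(structure.labels),
                provenance_component=float(prov_row["mean"].iloc[0]),
                ci_low=float(prov_row["ci_low"].iloc[0]),
                ci_high=float(prov_row["ci_high"].iloc[0]),
                structured_component=float(structured.iloc[0]) if len(structured) else float("nan"),
                nugget_component=float(nugget.iloc[0]) if len(nugget) else float("nan"),
            )
        )
    return pd.DataFrame(rows)
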