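"""Synthetic provenance-trial data with known ground truth.

None of the field data behind the analysis pipeline are deposited
anywhere, so every downstream stage is exercised on data from these
generators: microsatellite genotypes whose differentiation increases
with geographic distance (isolation by distance), tree phenotypes with a
latitudinal budburst cline and distance-dependent vigour decline, and
per-shoot gall counts from the generative inverse of the analysis GLMM —
Poisson counts on a log-linear predictor with structured provenance,
soil-zone, plot, tree and observation-level (unit) random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialDesign
from .errors import InvalidParameterError, StructureError
from .popgen import CovarianceStructure, GenotypeTable, great_circle_distance

#: Variance-component names understood by the count generator.
VARIANCE_TERMS = (
    "provenance_structured",
    "provenance_nugget",
    "soil_zone",
    "plot",
    "tree",
    "unit",
)


@dataclass
class TruthParams:
    """Generating parameters of a synthetic gall-count dataset.

    ``fixed_coefficients`` maps term names to log-scale coefficients:
    ``intercept``, ``year_<label>`` for non-reference years, and
    optionally ``budburst``, ``budburst_sq``, ``dbh``, ``form``.
    ``variance_components`` maps the names in :data:`VARIANCE_TERMS` to
    nonnegative variances (absent terms default to 0).
    """

    fixed_coefficients: dict
    variance_components: dict = field(default_factory=dict)
    covariance_mode: str = "identity"
    seed: int = 0

    def __post_init__(self):
        for name, v in self.variance_components.items():
            if name not in VARIANCE_TERMS:
                raise InvalidParameterError(f"unknown variance term {name!r}")
            if v < 0:
                raise InvalidParameterError(f"variance {name!r} must be >= 0")

    def variance(self, name: str) -> float:
        return float(self.variance_components.get(name, 0.0))

    @property
    def total_random_variance(self) -> float:
        return float(sum(self.variance_components.values()))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    design: TrialDesign,
    n_loci: int = 10,
    n_ind_per_prov: int = 24,
    ibd_decay: float = 1.0 / 1500.0,
    seed: int = 0,
    amplitude: float = 0.6,
    min_alleles: int = 4,
    max_alleles: int = 8,
    missing_rate: float = 0.0,
) -> GenotypeTable:
    """Simulate diploid multiallelic genotypes with isolation by distance.

    Per locus, allele frequencies on the log scale are the sum of a
    shared base vector and a per-allele Gaussian field over provenances
    with exponential correlation ``exp(-ibd_decay * d_km)``, then
    normalised (softmax).  Nearby provenances therefore share nearly
    identical frequencies, and expected pairwise F_ST grows monotonically
    with great-circle distance.  ``ibd_decay = 0`` collapses the field
    to a single shared frequency vector (no differentiation); negative
    values are rejected.
    """
    if n_loci < 1:
        raise InvalidParameterError("n_loci must be >= 1")
    if n_ind_per_prov < 5:
        raise InvalidParameterError("need at least 5 individuals per provenance")
    if ibd_decay < 0:
        raise InvalidParameterError("ibd_decay must be >= 0")
    rng = np.random.default_rng(seed)
    prov = design.provenances
    codes = list(prov["code"])
    k = len(codes)
    d = great_circle_distance(prov)
    corr = np.exp(-ibd_decay * d)
    w, v = np.linalg.eigh(corr)
    L = v * np.sqrt(np.clip(w, 0.0, None))

    rows = []
    for locus_i in range(n_loci):
        locus = f"L{locus_i + 1:02d}"
        n_alleles = int(rng.integers(min_alleles, max_alleles + 1))
        base = np.log(rng.dirichlet(np.full(n_alleles, 1.5)) + 1e-9)
        # provenance-level perturbation field, one per allele
        z = amplitude * (L @ rng.standard_normal((k, n_alleles)))
        logits = base[None, :] + z
        freqs = np.exp(logits - logits.max(axis=1, keepdims=True))
        freqs /= freqs.sum(axis=1, keepdims=True)
        for pi, code in enumerate(codes):
            calls = rng.choice(n_alleles, size=(n_ind_per_prov, 2), p=freqs[pi]) + 1
            miss = rng.random(n_ind_per_prov) < missing_rate
            for ind_i in range(n_ind_per_prov):
                if miss[ind_i]:
                    rows.append((f"{code}-I{ind_i + 1:03d}", code, locus, None, None))
                else:
                    rows.append(
                        (
                            f"{code}-I{ind_i + 1:03d}",
                            code,
                            locus,
                            int(calls[ind_i, 0]),
                            int(calls[ind_i, 1]),
                        )
                    )
    df = pd.DataFrame(
        rows, columns=["individual", "provenance", "locus", "allele1", "allele2"]
    )
    return GenotypeTable(df)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    design: TrialDesign,
    cline_slope: float = -0.15,
    vigour_decay: float = 0.3,
    noise_sd: float = 0.8,
    seed: int = 0,
    budburst_ref: float = 1.8,
    dbh_local: float = 115.0,
    dbh_noise_sd: float = 14.0,
    form_baseline: float = 4.3,
    genetic_distance=None,
) -> pd.DataFrame:
    """Per-tree phenotypes: budburst (0-5), DBH (cm) and form (1-10).

    Budburst follows a latitudinal cline with slope ``cline_slope``
    (score per degree latitude; negative = southern provenances flush
    earlier/higher on the survey date).  Expected DBH declines with the
    provenance's genetic distance from the local provenance by a factor
    ``1 - vigour_decay * g`` with ``g`` in [0, 1]; unless supplied,
    ``g`` is proxied by great-circle distance to the local provenance
    scaled to [0, 1].  Ordinal traits are latent-Gaussian values rounded
    and clipped to their scales.
    """
    rng = np.random.default_rng(seed)
    prov = design.provenances
    codes = list(prov["code"])
    site_lat = design.trial_site[0]

    if genetic_distance is None:
        d = great_circle_distance(prov)
        local_i = codes.index(design.local_code)
        dloc = d[local_i]
        g = dloc / dloc.max() if dloc.max() > 0 else np.zeros_like(dloc)
    else:
        g = np.asarray(genetic_distance, dtype=float)
        if g.shape != (len(codes),):
            raise InvalidParameterError(
                "genetic_distance must have one entry per provenance"
            )
        if g.max() > 0:
            g = g / g.max()

    bb_base = budburst_ref + cline_slope * (prov["latitude"].to_numpy() - site_lat)
    dbh_base = dbh_local * np.clip(1.0 - vigour_decay * g, 0.05, None)
    base = pd.DataFrame(
        {
            "provenance": codes,
            "bb_base": bb_base,
            "dbh_base": dbh_base,
            "form_base": form_baseline,
        }
    )
    trees = design.tree_table().merge(base, on="provenance")
    n = len(trees)
    bb = trees["bb_base"] + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else trees["bb_base"]
    form = trees["form_base"] + rng.normal(0.0, max(noise_sd, 1e-12) * 1.0, n)
    dbh = trees["dbh_base"] + rng.normal(0.0, dbh_noise_sd, n)
    out = trees[["tree", "provenance", "soil_zone", "plot"]].copy()
    out["budburst"] = np.clip(np.rint(bb), 0, 5).astype(int)
    out["dbh"] = np.clip(dbh, 1.0, None)
    out["form"] = np.clip(np.rint(form), 1, 10).astype(int)
    return out


# ---------------------------------------------------------------------------
# gall counts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSurvey:
    """Shoot-level gall-count records plus the generating ground truth."""

    records: pd.DataFrame
    truth: TruthParams
    random_effects: dict


def simulate_gall_counts(
    design: TrialDesign,
    truth: TruthParams,
    covariance: CovarianceStructure,
    phenotypes: pd.DataFrame | None = None,
    gall_type: str = "synthetic_gall",
    season: str = "spring",
    years=None,
) -> SimulatedSurvey:
    """Draw per-shoot gall counts from the generative GLMM.

    The log rate of each shoot record is the sum of the fixed terms, a
    provenance effect drawn from MVN(0, sigma2_prov * C) for the supplied
    covariance structure C, an identity-structured provenance nugget,
    soil-zone, plot and tree effects, and a per-record unit effect;
    counts are Poisson with that rate.  All realised effects are
    returned for recovery tests.
    """
    if list(covariance.labels) != list(design.codes):
        raise StructureError("covariance labels must match design provenances")
    if covariance.min_eigenvalue() < -1e-8:
        raise StructureError("covariance structure is not positive semidefinite")
    rng = np.random.default_rng(truth.seed)
    years = list(years) if years is not None else list(design.years)

    shoots = design.shoot_table()
    recs = shoots.merge(pd.DataFrame({"year": years}), how="cross")
    recs["season"] = season
    recs["gall_type"] = gall_type
    n = len(recs)

    beta = dict(truth.fixed_coefficients)
    eta = np.full(n, float(beta.get("intercept", 0.0)))
    for yr in years[1:]:
        key = f"year_{yr}"
        if key in beta:
            eta += float(beta[key]) * (recs["year"] == yr).to_numpy(float)
    if phenotypes is not None:
        ph = phenotypes.set_index("tree")
        for term, col in (("budburst", "budburst"), ("dbh", "dbh"), ("form", "form")):
            if term in beta:
                eta += float(beta[term]) * ph.loc[recs["tree"], col].to_numpy(float)
        if "budburst_sq" in beta:
            eta += float(beta["budburst_sq"]) * ph.loc[recs["tree"], "budburst"].to_numpy(float) ** 2

    effects = {}
    codes = design.codes
    prov_idx = recs["provenance"].map({c: i for i, c in enumerate(codes)}).to_numpy()

    s2 = truth.variance("provenance_structured")
    u_str = np.sqrt(s2) * (covariance.factor() @ rng.standard_normal(len(codes)))
    effects["provenance_structured"] = pd.Series(u_str, index=codes)
    eta += u_str[prov_idx]

    u_nug = np.sqrt(truth.variance("provenance_nugget")) * rng.standard_normal(len(codes))
    effects["provenance_nugget"] = pd.Series(u_nug, index=codes)
    eta += u_nug[prov_idx]

    for term, col in (("soil_zone", "soil_zone"), ("plot", "plot"), ("tree", "tree")):
        levels = sorted(recs[col].unique())
        u = np.sqrt(truth.variance(term)) * rng.standard_normal(len(levels))
        effects[term] = pd.Series(u, index=levels)
        idx = recs[col].map({l: i for i, l in enumerate(levels)}).to_numpy()
        eta += u[idx]

    e_unit = np.sqrt(truth.variance("unit")) * rng.standard_normal(n)
    effects["unit_sd_realised"] = float(e_unit.std())
    eta += e_unit

    recs["count"] = rng.poisson(np.exp(eta))
    cols = ["provenance", "soil_zone", "plot", "tree", "shoot",
            "year", "season", "gall_type", "count"]
    return SimulatedSurvey(records=recs[cols], truth=truth, random_effects=effects)
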