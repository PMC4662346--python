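"""Population structure among provenances.

Pairwise genetic differentiation between seed-source populations is
estimated with the Weir & Cockerham (1984) theta estimator of F_ST,
combined across alleles and loci as a ratio of summed variance
components (the fstat convention).  Isolation by distance is tested with
a one-sided Mantel permutation test, and the fitted F_ST-vs-distance
regression is used to predict a pseudo-differentiation ("GeoF_ST") for
provenances without genotype data.  Either matrix is turned into a
provenance-level variance-covariance structure as 1 - F_ST.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InvalidCoordinateError,
    SchemaError,
    StructureError,
    UndefinedCorrelationError,
    UndefinedPairError,
    UnderdeterminedFitError,
    ConfigurationError,
)

EARTH_RADIUS_KM = 6371.0

COVARIANCE_MODES = ("identity", "one_minus_fst", "one_minus_geofst")


# ---------------------------------------------------------------------------
# genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid multiallelic genotypes in long format.

    ``calls`` has one row per individual x locus with columns
    ``individual``, ``provenance``, ``locus``, ``allele1``, ``allele2``.
    Missing calls carry NA in both allele columns (never zero-filled);
    allele codes are positive integers.
    """

    calls: pd.DataFrame

    def __post_init__(self):
        required = {"individual", "provenance", "locus", "allele1", "allele2"}
        missing = required - set(self.calls.columns)
        if missing:
            raise SchemaError(f"genotype table missing columns {sorted(missing)}")
        df = self.calls.copy()
        for col in ("allele1", "allele2"):
            df[col] = pd.array(df[col], dtype="Int64")
            vals = df[col].dropna()
            if (vals <= 0).any():
                raise SchemaError("allele codes must be positive integers")
        # a call is missing as a unit: half-missing calls are dropped to NA
        half = df["allele1"].isna() != df["allele2"].isna()
        if half.any():
            df.loc[half, ["allele1", "allele2"]] = pd.NA
        self.calls = df

    @property
    def provenances(self) -> list:
        return sorted(self.calls["provenance"].unique())

    @property
    def loci(self) -> list:
        return sorted(self.calls["locus"].unique())

    def subset(self, provenances) -> "GenotypeTable":
        keep = self.calls["provenance"].isin(list(provenances))
        return GenotypeTable(self.calls.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(geno_by_pop):
    """Per-allele Weir-Cockerham variance components at one locus.

    ``geno_by_pop`` is a list (one entry per population) of (n_i, 2)
    integer arrays of allele calls for genotyped individuals.  Returns
    summed (a, b, c) over all alleles observed at the locus.
    """
    r = len(geno_by_pop)
    n = np.array([g.shape[0] for g in geno_by_pop], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in geno_by_pop]))
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p = np.array([(g == al).mean() for g in geno_by_pop])
        h = np.array(
            [((g[:, 0] == al) != (g[:, 1] == al)).mean() for g in geno_by_pop]
        )
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta(genotypes: GenotypeTable, populations=None) -> float:
    """Multilocus Weir-Cockerham theta over the given populations.

    Components are summed over alleles and loci and combined as
    ``sum(a) / sum(a + b + c)``.  Loci at which any population has fewer
    than two genotyped individuals are skipped.
    """
    pops = populations if populations is not None else genotypes.provenances
    df = genotypes.calls.dropna(subset=["allele1"])
    a_tot = d_tot = 0.0
    used = 0
    for locus, ldf in df[df["provenance"].isin(pops)].groupby("locus"):
        geno_by_pop = []
        ok = True
        for pop in pops:
            g = ldf.loc[ldf["provenance"] == pop, ["allele1", "allele2"]]
            if len(g) < 2:
                ok = False
                break
            geno_by_pop.append(g.to_numpy(dtype=int))
        if not ok:
            continue
        a, b, c = _wc_components_locus(geno_by_pop)
        a_tot += a
        d_tot += a + b + c
        used += 1
    if used == 0:
        raise UndefinedPairError(
            f"populations {list(pops)} share no locus with >=2 genotyped "
            "individuals each"
        )
    if d_tot == 0.0:
        return 0.0  # monomorphic across the pair
    return a_tot / d_tot


@dataclass
class PairwiseFstMatrix:
    """Symmetric matrix of pairwise theta estimates, zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise StructureError("F_ST matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise StructureError("F_ST matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise StructureError("F_ST matrix must be finite")
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.labels = list(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_fst(genotypes: GenotypeTable) -> PairwiseFstMatrix:
    """All pairwise Weir-Cockerham theta estimates between provenances.

    Negative estimates are retained (the estimator is unbiased around
    zero); they are clamped only later, when a covariance structure is
    built.
    """
    pops = genotypes.provenances
    if len(pops) < 2:
        raise UndefinedPairError("need at least two provenances")
    k = len(pops)
    out = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        try:
            th = wc_theta(genotypes, [pops[i], pops[j]])
        except UndefinedPairError:
            raise UndefinedPairError(
                f"pair ({pops[i]}, {pops[j]}) shares no usable locus"
            ) from None
        out[i, j] = out[j, i] = th
    return PairwiseFstMatrix(labels=pops, values=out)


# ---------------------------------------------------------------------------
# geographic distance
# ---------------------------------------------------------------------------

def great_circle_distance(lat, lon=None) -> np.ndarray:
    """Pairwise great-circle distances (km), haversine on a 6371 km sphere.

    Accepts either a provenance table with ``latitude``/``longitude``
    columns or two coordinate arrays.
    """
    if lon is None:
        lat, lon = lat["latitude"].to_numpy(), lat["longitude"].to_numpy()
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise InvalidCoordinateError(
            "latitude must lie in [-90, 90] and longitude in [-180, 180]"
        )
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(
        dlam / 2.0
    ) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # enforce exact symmetry


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _upper(mat):
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(A, B, n_perm: int = 999, seed: int = 0, exact: bool = False):
    """One-sided (greater) Mantel permutation test between two matrices.

    r is the Pearson correlation of the upper off-diagonal triangles;
    rows and columns of ``B`` are permuted jointly.  The sampled p-value
    is ``(1 + #{r_perm >= r_obs}) / (n_perm + 1)``; with ``exact=True``
    all label permutations are enumerated instead and
    ``p = #{r_perm >= r_obs} / n!`` (the identity included).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise StructureError("Mantel inputs must be square matrices of equal size")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise StructureError("Mantel inputs must be symmetric")
    n = A.shape[0]
    x = _upper(A)
    if x.std() == 0.0 or _upper(B).std() == 0.0:
        raise UndefinedCorrelationError("a Mantel input matrix is constant")

    xc = (x - x.mean()) / x.std()

    def _r(mat):
        y = _upper(mat)
        s = y.std()
        if s == 0.0:
            return 0.0
        return float(np.mean(xc * (y - y.mean()) / s))

    r_obs = _r(B)
    if exact:
        perms = itertools.permutations(range(n))
        count = total = 0
        for p in perms:
            idx = np.array(p)
            if _r(B[np.ix_(idx, idx)]) >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if _r(B[np.ix_(idx, idx)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# GeoF_ST regression
# ---------------------------------------------------------------------------

@dataclass
class GeoFstModel:
    """Least-squares fit of pairwise F_ST on pairwise distance (km)."""

    intercept: float
    slope: float
    r_squared: float
    n_pairs: int
    transform: str = "raw"  # raw | log_distance | linearized_fst


def _transform_xy(fst_vec, dist_vec, transform):
    if transform == "raw":
        return dist_vec, fst_vec
    if transform == "log_distance":
        return np.log(np.maximum(dist_vec, 1e-9)), fst_vec
    if transform == "linearized_fst":
        f = np.clip(fst_vec, None, 0.999)
        return dist_vec, f / (1.0 - f)
    raise ConfigurationError(f"unknown transform {transform!r}")


def fit_geo_fst(fst: PairwiseFstMatrix, dist: np.ndarray, transform: str = "raw"):
    """Fit the isolation-by-distance regression over upper-triangle pairs."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != fst.values.shape:
        raise StructureError("distance matrix shape does not match F_ST labels")
    y_raw = _upper(fst.values)
    x_raw = _upper(dist)
    if len(y_raw) < 3:
        raise UnderdeterminedFitError("need at least 3 provenance pairs to fit")
    x, y = _transform_xy(y_raw, x_raw, transform)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return GeoFstModel(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        r_squared=float(r2),
        n_pairs=len(y),
        transform=transform,
    )


def predict_geo_fst(model: GeoFstModel, dist_full: np.ndarray, labels) -> PairwiseFstMatrix:
    """Predict a complete symmetric pseudo-F_ST matrix from distances.

    Covers provenances absent from the genotyped set; the diagonal is
    zero.  Back-transforms when the fit used the linearised F_ST scale.
    """
    dist_full = np.asarray(dist_full, dtype=float)
    x = dist_full.copy()
    if model.transform == "log_distance":
        x = np.log(np.maximum(x, 1e-9))
    pred = model.intercept + model.slope * x
    if model.transform == "linearized_fst":
        pred = pred / (1.0 + np.maximum(pred, 0.0))
    np.fill_diagonal(pred, 0.0)
    pred = (pred + pred.T) / 2.0
    return PairwiseFstMatrix(labels=list(labels), values=pred)


# ---------------------------------------------------------------------------
# covariance structures
# ---------------------------------------------------------------------------

@dataclass
class CovarianceStructure:
    """Provenance-level variance-covariance structure for the GLMM.

    ``matrix`` is symmetric positive-semidefinite; ``mode`` records how
    it was built and ``psd_repair_applied`` whether negative eigenvalues
    had to be clipped.
    """

    labels: list
    matrix: np.ndarray
    mode: str
    psd_repair_applied: bool = False
    nugget_requested: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise StructureError("covariance shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise StructureError("covariance must be symmetric")
        self.matrix = (m + m.T) / 2.0
        self.labels = list(self.labels)

    @property
    def dim(self) -> int:
        return len(self.labels)

    def factor(self) -> np.ndarray:
        """A matrix L with L L' = matrix (eigen square root; PSD-safe)."""
        w, v = np.linalg.eigh(self.matrix)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())


def identity_structure(labels) -> CovarianceStructure:
    k = len(list(labels))
    return CovarianceStructure(
        labels=list(labels), matrix=np.eye(k), mode="identity"
    )


def build_covariance(
    source: PairwiseFstMatrix | None,
    mode: str,
    labels=None,
    nugget_requested: bool = False,
) -> CovarianceStructure:
    """Build the provenance covariance structure for a given mode.

    ``identity`` needs only labels and returns the exact identity
    matrix.  The other modes take a (pseudo-)F_ST matrix and set
    off-diagonal covariances to ``1 - clamp(F, 0, 0.999)`` with unit
    diagonal, then repair any negative eigenvalues by clipping (the
    repair is flagged, never silent).
    """
    if mode not in COVARIANCE_MODES:
        raise ConfigurationError(f"unknown covariance mode {mode!r}")
    if mode == "identity":
        if labels is None and source is None:
            raise ConfigurationError("identity mode needs labels")
        use = list(labels) if labels is not None else source.labels
        return CovarianceStructure(
            labels=use, matrix=np.eye(len(use)), mode="identity",
            nugget_requested=nugget_requested,
        )
    if source is None:
        raise ConfigurationError(f"mode {mode!r} requires a (pseudo-)F_ST matrix")
    f = np.clip(source.values, 0.0, 0.999)
    cov = 1.0 - f
    np.fill_diagonal(cov, 1.0)
    w = np.linalg.eigvalsh(cov)
    repaired = False
    if w.min() < 0.0:
        # sampling noise in theta routinely makes 1-F_ST slightly indefinite;
        # clip negative eigenvalues and flag (never silent)
        if w.min() < -1e-8:
            logging.getLogger("provgall").warning(
                "1-F_ST covariance repaired: min eigenvalue %.3g clipped to 0",
                w.min(),
            )
        wc, v = np.linalg.eigh(cov)
        cov = (v * np.clip(wc, 0.0, None)) @ v.T
        # restore the unit diagonal (correlation rescale preserves PSD and
        # bounds off-diagonals at 1 by Cauchy-Schwarz)
        d = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
        cov = cov / np.outer(d, d)
        cov = (cov + cov.T) / 2.0
        repaired = True
    return CovarianceStructure(
        labels=source.labels, matrix=cov, mode=mode,
        psd_repair_applied=repaired, nugget_requested=nugget_requested,
    )
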