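"""Common-garden provenance-trial design.

The sampling frame is nested: provenance -> soil zone -> plot -> tree ->
shoot.  The default constants reproduce a large European oak trial layout:
20 provenances, 5 soil zones, 2 study plots per zone per provenance, 24
trees per plot of which 12 are surveyed, and 10 terminal shoots surveyed
per tree — 200 study plots, 4800 trees, 2400 surveyed trees and 24 000
shoot records per survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidCoordinateError, InvalidDesignError

#: Trial-site coordinate (decimal degrees, WGS84) used to flag the most
#: local provenance; defaults to a site in Northwest France.
DEFAULT_TRIAL_SITE = (48.086, -0.168)

#: Trees planted per plot; only ``trees_per_plot_surveyed`` of them are
#: surveyed (the two internal rows, to minimise edge effects).
TREES_PLANTED_PER_PLOT = 24

SEASONS = ("spring", "autumn")


def _check_coords(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise InvalidCoordinateError(
            "latitude must lie in [-90, 90] and longitude in [-180, 180]"
        )
    return lat, lon


@dataclass
class TrialDesign:
    """Nested sampling frame of a provenance trial.

    Parameters
    ----------
    provenances
        One row per provenance with columns ``code``, ``latitude``,
        ``longitude``, ``altitude`` and boolean ``is_local``.
    n_soil_zones, plots_per_zone_per_provenance, trees_per_plot_surveyed,
    shoots_per_tree
        Design constants; defaults match the full trial.
    years
        Survey years (labels for the two-level year fixed effect).
    trial_site
        (lat, lon) of the plantation, used for the "local" flag.
    """

    provenances: pd.DataFrame
    n_soil_zones: int = 5
    plots_per_zone_per_provenance: int = 2
    trees_per_plot_surveyed: int = 12
    shoots_per_tree: int = 10
    years: tuple = (2008, 2009)
    seasons: tuple = SEASONS
    trial_site: tuple = DEFAULT_TRIAL_SITE

    def __post_init__(self):
        prov = self.provenances
        required = {"code", "latitude", "longitude", "altitude"}
        missing = required - set(prov.columns)
        if missing:
            raise InvalidDesignError(f"provenance table missing columns {sorted(missing)}")
        if len(prov) < 2:
            raise InvalidDesignError("a trial needs at least 2 provenances")
        if prov["code"].duplicated().any():
            raise InvalidDesignError("provenance codes must be unique")
        for name in ("n_soil_zones", "plots_per_zone_per_provenance",
                     "trees_per_plot_surveyed", "shoots_per_tree"):
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be a positive integer")
        _check_coords(prov["latitude"].to_numpy(), prov["longitude"].to_numpy())

    # -- derived design arithmetic -------------------------------------
    @property
    def n_provenances(self) -> int:
        return len(self.provenances)

    @property
    def n_study_plots(self) -> int:
        return self.n_provenances * self.n_soil_zones * self.plots_per_zone_per_provenance

    @property
    def n_trees_planted(self) -> int:
        return self.n_study_plots * TREES_PLANTED_PER_PLOT

    @property
    def n_trees_surveyed(self) -> int:
        return self.n_study_plots * self.trees_per_plot_surveyed

    @property
    def n_shoot_records_per_survey(self) -> int:
        return self.n_trees_surveyed * self.shoots_per_tree

    @property
    def codes(self) -> list:
        return list(self.provenances["code"])

    @property
    def local_code(self) -> str:
        loc = self.provenances.loc[self.provenances["is_local"], "code"]
        return str(loc.iloc[0])

    # -- tables ---------------------------------------------------------
    def tree_table(self) -> pd.DataFrame:
        """One row per surveyed tree with provenance/zone/plot identifiers.

        Plot and tree identifiers are globally unique strings; every tree
        belongs to exactly one plot, zone and provenance.
        """
        rows = []
        for code in self.codes:
            for zone in range(1, self.n_soil_zones + 1):
                for plot in range(1, self.plots_per_zone_per_provenance + 1):
                    plot_id = f"{code}-Z{zone}-P{plot}"
                    for tree in range(1, self.trees_per_plot_surveyed + 1):
                        rows.append(
                            (code, f"Z{zone}", plot_id, f"{plot_id}-T{tree:02d}")
                        )
        return pd.DataFrame(rows, columns=["provenance", "soil_zone", "plot", "tree"])

    def shoot_table(self) -> pd.DataFrame:
        """One row per surveyed shoot (tree table crossed with shoot index)."""
        trees = self.tree_table()
        shoots = pd.DataFrame({"shoot": np.arange(1, self.shoots_per_tree + 1)})
        return trees.merge(shoots, how="cross")


def generate_origins(
    n_prov: int,
    lat_span: float = 15.0,
    lon_span: float = 34.0,
    seed: int = 0,
    trial_site: tuple = DEFAULT_TRIAL_SITE,
    **design_kwargs,
) -> TrialDesign:
    """Draw provenance origins spread across the requested spans.

    Origins are drawn uniformly in a box centred on the trial site and
    rescaled so the realised latitudinal and longitudinal ranges equal
    ``lat_span`` and ``lon_span`` exactly.  Exactly one provenance — the
    one nearest the trial site by great-circle distance — is flagged
    ``is_local``.

    Returns a :class:`TrialDesign` built with the default design
    constants (override via ``design_kwargs``).
    """
    if n_prov < 2:
        raise InvalidDesignError("need at least 2 provenances to span a cline")
    if lat_span <= 0 or lon_span <= 0:
        raise InvalidDesignError("latitude and longitude spans must be positive")
    site_lat, site_lon = trial_site
    rng = np.random.default_rng(seed)
    lat = rng.uniform(0.0, 1.0, n_prov)
    lon = rng.uniform(0.0, 1.0, n_prov)

    def _stretch(x, centre, span):
        lo, hi = x.min(), x.max()
        unit = (x - lo) / (hi - lo) if hi > lo else np.full_like(x, 0.5)
        return centre - span / 2.0 + unit * span

    # bias the box east/south of the site the way continental seed sources
    # sit relative to an Atlantic-margin trial, then clip to valid coords
    lat = np.clip(_stretch(lat, site_lat - 0.1 * lat_span, lat_span), -90.0, 90.0)
    lon = np.clip(_stretch(lon, site_lon + 0.35 * lon_span, lon_span), -180.0, 180.0)
    alt = np.round(rng.uniform(50.0, 700.0, n_prov), 0)

    from .popgen import great_circle_distance  # local import, no cycle at runtime

    codes = [f"P{i + 1:02d}" for i in range(n_prov)]
    d_site = great_circle_distance(
        np.append(lat, site_lat), np.append(lon, site_lon)
    )[-1, :-1]
    is_local = np.zeros(n_prov, dtype=bool)
    is_local[int(np.argmin(d_site))] = True

    prov = pd.DataFrame(
        {
            "code": codes,
            "latitude": lat,
            "longitude": lon,
            "altitude": alt,
            "is_local": is_local,
        }
    )
    return TrialDesign(provenances=prov, trial_site=trial_site, **design_kwargs)
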