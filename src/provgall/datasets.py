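"""Bundled worked-example tables.

Two small published summary tables from a 20-provenance sessile-oak
(*Quercus petraea*) common-garden trial in Northwest France are shipped
with the package:

* the provenance origin table (INRA three-digit codes, coordinates,
  altitude, genotype availability, and provenance-mean budburst, DBH and
  form scores), and
* per-gall-type survey summaries for the 2008 and 2009 seasons (totals,
  mean galls per shoot and incidence for 20 cynipid gall types).

The underlying shoot-level field data are not deposited anywhere; these
printed summaries are the only real numbers the package's worked
examples and acceptance checks can recompute against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("provgall.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_provenance_origins() -> pd.DataFrame:
    """Provenance origin table: code, site, coordinates and trait means.

    ``is_local`` marks the provenance nearest the trial site;
    ``genotyped`` marks the 17 provenances with microsatellite data.
    """
    df = _load("provenance_origins.csv")
    df["code"] = df["code"].astype(str)
    return df


def load_gall_survey_summary() -> pd.DataFrame:
    """Published per-gall-type survey summaries for 2008 and 2009.

    One row per gall type (species x generation) per year with the
    printed total, mean galls per shoot and incidence.  Adds a
    ``gall_type`` label combining species and generation.
    """
    df = _load("gall_survey_summary.csv")
    df["gall_type"] = df["species"] + " (" + df["generation"] + ")"
    return df
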