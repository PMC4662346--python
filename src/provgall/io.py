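"""Readers and writers for the pipeline's plain-text formats.

Canonical layouts are tidy CSVs: the survey table has one row per shoot
x survey x gall type with zeros explicit; genotypes travel either as a
long CSV (individual, provenance, locus, allele1, allele2) or as a
GENEPOP file with 2- or 3-digit allele codes.  Every file the pipeline
writes starts with a comment header recording the tool version, config
hash and seed so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import TrialDesign
from .errors import DuplicateRecordError, SchemaError
from .popgen import GenotypeTable
from .simulate import TruthParams

SURVEY_COLUMNS = [
    "provenance", "soil_zone", "plot", "tree", "shoot",
    "year", "season", "gall_type", "count",
]
SURVEY_KEY = ["tree", "shoot", "year", "season", "gall_type"]
PHENOTYPE_COLUMNS = ["tree", "provenance", "budburst", "dbh", "form"]


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping."""
    canon = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def file_header(seed, cfg_hash: str = "none") -> str:
    return f"# provgall {__version__} config_hash={cfg_hash} seed={seed}\n"


def write_table(df: pd.DataFrame, path, seed=0, cfg_hash: str = "none") -> Path:
    """Write a CSV preceded by the reproducibility header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(file_header(seed, cfg_hash))
        df.to_csv(fh, index=False)
    return path


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require(df: pd.DataFrame, columns, what: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s) {missing}")


def read_survey(path) -> pd.DataFrame:
    """Shoot-level survey records; unknown extra columns are preserved."""
    df = _read_csv(path)
    _require(df, SURVEY_COLUMNS, "survey table")
    if df.duplicated(subset=SURVEY_KEY).any():
        dup = df[df.duplicated(subset=SURVEY_KEY)].iloc[0]
        raise DuplicateRecordError(
            "duplicate survey key "
            + str(tuple(dup[k] for k in SURVEY_KEY))
        )
    if (df["count"] < 0).any():
        raise SchemaError("gall counts must be nonnegative")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Per-tree phenotypes with range validation (budburst 0-5, form 1-10)."""
    df = _read_csv(path)
    _require(df, PHENOTYPE_COLUMNS, "phenotype table")
    bb = df["budburst"].dropna()
    if ((bb < 0) | (bb > 5)).any():
        raise SchemaError("budburst scores must lie on the 0-5 ordinal scale")
    fm = df["form"].dropna()
    if ((fm < 1) | (fm > 10)).any():
        raise SchemaError("form scores must lie on the 1-10 ordinal scale")
    if (df["dbh"].dropna() <= 0).any():
        raise SchemaError("DBH must be positive")
    return df


def read_origins(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, ["code", "latitude", "longitude", "altitude"], "origins table")
    df["code"] = df["code"].astype(str)
    if "is_local" not in df.columns:
        df["is_local"] = False
    return df


def write_matrix(values: np.ndarray, labels, path, seed=0, cfg_hash="none") -> Path:
    """Labelled symmetric matrix as CSV (labels both axes)."""
    df = pd.DataFrame(np.asarray(values), index=list(labels), columns=list(labels))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(file_header(seed, cfg_hash))
        df.to_csv(fh, index_label="label")
    return path


def read_matrix(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, comment="#", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "long_csv") -> GenotypeTable:
    if dialect == "long_csv":
        df = _read_csv(path)
        _require(df, ["individual", "provenance", "locus", "allele1", "allele2"],
                 "genotype table")
        return GenotypeTable(df)
    if dialect == "genepop":
        return read_genepop(path)
    raise SchemaError(f"unknown genotype dialect {dialect!r}")


def write_long_genotypes(genotypes: GenotypeTable, path, seed=0, cfg_hash="none") -> Path:
    return write_table(genotypes.calls, path, seed, cfg_hash)


def write_genepop(genotypes: GenotypeTable, path, digits: int = 3,
                  title: str = "provgall export") -> Path:
    """GENEPOP export: one POP block per provenance, zero-coded missing."""
    path = Path(path)
    loci = genotypes.loci
    table = genotypes.calls
    gmap = {
        (row.individual, row.locus): (row.allele1, row.allele2)
        for row in table.itertuples(index=False)
    }
    members = table[["individual", "provenance"]].drop_duplicates()
    lines = [title]
    lines.extend(loci)
    fmt = f"0{digits}d"
    for prov in genotypes.provenances:
        lines.append("POP")
        inds = sorted(members.loc[members["provenance"] == prov, "individual"])
        for ind in inds:
            calls = []
            for locus in loci:
                a1, a2 = gmap.get((ind, locus), (pd.NA, pd.NA))
                if pd.isna(a1) or pd.isna(a2):
                    calls.append("0" * (2 * digits))
                else:
                    calls.append(f"{int(a1):{fmt}}{int(a2):{fmt}}")
            lines.append(f"{ind} , " + " ".join(calls))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_genepop(path) -> GenotypeTable:
    """GENEPOP reader for diploid 2- or 3-digit allele codes.

    Population labels are taken from the first individual's identifier
    prefix (text before the last ``-``) when present, else ``POP<k>``.
    """
    text = Path(path).read_text().splitlines()
    if not text:
        raise SchemaError("empty GENEPOP file")
    loci: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().lower() != "pop":
        line = text[i].strip()
        if line:
            loci.extend(l.strip() for l in line.split(",") if l.strip())
        i += 1
    if i >= len(text):
        raise SchemaError("GENEPOP file has no POP section")
    rows = []
    pop_k = 0
    pop_label = None
    while i < len(text):
        line = text[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_k += 1
            pop_label = None
            continue
        if "," not in line:
            raise SchemaError(f"malformed GENEPOP individual line: {line!r}")
        ind, geno = line.split(",", 1)
        ind = ind.strip()
        if pop_label is None:
            pop_label = ind.rsplit("-", 1)[0] if "-" in ind else f"POP{pop_k}"
        calls = geno.split()
        if len(calls) != len(loci):
            raise SchemaError(
                f"individual {ind!r} has {len(calls)} genotypes for {len(loci)} loci"
            )
        for locus, call in zip(loci, calls):
            if len(call) not in (4, 6):
                raise SchemaError(f"genotype {call!r} is not 2- or 3-digit diploid")
            d = len(call) // 2
            a1, a2 = int(call[:d]), int(call[d:])
            rows.append(
                (ind, pop_label, locus,
                 a1 if a1 > 0 else None, a2 if a2 > 0 else None)
            )
    df = pd.DataFrame(
        rows, columns=["individual", "provenance", "locus", "allele1", "allele2"]
    )
    return GenotypeTable(df)


# ---------------------------------------------------------------------------
# truth sidecar
# ---------------------------------------------------------------------------

def write_truth_yaml(truth: TruthParams, path) -> Path:
    """Ground-truth parameters of a synthetic dataset, for recovery tests."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "fixed_coefficients": {k: float(v) for k, v in truth.fixed_coefficients.items()},
        "variance_components": {k: float(v) for k, v in truth.variance_components.items()},
        "covariance_mode": truth.covariance_mode,
        "seed": int(truth.seed),
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_truth_yaml(path) -> TruthParams:
    payload = yaml.safe_load(Path(path).read_text())
    return TruthParams(**payload)


def design_from_origins(origins: pd.DataFrame, **kwargs) -> TrialDesign:
    """Build a TrialDesign from an origins table (e.g. the bundled one)."""
    prov = origins[["code", "latitude", "longitude", "altitude"]].copy()
    prov["is_local"] = origins["is_local"] if "is_local" in origins.columns else False
    if not prov["is_local"].any():
        prov.loc[prov.index[0], "is_local"] = True
    return TrialDesign(provenances=prov.reset_index(drop=True), **kwargs)
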