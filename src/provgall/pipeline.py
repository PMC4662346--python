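"""End-to-end pipeline: inputs -> structure -> GLMM fits -> reports.

All randomness flows from the single configured seed: a
``numpy.random.SeedSequence`` is spawned into per-stage child seeds in
the fixed order (origins, genotypes, phenotypes, counts, mcmc), so any
stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TrialDesign, generate_origins
from .errors import ConfigurationError
from .glmm import MCMCSchedule, schedule_preset
from .io import (
    config_hash,
    design_from_origins,
    read_genotypes,
    read_origins,
    read_phenotypes,
    read_survey,
    write_matrix,
    write_table,
)
from .popgen import (
    build_covariance,
    fit_geo_fst,
    great_circle_distance,
    mantel_test,
    pairwise_fst,
    predict_geo_fst,
)
from .reports import (
    compare_structures,
    fixed_effect_table,
    incidence_filter,
    standard_gall_spec,
    survey_summary,
    variance_components,
)
from .simulate import TruthParams, simulate_gall_counts, simulate_genotypes, simulate_phenotypes
from .glmm import fit_glmm

log = logging.getLogger("provgall")

STAGES = ("origins", "genotypes", "phenotypes", "counts", "mcmc")


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage child seeds (< 2^31) from the run seed."""
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(len(STAGES)) % (2**31)
    return dict(zip(STAGES, (int(s) for s in state)))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate=True`` (synthetic inputs generated in place) or
    paths to survey/phenotype/origins (and optionally genotype) tables.
    """

    outdir: str = "provgall_out"
    seed: int = 0
    simulate: bool = False
    survey: str | None = None
    phenotypes: str | None = None
    origins: str | None = None
    genotypes: str | None = None
    genotype_dialect: str = "long_csv"
    covariance_modes: list = field(default_factory=lambda: ["identity", "one_minus_geofst"])
    preset: str = "desk"
    fdr_method: str = "BH"
    incidence_threshold: float = 0.01
    mantel_permutations: int = 999
    phenotype_fixed_terms: list = field(default_factory=list)
    geofst_fill_missing_only: bool = False
    # synthetic-generation knobs (used when simulate=True)
    sim_n_provenances: int = 20
    sim_design: dict = field(default_factory=dict)
    sim_ibd_decay: float = 1.0 / 1500.0
    sim_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        for mode in self.covariance_modes:
            if mode not in ("identity", "one_minus_fst", "one_minus_geofst"):
                raise ConfigurationError(f"unknown covariance mode {mode!r}")
        if not self.simulate:
            for name in ("survey", "phenotypes", "origins"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigurationError(f"{name} path required unless simulate=true")
                if not Path(path).exists():
                    raise ConfigurationError(f"{name} file not found: {path}")
            if self.genotypes is not None and not Path(self.genotypes).exists():
                raise ConfigurationError(f"genotypes file not found: {self.genotypes}")
        needs_geno = {"one_minus_fst", "one_minus_geofst"} & set(self.covariance_modes)
        if needs_geno and not self.simulate and self.genotypes is None:
            raise ConfigurationError(
                f"covariance modes {sorted(needs_geno)} need a genotypes file"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _simulate_inputs(config: RunConfig, seeds: dict):
    design = generate_origins(
        config.sim_n_provenances, seed=seeds["origins"], **config.sim_design
    )
    genotypes = simulate_genotypes(
        design, ibd_decay=config.sim_ibd_decay, seed=seeds["genotypes"]
    )
    phenotypes = simulate_phenotypes(design, seed=seeds["phenotypes"])
    truth_kwargs = dict(
        fixed_coefficients={"intercept": 0.0, f"year_{design.years[1]}": -0.4},
        variance_components={
            "provenance_structured": 0.3,
            "provenance_nugget": 0.05,
            "soil_zone": 0.05,
            "plot": 0.1,
            "tree": 0.1,
            "unit": 0.3,
        },
        covariance_mode="one_minus_geofst",
    )
    truth_kwargs.update(config.sim_truth)
    truth = TruthParams(seed=seeds["counts"], **truth_kwargs)
    dist = great_circle_distance(design.provenances)
    fst = pairwise_fst(genotypes)
    model = fit_geo_fst(fst, dist)
    geo = predict_geo_fst(model, dist, design.codes)
    cov = build_covariance(geo, "one_minus_geofst")
    sim = simulate_gall_counts(design, truth, cov, phenotypes)
    return design, genotypes, phenotypes, sim.records, truth


def _load_inputs(config: RunConfig):
    origins = read_origins(config.origins)
    design = design_from_origins(origins)
    records = read_survey(config.survey)
    phenotypes = read_phenotypes(config.phenotypes)
    genotypes = (
        read_genotypes(config.genotypes, config.genotype_dialect)
        if config.genotypes
        else None
    )
    return design, genotypes, phenotypes, records


def build_structures(config: RunConfig, design: TrialDesign, genotypes):
    """Covariance structures (and IBD diagnostics) for the requested modes."""
    out = {}
    diagnostics = {}
    dist_full = great_circle_distance(design.provenances)
    fst = geo = None
    if genotypes is not None:
        geno_labels = [c for c in design.codes if c in genotypes.provenances]
        fst = pairwise_fst(genotypes.subset(geno_labels))
        idx = [design.codes.index(c) for c in fst.labels]
        dist_sub = dist_full[np.ix_(idx, idx)]
        r, p = mantel_test(
            fst.values, dist_sub, n_perm=config.mantel_permutations,
            seed=config.seed,
        )
        model = fit_geo_fst(fst, dist_sub)
        geo = predict_geo_fst(model, dist_full, design.codes)
        if config.geofst_fill_missing_only:
            lut = {l: i for i, l in enumerate(fst.labels)}
            vals = geo.values.copy()
            for a in fst.labels:
                for b in fst.labels:
                    ia, ib = design.codes.index(a), design.codes.index(b)
                    vals[ia, ib] = fst.values[lut[a], lut[b]]
            geo = dataclasses.replace(geo, values=vals)
        diagnostics.update(
            mantel_r=r, mantel_p=p,
            geofst_slope=model.slope, geofst_intercept=model.intercept,
            geofst_r_squared=model.r_squared,
        )
    for mode in config.covariance_modes:
        if mode == "identity":
            out[mode] = build_covariance(None, "identity", labels=design.codes)
        elif mode == "one_minus_fst":
            out[mode] = build_covariance(fst, mode)
        else:
            out[mode] = build_covariance(geo, mode)
    return out, diagnostics


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> structure -> fits -> reports.

    Writes three report CSVs (survey summary, variance components,
    fixed effects) plus the structure matrices to ``config.outdir``;
    every file carries the config hash and seed in its header.
    """
    t0 = time.time()
    # the output location does not affect results, so it is not hashed
    cfg_hash = config_hash({k: v for k, v in config.to_dict().items() if k != "outdir"})
    seeds = stage_seeds(config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        design, genotypes, phenotypes, records, truth = _simulate_inputs(config, seeds)
    else:
        design, genotypes, phenotypes, records = _load_inputs(config)
    log.info("inputs ready: %d survey records, %d provenances",
             len(records), design.n_provenances)

    structures, structure_diag = build_structures(config, design, genotypes)
    for mode, structure in structures.items():
        write_matrix(structure.matrix, structure.labels,
                     outdir / f"covariance_{mode}.csv", config.seed, cfg_hash)

    summary = survey_summary(records)
    retained, excluded = incidence_filter(summary, config.incidence_threshold)
    log.info("incidence filter: %d retained, %d excluded", len(retained), len(excluded))
    summary_out = summary.per_year.merge(summary.ratios, on="gall_type", how="left")
    write_table(summary_out, outdir / "survey_summary.csv", config.seed, cfg_hash)

    schedule = schedule_preset(config.preset, seed=seeds["mcmc"])
    data = records.merge(
        phenotypes[["tree", "budburst", "dbh", "form"]], on="tree", how="left"
    )
    fixed_terms = []
    if records["year"].nunique() > 1:
        fixed_terms.append("year")
    fixed_terms.extend(config.phenotype_fixed_terms)

    comp_rows, fix_rows = [], []
    for gall_type in retained:
        sub_all = data[data["gall_type"] == gall_type]
        for mode, structure in structures.items():
            t_fit = time.time()
            sub = sub_all[sub_all["provenance"].isin(structure.labels)]
            spec = standard_gall_spec(
                structure, fixed_terms=fixed_terms, schedule=schedule
            )
            fit = fit_glmm(sub, spec)
            comps = variance_components(fit)
            comps.insert(0, "gall_type", gall_type)
            comps.insert(1, "mode", mode)
            comp_rows.append(comps)
            fx = fixed_effect_table(fit, fdr_method=config.fdr_method)
            fx.insert(0, "gall_type", gall_type)
            fx.insert(1, "mode", mode)
            fix_rows.append(fx)
            log.info("fitted %s / %s in %.1fs (acceptance %.2f)",
                     gall_type, mode, time.time() - t_fit,
                     fit.acceptance_rate or float("nan"))
    components = pd.concat(comp_rows, ignore_index=True) if comp_rows else pd.DataFrame()
    fixed_effects = pd.concat(fix_rows, ignore_index=True) if fix_rows else pd.DataFrame()
    if not components.empty:
        components = components.drop(columns=[], errors="ignore")
    write_table(components, outdir / "variance_components.csv", config.seed, cfg_hash)
    write_table(fixed_effects, outdir / "fixed_effects.csv", config.seed, cfg_hash)

    log.info("pipeline complete in %.1fs", time.time() - t0)
    return {
        "design": design,
        "structures": structures,
        "structure_diagnostics": structure_diag,
        "summary": summary,
        "retained": retained,
        "excluded": excluded,
        "components": components,
        "fixed_effects": fixed_effects,
        "outdir": outdir,
        "config_hash": cfg_hash,
    }
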