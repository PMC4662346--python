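# provgall

Analysis pipeline for herbivore abundance in tree provenance trials,
with explicit control for the statistical nonindependence of seed-source
populations.

## The problem

Common-garden provenance trials plant seed from many source populations
("provenances") of a tree species under identical conditions, separating
genetic from environmental effects. Surveying herbivores — here, cynipid
gallwasp galls counted on individual oak shoots — across provenances asks
how much of the variation in abundance is attributable to host provenance
and to provenance phenotypes (spring budburst phenology, diameter growth,
tree form). But provenances share ancestry and gene flow, so they are not
independent replicates: treating them as independent understates the
provenance effect. `provgall` is for ecologists and quantitative
geneticists who need that analysis end to end, including the
population-genetic machinery that builds the covariance control.

## The model

Per-shoot gall counts `y` are modelled with a Bayesian Poisson GLMM on the
log scale:

```
y_i ~ Poisson(exp(eta_i))
eta_i = x_i'B + u_prov(i) + u_zone(i) + u_plot(i) + u_tree(i) + e_i
```

with year (and optionally budburst, budburst², DBH, form) as fixed
effects, nested random effects for provenance, soil zone, plot and tree,
and an observation-level UNIT effect `e_i` absorbing overdispersion.
Provenance nonindependence enters through the structured term
`u_prov ~ N(0, sigma² C)` where `C = 1 − F_ST` (pairwise Weir–Cockerham
theta from microsatellites) or `C = 1 − GeoF_ST` (pseudo-differentiation
predicted from the isolation-by-distance regression of F_ST on
great-circle distance), accompanied by an identity-structured "nugget"
term. Priors are diffuse normal `N(0, 10^8)` on fixed effects, scaled
F(1,1) with scale 1000 on random-effect variances (via parameter
expansion) and inverse-gamma(0.001, 0.001) on the residual. Reported
quantities follow the field's conventions: variance components on the
0–1 scale weighted by `1 − RsqM` (Nakagawa–Schielzeth marginal R²),
pMCMC for fixed effects, Benjamini–Hochberg/Yekutieli FDR control, and
lognormal-corrected prediction curves.

Because the underlying field data are not deposited, the package ships a
synthetic trial generator with known ground truth (isolation-by-distance
microsatellites, clinal phenotypes, GLMM-generative counts) plus the
published summary tables as a bundled worked example.

## Worked example

```sh
python examples/03_gall_count_glmm.py
```

simulates a reduced 20-provenance trial (6400 shoot records) with known
variance components and refits it:

```
variance components (0-1 scale; generating values 0.3/0.2/0.1/0.4):
      term  mean  ci_low  ci_high
provenance 0.275   0.151    0.433
      plot 0.216   0.149    0.284
      tree 0.107   0.072    0.145
      unit 0.374   0.285    0.453

marginal R^2 of the year effect: 0.027 [0.020, 0.037]
```

Each row is the share of latent-scale variance attributed to that level
of the design; the posterior means land on the generating values and the
95% credible intervals cover them. `examples/04_structure_comparison.py`
shows the headline covariance contrast — on data generated with
distance-structured provenance effects the identity model reports a
provenance component of 0.377 against 0.546 for the structured model,
i.e. assuming independence understates the provenance effect. The other
examples cover the published summary tables, the F_ST/Mantel/GeoF_ST
workflow, and phenotype fixed effects with FDR control.

A thin CLI mirrors the library (`provgall simulate|fst|mantel|geofst|
fit|report|compare|run`); see `provgall --help`.

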