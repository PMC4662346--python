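"""Worked example: identity vs structured provenance covariance.

Generates gall counts whose provenance effects are correlated by a
distance-decay covariance, then fits the same data under an identity
structure (provenances independent) and under the true structure.
Ignoring the covariance understates the provenance variance component.
"""

import numpy as np

import provgall as pg

design = pg.generate_origins(
    20, seed=5, trees_per_plot_surveyed=4, shoots_per_tree=4
)
d = pg.great_circle_distance(design.provenances)
structure = pg.CovarianceStructure(
    labels=design.codes, matrix=np.exp(-d / 1200.0), mode="one_minus_geofst"
)
truth = pg.TruthParams(
    fixed_coefficients={"intercept": 0.2},
    variance_components={"provenance_structured": 0.4, "plot": 0.1, "unit": 0.3},
    seed=6,
)
sim = pg.simulate_gall_counts(design, truth, structure, years=[2008])

table = pg.compare_structures(
    sim.records, "synthetic_gall",
    {"identity": pg.identity_structure(design.codes), "structured": structure},
    fixed_terms=[],
    schedule=pg.MCMCSchedule(20_000, 5_000, 15, seed=7),
    include_zone=False, include_tree=False,
)
cols = ["mode", "provenance_component", "ci_low", "ci_high"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nThe structured model attributes more of the variance to provenance "
      "because the identity model books the correlated part of the signal "
      "elsewhere — the qualitative pattern the covariance control exists for.")
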