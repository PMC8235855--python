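"""Design-driven missingness and the interpolation the phenotypic model needs.

Weekly production records are heavily missing (sex-specific weighing
schedules); the multi-SAD model simply drops missing cells from the
likelihood, while the phenotypic-regression model requires a complete
production covariate at every FI record and therefore linear interpolation
first.
"""

import numpy as np

from longsad import build_A, fit_phenotypic_regression_model
from longsad.mixed_model import DesignError
from longsad.simulate import default_config, interpolate_missing, simulate_dataset

cfg = default_config(n_generations=2, n_sires=5, n_dams=15, litter_size=4,
                     seed=3)
ped, pheno, _ = simulate_dataset(cfg, complete=False)
A = build_A(ped)

counts = pheno.data.groupby(["trait", "week"]).size().unstack()
print("records per trait and week (of", len(pheno.animals), "animals):")
print(counts)

try:
    fit_phenotypic_regression_model(pheno, A, grid=cfg.grid,
                                    compute_information=False)
except DesignError as err:
    print("\nphenotypic model on raw data:", err)

completed = interpolate_missing(pheno, ["ADG", "MBW", "BF"], cfg.grid)
n_filled = int(completed.data["interpolated"].sum())
print(f"\nlinear interpolation filled {n_filled} production cells")

# Interpolation needs >= 2 observations of a trait per animal; under random
# missingness a few animals stay incomplete and must be dropped for the
# phenotypic model (the real study's weighing design guaranteed enough
# records per animal).
counts = completed.data.groupby(["animal", "trait"]).size().unstack(fill_value=0)
full = counts.index[(counts >= len(cfg.grid.times)).all(axis=1)]
subset = completed.data[completed.data["animal"].isin(full)]
print(f"{len(full)} of {len(pheno.animals)} animals complete after interpolation")

from longsad import PhenotypeTable
fit = fit_phenotypic_regression_model(PhenotypeTable(subset), A, grid=cfg.grid,
                                      compute_information=False, seed=1)
print("phenotypic model on interpolated subset: converged =", fit.converged)
# Interpolated covariates let the phenotypic model run, at the price of
# treating predicted values as observed — one reason to prefer the multi-SAD
# model when many records are missing.
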