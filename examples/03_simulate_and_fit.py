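"""Simulate a small dataset and fit the two-stage multi-SAD regression model.

The joint model regresses feed intake's genetic and environmental effects on
the production traits with time-varying (cross-antedependence) coefficients;
the two-stage scheme first fits each production trait alone and freezes its
parameters in the joint fit.  Small n keeps this demo around a minute; expect
visibly noisy estimates at this scale.
"""

import numpy as np

from longsad import build_A, fit_multi_sad_model, information_condition_number, regression_trajectories
from longsad.simulate import default_config, default_spec, simulate_dataset

cfg = default_config(n_generations=3, n_sires=8, n_dams=15, litter_size=8,
                     seed=42)
ped, pheno, effects = simulate_dataset(cfg, complete=True)
A = build_A(ped)
print(f"{len(pheno.animals)} phenotyped animals, {len(ped)} in the pedigree")

fit = fit_multi_sad_model(pheno, A, default_spec(), grid=cfg.grid,
                          two_stage=True, seed=1)
print("converged:", fit.converged, " restricted logL:", round(fit.reml_loglik, 1))
cond, flagged = information_condition_number(fit)
print(f"information condition number: {cond:.0f} (flagged: {flagged})")

traj = regression_trajectories(fit)
adg = traj.query("trait == 'ADG'")
print("\ngenetic regression of FI on ADG by week (truth: 1.13 -> 0.59):")
print(np.round(adg["b_u"].to_numpy(), 2).tolist())
print("environmental (truth: ~0.92):")
print(np.round(adg["b_e"].to_numpy(), 2).tolist())
# The genetic coefficient declines over the test period while the
# environmental one stays flat: feed use per unit of gain changes genetically
# with age, which a single averaged RFI would hide.
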