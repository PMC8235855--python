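"""SAD covariance functions of the default (study-calibrated) world.

Shows how a handful of polynomial coefficients generate full trait-by-time
genetic and environmental covariance matrices, and how the RFI* construction
yields a genetic covariance (G*) free of the production traits.
"""

import numpy as np

from longsad import (
    GENETIC,
    TimeGrid,
    genetic_correlation_matrix,
    multi_trait_covariance,
    rfi_star_covariances,
)
from longsad.simulate import default_params

params = default_params()
grid = TimeGrid.weeks(10)
n = grid.n

Sg = multi_trait_covariance(params, grid, GENETIC)
fi = 3 * n
print("FI genetic variance by week:", np.round(np.diag(Sg)[fi:], 0).tolist())

cs = rfi_star_covariances(params, grid)
print("RFI* genetic variance by week:", np.round(np.diag(cs.genetic), 0).tolist())

R = genetic_correlation_matrix(cs.genetic)
print("genetic correlation of RFI*, week 1 vs weeks 1..10:")
print(np.round(R[0], 2).tolist())
# Correlations decay with the time lag — the antedependence signature: RFI*
# in week 1 is nearly uncorrelated with RFI* in week 10, so early and late
# feed efficiency are partly different genetic traits.

h2 = np.diag(cs.genetic) / (np.diag(cs.genetic) + np.diag(cs.environmental)[fi:])
print("RFI* heritability by week:", np.round(h2, 2).tolist())
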