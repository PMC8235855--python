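"""Shared simulation worlds for the heavier model-level tests."""

import numpy as np

from longsad import SadParams, SadSpec, TimeGrid
from longsad.sad import ENVIRONMENTAL, GENETIC
from longsad.simulate import TRAIT_MEANS, default_config, default_params


def subset_world(traits, cross_targets):
    """Restrict the default 4-trait world to a subset of traits (FI last)."""
    p4 = default_params()
    degrees = {(s, c): p4.spec.degrees[(s, c)] for s in traits
               for c in (GENETIC, ENVIRONMENTAL)}
    spec = SadSpec(traits=traits, degrees=degrees,
                   cross_degree={GENETIC: 1, ENVIRONMENTAL: 1})
    params = SadParams(
        spec,
        theta={(s, c): p4.theta[(s, c)] for s in traits
               for c in (GENETIC, ENVIRONMENTAL)},
        logvar={(s, c): p4.logvar[(s, c)] for s in traits
                for c in (GENETIC, ENVIRONMENTAL)},
        cross={(c, t): p4.cross[(c, t)] for c in (GENETIC, ENVIRONMENTAL)
               for t in cross_targets},
    )
    return spec, params


def three_trait_world(n_sires=20, n_dams=50, litter=10):
    """(ADG, MBW, FI) restriction of the default world, ~500 phenotyped."""
    traits = ("ADG", "MBW", "FI")
    spec, params = subset_world(traits, ("ADG", "MBW"))

    def make_cfg(seed):
        cfg = default_config(n_generations=3, n_sires=n_sires, n_dams=n_dams,
                             litter_size=litter, seed=1000 + seed)
        cfg.params = params
        cfg.trait_means = {s: TRAIT_MEANS[s] for s in traits}
        return cfg

    return spec, make_cfg


def kennedy_world(h2=0.4):
    """Two-trait world with Sigma_e proportional to Sigma_g: the parameter
    regime in which phenotypic-regression RFI is genetically independent of
    the production trait at every week."""
    traits = ("ADG", "FI")
    c = (1 - h2) / h2
    spec = SadSpec(
        traits=traits,
        degrees={
            ("ADG", GENETIC): (0, 0), ("ADG", ENVIRONMENTAL): (0, 0),
            ("FI", GENETIC): (1, 1), ("FI", ENVIRONMENTAL): (1, 1),
        },
        cross_degree={GENETIC: 1, ENVIRONMENTAL: 1},
    )
    params = SadParams(
        spec,
        theta={
            ("ADG", GENETIC): (0.6,), ("ADG", ENVIRONMENTAL): (0.6,),
            ("FI", GENETIC): (0.45, 0.02), ("FI", ENVIRONMENTAL): (0.45, 0.02),
        },
        logvar={
            ("ADG", GENETIC): (np.log(80.0),),
            ("ADG", ENVIRONMENTAL): (np.log(80.0 * c),),
            ("FI", GENETIC): (np.log(250.0), -0.01),
            ("FI", ENVIRONMENTAL): (np.log(250.0 * c), -0.01),
        },
        cross={(GENETIC, "ADG"): (1.1, -0.05),
               (ENVIRONMENTAL, "ADG"): (1.1, -0.05)},
    )

    def make_cfg(seed):
        cfg = default_config(n_generations=3, n_sires=25, n_dams=100,
                             litter_size=10, seed=3000 + seed)
        cfg.params = params
        cfg.trait_means = {"ADG": TRAIT_MEANS["ADG"], "FI": TRAIT_MEANS["FI"]}
        return cfg

    return spec, params, make_cfg
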