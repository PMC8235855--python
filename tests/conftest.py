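import numpy as np
import pytest

from longsad import (
    ENVIRONMENTAL,
    GENETIC,
    Pedigree,
    SadParams,
    SadSpec,
    TimeGrid,
)
from longsad.simulate import default_params


@pytest.fixture
def trio():
    return Pedigree([("s", "0", "0"), ("d", "0", "0"), ("x", "s", "d")])


@pytest.fixture
def grid4():
    return TimeGrid.weeks(4)


@pytest.fixture
def params4():
    """Default 4-trait world restricted to any grid (polynomials evaluate anywhere)."""
    return default_params()


def two_trait_spec(cross_degree=0, fi_env=(1, 1)):
    return SadSpec(
        traits=("ADG", "FI"),
        degrees={
            ("ADG", GENETIC): (0, 0),
            ("ADG", ENVIRONMENTAL): (0, 0),
            ("FI", GENETIC): (1, 1),
            ("FI", ENVIRONMENTAL): fi_env,
        },
        cross_degree={GENETIC: cross_degree, ENVIRONMENTAL: cross_degree},
    )


@pytest.fixture
def two_trait_params():
    spec = two_trait_spec(cross_degree=0)
    return SadParams(
        spec,
        theta={
            ("ADG", GENETIC): (0.6,),
            ("ADG", ENVIRONMENTAL): (0.5,),
            ("FI", GENETIC): (0.4, 0.02),
            ("FI", ENVIRONMENTAL): (0.5, 0.01),
        },
        logvar={
            ("ADG", GENETIC): (np.log(60.0),),
            ("ADG", ENVIRONMENTAL): (np.log(130.0),),
            ("FI", GENETIC): (np.log(150.0), -0.02),
            ("FI", ENVIRONMENTAL): (np.log(900.0), -0.01),
        },
        cross={(GENETIC, "ADG"): (1.0,), (ENVIRONMENTAL, "ADG"): (0.9,)},
    )


def random_params(rng, n_traits=4, cross_degree=1, max_degree=1):
    """Random valid SadParams for property tests (moderate thetas, bounded vars)."""
    traits = tuple(f"T{i}" for i in range(n_traits - 1)) + ("FI",)
    degrees = {}
    theta, logvar, cross = {}, {}, {}
    for s in traits:
        for comp in (GENETIC, ENVIRONMENTAL):
            bt = int(rng.integers(0, max_degree + 1))
            gv = int(rng.integers(0, max_degree + 1))
            degrees[(s, comp)] = (bt, gv)
            th = np.zeros(bt + 1)
            th[0] = rng.uniform(-0.8, 0.8)
            if bt > 0:
                th[1:] = rng.uniform(-0.05, 0.05, bt)
            lv = np.zeros(gv + 1)
            lv[0] = rng.uniform(-0.5, 2.0)
            if gv > 0:
                lv[1:] = rng.uniform(-0.1, 0.1, gv)
            theta[(s, comp)] = th
            logvar[(s, comp)] = lv
    spec = SadSpec(traits=traits, degrees=degrees,
                   cross_degree={GENETIC: cross_degree, ENVIRONMENTAL: cross_degree})
    if cross_degree is not None:
        for comp in (GENETIC, ENVIRONMENTAL):
            for tgt in traits[:-1]:
                cc = np.zeros(cross_degree + 1)
                cc[0] = rng.uniform(-1.0, 1.0)
                if cross_degree > 0:
                    cc[1:] = rng.uniform(-0.1, 0.1, cross_degree)
                cross[(comp, tgt)] = cc
    return SadParams(spec, theta, logvar, cross)


def random_pedigree(rng, n=50, n_founders=10):
    recs = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in recs]
    for i in range(n - n_founders):
        s, d = rng.choice(len(ids), size=2, replace=False)
        recs.append((f"A{i}", ids[s], ids[d]))
        ids.append(f"A{i}")
    return Pedigree(recs)
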