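"""End-to-end analysis steps as plain functions over a config dict.

The package is driven from Python; these functions are the batch interface:
``run_simulate`` writes a synthetic dataset, ``run_fit`` fits one of the two
RFI models and writes its artefacts, ``run_report`` turns fits into selection
outputs and model comparisons.  Every run writes a provenance block (config
hash, seed, package version) and all outputs are deterministic CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_tables import (
    FLOAT_FORMAT,
    config_hash,
    read_phenotypes,
    validate_config,
    write_fit_json,
    write_labelled_matrix,
    write_phenotypes,
    write_tebv,
)
from .mixed_model import blup_solve, information_condition_number, parameter_names
from .pedigree import build_A, read_pedigree
from .phenotypes import PhenotypeTable
from .rfi import (
    RfiComponents,
    fit_multi_sad_model,
    fit_phenotypic_regression_model,
    heritability_profile,
    regression_trajectories,
    rfi_star_covariances,
    rfi_star_from_blup,
)
from .sad import GENETIC, TimeGrid
from .selection import (
    cluster_trajectories,
    cohens_kappa,
    eigen_summary,
    spearman_by_week,
)
from .simulate import default_config, simulate_dataset

__all__ = ["run_simulate", "run_fit", "run_report", "CONFIG_SCHEMA"]

CONFIG_SCHEMA = {
    "paths": {"pedigree": None, "phenotypes": None, "out_dir": "out"},
    "simulate": {"n_generations": 3, "n_sires": 20, "n_dams": 50,
                 "litter_size": 8, "n_weeks": 10, "complete": False,
                 "seed": 20210625},
    "model": {"model": "multi_sad", "two_stage": True,
              "estar_coefficients": "genetic"},
    "fit": {"maxiter": 500, "seed": 0, "compute_information": True},
    "report": {"k_sbv": 2, "k_clusters": 3, "cluster_seed": 20210625},
}


def _provenance(cfg: dict, out: Path) -> None:
    with open(out / "provenance.json", "w") as fh:
        json.dump({"config_hash": config_hash(cfg), "version": __version__,
                   "config": cfg}, fh, indent=1, sort_keys=True, default=str)


def run_simulate(config: dict) -> dict:
    """Simulate the default world and write pedigree/phenotype/truth files."""
    cfg = validate_config(config, CONFIG_SCHEMA)
    out = Path(cfg["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    sc = cfg["simulate"]
    sim_cfg = default_config(
        n_generations=sc["n_generations"], n_sires=sc["n_sires"],
        n_dams=sc["n_dams"], litter_size=sc["litter_size"],
        grid=TimeGrid.weeks(sc["n_weeks"]), seed=sc["seed"],
    )
    ped, pheno, effects = simulate_dataset(sim_cfg, complete=sc["complete"])
    pd.DataFrame(ped.records, columns=["animal", "sire", "dam"]).to_csv(
        out / "pedigree.csv", index=False
    )
    write_phenotypes(pheno, out / "phenotypes.csv")
    from .mixed_model import params_to_vector
    truth = dict(zip(parameter_names(sim_cfg.params.spec),
                     map(float, params_to_vector(sim_cfg.params))))
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    _provenance(cfg, out)
    return {"pedigree": ped, "phenotypes": pheno, "effects": effects,
            "out_dir": out}


def run_fit(config: dict, pheno: PhenotypeTable | None = None, ped=None) -> dict:
    """Fit the configured RFI model and write fit artefacts."""
    cfg = validate_config(config, CONFIG_SCHEMA)
    out = Path(cfg["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    if pheno is None:
        pheno = read_phenotypes(cfg["paths"]["phenotypes"])
    if ped is None:
        ped = read_pedigree(cfg["paths"]["pedigree"])
    A = build_A(ped)
    grid = pheno.grid()
    mc, fc = cfg["model"], cfg["fit"]
    kwargs = dict(maxiter=fc["maxiter"], seed=fc["seed"],
                  compute_information=fc["compute_information"])
    if mc["model"] == "multi_sad":
        from .simulate import default_spec
        fit = fit_multi_sad_model(pheno, A, default_spec(), grid=grid,
                                  two_stage=mc["two_stage"], **kwargs)
    elif mc["model"] == "phenotypic_regression":
        fit = fit_phenotypic_regression_model(pheno, A, grid=grid, **kwargs)
    else:
        raise ValueError(f"unknown model {mc['model']!r}")
    extra = {}
    if fit.information is not None:
        cond, flagged = information_condition_number(fit)
        extra["information_condition_number"] = cond
        extra["identifiability_flagged"] = bool(flagged)
    write_fit_json(fit, out / f"fit_{fit.model}.json", extra=extra)
    labels = [f"{s}:{int(t)}" for s in fit.spec.traits for t in grid.times]
    write_labelled_matrix(fit.sigma_g(), labels, out / f"Sg_{fit.model}.csv")
    write_labelled_matrix(fit.sigma_e(), labels, out / f"Se_{fit.model}.csv")
    blup = blup_solve(fit, A)
    write_tebv(blup, out / f"tebv_{fit.model}.csv")
    regression_trajectories(fit).to_csv(
        out / f"trajectories_{fit.model}.csv", index=False,
        float_format=FLOAT_FORMAT,
    )
    _provenance(cfg, out)
    return {"fit": fit, "blup": blup, "A": A, "out_dir": out}


def run_report(config: dict, fits: dict) -> dict:
    """Selection outputs and (when two fits are given) model comparison.

    ``fits`` maps model tag -> the dict returned by :func:`run_fit`.
    """
    cfg = validate_config(config, CONFIG_SCHEMA)
    out = Path(cfg["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    rc = cfg["report"]
    results = {}
    rfi_by_model = {}
    for tag, rf in fits.items():
        fit, blup = rf["fit"], rf["blup"]
        grid = fit.data.grid
        n = grid.n
        if fit.information is not None:
            heritability_profile(fit).to_csv(
                out / f"h2_{tag}.csv", index=False, float_format=FLOAT_FORMAT)
        if tag == "multi_sad":
            cs = rfi_star_covariances(
                fit.params, grid,
                coefficients=cfg["model"]["estar_coefficients"])
            G = cs.genetic
            comp = rfi_star_from_blup(fit, blup)
        else:
            G = fit.sigma_g()
            pos = {a: i for i, a in enumerate(blup["ids"])}
            idx = [pos[a] for a in blup["animals"]]
            comp = RfiComponents(blup["animals"], [int(t) for t in grid.times],
                                 blup["tebv"][idx], blup["residual"], tag)
        rfi_by_model[tag] = comp
        comp.to_frame().to_csv(out / f"rfi_{tag}.csv", index=False,
                               float_format=FLOAT_FORMAT)
        k = min(rc["k_sbv"], n)
        bv = eigen_summary(G, comp.u, k=k, animals=comp.animals,
                           weeks=comp.weeks)
        bv.to_frame().to_csv(out / f"sbv_{tag}.csv", index=False,
                             float_format=FLOAT_FORMAT)
        labels = cluster_trajectories(comp.u, rc["k_clusters"],
                                      seed=rc["cluster_seed"])
        pd.DataFrame({"animal": comp.animals, "cluster": labels}).to_csv(
            out / f"clusters_{tag}.csv", index=False)
        results[tag] = {"bv": bv, "clusters": labels, "rfi": comp}
    if len(fits) >= 2:
        (a, ra), (b, rb) = list(results.items())[:2]
        shared = sorted(set(rfi_by_model[a].animals) & set(rfi_by_model[b].animals))
        ia = [rfi_by_model[a].animals.index(x) for x in shared]
        ib = [rfi_by_model[b].animals.index(x) for x in shared]
        sp = spearman_by_week(rfi_by_model[a].u[ia], rfi_by_model[b].u[ib],
                              weeks=rfi_by_model[a].weeks)
        sp.to_csv(out / "ebv_spearman.csv", index=False,
                  float_format=FLOAT_FORMAT)
        kappa = cohens_kappa(ra["clusters"][np.array(ia)],
                             rb["clusters"][np.array(ib)])
        results["comparison"] = {"spearman": sp, "kappa": kappa}
        with open(out / "comparison.json", "w") as fh:
            json.dump({"kappa": kappa,
                       "spearman_mean": float(sp["rho"].mean())}, fh, indent=1)
    else:
        (out / "comparison.json").write_text('{"note": "single fit, no comparison"}\n')
    _provenance(cfg, out)
    return results
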