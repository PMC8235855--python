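"""Bit-stable tabular I/O: labelled CSV matrices, fit summaries, configs.

Everything is plain CSV/JSON text; floating point is written with 10
significant digits so repeated runs under the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .phenotypes import PhenotypeTable
from .sad import TimeGrid

__all__ = [
    "FLOAT_FORMAT",
    "write_phenotypes",
    "read_phenotypes",
    "write_labelled_matrix",
    "read_labelled_matrix",
    "write_fit_json",
    "write_tebv",
    "validate_config",
    "config_hash",
]

FLOAT_FORMAT = "%.10g"


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, dtype={"animal": str, "trait": str}))


def write_labelled_matrix(M: np.ndarray, labels: list[str], path) -> None:
    """Square matrix as CSV with `trait:week` row/column labels."""
    pd.DataFrame(M, index=labels, columns=labels).to_csv(
        path, float_format=FLOAT_FORMAT
    )


def read_labelled_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), list(df.index)


def _spec_dict(spec) -> dict:
    return {
        "traits": list(spec.traits),
        "degrees": {f"{s}:{c}": list(spec.degrees[(s, c)])
                    for (s, c) in spec.degrees},
        "cross_degree": {c: spec.cross_degree[c] for c in spec.cross_degree},
    }


def write_fit_json(fit, path, extra: dict | None = None) -> None:
    from .mixed_model import parameter_names

    payload = {
        "model": fit.model,
        "spec": _spec_dict(fit.spec),
        "parameters": dict(zip(parameter_names(fit.spec),
                               [float(v) for v in fit.omega])),
        "free": [bool(f) for f in fit.free],
        "reml_loglik": float(fit.reml_loglik),
        "converged": bool(fit.converged),
        "n_obs": int(fit.data.n_obs),
        "fixed_effects": {":".join(map(str, k)): float(v)
                          for k, v in fit.fixed_effects.items()},
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_tebv(blup: dict, path, phenotyped_only: bool = False) -> None:
    """TEBV as long CSV: animal, trait, week, value."""
    ids = blup["animals"] if phenotyped_only else blup["ids"]
    pos = {a: i for i, a in enumerate(blup["ids"])}
    grid: TimeGrid = blup["grid"]
    n = grid.n
    rows = []
    for a in ids:
        row = blup["tebv"][pos[a]]
        for si, s in enumerate(blup["traits"]):
            for j, w in enumerate(grid.times):
                rows.append((a, s, int(w), row[si * n + j]))
    pd.DataFrame(rows, columns=["animal", "trait", "week", "value"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def validate_config(config: dict, schema: dict) -> dict:
    """Reject unknown keys, apply defaults from a nested schema."""
    out = {}
    for section, fields in schema.items():
        sub = dict(config.get(section, {}))
        unknown = set(sub) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys in [{section}]: {sorted(unknown)}")
        out[section] = {k: sub.get(k, default) for k, default in fields.items()}
    unknown = set(config) - set(schema)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
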