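"""Selection criteria and model-comparison statistics from TEBV trajectories.

An animal's time-specific breeding values (TEBV) form a trajectory over the
test period.  Projecting that trajectory onto the leading eigenvectors of the
genetic covariance matrix gives summarised breeding values: SBV1 tracks the
average genetic level of feed efficiency, SBV2 the main slope of its change
over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "BreedingValueSet",
    "eigen_summary",
    "cluster_trajectories",
    "cohens_kappa",
    "spearman_by_week",
    "generation_trend",
]

DEFAULT_SEED = 20210625


@dataclass
class BreedingValueSet:
    """TEBV trajectories with their eigen summary."""

    animals: list[str]
    weeks: list[int]
    tebv: np.ndarray            # (N, n)
    eigenvalues: np.ndarray     # (k,) descending
    eigenvectors: np.ndarray    # (n, k), unit columns, non-negative entry sum
    sbv: np.ndarray             # (N, k)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"SBV{k + 1}": self.sbv[:, k] for k in range(self.sbv.shape[1])}
        return pd.DataFrame({"animal": self.animals, **cols})


def eigen_summary(G: np.ndarray, tebv: np.ndarray, k: int,
                  animals: list[str] | None = None,
                  weeks: list[int] | None = None) -> BreedingValueSet:
    """Top-k eigenpairs of the genetic covariance matrix and SBV projections.

    Eigenvector signs are fixed by making each column's entry sum
    non-negative, so SBV are deterministic across runs and platforms.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    tebv = np.asarray(tebv, dtype=float)
    lam, vec = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(lam)[::-1][:k]
    lam, vec = lam[order], vec[:, order]
    sign = np.where(vec.sum(axis=0) < 0, -1.0, 1.0)
    vec = vec * sign
    sbv = tebv @ vec
    return BreedingValueSet(
        animals=list(animals) if animals is not None else [str(i) for i in range(len(tebv))],
        weeks=list(weeks) if weeks is not None else list(range(1, n + 1)),
        tebv=tebv, eigenvalues=lam, eigenvectors=vec, sbv=sbv,
    )


def cluster_trajectories(tebv: np.ndarray, k: int = 3,
                         seed: int = DEFAULT_SEED, n_init: int = 25) -> np.ndarray:
    """k-means clustering of TEBV trajectories, deterministic under seed.

    Cluster labels are relabelled by ascending cluster-mean trajectory average
    (label 0 = lowest mean), removing k-means label arbitrariness.
    """
    tebv = np.asarray(tebv, dtype=float)
    if np.isnan(tebv).any():
        raise ValueError("trajectories contain missing entries")
    if not (2 <= k <= len(tebv)):
        raise ValueError("need 2 <= k <= number of animals")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(tebv)
    means = np.array([tebv[raw == c].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[np.argsort(means)] = np.arange(k)
    return relabel[raw]


def _align_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Relabel b to best match a (Hungarian assignment on the confusion table)."""
    la, lb = np.unique(a), np.unique(b)
    conf = np.zeros((len(la), len(lb)))
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            conf[i, j] = np.sum((a == x) & (b == y))
    ri, ci = linear_sum_assignment(-conf)
    mapping = {lb[j]: la[i] for i, j in zip(ri, ci)}
    # unmatched labels of b (if more clusters in b) keep themselves
    return np.array([mapping.get(y, y) for y in b])


def cohens_kappa(labels_a, labels_b, match: bool = True) -> float:
    """Cohen's kappa agreement, after optimal label matching by default.

    Raw clustering labels are arbitrary, so b is first permuted to maximise
    the diagonal of the confusion table (Hungarian assignment).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if len(np.unique(np.concatenate([a, b]))) < 2:
        raise ValueError("kappa undefined for a single shared label")
    if match:
        b = _align_labels(a, b)
    labels = np.unique(np.concatenate([a, b]))
    po = np.mean(a == b)
    pe = sum(np.mean(a == lev) * np.mean(b == lev) for lev in labels)
    if pe == 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return float((po - pe) / (1.0 - pe))


def spearman_by_week(
    values_a: np.ndarray,
    values_b: np.ndarray,
    weeks: list[int] | None = None,
    grouping: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-week (and per-group) Spearman rank correlation with Fisher-z 95% CI."""
    A = np.asarray(values_a, dtype=float)
    B = np.asarray(values_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("arrays must share (animals, weeks) shape")
    N, n = A.shape
    weeks = weeks if weeks is not None else list(range(1, n + 1))
    groups = (np.asarray(grouping) if grouping is not None
              else np.array(["all"] * N))
    rows = []
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() < 3:
            raise ValueError(f"fewer than 3 shared animals in group {g!r}")
        for j, w in enumerate(weeks):
            rho = stats.spearmanr(A[sel, j], B[sel, j]).statistic
            z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
            hw = 1.959964 / np.sqrt(sel.sum() - 3)
            rows.append({
                "group": g, "week": int(w), "rho": float(rho),
                "ci_low": float(np.tanh(z - hw)), "ci_high": float(np.tanh(z + hw)),
            })
    return pd.DataFrame(rows)


def generation_trend(
    sbv: BreedingValueSet, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-line, per-generation SBV means with standard errors.

    ``metadata`` columns: animal, line, generation; it must cover every
    animal in the breeding-value set.  Empty line-generation groups are
    simply absent from the output.
    """
    meta = metadata.set_index("animal")
    missing = [a for a in sbv.animals if a not in meta.index]
    if missing:
        raise ValueError(f"metadata lacks animals {missing[:5]}")
    df = sbv.to_frame()
    df["line"] = [meta.loc[a, "line"] for a in sbv.animals]
    df["generation"] = [meta.loc[a, "generation"] for a in sbv.animals]
    comps = [c for c in df.columns if c.startswith("SBV")]
    out = df.groupby(["line", "generation"])[comps].agg(["mean", "sem"])
    out.columns = [f"{c}_{stat}" for c, stat in out.columns]
    return out.reset_index()
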