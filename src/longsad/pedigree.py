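"""Pedigree handling and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` encodes expected
additive-genetic relatedness between animals given a pedigree: the kernel of
every genetic covariance in the animal models of this package.  ``A`` is built
with the tabular method (exact inbreeding), and its inverse with Henderson's
rules corrected for inbreeding, so that large pedigrees never require a dense
matrix inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "RelationshipMatrix",
    "read_pedigree",
    "build_A",
    "build_A_inverse",
    "write_relationship_matrix",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate, dangling parent)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree: parents always precede offspring.

    ``records`` is a list of ``(animal, sire, dam)`` string tokens, with
    :data:`UNKNOWN` (``"0"``) for unknown parents.  Unknown parents are treated
    as unrelated, non-inbred founders (single-population design, no genetic
    groups).
    """

    records: list[tuple[str, str, str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._validate_and_sort()

    def _validate_and_sort(self) -> None:
        ids = [r[0] for r in self.records]
        seen: set[str] = set()
        for a in ids:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            if a == UNKNOWN:
                raise PedigreeError(f"animal id may not be the missing code {UNKNOWN!r}")
            seen.add(a)
        parents = {r[0]: tuple(p for p in r[1:] if p != UNKNOWN) for r in self.records}
        for a, ps in parents.items():
            for p in ps:
                if p not in parents:
                    raise PedigreeError(f"parent {p!r} of {a!r} has no pedigree record")
        # Kahn topological sort; stable w.r.t. input order for determinism.
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited, 1 on stack, 2 done

        def visit(a: str, stack: list[str]) -> None:
            if state.get(a) == 2:
                return
            if state.get(a) == 1:
                cyc = stack[stack.index(a):] + [a]
                raise PedigreeError("pedigree cycle: " + " -> ".join(cyc))
            state[a] = 1
            stack.append(a)
            for p in parents[a]:
                visit(p, stack)
            stack.pop()
            state[a] = 2
            order.append(a)

        for a in parents:
            visit(a, [])
        rec = {r[0]: r for r in self.records}
        self.records = [rec[a] for a in order]
        self._index = {a: i for i, a in enumerate(order)}

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of sire/dam positions, -1 for unknown."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, (_, s, d) in enumerate(self.records):
            if s != UNKNOWN:
                out[i, 0] = self._index[s]
            if d != UNKNOWN:
                out[i, 1] = self._index[d]
        return out


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix with its id ordering."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")

    def submatrix(self, ids: list[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[a] for a in ids])
        return self.values[np.ix_(idx, idx)]

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0


def read_pedigree(path) -> Pedigree:
    """Read a 3-column (animal, sire, dam) CSV/TSV pedigree.

    Missing parents may be coded ``0`` or left empty.  The result is
    topologically sorted regardless of row order in the file.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs 3 columns: animal, sire, dam")
    recs = []
    for a, s, d in df.iloc[:, :3].itertuples(index=False):
        recs.append(
            (a.strip(), s.strip() or UNKNOWN, d.strip() or UNKNOWN)
        )
    return Pedigree(recs)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ij = (A_{j,sire(i)} + A_{j,dam(i)}) / 2 for j earlier than i, and
    A_ii = 1 + A_{sire(i),dam(i)} / 2; unknown parents contribute zero.
    Inbreeding is therefore exact.
    """
    n = len(ped)
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(ped.ids, A)


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Inverse of A by Henderson's rules with Meuwissen–Luo style inbreeding.

    Uses the decomposition A = T D T' implied by the pedigree: the Mendelian
    sampling variance of animal i is
    d_i = 0.5 - 0.25 (F_sire + F_dam) with each known parent contributing,
    i.e. d_i = 1 - 0.25 sum_p (1 + F_p) over known parents p.  Then
    A^{-1} = sum_i (1/d_i) (e_i - 0.5 e_s - 0.5 e_d)(...)'.
    """
    n = len(ped)
    par = ped.parent_indices()
    F = build_A(ped).inbreeding()  # exact F via tabular method
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        dii = 1.0
        for p in (s, d):
            if p >= 0:
                dii -= 0.25 * (1.0 + F[p])
        w = 1.0 / dii
        Ainv[i, i] += w
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= 0.5 * w
                Ainv[p, i] -= 0.5 * w
                Ainv[p, p] += 0.25 * w
        if s >= 0 and d >= 0:
            Ainv[s, d] += 0.25 * w
            Ainv[d, s] += 0.25 * w
    return RelationshipMatrix(ped.ids, Ainv)


def write_relationship_matrix(rel: RelationshipMatrix, path, id_map_path=None) -> None:
    """Write A (or its inverse) as a sparse triplet CSV plus an id map."""
    i, j = np.nonzero(np.triu(rel.values != 0.0))
    pd.DataFrame({"i": i, "j": j, "value": rel.values[i, j]}).to_csv(path, index=False)
    if id_map_path is not None:
        pd.DataFrame({"index": range(len(rel.ids)), "animal": rel.ids}).to_csv(
            id_map_path, index=False
        )
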