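"""Pedigree algebra for quantitative-genetic analyses.

A pedigree is a set of ``(individual, dam, sire)`` triples with missing
parents allowed.  From it we derive the additive (numerator) relationship
matrix **A** by the tabular method, inbreeding coefficients under the
"known parents and grandparents" reporting rule used for wild pedigrees
with partial parentage information, generation depths, and simulated
breeding values (gene-dropping of additive effects with Mendelian
sampling variance) for power analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, unknown ids)."""


@dataclass
class Pedigree:
    """Ordered pedigree with integer-coded parents.

    Parameters
    ----------
    ids :
        Individual identifiers, parents before offspring after construction
        (:meth:`from_triples` topologically sorts).
    dam, sire :
        Integer index into ``ids`` of each individual's dam/sire, or
        ``UNKNOWN`` (−1).
    """

    ids: list
    dam: np.ndarray
    sire: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.ids)}
        # parents must precede offspring
        idx = np.arange(len(self.ids))
        for par in (self.dam, self.sire):
            known = par >= 0
            if np.any(par[known] >= idx[known]):
                bad = self.ids[int(idx[known][par[known] >= idx[known]][0])]
                raise PedigreeError(f"parent listed after offspring near {bad!r}; not topologically sorted")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, individual: Hashable) -> int:
        return self._index[individual]

    @classmethod
    def from_triples(
        cls, triples: Iterable[tuple[Hashable, Hashable | None, Hashable | None]]
    ) -> "Pedigree":
        """Build from ``(id, dam, sire)`` triples, sorting parents first.

        ``None``, ``NaN`` or empty-string parents are unknown.  Parents that
        never appear as individuals are added as founders.  Cycles raise
        :class:`PedigreeError` naming one individual on the cycle.
        """
        triples = list(triples)

        def _norm(v):
            if v is None:
                return None
            if isinstance(v, float) and np.isnan(v):
                return None
            if isinstance(v, str) and v.strip() == "":
                return None
            return v

        parents: dict = {}
        for ind, dam, sire in triples:
            ind = _norm(ind)
            if ind is None:
                raise PedigreeError("individual id may not be missing")
            if ind in parents:
                raise PedigreeError(f"duplicate individual {ind!r}")
            parents[ind] = (_norm(dam), _norm(sire))
        # implicit founders
        for dam, sire in list(parents.values()):
            for p in (dam, sire):
                if p is not None and p not in parents:
                    parents[p] = (None, None)

        # Kahn-style topological sort, stable in input order
        order: list = []
        state: dict = {}  # 0 unvisited, 1 in-stack, 2 done

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    state[n] = 2
                    order.append(n)
                    continue
                st = state.get(n, 0)
                if st == 2:
                    continue
                if st == 1:
                    raise PedigreeError(f"pedigree cycle detected through {n!r}")
                state[n] = 1
                stack.append((n, True))
                for p in parents[n]:
                    if p is not None and state.get(p, 0) != 2:
                        if state.get(p, 0) == 1:
                            raise PedigreeError(f"pedigree cycle detected through {p!r}")
                        stack.append((p, False))

        for ind in parents:
            if state.get(ind, 0) == 0:
                visit(ind)

        index = {v: i for i, v in enumerate(order)}
        dam = np.array([index[parents[i][0]] if parents[i][0] is not None else UNKNOWN for i in order])
        sire = np.array([index[parents[i][1]] if parents[i][1] is not None else UNKNOWN for i in order])
        return cls(ids=order, dam=dam, sire=sire, _index=index)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_col: str = "id", dam_col: str = "dam", sire_col: str = "sire") -> "Pedigree":
        return cls.from_triples(zip(df[id_col], df[dam_col], df[sire_col]))

    def to_frame(self) -> pd.DataFrame:
        def name(j):
            return self.ids[j] if j >= 0 else None

        return pd.DataFrame(
            {
                "id": self.ids,
                "dam": [name(j) for j in self.dam],
                "sire": [name(j) for j in self.sire],
            }
        )

    def subset_descendants_of_cohort(self, keep: Sequence[Hashable]) -> "Pedigree":
        """Restrict to the given individuals, pruning parent links that leave the set."""
        keep_set = set(keep)
        rows = []
        for i, ind in enumerate(self.ids):
            if ind not in keep_set:
                continue
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else None
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else None
            rows.append((ind, d if d in keep_set else None, s if s in keep_set else None))
        return Pedigree.from_triples(rows)


def additive_relationship(ped: Pedigree) -> np.ndarray:
    """Additive (numerator) relationship matrix **A** by the tabular method.

    ``A[i, i] = 1 + F_i`` with ``F_i = A[dam_i, sire_i] / 2``;
    ``A[i, j] = (A[j, dam_i] + A[j, sire_i]) / 2`` for ``j < i``.
    Unknown parents contribute zero (treated as unique unrelated founders).
    """
    n = len(ped)
    A = np.zeros((n, n))
    dam, sire = ped.dam, ped.sire
    for i in range(n):
        d, s = dam[i], sire[i]
        if i > 0:
            row = np.zeros(i)
            if d >= 0:
                row += A[d, :i]
            if s >= 0:
                row += A[s, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        f = 0.5 * A[d, s] if (d >= 0 and s >= 0) else 0.0
        A[i, i] = 1.0 + f
    return A


def inbreeding_coefficients(ped: Pedigree, require_grandparents: bool = True) -> pd.Series:
    """Per-individual inbreeding coefficient ``F``, NaN where unreliable.

    ``F`` is the diagonal of **A** minus one, but reported as missing for any
    individual with at least one unknown parent or — under the default
    reporting rule — unknown grandparent, since missing ancestry biases ``F``
    towards zero.
    """
    A = additive_relationship(ped)
    F = np.diag(A) - 1.0
    out = F.copy()
    for i in range(len(ped)):
        d, s = ped.dam[i], ped.sire[i]
        if d < 0 or s < 0:
            out[i] = np.nan
            continue
        if require_grandparents:
            gps = [ped.dam[d], ped.sire[d], ped.dam[s], ped.sire[s]]
            if any(g < 0 for g in gps):
                out[i] = np.nan
    return pd.Series(out, index=pd.Index(ped.ids, name="id"), name="F")


def pedigree_depth(ped: Pedigree, founders_at_one: bool = False) -> tuple[pd.Series, dict]:
    """Generation depth per individual plus (max, mean) summary.

    Depth is the length of the longest known ancestor chain ending at the
    individual; founders have depth 0.  ``founders_at_one`` shifts the whole
    scale by one (founders = 1), an alternative convention some studies use
    when reporting mean pedigree depth.
    """
    n = len(ped)
    depth = np.zeros(n, dtype=int)
    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        cands = [depth[d] + 1 if d >= 0 else 0, depth[s] + 1 if s >= 0 else 0]
        depth[i] = max(cands)
    if founders_at_one:
        depth = depth + 1
    series = pd.Series(depth, index=pd.Index(ped.ids, name="id"), name="depth")
    summary = {"max": int(depth.max()), "mean": float(depth.mean())}
    return series, summary


def simulate_breeding_values(
    ped: Pedigree,
    sigma2_A: float,
    seed: int | np.random.Generator | None = None,
    inbreeding: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate additive breeding values along the pedigree.

    Founders draw from ``N(0, sigma2_A)``.  An individual with both parents
    known gets the mid-parent value plus a Mendelian deviation of variance
    ``sigma2_A * (1/2 − (F_dam + F_sire)/4)``.  A missing parent's share is
    replaced by an independent founder draw (variance accounting identical to
    the tabular-method convention of unknown = unrelated founder).
    """
    if sigma2_A < 0:
        raise ValueError("sigma2_A must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(ped)
    if sigma2_A == 0:
        return np.zeros(n)
    if inbreeding is None:
        inbreeding = np.diag(additive_relationship(ped)) - 1.0
    bv = np.zeros(n)
    z = rng.standard_normal(n)
    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        if d < 0 and s < 0:
            bv[i] = np.sqrt(sigma2_A) * z[i]
            continue
        mid = 0.0
        # variance of the Mendelian/phantom deviation so Var(bv_i) stays consistent
        if d >= 0 and s >= 0:
            mid = 0.5 * (bv[d] + bv[s])
            v = sigma2_A * (0.5 - 0.25 * (inbreeding[d] + inbreeding[s]))
        else:
            p = d if d >= 0 else s
            mid = 0.5 * bv[p]
            v = sigma2_A * (0.75 - 0.25 * inbreeding[p])
        bv[i] = mid + np.sqrt(max(v, 0.0)) * z[i]
    return bv


def write_sparse_triplets(A: np.ndarray, ids: Sequence, path, tol: float = 0.0) -> None:
    """Write the lower triangle of a relationship matrix as ``i\tj\tvalue`` text."""
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        n = A.shape[0]
        for i in range(n):
            for j in range(i + 1):
                if abs(A[i, j]) > tol:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{A[i, j]:.10g}\n")


def read_pedigree_csv(path, id_col: str = "id", dam_col: str = "dam", sire_col: str = "sire") -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Pedigree.from_frame(df, id_col, dam_col, sire_col)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)
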