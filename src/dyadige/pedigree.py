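"""Pedigree handling and additive relationship matrices.

A pedigree is the substrate of every animal model: the numerator
relationship matrix ``A`` it implies gives the expected additive genetic
covariance between any two individuals, and its sparse inverse is what
mixed-model equations consume.  This module provides

* :class:`Pedigree` — validated, topologically ordered pedigree records
  with CSV round-trip (header ``id,sire,dam,sex``, unknown parent ``"0"``);
* :func:`build_half_sib_design` — a paternal half-sib breeding design
  generator (sires each mated to several dams, whole-family failures);
* :func:`relationship_matrix` — the tabular (recursive) method for ``A``
  with inbreeding on the diagonal (``A_ii = 1 + F_i``);
* :func:`inverse_relationship` — Henderson's rules with inbreeding,
  returning a sparse ``A^{-1}`` that touches only individual/parent
  triplets.

Founders are assumed unrelated and non-inbred.  Inbreeding is handled
throughout even when a particular design cannot produce it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"
MALE = "M"
FEMALE = "F"

__all__ = [
    "UNKNOWN",
    "MALE",
    "FEMALE",
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "DuplicateIdError",
    "UndefinedParentError",
    "PedigreeCycleError",
    "SexInconsistencyError",
    "read_pedigree",
    "build_half_sib_design",
    "relationship_matrix",
    "inverse_relationship",
]


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIdError(PedigreeError):
    """An individual id occurs more than once."""


class UndefinedParentError(PedigreeError):
    """A sire or dam id is referenced but never defined (and is not UNKNOWN)."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


class SexInconsistencyError(PedigreeError):
    """An id is used as a sire but recorded female, as a dam but recorded male,
    or appears on both sides."""


def _as_str(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    s = str(value).strip()
    return s if s else UNKNOWN


class Pedigree:
    """An ordered, validated pedigree.

    Parameters
    ----------
    table:
        DataFrame with columns ``id``, ``sire``, ``dam``, ``sex``.  Unknown
        parents may be given as ``"0"``, empty string or NA.  ``sex`` must be
        ``"M"`` or ``"F"``.
    sort:
        If True (default) the entries are re-sorted into a topological order
        (parents before offspring) when necessary instead of rejecting the
        input; the fact that a re-sort happened is recorded in
        :attr:`was_reordered`.
    """

    def __init__(self, table: pd.DataFrame, sort: bool = True):
        df = table.copy()
        required = ["id", "sire", "dam", "sex"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise PedigreeError(f"missing pedigree columns: {missing}")
        for col in ("id", "sire", "dam", "sex"):
            df[col] = df[col].map(_as_str)
        df["sex"] = df["sex"].str.upper()
        bad_sex = sorted(set(df["sex"]) - {MALE, FEMALE})
        if bad_sex:
            raise PedigreeError(f"sex must be M or F, got {bad_sex}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise DuplicateIdError(f"duplicate individual ids: {dups}")
        if (df["id"] == UNKNOWN).any():
            raise PedigreeError(f"individual id may not be the unknown code {UNKNOWN!r}")

        ids = set(df["id"])
        sex_of = dict(zip(df["id"], df["sex"]))
        sires = set(df["sire"]) - {UNKNOWN}
        dams = set(df["dam"]) - {UNKNOWN}
        undefined = sorted((sires | dams) - ids)
        if undefined:
            raise UndefinedParentError(f"parents referenced but never defined: {undefined}")
        both = sorted(sires & dams)
        if both:
            raise SexInconsistencyError(f"ids used as both sire and dam: {both}")
        wrong_sire = sorted(s for s in sires if sex_of[s] != MALE)
        if wrong_sire:
            raise SexInconsistencyError(f"sires recorded as female: {wrong_sire}")
        wrong_dam = sorted(d for d in dams if sex_of[d] != FEMALE)
        if wrong_dam:
            raise SexInconsistencyError(f"dams recorded as male: {wrong_dam}")

        # Topological order (parents before offspring); cycles are fatal.
        pos = {i: k for k, i in enumerate(df["id"])}
        g = nx.DiGraph()
        g.add_nodes_from(df["id"])
        for child, sire, dam in zip(df["id"], df["sire"], df["dam"]):
            for parent in (sire, dam):
                if parent != UNKNOWN:
                    g.add_edge(parent, child)
        try:
            order = list(nx.lexicographical_topological_sort(g, key=lambda i: pos[i]))
        except nx.NetworkXUnfeasible as exc:
            raise PedigreeCycleError("pedigree contains a cycle (an individual is "
                                     "its own ancestor)") from exc
        self.was_reordered = order != list(df["id"])
        if self.was_reordered:
            if not sort:
                raise PedigreeError("pedigree not in topological order and sort=False")
            df = df.set_index("id").loc[order].reset_index()

        self._df = df.reset_index(drop=True)
        self.ids: list[str] = list(df["id"])
        self.index: dict[str, int] = {i: k for k, i in enumerate(self.ids)}
        self.sire_idx = np.array(
            [self.index.get(s, -1) for s in df["sire"]], dtype=np.int64
        )
        self.dam_idx = np.array(
            [self.index.get(d, -1) for d in df["dam"]], dtype=np.int64
        )
        self.sex = np.array(df["sex"])

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self._df.equals(other._df)

    @property
    def table(self) -> pd.DataFrame:
        """Copy of the underlying table (columns id, sire, dam, sex)."""
        return self._df.copy()

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def males(self) -> list[str]:
        return [i for i, s in zip(self.ids, self.sex) if s == MALE]

    def females(self) -> list[str]:
        return [i for i, s in zip(self.ids, self.sex) if s == FEMALE]

    def offspring_ids(self) -> list[str]:
        founder = self.is_founder
        return [i for i, f in zip(self.ids, founder) if not f]

    # ------------------------------------------------------------------
    def to_csv(self, path_or_buf=None):
        """Write as CSV with header ``id,sire,dam,sex``; unknown parents as "0"."""
        return self._df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, source) -> "Pedigree":
        df = pd.read_csv(source, dtype=str)
        return cls(df)


def read_pedigree(source: Union[str, Path, io.IOBase]) -> Pedigree:
    """Read and validate a pedigree from a CSV file or stream.

    The file must carry columns ``id,sire,dam,sex``; unknown parents may be
    encoded as ``"0"`` or left empty.  Entries are re-sorted into topological
    order when needed (recorded on the returned object).
    """
    return Pedigree.from_csv(source)


def build_half_sib_design(
    n_sires: int,
    dams_per_sire: int,
    offspring_per_family: int,
    family_failure_rate: float = 0.0,
    sex_ratio: float = 0.5,
    seed: int = 0,
) -> Pedigree:
    """Generate a paternal half-sib breeding design.

    ``n_sires`` unrelated sires are each mated to ``dams_per_sire`` unrelated
    dams; every (sire, dam) pair is one full-sib family.  Whole families fail
    independently with probability ``family_failure_rate`` (breeding failure),
    and each surviving family contributes ``offspring_per_family`` offspring
    whose sexes are independent Bernoulli draws with ``P(male) = sex_ratio``.

    Deterministic given ``seed``.
    """
    if n_sires < 1 or dams_per_sire < 1 or offspring_per_family < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 <= family_failure_rate <= 1.0 and 0.0 <= sex_ratio <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_sires + 1):
        rows.append((f"S{s:03d}", UNKNOWN, UNKNOWN, MALE))
    for s in range(1, n_sires + 1):
        for d in range(1, dams_per_sire + 1):
            rows.append((f"D{s:03d}_{d}", UNKNOWN, UNKNOWN, FEMALE))
    for s in range(1, n_sires + 1):
        for d in range(1, dams_per_sire + 1):
            if rng.random() < family_failure_rate:
                continue
            sire, dam = f"S{s:03d}", f"D{s:03d}_{d}"
            for k in range(1, offspring_per_family + 1):
                sex = MALE if rng.random() < sex_ratio else FEMALE
                rows.append((f"O{s:03d}_{d}_{k:02d}", sire, dam, sex))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix over a pedigree.

    ``A[i, j]`` is twice the kinship coefficient of individuals ``order[i]``
    and ``order[j]``; ``A[i, i] = 1 + F[i]`` where ``F`` is the inbreeding
    coefficient (0 for founders).
    """

    order: list[str]
    A: np.ndarray
    F: np.ndarray

    def loc(self, i: str, j: str) -> float:
        idx = {v: k for k, v in enumerate(self.order)}
        return float(self.A[idx[i], idx[j]])


def relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Compute A by the tabular method.

    For individual ``i`` with parents ``s, d`` (appearing earlier in order):
    ``A_ij = 0.5 (A_js + A_jd)`` for earlier ``j`` and
    ``A_ii = 1 + 0.5 A_sd``; unknown-parent terms contribute 0.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s_idx, d_idx = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(order=list(ped.ids), A=A, F=np.diag(A) - 1.0)


def mendelian_variance(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian sampling) variance fraction per individual.

    1 for unknown-unknown, ``0.75 - 0.25 F_p`` with one known parent, and
    ``0.5 - 0.25 (F_s + F_d)`` with both parents known.
    """
    if F is None:
        F = relationship_matrix(ped).F
    d = np.ones(len(ped))
    for i in range(len(ped)):
        s, t = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and t >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[t])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif t >= 0:
            d[i] = 0.75 - 0.25 * F[t]
    return d


def inverse_relationship(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix.

    Henderson's rules with inbreeding: for each individual ``i`` with
    Mendelian variance ``d_i`` and known parents ``p``, add ``1/d_i`` at
    ``(i,i)``, ``-1/(2 d_i)`` at ``(i,p)``, and ``1/(4 d_i)`` at every
    known-parent pair ``(p,q)``.  Nonzeros therefore touch only
    (individual, parent, parent-pair) triplets.
    """
    n = len(ped)
    F = relationship_matrix(ped).F
    d = mendelian_variance(ped, F)
    assert np.all(d > 0), "singular A cannot occur for a valid pedigree"
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        ai = 1.0 / d[i]
        parents = [p for p in (ped.sire_idx[i], ped.dam_idx[i]) if p >= 0]
        add(i, i, ai)
        for p in parents:
            add(i, p, -0.5 * ai)
            add(p, i, -0.5 * ai)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * ai)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
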