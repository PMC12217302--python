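"""Bee-specific pedigree bookkeeping, relationship matrix A, and its inverse.

Honeybee pedigrees differ from plain diploid pedigrees in three ways:

* a queen's mate is not one male but a *drone group*: 8 drones (the
  polyandry level) produced by a single drone-producing queen (DPQ) for
  instrumental insemination, or by many unknown queens for open mating;
* drones are haploid — a drone is genetically one gamete of its mother and
  fathers every daughter with that identical genome, which creates
  super-sisters (same father drone) and half-sisters (different drones of
  the same DPQ) within one colony;
* the colony's worker group is itself a genetic entity (it expresses the
  worker effect on colony phenotypes) and equals, with very many workers,
  ``0.5 * queen + drone-group mean``.

The pedigree therefore holds four node kinds.  ``QUEEN`` nodes have a dam
(a queen) and a sire (a mating node).  ``SIRE`` nodes represent the drone
group of one insemination and descend from their DPQ.  ``PSEUDO_SIRE``
nodes represent one open mating: a drone group whose 8 drones come from a
private pool of 100 unknown, unrelated, non-inbred dummy DPQs.
``WORKER_GROUP`` nodes descend deterministically from their queen and her
mating node.

Relationships are expected additive covariances (in units of the base
additive variance).  They are generated by a directed Gaussian recursion:
conditional on the drone-group mean, the paternal contributions of
different daughters of one mating are uncorrelated (an exchangeability
identity: the covariance between two random picks of the 8 drones equals
the variance of the drone-group mean), so the Henderson-style
factorization A = (I-B)^-1 D (I-B)^-T is exact for the generating node set
{queens, sires, pseudo-sires}, including the super/half-sister mixture.
Worker-group rows are exact linear combinations of generating rows and are
appended on demand; jointly with their generators they make A singular,
which is why A^-1 is defined on the generating set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "NodeKind",
    "Pedigree",
    "RelationshipStore",
    "compute_A",
    "compute_A_inverse",
    "gene_drop_covariance",
    "inbreeding_trajectory",
]


class NodeKind(str, Enum):
    QUEEN = "QUEEN"
    WORKER_GROUP = "WORKER_GROUP"
    SIRE = "SIRE"
    PSEUDO_SIRE = "PSEUDO_SIRE"


_GENERATING = (NodeKind.QUEEN, NodeKind.SIRE, NodeKind.PSEUDO_SIRE)


class Pedigree:
    """Append-only bee pedigree; parents must be added before children."""

    def __init__(self) -> None:
        self.ids: list[str] = []
        self.kind: list[NodeKind] = []
        self.dam: list[int] = []          # -1 = unknown/base
        self.sire: list[int] = []         # -1 = unknown/base
        self.n_drones: list[int] = []
        self.n_dummy_dpq: list[int] = []
        self.birth_year: list[int | None] = []
        self._index: dict[str, int] = {}
        # lazy caches for relationship queries
        self._var: dict[int, float] = {}
        self._F: dict[int, float] = {}
        self._rel_memo: dict[tuple[int, int], float] = {}
        self._coeff_memo: dict[int, tuple[list[int], list[float], float]] = {}

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown pedigree node id {node_id!r}") from None

    def add_node(self, kind: NodeKind | str, dam_id: str | None = None,
                 sire_id: str | None = None, *, n_drones: int = 8,
                 n_dummy_dpq: int = 100, birth_year: int | None = None,
                 node_id: str | None = None) -> str:
        """Append one node and return its id.

        ``dam_id``/``sire_id`` must reference existing nodes or be None
        (unknown/base).  Kind/parent compatibility is enforced: queens and
        worker groups take a QUEEN dam and a SIRE/PSEUDO_SIRE sire; a SIRE
        node takes its DPQ as dam; pseudo-sires are base nodes.
        """
        kind = NodeKind(kind)
        dam = -1 if dam_id is None else self.index_of(dam_id)
        sire = -1 if sire_id is None else self.index_of(sire_id)
        if dam >= 0 and self.kind[dam] is not NodeKind.QUEEN:
            raise ValueError(f"dam of a {kind.value} must be a QUEEN, "
                             f"got {self.kind[dam].value}")
        if kind in (NodeKind.QUEEN, NodeKind.WORKER_GROUP):
            if sire >= 0 and self.kind[sire] not in (NodeKind.SIRE,
                                                     NodeKind.PSEUDO_SIRE):
                raise ValueError(f"sire of a {kind.value} must be a SIRE or "
                                 f"PSEUDO_SIRE node, got {self.kind[sire].value}")
            if kind is NodeKind.WORKER_GROUP and (dam < 0 or sire < 0):
                raise ValueError("a WORKER_GROUP needs its queen and her mating")
        elif kind is NodeKind.SIRE:
            if sire >= 0:
                raise ValueError("a SIRE node descends from its DPQ only "
                                 "(pass the DPQ as dam_id)")
        elif kind is NodeKind.PSEUDO_SIRE:
            if dam >= 0 or sire >= 0:
                raise ValueError("a PSEUDO_SIRE is a base node without parents")
        if node_id is None:
            node_id = f"{kind.value[0]}{len(self.ids)}"
        if node_id in self._index:
            raise ValueError(f"duplicate node id {node_id!r}")

        self._index[node_id] = len(self.ids)
        self.ids.append(node_id)
        self.kind.append(kind)
        self.dam.append(dam)
        self.sire.append(sire)
        self.n_drones.append(int(n_drones))
        self.n_dummy_dpq.append(int(n_dummy_dpq))
        self.birth_year.append(birth_year)
        return node_id

    # convenience wrappers used by the scheme engine
    def add_queen(self, dam_id: str | None, mating_id: str | None,
                  birth_year: int | None = None, node_id: str | None = None) -> str:
        return self.add_node(NodeKind.QUEEN, dam_id, mating_id,
                             birth_year=birth_year, node_id=node_id)

    def add_mating(self, dpq_id: str, n_drones: int = 8,
                   node_id: str | None = None) -> str:
        """Drone group of one instrumental insemination from a single DPQ."""
        return self.add_node(NodeKind.SIRE, dam_id=dpq_id, n_drones=n_drones,
                             node_id=node_id)

    def add_open_mating(self, n_drones: int = 8, n_dummy_dpq: int = 100,
                        node_id: str | None = None) -> str:
        return self.add_node(NodeKind.PSEUDO_SIRE, n_drones=n_drones,
                             n_dummy_dpq=n_dummy_dpq, node_id=node_id)

    def add_worker_group(self, queen_id: str, mating_id: str,
                         node_id: str | None = None) -> str:
        return self.add_node(NodeKind.WORKER_GROUP, queen_id, mating_id,
                             node_id=node_id)

    # ------------------------------------------------------------------ #
    # generating coefficients of the directed Gaussian model
    # ------------------------------------------------------------------ #

    def _coeffs(self, i: int) -> tuple[list[int], list[float], float]:
        """Parents, regression coefficients, and conditional variance d_i."""
        cached = self._coeff_memo.get(i)
        if cached is not None:
            return cached
        out = self._coeffs_uncached(i)
        self._coeff_memo[i] = out
        return out

    def _coeffs_uncached(self, i: int) -> tuple[list[int], list[float], float]:
        kind = self.kind[i]
        dam, sire = self.dam[i], self.sire[i]
        if kind is NodeKind.PSEUDO_SIRE:
            n, m = self.n_drones[i], self.n_dummy_dpq[i]
            d = 0.5 / n + (n - 1) / n * 0.25 / m
            return [], [], d
        if kind is NodeKind.SIRE:
            if dam < 0:  # unknown DPQ: base drone group
                n = self.n_drones[i]
                return [], [], 0.25 + 0.25 / n
            n = self.n_drones[i]
            d = 0.25 * (1.0 - self._inbreeding(dam)) / n
            return [dam], [0.5], d
        if kind is NodeKind.WORKER_GROUP:
            # infinite workers: exactly 0.5*queen + drone-group mean
            return [dam, sire], [0.5, 1.0], 0.0
        # QUEEN
        parents, coefs, d = [], [], 0.0
        if dam >= 0:
            parents.append(dam)
            coefs.append(0.5)
            d += 0.25 * (1.0 - self._inbreeding(dam))
        else:
            d += 0.5  # base maternal gamete
        if sire >= 0:
            parents.append(sire)
            coefs.append(1.0)
            d += 0.5 - self._variance(sire)  # pick of one drone given the mean
        else:
            d += 0.5  # base paternal drone
        return parents, coefs, d

    # ------------------------------------------------------------------ #
    # pairwise relationships, variances and inbreeding (memoized)
    # ------------------------------------------------------------------ #

    def _variance(self, i: int) -> float:
        v = self._var.get(i)
        if v is None:
            parents, coefs, d = self._coeffs(i)
            v = d
            for k, bk in zip(parents, coefs):
                for l, bl in zip(parents, coefs):
                    v += bk * bl * self.relationship_idx(k, l)
            self._var[i] = v
        return v

    def _inbreeding(self, i: int) -> float:
        """F of a queen = relationship between her dam and her mating node."""
        f = self._F.get(i)
        if f is None:
            if self.kind[i] is not NodeKind.QUEEN:
                f = 0.0
            else:
                dam, sire = self.dam[i], self.sire[i]
                f = 0.0 if (dam < 0 or sire < 0) else self.relationship_idx(dam, sire)
            self._F[i] = f
        return f

    def relationship_idx(self, i: int, j: int) -> float:
        if i == j:
            return self._variance(i)
        if i < j:
            i, j = j, i
        key = (i, j)
        memo = self._rel_memo
        val = memo.get(key)
        if val is None:
            parents, coefs, _ = self._coeffs(i)
            val = 0.0
            for k, bk in zip(parents, coefs):
                val += bk * self.relationship_idx(k, j)
            memo[key] = val
        return val

    def relationship(self, id_i: str, id_j: str) -> float:
        """Expected additive relationship a_ij (diag of a queen = 1 + F)."""
        return self.relationship_idx(self.index_of(id_i), self.index_of(id_j))

    def inbreeding(self, queen_id: str) -> float:
        return self._inbreeding(self.index_of(queen_id))

    def inbreeding_all(self) -> np.ndarray:
        """F for every node (0 for non-queen kinds)."""
        return np.array([self._inbreeding(i) for i in range(len(self))])

    def generating_nodes(self) -> list[int]:
        """Indices of queens, sires and pseudo-sires (invertible A subset)."""
        return [i for i, k in enumerate(self.kind) if k in _GENERATING]

    # ------------------------------------------------------------------ #
    # CSV round trip
    # ------------------------------------------------------------------ #

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "kind": [k.value for k in self.kind],
            "dam_id": [self.ids[d] if d >= 0 else "" for d in self.dam],
            "sire_id": [self.ids[s] if s >= 0 else "" for s in self.sire],
            "n_drones": self.n_drones,
            "n_dummy_dpq": self.n_dummy_dpq,
            "birth_year": [y if y is not None else "" for y in self.birth_year],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ped = cls()
        for row in df.itertuples(index=False):
            year = getattr(row, "birth_year", "")
            year = None if year in ("", None) or pd.isna(year) else int(year)
            ped.add_node(NodeKind(row.kind),
                         dam_id=row.dam_id or None if isinstance(row.dam_id, str)
                         else (None if pd.isna(row.dam_id) else str(row.dam_id)),
                         sire_id=row.sire_id or None if isinstance(row.sire_id, str)
                         else (None if pd.isna(row.sire_id) else str(row.sire_id)),
                         n_drones=int(row.n_drones),
                         n_dummy_dpq=int(row.n_dummy_dpq),
                         birth_year=year, node_id=str(row.id))
        return ped

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


@dataclass
class RelationshipStore:
    """A and/or A^-1 over a fixed node subset, plus inbreeding coefficients."""

    node_indices: list[int]
    ids: list[str]
    F: np.ndarray
    A: np.ndarray | None = None
    A_inv: sparse.csr_matrix | None = None
    logdet_A: float | None = None
    _pos: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._pos = {node: p for p, node in enumerate(self.node_indices)}

    def position(self, node_idx: int) -> int:
        return self._pos[node_idx]


def compute_A(pedigree: Pedigree, include_worker_groups: bool = True,
              max_nodes: int = 5000) -> RelationshipStore:
    """Dense relationship matrix by forward recursion over the pedigree.

    With ``include_worker_groups`` the matrix carries a row/column per
    worker group as well; note that those rows are exact linear functions
    of their queen and drone-group rows, so the full matrix is PSD but
    rank-deficient.  Restricted to the generating set it is invertible and
    equals the inverse of :func:`compute_A_inverse` up to numerical error.
    """
    if include_worker_groups:
        nodes = list(range(len(pedigree)))
    else:
        nodes = pedigree.generating_nodes()
    if len(nodes) > max_nodes:
        raise ValueError(f"dense A limited to {max_nodes} nodes, "
                         f"got {len(nodes)}; use compute_A_inverse")
    pos = {node: p for p, node in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for p, i in enumerate(nodes):
        parents, coefs, d = pedigree._coeffs(i)
        pp = [pos[k] for k in parents]  # parents precede children
        if pp:
            b = np.asarray(coefs)
            row = b @ A[pp, :p]
            A[p, :p] = row
            A[:p, p] = row
            A[p, p] = b @ A[np.ix_(pp, pp)] @ b + d
        else:
            A[p, p] = d
    F = np.array([pedigree._inbreeding(i) for i in nodes])
    return RelationshipStore(node_indices=nodes,
                             ids=[pedigree.ids[i] for i in nodes], F=F, A=A)


def compute_A_inverse(pedigree: Pedigree) -> RelationshipStore:
    """Sparse A^-1 over the generating node set (queens, sires, pseudo-sires).

    Henderson-style construction from the directed factorization
    A = (I-B)^-1 D (I-B)^-T: each node contributes the outer product of
    ``[1, -b]/sqrt(d_i)`` on (itself, its parents).  Also returns
    ``log|A| = sum(log d_i)`` and the per-node inbreeding coefficients.
    """
    nodes = pedigree.generating_nodes()
    pos = {node: p for p, node in enumerate(nodes)}
    rows, cols, vals = [], [], []
    logdet = 0.0
    for i in nodes:
        parents, coefs, d = pedigree._coeffs(i)
        if d <= 0:
            raise ValueError(
                f"node {pedigree.ids[i]} has non-positive conditional "
                f"variance {d}; A over these nodes is singular")
        logdet += np.log(d)
        vec_pos = [pos[i]] + [pos[k] for k in parents]
        vec = np.array([1.0] + [-c for c in coefs]) / np.sqrt(d)
        for a, va in zip(vec_pos, vec):
            for b, vb in zip(vec_pos, vec):
                rows.append(a)
                cols.append(b)
                vals.append(va * vb)
    n = len(nodes)
    A_inv = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A_inv.sum_duplicates()
    F = np.array([pedigree._inbreeding(i) for i in nodes])
    return RelationshipStore(node_indices=nodes,
                             ids=[pedigree.ids[i] for i in nodes], F=F,
                             A_inv=A_inv, logdet_A=logdet)


def inbreeding_trajectory(pedigree: Pedigree,
                          cohort_by_year: dict[int, list[str]],
                          ref_year: int | None = None) -> pd.DataFrame:
    """Per-year mean F of the given cohorts, and the change vs a reference.

    Returns a frame with columns ``year``, ``mean_F`` and, when a reference
    year is given, ``added_F_pct`` = 100 * (mean_F(year) - mean_F(ref)).
    """
    years = sorted(cohort_by_year)
    rows = []
    for y in years:
        ids = cohort_by_year[y]
        if not ids:
            raise ValueError(f"empty cohort for year {y}")
        rows.append((y, float(np.mean([pedigree.inbreeding(q) for q in ids]))))
    df = pd.DataFrame(rows, columns=["year", "mean_F"])
    if ref_year is not None:
        if ref_year not in cohort_by_year:
            raise ValueError(f"reference year {ref_year} has no cohort")
        ref = float(df.loc[df.year == ref_year, "mean_F"].iloc[0])
        df["added_F_pct"] = 100.0 * (df["mean_F"] - ref)
    return df


# ---------------------------------------------------------------------- #
# gene-dropping oracle
# ---------------------------------------------------------------------- #

def _enforce_shared_drones(values: np.ndarray, dam_pick: np.ndarray,
                           allele_pick: np.ndarray) -> np.ndarray:
    """Make drones that drew the same (dam, allele) carry the same value."""
    n_drones = values.shape[1]
    for j in range(1, n_drones):
        for i in range(j):
            same = (dam_pick[:, i] == dam_pick[:, j]) & \
                   (allele_pick[:, i] == allele_pick[:, j])
            if same.any():
                values[same, j] = values[same, i]
    return values


def gene_drop_covariance(pedigree: Pedigree, n_rep: int,
                         rng: np.random.Generator,
                         node_ids: list[str] | None = None) -> np.ndarray:
    """Monte-Carlo estimate of the relationship matrix by gene dropping.

    A single unlinked locus is dropped through the pedigree with *discrete*
    inheritance: base queens receive two independent N(0, 1/2) allelic
    values; a gamete is an equal-probability pick of one of the parent's
    two values; a drone is one such pick from its DPQ; a daughter combines
    her dam's pick with one drone picked uniformly from her mating's drone
    group; a worker group averages its queen's half-contribution with the
    full drone group.  Identity-by-descent (and hence inbreeding) emerges
    from value identity rather than from any (1-F) formula, which makes
    this an independent oracle for :func:`compute_A`.

    Returns the empirical covariance matrix over ``node_ids`` (all nodes by
    default).  The Monte-Carlo SE of entry (i, j) is about
    ``sqrt((a_ii*a_jj + a_ij^2) / n_rep)``.
    """
    n = len(pedigree)
    maternal = np.empty((n, n_rep))   # queens: allelic value of maternal genome
    paternal = np.empty((n, n_rep))   # queens: allelic value of paternal genome
    group_drones: dict[int, np.ndarray] = {}  # mating node -> (n_rep, n_drones)
    value = np.empty((n, n_rep))

    for i in range(n):
        kind = pedigree.kind[i]
        dam, sire = pedigree.dam[i], pedigree.sire[i]
        if kind is NodeKind.PSEUDO_SIRE:
            nd, ndum = pedigree.n_drones[i], pedigree.n_dummy_dpq[i]
            dam_pick = rng.integers(0, ndum, size=(n_rep, nd))
            allele_pick = rng.integers(0, 2, size=(n_rep, nd))
            drones = rng.standard_normal((n_rep, nd)) * np.sqrt(0.5)
            group_drones[i] = _enforce_shared_drones(drones, dam_pick, allele_pick)
            value[i] = group_drones[i].mean(axis=1)
        elif kind is NodeKind.SIRE:
            nd = pedigree.n_drones[i]
            if dam >= 0:
                pick = rng.integers(0, 2, size=(n_rep, nd))
                drones = np.where(pick == 0, maternal[dam][:, None],
                                  paternal[dam][:, None])
            else:
                dam_pick = np.tile(np.arange(nd), (n_rep, 1))  # distinct base dams
                allele_pick = rng.integers(0, 2, size=(n_rep, nd))
                drones = rng.standard_normal((n_rep, nd)) * np.sqrt(0.5)
            group_drones[i] = drones
            value[i] = drones.mean(axis=1)
        elif kind is NodeKind.WORKER_GROUP:
            value[i] = 0.5 * value[dam] + value[sire]
        else:  # QUEEN
            if dam >= 0:
                pick = rng.integers(0, 2, size=n_rep)
                maternal[i] = np.where(pick == 0, maternal[dam], paternal[dam])
            else:
                maternal[i] = rng.standard_normal(n_rep) * np.sqrt(0.5)
            if sire >= 0:
                drones = group_drones[sire]
                choice = rng.integers(0, drones.shape[1], size=n_rep)
                paternal[i] = drones[np.arange(n_rep), choice]
            else:
                paternal[i] = rng.standard_normal(n_rep) * np.sqrt(0.5)
            value[i] = maternal[i] + paternal[i]

    if node_ids is None:
        sel = np.arange(n)
    else:
        sel = np.array([pedigree.index_of(x) for x in node_ids])
    v = value[sel]
    v = v - v.mean(axis=1, keepdims=True)
    return (v @ v.T) / (n_rep - 1)
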