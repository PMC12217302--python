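"""Two-trait colony-model genetic evaluation: BLUP and REML.

The observation model for a colony phenotype of trait *t* is

    y = apiary-by-year fixed effect (per trait)
        + queen effect of the colony queen (Q_t)
        + mean worker effect of the worker group (W_t)
        + residual,

where the worker-group effect is carried exactly by its generators,
``0.5 * u_W(queen) + u_W(drone group)`` (see :mod:`apisim.pedigree`).
Every pedigree node carries a worker and a queen effect per trait; the
effects are correlated across nodes through the relationship matrix A and
across effect-traits through the genetic covariance G, i.e.
``Var(u) = G (x) A``.  Missing late-trait records (candidate dams in the
accelerated scheme) simply contribute no row — no imputation.

REML maximizes the exact restricted log-likelihood

    -2 lnL = log|R| + log|G (x) A| + log|C| + y' P y  (+ const)

over Cholesky factors of G and R, where C is the mixed-model (Henderson)
coefficient matrix; all log-determinants come from one sparse LU
factorization per likelihood evaluation, so no trace of a large inverse is
ever needed.  Start values follow the simulation protocol (0.9x the true
genetic and 1.1x the true residual covariances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import cg, splu

from apisim.pedigree import NodeKind, Pedigree, compute_A_inverse


def _splu_spd(C):
    """Sparse LU tuned for the SPD Henderson matrix (symmetric ordering)."""
    try:
        return splu(C, permc_spec="MMD_AT_PLUS_A",
                    options={"SymmetricMode": True, "DiagPivotThresh": 0.001})
    except RuntimeError:
        return splu(C)

__all__ = [
    "PerformanceFile",
    "VarianceEstimates",
    "EBVTable",
    "MMESystem",
    "assemble_mme",
    "solve_blup",
    "reml_estimate",
    "selection_index",
    "index_accuracy",
]

_GRID_WEIGHTS = {(1.0, 0.0), (0.75, 0.25), (0.5, 0.5), (0.25, 0.75), (0.0, 1.0)}

PERFORMANCE_COLUMNS = ["colony_id", "queen_id", "worker_group_id",
                       "apiary", "year", "y_T1", "y_T2"]


@dataclass
class PerformanceFile:
    """Colony phenotype records feeding one genetic evaluation.

    ``data`` columns: colony_id, queen_id, worker_group_id, apiary, year,
    y_T1, y_T2 (NaN = missing).  All present and past candidates'
    phenotypes available at the moment of selection belong in here.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PERFORMANCE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"performance file lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def n_records(self, trait: int) -> int:
        return int(self.data[f"y_T{trait + 1}"].notna().sum())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PerformanceFile":
        return cls(pd.read_csv(path))


@dataclass
class VarianceEstimates:
    """REML output: genetic and residual covariances plus convergence state."""

    G: np.ndarray
    R: np.ndarray
    converged: bool
    n_iterations: int
    loglik: float = np.nan
    message: str = ""


@dataclass
class EBVTable:
    """Estimated worker/queen effects per trait for every evaluated node.

    ``ebv`` is indexed by node id with one column per effect-trait
    (W1, Q1, W2, Q2 for the full two-trait model).  Worker-group nodes get
    their exact linear-combination EBVs.  ``wg_of_queen`` maps a queen id
    to her colony's worker-group id when one exists.
    """

    ebv: pd.DataFrame
    traits: tuple[int, ...]
    wg_of_queen: dict[str, str] = field(default_factory=dict)

    def _summed(self, ids) -> np.ndarray:
        """Worker+queen effect sums per trait, rows aligned with ids."""
        arr = self.ebv.loc[ids].to_numpy()
        return arr[:, 0::2] + arr[:, 1::2]

    def score(self, ids, weights: tuple[float, float]) -> np.ndarray:
        """Weighted selection-index scores (worker+queen summed per trait)."""
        w = np.asarray(weights, dtype=float)[list(self.traits)]
        return self._summed(list(ids)) @ w

    def to_csv(self, path) -> None:
        """EBV report: one row per evaluated node (worker groups included)."""
        self.ebv.to_csv(path)


def _effect_columns(traits: tuple[int, ...]) -> list[str]:
    return [f"{eff}{t + 1}" for t in traits for eff in ("W", "Q")]


@dataclass
class MMESystem:
    """Assembled Henderson system plus the pieces REML re-uses."""

    C: sparse.csc_matrix
    rhs: np.ndarray
    n_fixed: int
    fixed_labels: list
    node_ids: list[str]
    traits: tuple[int, ...]
    y: np.ndarray
    yRy: float
    logdet_R: float
    logdet_A: float
    n_nodes: int
    pedigree: Pedigree
    obs_queen_pos: np.ndarray
    obs_mating_pos: np.ndarray
    obs_trait: np.ndarray
    wg_of_queen: dict[str, str]


def _closure(pedigree: Pedigree, seed_nodes: set[int]) -> list[int]:
    """Ancestor closure (generating kinds only), in pedigree order."""
    needed = set()
    stack = list(seed_nodes)
    while stack:
        i = stack.pop()
        if i in needed or i < 0:
            continue
        needed.add(i)
        stack.append(pedigree.dam[i])
        stack.append(pedigree.sire[i])
    return sorted(needed)


def assemble_mme(perf: PerformanceFile, pedigree: Pedigree, G: np.ndarray,
                 R: np.ndarray, traits: tuple[int, ...] = (0, 1),
                 prune: bool = True) -> MMESystem:
    """Build the sparse mixed-model equations for the colony model.

    Fixed effects: one cell mean per (apiary, year) level and trait (only
    levels with data get a column, so the system is always full rank).
    Random effects: worker and queen effect per trait for every pedigree
    node in the ancestor closure of the phenotyped colonies.
    """
    ws = REMLWorkspace(perf, pedigree, traits, prune=prune)
    return ws.to_system(np.asarray(G, dtype=float), np.asarray(R, dtype=float))


def _subset_A_inverse(pedigree: Pedigree, nodes: list[int]):
    """A^-1 restricted to an ancestor-closed generating subset."""
    from apisim.pedigree import RelationshipStore
    pos = {node: p for p, node in enumerate(nodes)}
    rows, cols, vals = [], [], []
    logdet = 0.0
    for i in nodes:
        parents, coefs, d = pedigree._coeffs(i)
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


def solve_blup(system: MMESystem, method: str = "auto",
               x0: np.ndarray | None = None,
               rtol: float = 1e-10) -> tuple[EBVTable, np.ndarray]:
    """Solve the assembled MME and return EBVs (plus the raw solution).

    ``method``: 'splu' (direct sparse LU), 'cg' (Jacobi-preconditioned
    conjugate gradients, supports warm starts), or 'auto' (LU for small
    systems, CG above 50k unknowns).  The solution is accepted only if the
    relative residual norm is below 1e-8.
    """
    C, rhs = system.C, system.rhs
    n = C.shape[0]
    if method == "auto":
        method = "splu" if n <= 50_000 else "cg"
    if method == "splu":
        sol = _splu_spd(C).solve(rhs)
    elif method == "cg":
        d = C.diagonal()
        M = sparse.diags(1.0 / np.where(d > 0, d, 1.0))
        sol, info = cg(C, rhs, x0=x0, rtol=rtol, maxiter=20 * int(np.sqrt(n)) + 2000,
                       M=M)
        if info != 0:
            sol = splu(C.tocsc()).solve(rhs)  # direct fallback
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = np.linalg.norm(C @ sol - rhs)
    scale = max(1.0, np.linalg.norm(rhs))
    if resid > 1e-8 * scale:
        raise RuntimeError(f"MME solve did not converge: residual {resid:.3g} "
                           f"(scale {scale:.3g})")

    n_t = len(system.traits)
    u = sol[system.n_fixed:].reshape(2 * n_t, system.n_nodes)
    cols = _effect_columns(system.traits)
    ebv = pd.DataFrame(u.T, index=pd.Index(system.node_ids, name="id"),
                       columns=cols)

    # exact worker-group EBVs: 0.5 * queen + drone group
    ped = system.pedigree
    wg_rows, wg_ids = [], []
    idpos = {nid: p for p, nid in enumerate(system.node_ids)}
    for i, k in enumerate(ped.kind):
        if k is NodeKind.WORKER_GROUP:
            q, m = ped.dam[i], ped.sire[i]
            pq, pm = idpos.get(ped.ids[q]), idpos.get(ped.ids[m])
            if pq is None or pm is None:
                continue
            wg_rows.append(0.5 * u[:, pq] + u[:, pm])
            wg_ids.append(ped.ids[i])
    if wg_ids:
        ebv = pd.concat([ebv, pd.DataFrame(np.array(wg_rows),
                                           index=pd.Index(wg_ids, name="id"),
                                           columns=cols)])
    table = EBVTable(ebv=ebv, traits=system.traits,
                     wg_of_queen=system.wg_of_queen)
    return table, sol


# ---------------------------------------------------------------------- #
# REML
# ---------------------------------------------------------------------- #

def _tril_pack(L: np.ndarray) -> np.ndarray:
    return L[np.tril_indices_from(L)]


def _tril_unpack(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = theta
    return L


def _safe_chol(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(M)
        w = np.clip(w, 1e-8 * max(w.max(), 1.0), None)
        return np.linalg.cholesky((v * w) @ v.T)


class REMLWorkspace:
    """Precomputed structure for repeated restricted-likelihood evaluations.

    The design (X, Z), the relationship inverse and its log-determinant,
    and the per-colony missingness patterns do not change across REML
    iterations; only the values of G and R do.  One likelihood evaluation
    then costs a few sparse products and one sparse LU factorization.
    """

    def __init__(self, perf: PerformanceFile, pedigree: Pedigree,
                 traits: tuple[int, ...] = (0, 1), prune: bool = True):
        self.traits = tuple(traits)
        n_t = len(traits)
        df = perf.data
        wg_idx = df["worker_group_id"].map(pedigree.index_of).to_numpy()
        for c, i in zip(df["worker_group_id"], wg_idx):
            if pedigree.kind[i] is not NodeKind.WORKER_GROUP:
                raise ValueError(f"{c!r} is not a WORKER_GROUP node")
        queen_idx = np.array([pedigree.dam[i] for i in wg_idx])
        mating_idx = np.array([pedigree.sire[i] for i in wg_idx])
        qcheck = df["queen_id"].map(pedigree.index_of).to_numpy()
        if not np.array_equal(qcheck, queen_idx):
            raise ValueError("worker_group_id is not the worker group of "
                             "queen_id")

        if prune:
            nodes = _closure(pedigree, set(queen_idx) | set(mating_idx))
            nodes = [i for i in nodes
                     if pedigree.kind[i] is not NodeKind.WORKER_GROUP]
        else:
            nodes = pedigree.generating_nodes()
        store = _subset_A_inverse(pedigree, nodes)
        self.A_inv = store.A_inv.tocsr()
        self.logdet_A = store.logdet_A
        self.n_nodes = len(nodes)
        self.node_ids = [pedigree.ids[i] for i in nodes]
        pos = {node: p for p, node in enumerate(nodes)}

        obs_col, obs_trait, obs_y = [], [], []
        for t_local, t in enumerate(traits):
            col = df[f"y_T{t + 1}"].to_numpy(dtype=float)
            mask = np.isfinite(col)
            obs_col.append(np.flatnonzero(mask))
            obs_trait.append(np.full(int(mask.sum()), t_local))
            obs_y.append(col[mask])
        obs_col = np.concatenate(obs_col)
        self.obs_trait = np.concatenate(obs_trait)
        self.y = np.concatenate(obs_y)
        n_obs = len(self.y)
        if n_obs == 0:
            raise ValueError("no phenotype records")
        oq = np.array([pos[q] for q in queen_idx[obs_col]])
        om = np.array([pos[m] for m in mating_idx[obs_col]])

        ay = list(zip(df["apiary"].to_numpy()[obs_col],
                      df["year"].to_numpy()[obs_col], self.obs_trait))
        self.fixed_labels = sorted(set(ay))
        fmap = {lab: j for j, lab in enumerate(self.fixed_labels)}
        fcol = np.array([fmap[lab] for lab in ay])
        self.n_fixed = len(self.fixed_labels)
        X = sparse.csr_matrix((np.ones(n_obs), (np.arange(n_obs), fcol)),
                              shape=(n_obs, self.n_fixed))
        w_e = 2 * self.obs_trait
        q_e = w_e + 1
        rows = np.repeat(np.arange(n_obs), 3)
        cols = np.stack([w_e * self.n_nodes + oq, w_e * self.n_nodes + om,
                         q_e * self.n_nodes + oq], axis=1).ravel()
        vals = np.tile([0.5, 1.0, 1.0], n_obs)
        Z = sparse.csr_matrix((vals, (rows, cols)),
                              shape=(n_obs, 2 * n_t * self.n_nodes))
        self.W = sparse.hstack([X, Z], format="csr")
        self.Wt = self.W.T.tocsr()
        self.obs_queen_pos, self.obs_mating_pos = oq, om

        # group each colony's observation rows by missingness pattern
        self.patterns: dict[tuple[int, ...], np.ndarray] = {}
        if n_t == 1:
            self.patterns[(0,)] = np.arange(n_obs)[:, None]
        else:
            blk0, blk1 = obs_col[self.obs_trait == 0], \
                obs_col[self.obs_trait == 1]
            off1 = len(blk0)
            both, i0, i1 = np.intersect1d(blk0, blk1, return_indices=True)
            if len(both):
                self.patterns[(0, 1)] = np.stack([i0, i1 + off1], axis=1)
            only0 = np.setdiff1d(np.arange(len(blk0)), i0)
            if len(only0):
                self.patterns[(0,)] = only0[:, None]
            only1 = np.setdiff1d(np.arange(len(blk1)), i1)
            if len(only1):
                self.patterns[(1,)] = (only1 + off1)[:, None]
        self.n_obs = n_obs

        # wg id -> queen id map for downstream EBV tables
        self.wg_of_queen: dict[str, str] = {}
        for wid, qi in zip(df["worker_group_id"], queen_idx):
            self.wg_of_queen.setdefault(pedigree.ids[qi], wid)
        self.pedigree = pedigree

    def _rinv(self, R0: np.ndarray) -> tuple[sparse.csr_matrix, float]:
        rows, cols, vals = [], [], []
        logdet = 0.0
        for key, obs_rows in self.patterns.items():
            idx = list(key)
            sub = R0[np.ix_(idx, idx)]
            inv = np.linalg.inv(sub)
            logdet += len(obs_rows) * float(np.linalg.slogdet(sub)[1])
            k = len(idx)
            for a in range(k):
                for b in range(k):
                    rows.append(obs_rows[:, a])
                    cols.append(obs_rows[:, b])
                    vals.append(np.full(len(obs_rows), inv[a, b]))
        Rinv = sparse.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_obs, self.n_obs))
        return Rinv, logdet

    def build_system(self, G: np.ndarray, R0: np.ndarray):
        """Coefficient matrix, RHS and determinant pieces for given G, R."""
        Rinv, logdet_R = self._rinv(np.asarray(R0, dtype=float))
        B = Rinv @ self.W
        Ginv = np.linalg.inv(G)
        pen = sparse.kron(Ginv, self.A_inv, format="csr")
        C = (self.Wt @ B + sparse.block_diag(
            [sparse.csr_matrix((self.n_fixed, self.n_fixed)), pen],
            format="csr")).tocsc()
        ry = Rinv @ self.y
        rhs = self.Wt @ ry
        yRy = float(self.y @ ry)
        return C, np.asarray(rhs).ravel(), yRy, logdet_R

    def to_system(self, G: np.ndarray, R0: np.ndarray) -> "MMESystem":
        """Assemble a solvable Henderson system for given G and R."""
        n_t = len(self.traits)
        if G.shape != (2 * n_t, 2 * n_t):
            raise ValueError(f"G must be {2 * n_t}x{2 * n_t} for traits "
                             f"{self.traits}")
        if np.atleast_2d(R0).shape != (n_t, n_t):
            raise ValueError(f"R must be {n_t}x{n_t} for traits {self.traits}")
        C, rhs, yRy, logdet_R = self.build_system(G, np.atleast_2d(R0))
        return MMESystem(C=C, rhs=rhs, n_fixed=self.n_fixed,
                         fixed_labels=self.fixed_labels,
                         node_ids=self.node_ids, traits=self.traits,
                         y=self.y, yRy=yRy, logdet_R=logdet_R,
                         logdet_A=self.logdet_A, n_nodes=self.n_nodes,
                         pedigree=self.pedigree,
                         obs_queen_pos=self.obs_queen_pos,
                         obs_mating_pos=self.obs_mating_pos,
                         obs_trait=self.obs_trait,
                         wg_of_queen=self.wg_of_queen)

    def neg_loglik(self, G: np.ndarray, R0: np.ndarray) -> float:
        detG = np.linalg.det(G)
        detR = np.linalg.det(np.atleast_2d(R0))
        if detG < 1e-12 or detR < 1e-12:
            return 1e30
        C, rhs, yRy, logdet_R = self.build_system(G, R0)
        try:
            lu = _splu_spd(C)
        except RuntimeError:
            return 1e30
        diagU = lu.U.diagonal()
        if np.any(diagU == 0) or not np.all(np.isfinite(diagU)):
            return 1e30
        logdet_C = float(np.sum(np.log(np.abs(diagU))))
        sol = lu.solve(rhs)
        yPy = yRy - float(rhs @ sol)
        kG = G.shape[0]
        logdet_Gt = self.n_nodes * float(np.linalg.slogdet(G)[1]) \
            + kG * self.logdet_A
        ll = -0.5 * (logdet_R + logdet_Gt + logdet_C + yPy)
        return -ll if np.isfinite(ll) else 1e30


def reml_estimate(perf: PerformanceFile, pedigree: Pedigree,
                  true_G: np.ndarray, true_R: np.ndarray,
                  traits: tuple[int, ...] = (0, 1), tol: float = 1e-11,
                  max_iter: int = 500,
                  workspace: REMLWorkspace | None = None) -> VarianceEstimates:
    """REML variance components for the colony model.

    Start values are 0.9x the true genetic and 1.1x the true residual
    covariances (the simulation protocol).  The restricted likelihood is
    maximized over Cholesky factors of G and R (which keeps both PSD,
    including at zero-variance boundaries) with quasi-Newton iterations;
    each likelihood value is exact, assembled from one sparse LU of the
    mixed-model matrix.  ``converged=False`` flags an unusable fit — the
    caller is expected to record the failure and abandon the replicate.
    """
    n_t = len(traits)
    kG = 2 * n_t
    ws = workspace or REMLWorkspace(perf, pedigree, traits)
    LG0 = _safe_chol(0.9 * np.asarray(true_G, dtype=float))
    LR0 = _safe_chol(1.1 * np.asarray(np.atleast_2d(true_R), dtype=float))
    theta0 = np.concatenate([_tril_pack(LG0), _tril_pack(LR0)])
    nG = kG * (kG + 1) // 2
    # scale parameters so a unit step is comparable in every coordinate
    scale = np.where(np.abs(theta0) > 1e-3, np.abs(theta0), 1.0)

    def unpack(z):
        theta = z * scale
        LG = _tril_unpack(theta[:nG], kG)
        LR = _tril_unpack(theta[nG:], n_t)
        return LG @ LG.T, LR @ LR.T

    def objective(z):
        G, R = unpack(z)
        return ws.neg_loglik(G, R)

    iterates = [theta0 / scale]

    def track(z):
        iterates.append(z.copy())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = optimize.minimize(objective, theta0 / scale, method="L-BFGS-B",
                                callback=track,
                                options={"maxiter": max_iter,
                                         "maxfun": 20 * max_iter,
                                         "ftol": 1e-13, "gtol": 1e-7})
    G_hat, R_hat = unpack(res.x)
    if len(iterates) >= 2:
        denom = max(1.0, float(np.linalg.norm(iterates[-1])))
        param_change = float(
            np.linalg.norm(iterates[-1] - iterates[-2])) / denom
    else:
        param_change = np.inf
    converged = bool(res.success) and np.isfinite(res.fun) and res.fun < 1e29
    return VarianceEstimates(G=G_hat, R=R_hat, converged=converged,
                             n_iterations=int(res.nit), loglik=-float(res.fun),
                             message=f"{res.message}; final relative parameter "
                                     f"change {param_change:.2e} (tol {tol:g})")


# ---------------------------------------------------------------------- #
# selection indices and accuracy
# ---------------------------------------------------------------------- #

def selection_index(ebv_table: EBVTable, weights: tuple[float, float],
                    role: str, candidates: list[str]) -> pd.DataFrame:
    """Rank candidates on the weighted (worker+queen) EBV sum per trait.

    Dams are ranked on their worker group's EBVs (their workers share the
    expected breeding value of the offspring queens, and a mated queen's
    mating cannot be changed); sires on their own EBVs.  Ties break by id.
    """
    if role not in ("dam", "sire"):
        raise ValueError("role must be 'dam' or 'sire'")
    w = (float(weights[0]), float(weights[1]))
    if w not in _GRID_WEIGHTS and w != (0.0, 0.0):
        warnings.warn(f"weights {w} are off the study grid", stacklevel=2)
    if role == "dam":
        ids = []
        for q in candidates:
            wg = ebv_table.wg_of_queen.get(q)
            if wg is None:
                raise KeyError(f"candidate dam {q!r} has no worker group "
                               f"in the evaluation")
            ids.append(wg)
    else:
        ids = list(candidates)
    scores = ebv_table.score(ids, weights)
    out = pd.DataFrame({"candidate": candidates, "score": scores})
    out = out.sort_values(["score", "candidate"],
                          ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def index_accuracy(true_index: np.ndarray, estimated_index: np.ndarray) -> float:
    """Pearson correlation between true and estimated selection indices.

    Returns NaN (with a warning) when either side has zero variance or
    fewer than two candidates are available.
    """
    t = np.asarray(true_index, dtype=float)
    e = np.asarray(estimated_index, dtype=float)
    if t.size != e.size:
        raise ValueError("index vectors differ in length")
    if t.size < 2 or np.std(t) == 0 or np.std(e) == 0:
        warnings.warn("index accuracy undefined (zero variance or n < 2)",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(t, e)[0, 1])
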