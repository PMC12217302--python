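"""True breeding-value machinery for the two-trait honeybee colony model.

Every genetic entity (queen, drone, worker group) carries a length-4 vector
of additive effects ordered ``(W-T1, Q-T1, W-T2, Q-T2)``: the worker and
queen effect for the early trait T1, then for the late trait T2.  A colony
phenotype for trait *t* is the queen effect of its queen plus the mean
worker effect of its worker group, plus an apiary-by-year effect and a
residual::

    y_t = a_q^Q(t) + abar_w^W(t) + E_t + eps_t

Queens are diploid; drones are haploid and genetically a single gamete of
their mother, transmitted clonally to every daughter.  Gametes are modelled
on the half-genome scale: a gamete of a parent with breeding value ``a`` and
inbreeding coefficient ``F`` is ``0.5*a + delta`` with
``delta ~ N(0, 0.25*(1-F)*G)`` (Mendelian sampling shrinks linearly in F).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EFFECT_NAMES",
    "W1",
    "Q1",
    "W2",
    "Q2",
    "GeneticParams",
    "ColonyRecord",
    "build_G",
    "draw_founder_bvs",
    "make_gamete",
    "make_drone",
    "make_offspring_queen",
    "worker_group_mean_bv",
    "colony_phenotype",
]

#: index layout of the 4-vector of additive effects
EFFECT_NAMES = ("W1", "Q1", "W2", "Q2")
W1, Q1, W2, Q2 = 0, 1, 2, 3

#: worker-effect and queen-effect positions per trait (trait 0 = early)
W_IDX = (W1, W2)
Q_IDX = (Q1, Q2)

_STUDY_R_WQ = (0.0, -0.5)
_STUDY_R_T1T2 = (-0.6, -0.3, 0.0, 0.3, 0.6)


@dataclass
class GeneticParams:
    """Base-population (co)variance parameters, in units of sigma2_AW = 1.

    The study design fixes the queen-effect variance at half the worker
    effect and a third of the residual, the polyandry level at 8 drones per
    queen, and the apiary-by-year variances at roughly 1/3 (early trait) and
    2/3 (late trait) of the phenotypic variance
    sigma2_P = sigma2_AW + sigma2_AQ + sigma2_eps = 3.
    """

    sigma2_AW: float = 1.0
    sigma2_AQ: float = 0.5
    r_WQ: float = 0.0
    r_T1T2: float = 0.0
    sigma2_eps: float = 1.5
    sigma2_apiary_T1: float = 1.0
    sigma2_apiary_T2: float = 2.0
    n_drones: int = 8

    def validate(self) -> None:
        """Raise on invalid values; warn when off the study grid."""
        for name in ("sigma2_AW", "sigma2_AQ", "sigma2_eps",
                     "sigma2_apiary_T1", "sigma2_apiary_T2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (-1.0 <= self.r_WQ <= 1.0 and -1.0 <= self.r_T1T2 <= 1.0):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n_drones < 1:
            raise ValueError("n_drones must be >= 1")
        if self.r_WQ not in _STUDY_R_WQ:
            warnings.warn(f"r_WQ={self.r_WQ} is off the study grid {_STUDY_R_WQ}",
                          stacklevel=2)
        if round(self.r_T1T2, 10) not in _STUDY_R_T1T2:
            warnings.warn(
                f"r_T1T2={self.r_T1T2} is off the study grid {_STUDY_R_T1T2}",
                stacklevel=2)
        if not np.isclose(self.sigma2_AQ, 0.5 * self.sigma2_AW) or \
                not np.isclose(self.sigma2_AQ, self.sigma2_eps / 3.0):
            warnings.warn("variance ratios deviate from the study design "
                          "(sigma2_AQ = sigma2_AW/2 = sigma2_eps/3)", stacklevel=2)

    @property
    def sigma_AWQ(self) -> float:
        """Worker-queen genetic covariance within a trait."""
        return self.r_WQ * np.sqrt(self.sigma2_AW * self.sigma2_AQ)

    @property
    def residual_cov(self) -> np.ndarray:
        """2x2 residual covariance (traits independent in the base model)."""
        return np.diag([self.sigma2_eps, self.sigma2_eps])


def build_G(params: GeneticParams) -> np.ndarray:
    """4x4 additive covariance among (W1, Q1, W2, Q2) effects.

    G is the Kronecker product of the 2x2 between-trait correlation matrix
    with the 2x2 worker/queen covariance block.  Raises ``ValueError`` if
    the correlation combination is not positive semi-definite.
    """
    params.validate()
    trait_corr = np.array([[1.0, params.r_T1T2], [params.r_T1T2, 1.0]])
    wq = np.array([[params.sigma2_AW, params.sigma_AWQ],
                   [params.sigma_AWQ, params.sigma2_AQ]])
    G = np.kron(trait_corr, wq)
    eigs = np.linalg.eigvalsh(G)
    if eigs[0] < -1e-10 * max(1.0, eigs[-1]):
        raise ValueError(
            f"G is not positive semi-definite for r_WQ={params.r_WQ}, "
            f"r_T1T2={params.r_T1T2} (min eigenvalue {eigs[0]:.3g})")
    return G


_FACTOR_CACHE: dict[bytes, np.ndarray] = {}


def _psd_factor(G: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = G, tolerant of semi-definite G (memoized:
    the same covariance is factored millions of times in a scheme run)."""
    G = np.asarray(G, dtype=float)
    key = G.tobytes()
    L = _FACTOR_CACHE.get(key)
    if L is None:
        w, v = np.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        L = v * np.sqrt(w)
        if len(_FACTOR_CACHE) > 64:
            _FACTOR_CACHE.clear()
        _FACTOR_CACHE[key] = L
    return L


def draw_founder_bvs(G: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. N(0, G) breeding-value vectors (rows)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    L = _psd_factor(G)
    return rng.standard_normal((n, G.shape[0])) @ L.T


def make_gamete(parent_bv: np.ndarray, parent_F: float, G: np.ndarray,
                rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """One (or ``size``) gametic value(s) of a diploid parent.

    gamete = 0.5*parent_bv + delta with delta ~ N(0, 0.25*(1-F)*G).
    A fully inbred parent (F=1) transmits 0.5*parent_bv deterministically.
    """
    if not 0.0 <= parent_F <= 1.0:
        raise ValueError(f"inbreeding coefficient F={parent_F} outside [0, 1]")
    parent_bv = np.asarray(parent_bv, dtype=float)
    scale = 0.5 * np.sqrt(1.0 - parent_F)
    L = _psd_factor(G) * scale
    if size is None:
        return 0.5 * parent_bv + L @ rng.standard_normal(len(parent_bv))
    return 0.5 * parent_bv + rng.standard_normal((size, len(parent_bv))) @ L.T


def make_drone(dpq_bv: np.ndarray, dpq_F: float, G: np.ndarray,
               rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Drone(s) of a drone-producing queen.

    A drone develops from an unfertilized egg: it *is* one gamete of its
    mother and transmits that genome clonally (no further sampling) to
    every daughter it fathers.
    """
    return make_gamete(dpq_bv, dpq_F, G, rng, size=size)


def make_offspring_queen(dam_bv: np.ndarray, dam_F: float,
                         father_drone: np.ndarray, G: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Breeding value of a daughter queen: dam gamete + father drone genome."""
    return make_gamete(dam_bv, dam_F, G, rng) + np.asarray(father_drone, dtype=float)


def worker_group_mean_bv(queen_bv: np.ndarray, queen_F: float,
                         father_drones: np.ndarray,
                         n_drones: int = 8) -> np.ndarray:
    """Mean breeding value of a colony's worker group.

    Uses the infinite-worker approximation: with very many workers the
    maternal Mendelian deviations average to zero, and each of the queen's
    mates (equal paternal shares) contributes its clonal genome, so

        wbar = 0.5*queen_bv + mean(father_drones).

    ``father_drones`` must hold exactly ``n_drones`` rows (polyandry level).
    """
    drones = np.atleast_2d(np.asarray(father_drones, dtype=float))
    if drones.shape[0] != n_drones:
        raise ValueError(f"expected {n_drones} father drones, got {drones.shape[0]}")
    if not 0.0 <= queen_F <= 1.0:
        raise ValueError(f"inbreeding coefficient F={queen_F} outside [0, 1]")
    return 0.5 * np.asarray(queen_bv, dtype=float) + drones.mean(axis=0)


@dataclass
class ColonyRecord:
    """A phenotyped colony: ids, design factors, and per-trait phenotypes.

    ``y_T2`` is NaN when the colony was phenotyped early-only (candidate
    dams in the accelerated scheme).
    """

    queen_id: str
    worker_group_id: str
    apiary_id: int
    year: int
    y_T1: float = np.nan
    y_T2: float = np.nan
    true_queen_bv: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))
    true_worker_mean_bv: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))


def colony_phenotype(record: ColonyRecord, apiary_effect: np.ndarray,
                     params: GeneticParams, rng: np.random.Generator,
                     traits_to_record: tuple[bool, bool] = (True, True)) -> ColonyRecord:
    """Fill in a colony's phenotypes.

    For each recorded trait t:
    ``y_t = queen Q-effect(t) + worker-group mean W-effect(t) + E_t + eps_t``
    with ``eps_t ~ N(0, sigma2_eps)`` independent across traits and colonies.
    ``apiary_effect`` is the per-trait apiary-by-year effect (drawn once per
    apiary x year x trait by the caller).  Unrecorded traits stay NaN.
    """
    eps = rng.standard_normal(2) * np.sqrt(params.sigma2_eps)
    y = np.full(2, np.nan)
    for t, recorded in enumerate(traits_to_record):
        if recorded:
            y[t] = (record.true_queen_bv[Q_IDX[t]]
                    + record.true_worker_mean_bv[W_IDX[t]]
                    + apiary_effect[t] + eps[t])
    record.y_T1, record.y_T2 = float(y[0]), float(y[1])
    return record
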