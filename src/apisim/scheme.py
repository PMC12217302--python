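"""Breeding-scheme engine: Initialization, Base, and Alt phases.

One replicate simulates a closed honeybee breeding population over 30
years.  Years 1-10 (Initialization) build up pedigree and phenotypes under
phenotypic selection: 24 founder breeding queens (BQs) are open-mated; from
year 4 on, each of 24 selected dams produces 18 candidate BQs and 18
candidate drone-producing queens (DPQs) every other year; new BQs are
instrumentally inseminated with drones of a single selected DPQ; DPQs stay
open-mated.  25% of each cohort dies before phenotyping and another 25%
before selection, leaving 243 candidates per path.

From year 11 the population follows either scheme:

* **Base** — the reference: biennial cycles, complete phenotyping of both
  traits on both paths, dams and sires selected at 2 years old from 243
  candidates (9.9%) on BLUP EBV indices.
* **Alt** — the accelerated scheme: dams are selected at 1 year old from
  324 candidates (7.4%) with only the early trait phenotyped, halving the
  dam generation interval to 1 year (average interval 1.5 years); sires
  keep the 2-year cycle with complete phenotyping, so candidate DPQ
  cohorts are produced every year and overlap.

Both branches of a replicate fork from the *same* Initialization state, so
Alt-vs-Base differences can be computed within replicate.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from apisim import quantgen as qg
from apisim.evaluation import (EBVTable, PerformanceFile, assemble_mme,
                               index_accuracy, reml_estimate, selection_index,
                               solve_blup)
from apisim.pedigree import Pedigree

__all__ = [
    "SchemeConfig",
    "PopulationState",
    "ReplicateResult",
    "REMLFailure",
    "apply_mortality",
    "allocate_apiaries",
    "mate_cohort",
    "run_initialization",
    "run_base",
    "run_alt",
    "run_replicate_pair",
]

BQ, DPQ = "BQ", "DPQ"
_STREAMS = ("genetics", "mortality", "allocation", "mating", "phenotype",
            "selection")
_BRANCH_CODE = {"init": 0, "base": 1, "alt": 2}


class REMLFailure(RuntimeError):
    """REML did not converge at an in-loop evaluation; replicate is void."""


@dataclass
class SchemeConfig:
    """Design constants of one scenario.

    Defaults are the focal study design: 24 selected parents per path with
    sister groups of 18 (the 36-parent variant uses 36 and 12), 25% yearly
    mortality applied as an exact fraction, 18 test apiaries with each
    sister group split over 3 of them, Initialization during years 1-10,
    last births in year 30.
    """

    weights: tuple[float, float] = (0.5, 0.5)
    genetics: qg.GeneticParams = field(default_factory=qg.GeneticParams)
    n_selected_bq: int = 24
    n_selected_dpq: int = 24
    offspring_per_dam_bq: int = 18
    offspring_per_dam_dpq: int = 18
    mortality_rate: float = 0.25
    n_apiaries: int = 18
    apiaries_per_sister_group: int = 3
    init_end_year: int = 10
    end_year: int = 30
    #: 'known' = BLUP with true G and R; 'reml' = in-loop REML then BLUP;
    #: 'phenotypic' = own-phenotype index selection (validation comparator);
    #: 'dry' = random selection, bookkeeping only (cohort/record ledger).
    evaluation_mode: str = "known"
    seed: int = 0

    @property
    def cohort_size_bq(self) -> int:
        return self.n_selected_bq * self.offspring_per_dam_bq

    @property
    def cohort_size_dpq(self) -> int:
        return self.n_selected_bq * self.offspring_per_dam_dpq

    def validate(self) -> None:
        errors = []
        if self.evaluation_mode not in ("known", "reml", "dry", "phenotypic"):
            errors.append(f"evaluation_mode {self.evaluation_mode!r} unknown")
        if not 0.0 <= self.mortality_rate < 1.0:
            errors.append("mortality_rate must be in [0, 1)")
        apg = self.apiaries_per_sister_group
        for name, off in (("offspring_per_dam_bq", self.offspring_per_dam_bq),
                          ("offspring_per_dam_dpq", self.offspring_per_dam_dpq)):
            if off % apg:
                errors.append(f"{name}={off} not divisible by "
                              f"apiaries_per_sister_group={apg}")
        if (self.n_selected_bq * apg) % self.n_apiaries:
            errors.append(
                f"{self.n_selected_bq} sister groups x {apg} apiaries each "
                f"cannot cover {self.n_apiaries} apiaries evenly")
        if self.init_end_year < 4 or self.init_end_year % 2:
            errors.append("init_end_year must be an even year >= 4")
        if self.end_year <= self.init_end_year:
            errors.append("end_year must exceed init_end_year")
        w = self.weights
        if len(w) != 2 or any(x < 0 for x in w):
            errors.append(f"weights {w} must be two non-negative numbers")
        try:
            self.genetics.validate()
        except ValueError as exc:
            errors.append(str(exc))
        if errors:
            raise ValueError("invalid scheme configuration:\n  - "
                             + "\n  - ".join(errors))


@dataclass
class QueenMeta:
    role: str
    birth_year: int
    dam: str | None
    mating: str | None          # this queen's own mating node
    apiary: int | None = None
    sister_group: int | None = None
    alive: bool = True
    worker_group: str | None = None


@dataclass
class PopulationState:
    """Everything a replicate carries while it runs."""

    config: SchemeConfig
    branch: str = "init"
    pedigree: Pedigree = field(default_factory=Pedigree)
    bv: dict[str, np.ndarray] = field(default_factory=dict)
    drones: dict[str, np.ndarray] = field(default_factory=dict)
    queens: dict[str, QueenMeta] = field(default_factory=dict)
    cohorts: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    selected: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    records: list[dict] = field(default_factory=list)
    apiary_effects: dict[tuple[int, int, int], float] = field(default_factory=dict)
    ledger: list[dict] = field(default_factory=list)
    accuracies: list[dict] = field(default_factory=list)
    reml_log: list[dict] = field(default_factory=list)
    year: int = 0
    streams: dict[str, np.random.Generator] = field(default_factory=dict)
    warm: dict = field(default_factory=dict)
    G: np.ndarray | None = None

    def stream(self, name: str) -> np.random.Generator:
        return self.streams[name]

    def make_streams(self, branch: str) -> None:
        """Named substreams, deterministic in (seed, branch, stream name)."""
        code = _BRANCH_CODE[branch]
        self.streams = {
            name: np.random.default_rng(
                np.random.SeedSequence((self.config.seed, code, k)))
            for k, name in enumerate(_STREAMS)}

    def fork(self, branch: str) -> "PopulationState":
        """Deep copy for a scheme branch with fresh branch-specific streams."""
        clone = copy.deepcopy(self)
        clone.branch = branch
        clone.make_streams(branch)
        return clone

    def alive_in_cohort(self, role: str, year: int) -> list[str]:
        return [q for q in self.cohorts.get((role, year), [])
                if self.queens[q].alive]

    def performance_file(self, eval_year: int) -> PerformanceFile:
        rows = [r for r in self.records
                if min(r["avail_T1"], r["avail_T2"]) <= eval_year]
        df = pd.DataFrame(rows)
        for t in (1, 2):
            df.loc[df[f"avail_T{t}"] > eval_year, f"y_T{t}"] = np.nan
        return PerformanceFile(
            df[["colony_id", "queen_id", "worker_group_id", "apiary", "year",
                "y_T1", "y_T2"]].copy())


@dataclass
class ReplicateResult:
    """Per-replicate outcome of one scheme branch."""

    branch: str
    config: SchemeConfig
    trajectories: pd.DataFrame      # per BQ birth year: effect means, H, F
    accuracy: pd.DataFrame          # per evaluation year: dam/sire accuracy
    ledger: pd.DataFrame
    reml_log: pd.DataFrame
    dam_generations: int
    sire_generations: int
    mean_generation_interval: float

    def gain(self, weights: tuple[float, float] | None = None,
             from_year: int | None = None, to_year: int | None = None) -> float:
        """Change in mean true breeding-goal value between two birth cohorts."""
        w = weights if weights is not None else self.config.weights
        tr = self.trajectories.set_index("birth_year")
        a, b = (from_year or self.config.init_end_year,
                to_year or self.config.end_year)
        h = w[0] * (tr["mean_W1"] + tr["mean_Q1"]) + \
            w[1] * (tr["mean_W2"] + tr["mean_Q2"])
        return float(h.loc[b] - h.loc[a])

    def trait_gain(self, trait: int, from_year: int | None = None,
                   to_year: int | None = None) -> float:
        tr = self.trajectories.set_index("birth_year")
        a, b = (from_year or self.config.init_end_year,
                to_year or self.config.end_year)
        col = tr[f"mean_W{trait + 1}"] + tr[f"mean_Q{trait + 1}"]
        return float(col.loc[b] - col.loc[a])

    def added_inbreeding_pct(self, from_year: int | None = None,
                             to_year: int | None = None) -> float:
        tr = self.trajectories.set_index("birth_year")
        a, b = (from_year or self.config.init_end_year,
                to_year or self.config.end_year)
        return float(100.0 * (tr["mean_F"].loc[b] - tr["mean_F"].loc[a]))


# ---------------------------------------------------------------------- #
# elementary operations
# ---------------------------------------------------------------------- #

def apply_mortality(cohort: list[str], rate: float,
                    rng: np.random.Generator) -> list[str]:
    """Remove exactly ``rate * len(cohort)`` members uniformly at random.

    The exact-fraction rule (rather than binomial draws) reproduces the
    design's candidate counts (432 -> 324 -> 243).  Non-integer targets are
    rounded to nearest with a warning.
    """
    n = len(cohort)
    exact = rate * n
    k = int(round(exact))
    if abs(exact - k) > 1e-9:
        warnings.warn(f"mortality {rate} of {n} is not an integer; "
                      f"removing {k}", stacklevel=2)
    dead = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    return [q for i, q in enumerate(cohort) if i not in dead]


def allocate_apiaries(sister_groups: list[list[str]], n_apiaries: int,
                      rng: np.random.Generator,
                      apiaries_per_group: int = 3) -> dict[str, int]:
    """Assign queens to apiaries so that every sister group is split evenly
    over ``apiaries_per_group`` distinct apiaries and every apiary hosts the
    same number of groups.

    With the focal design (24 groups of 18, 18 apiaries, 3 apiaries per
    group) each apiary tests 4 sister groups of 6 queens per path, i.e. 24
    queens per path before mortality.  Returns a 1-based apiary per queen.
    """
    n_g = len(sister_groups)
    apg = apiaries_per_group
    if (n_g * apg) % n_apiaries:
        raise ValueError(f"{n_g} groups x {apg} cannot cover "
                         f"{n_apiaries} apiaries evenly")
    per_ap = n_g * apg // n_apiaries
    for g in sister_groups:
        if len(g) % apg:
            raise ValueError(f"group of {len(g)} not divisible by {apg}")

    # deal apiary slots to groups, then swap-repair duplicate apiaries
    slots = np.repeat(np.arange(n_apiaries), per_ap)
    rng.shuffle(slots)
    assign = slots.reshape(n_g, apg)
    for _ in range(10_000):
        bad = [g for g in range(n_g) if len(set(assign[g])) < apg]
        if not bad:
            break
        g = bad[0]
        vals, counts = np.unique(assign[g], return_counts=True)
        dup = vals[counts > 1][0]
        i = int(np.flatnonzero(assign[g] == dup)[1])
        # swap with a random slot elsewhere that keeps both groups duplicate-free
        for h in rng.permutation(n_g):
            if h == g:
                continue
            for j in range(apg):
                a, b = assign[g, i], assign[h, j]
                if b not in assign[g] and a not in np.delete(assign[h], j):
                    assign[g, i], assign[h, j] = b, a
                    break
            else:
                continue
            break
    else:  # pragma: no cover - repair loop failed
        raise RuntimeError("apiary allocation repair did not terminate")

    out: dict[str, int] = {}
    for g, members in enumerate(sister_groups):
        members = list(members)
        rng.shuffle(members)
        chunk = len(members) // apg
        for j, ap in enumerate(assign[g]):
            for q in members[j * chunk:(j + 1) * chunk]:
                out[q] = int(ap) + 1
    return out


def mate_cohort(new_bqs: list[str], selected_dpqs: list[str],
                rng: np.random.Generator) -> dict[str, str]:
    """Random balanced assignment of one sire (DPQ) to every new BQ."""
    n, k = len(new_bqs), len(selected_dpqs)
    if k == 0:
        raise ValueError("no selected DPQs to mate with")
    if n % k:
        warnings.warn(f"{n} queens cannot be split evenly over {k} sires; "
                      f"using nearest-balanced assignment", stacklevel=2)
    reps = -(-n // k)
    pool = np.tile(np.asarray(selected_dpqs, dtype=object), reps)[:n]
    rng.shuffle(pool)
    return dict(zip(new_bqs, pool))


# ---------------------------------------------------------------------- #
# internal building blocks
# ---------------------------------------------------------------------- #

def _inseminate(state: PopulationState, queen_id: str, dpq_id: str) -> str:
    """Create the 8-drone group of one instrumental insemination."""
    ped, cfg = state.pedigree, state.config
    n_d = cfg.genetics.n_drones
    mating = ped.add_mating(dpq_id, n_drones=n_d, node_id=f"M:{queen_id}")
    f = ped.inbreeding(dpq_id)
    state.drones[mating] = qg.make_drone(state.bv[dpq_id], f, state.G,
                                         state.stream("mating"), size=n_d)
    state.queens[queen_id].mating = mating
    return mating


def _open_mate(state: PopulationState, queen_id: str) -> str:
    """Open mating: pseudo-sire of 100 dummy DPQs supplying base drones."""
    ped, cfg = state.pedigree, state.config
    n_d = cfg.genetics.n_drones
    rng = state.stream("mating")
    mating = ped.add_open_mating(n_drones=n_d, node_id=f"PS:{queen_id}")
    dam_pick = rng.integers(0, 100, size=n_d)
    # dummy-dam values, shared when two drones draw the same pool dam
    uniq, inverse = np.unique(dam_pick, return_inverse=True)
    dams = qg.draw_founder_bvs(state.G, len(uniq), rng)[inverse]
    drones = 0.5 * dams + qg.make_gamete(np.zeros(state.G.shape[0]), 0.0,
                                         state.G, rng, size=n_d)
    state.drones[mating] = drones
    state.queens[queen_id].mating = mating
    return mating


def _born(state: PopulationState, role: str, year: int, dam: str | None,
          bv: np.ndarray, sister_group: int | None) -> str:
    ped = state.pedigree
    dam_mating = state.queens[dam].mating if dam else None
    qid = f"{role}{year}.{len(state.cohorts.get((role, year), []))}"
    ped.add_queen(dam, dam_mating, birth_year=year, node_id=qid)
    state.bv[qid] = bv
    state.queens[qid] = QueenMeta(role=role, birth_year=year, dam=dam,
                                  mating=None, sister_group=sister_group)
    state.cohorts.setdefault((role, year), []).append(qid)
    return qid


def _produce_cohorts(state: PopulationState, year: int, dams: list[str],
                     sires: list[str]) -> None:
    """Births of one year: per dam, offspring BQs and DPQs; new BQs are
    inseminated by the year's selected DPQs, new DPQs are open-mated; both
    cohorts are allocated to apiaries and suffer the first mortality."""
    cfg = state.config
    gen = state.stream("genetics")
    groups: dict[str, list[list[str]]] = {BQ: [], DPQ: []}
    for g, dam in enumerate(dams):
        meta = state.queens[dam]
        drones = state.drones[meta.mating]
        f_dam = state.pedigree.inbreeding(dam)
        for role, n_off in ((BQ, cfg.offspring_per_dam_bq),
                            (DPQ, cfg.offspring_per_dam_dpq)):
            members = []
            for _ in range(n_off):
                father = drones[gen.integers(drones.shape[0])]
                bv = qg.make_offspring_queen(state.bv[dam], f_dam, father,
                                             state.G, gen)
                members.append(_born(state, role, year, dam, bv, g))
            groups[role].append(members)

    new_bqs = [q for g in groups[BQ] for q in g]
    for bq, dpq in mate_cohort(new_bqs, sires, state.stream("mating")).items():
        _inseminate(state, bq, dpq)
    for dpq_grp in groups[DPQ]:
        for q in dpq_grp:
            _open_mate(state, q)

    for role in (BQ, DPQ):
        assign = allocate_apiaries(groups[role], cfg.n_apiaries,
                                   state.stream("allocation"),
                                   cfg.apiaries_per_sister_group)
        for q, ap in assign.items():
            state.queens[q].apiary = ap
        cohort = [q for g in groups[role] for q in g]
        survivors = set(apply_mortality(cohort, cfg.mortality_rate,
                                        state.stream("mortality")))
        for q in cohort:
            if q not in survivors:
                state.queens[q].alive = False
        state.ledger.append(dict(year=year, event="births", role=role,
                                 n=len(cohort), survivors=len(survivors)))


def _second_mortality(state: PopulationState, role: str, birth_year: int) -> None:
    alive = state.alive_in_cohort(role, birth_year)
    survivors = set(apply_mortality(alive, state.config.mortality_rate,
                                    state.stream("mortality")))
    for q in alive:
        if q not in survivors:
            state.queens[q].alive = False
    state.ledger.append(dict(year=birth_year + 2, event="second_mortality",
                             role=role, n=len(alive), survivors=len(survivors)))


def _apiary_effect(state: PopulationState, apiary: int, year: int) -> np.ndarray:
    par = state.config.genetics
    sd = (np.sqrt(par.sigma2_apiary_T1), np.sqrt(par.sigma2_apiary_T2))
    out = np.empty(2)
    for t in range(2):
        key = (apiary, year, t)
        if key not in state.apiary_effects:
            state.apiary_effects[key] = float(
                state.stream("phenotype").standard_normal() * sd[t])
        out[t] = state.apiary_effects[key]
    return out


def _phenotype_cohort(state: PopulationState, role: str, birth_year: int,
                      record_year: int, traits: tuple[bool, bool],
                      avail: tuple[int, int]) -> None:
    """Phenotype the surviving colonies of one cohort.

    ``avail`` gives, per trait, the first evaluation year in which the
    record is part of the performance file (late records are only usable
    the year after their season; in Alt a DPQ's early record is withheld
    until it becomes a 2-year-old candidate).
    """
    cfg = state.config
    par = cfg.genetics
    rng = state.stream("phenotype")
    n_rec = 0
    for q in state.alive_in_cohort(role, birth_year):
        meta = state.queens[q]
        wm = qg.worker_group_mean_bv(state.bv[q], state.pedigree.inbreeding(q),
                                     state.drones[meta.mating], par.n_drones)
        if meta.worker_group is None:
            meta.worker_group = state.pedigree.add_worker_group(
                q, meta.mating, node_id=f"W:{q}")
        rec = qg.ColonyRecord(queen_id=q, worker_group_id=meta.worker_group,
                              apiary_id=meta.apiary, year=record_year,
                              true_queen_bv=state.bv[q],
                              true_worker_mean_bv=wm)
        qg.colony_phenotype(rec, _apiary_effect(state, meta.apiary, record_year),
                            par, rng, traits_to_record=traits)
        state.records.append(dict(
            colony_id=f"C:{q}", queen_id=q, worker_group_id=meta.worker_group,
            apiary=meta.apiary, year=record_year, y_T1=rec.y_T1, y_T2=rec.y_T2,
            role=role, birth_year=birth_year,
            avail_T1=avail[0] if traits[0] else 10**9,
            avail_T2=avail[1] if traits[1] else 10**9))
        n_rec += 1
    state.ledger.append(dict(year=record_year, event="phenotyping", role=role,
                             n=n_rec,
                             traits="both" if all(traits) else "early"))


def _true_score(state: PopulationState, ids: list[str],
                source: str) -> np.ndarray:
    """True selection-index values (H weights on worker+queen sums)."""
    w = state.config.weights
    out = np.empty(len(ids))
    for i, q in enumerate(ids):
        if source == "own":
            v = state.bv[q]
        else:  # worker group of the candidate's colony
            meta = state.queens[q]
            v = qg.worker_group_mean_bv(
                state.bv[q], state.pedigree.inbreeding(q),
                state.drones[meta.mating], state.config.genetics.n_drones)
        out[i] = w[0] * (v[qg.W1] + v[qg.Q1]) + w[1] * (v[qg.W2] + v[qg.Q2])
    return out


def _phenotypic_selection(state: PopulationState, candidates: list[str],
                          n_select: int) -> list[str]:
    """Initialization-phase truncation selection on the weighted sum of
    both phenotypes in realized cohort standard-deviation units."""
    w = state.config.weights
    if w == (0.0, 0.0):
        rng = state.stream("selection")
        return sorted(rng.choice(candidates, size=n_select, replace=False))
    recs = {r["queen_id"]: r for r in state.records}
    y = np.array([[recs[q]["y_T1"], recs[q]["y_T2"]] for q in candidates])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sd = np.nanstd(y, axis=0, ddof=1)
    sd[~(sd > 0)] = 1.0
    z = y / sd
    z[np.isnan(z)] = 0.0  # unrecorded traits contribute nothing
    score = z @ np.asarray(w)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-score[i], candidates[i]))
    return [candidates[i] for i in order[:n_select]]


def _evaluate(state: PopulationState, year: int) -> EBVTable | None:
    """One genetic evaluation: (REML +) BLUP on all available records.

    In 'dry' and 'phenotypic' modes only the record bookkeeping is logged;
    no mixed-model system is built and ``None`` is returned.
    """
    cfg = state.config
    perf = state.performance_file(year)
    G_true = state.G
    R_true = cfg.genetics.residual_cov
    state.ledger.append(dict(year=year, event="evaluation",
                             n=perf.n_records(0), n_late=perf.n_records(1)))
    if cfg.evaluation_mode in ("dry", "phenotypic"):
        return None
    if cfg.evaluation_mode == "reml":
        est = reml_estimate(perf, state.pedigree, G_true, R_true)
        state.reml_log.append(dict(year=year, converged=est.converged,
                                   n_iterations=est.n_iterations))
        if not est.converged:
            raise REMLFailure(f"REML failed to converge in year {year}")
        G_use, R_use = est.G, est.R
    else:
        G_use, R_use = G_true, R_true
    system = assemble_mme(perf, state.pedigree, G_use, R_use)
    x0 = _warm_start(state, system)
    method = "splu" if system.C.shape[0] <= 40_000 else "cg"
    table, sol = solve_blup(system, method=method, x0=x0)
    _store_warm(state, system, sol)
    return table


def _warm_start(state: PopulationState, system) -> np.ndarray | None:
    if not state.warm:
        return None
    x0 = np.zeros(system.C.shape[0])
    warm = state.warm
    for j, lab in enumerate(system.fixed_labels):
        x0[j] = warm.get(("f", lab), 0.0)
    n_eff = 2 * len(system.traits)
    for p, nid in enumerate(system.node_ids):
        for e in range(n_eff):
            x0[system.n_fixed + e * system.n_nodes + p] = \
                warm.get(("u", e, nid), 0.0)
    return x0


def _store_warm(state: PopulationState, system, sol: np.ndarray) -> None:
    warm = {}
    for j, lab in enumerate(system.fixed_labels):
        warm[("f", lab)] = sol[j]
    n_eff = 2 * len(system.traits)
    for e in range(n_eff):
        base = system.n_fixed + e * system.n_nodes
        for p, nid in enumerate(system.node_ids):
            warm[("u", e, nid)] = sol[base + p]
    state.warm = warm


def _ebv_selection(state: PopulationState, table: EBVTable | None, year: int,
                   candidates: list[str], n_select: int, role: str) -> list[str]:
    w = state.config.weights
    mode = state.config.evaluation_mode
    if table is None and mode == "phenotypic":
        chosen = _phenotypic_selection(state, candidates, n_select)
        state.ledger.append(dict(year=year, event="selection", role=role,
                                 n=len(candidates), survivors=n_select))
        return chosen
    if w == (0.0, 0.0) or (table is None and mode == "dry"):
        rng = state.stream("selection")
        chosen = sorted(rng.choice(candidates, size=n_select, replace=False))
        state.ledger.append(dict(year=year, event="selection", role=role,
                                 n=len(candidates), survivors=n_select))
        return chosen
    else:
        ranking = selection_index(table, w, "dam" if role == BQ else "sire",
                                  candidates)
        chosen = ranking["candidate"].head(n_select).tolist()
    # index accuracy over the candidate cohort of the evaluation year
    src = "worker_group" if role == BQ else "own"
    true = _true_score(state, candidates, src)
    ids = [table.wg_of_queen[q] for q in candidates] if role == BQ \
        else candidates
    est = table.score(ids, w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc = index_accuracy(true, est)
    state.accuracies.append(dict(year=year, role=role, accuracy=acc,
                                 n_candidates=len(candidates)))
    state.ledger.append(dict(year=year, event="selection", role=role,
                             n=len(candidates), survivors=n_select))
    return chosen


# ---------------------------------------------------------------------- #
# phases
# ---------------------------------------------------------------------- #

def run_initialization(config: SchemeConfig,
                       seed: int | None = None) -> PopulationState:
    """Years 1 to ``init_end_year``: closed population under phenotypic
    selection, ending right after the final Initialization births and
    their first mortality (the state both schemes fork from)."""
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    state = PopulationState(config=config)
    state.make_streams("init")
    state.G = qg.build_G(config.genetics)
    gen = state.stream("genetics")

    # year 1: founder BQs, unrelated and non-inbred, open-mated
    founders = []
    for i, bv in enumerate(qg.draw_founder_bvs(state.G, config.n_selected_bq,
                                               gen)):
        qid = _born(state, BQ, 1, None, bv, None)
        state.queens[qid].apiary = 1 + i % config.n_apiaries
        _open_mate(state, qid)
        founders.append(qid)
    state.ledger.append(dict(year=1, event="founders", role=BQ,
                             n=len(founders)))

    # year 2: founder colonies phenotyped; founders produce the first cohort
    _phenotype_cohort(state, BQ, 1, 2, (True, True), (2, 3))
    dams, sires = founders, None
    for year in range(2, config.init_end_year + 1, 2):
        if sires is None:  # first cohort: offspring BQs open-mated too
            cfg = config
            groups: dict[str, list[list[str]]] = {BQ: [], DPQ: []}
            for g, dam in enumerate(dams):
                drones = state.drones[state.queens[dam].mating]
                f_dam = state.pedigree.inbreeding(dam)
                for role, n_off in ((BQ, cfg.offspring_per_dam_bq),
                                    (DPQ, cfg.offspring_per_dam_dpq)):
                    members = []
                    for _ in range(n_off):
                        father = drones[gen.integers(drones.shape[0])]
                        bv = qg.make_offspring_queen(state.bv[dam], f_dam,
                                                     father, state.G, gen)
                        members.append(_born(state, role, year, dam, bv, g))
                    groups[role].append(members)
            for role in (BQ, DPQ):
                for grp in groups[role]:
                    for q in grp:
                        _open_mate(state, q)
                assign = allocate_apiaries(groups[role], cfg.n_apiaries,
                                           state.stream("allocation"),
                                           cfg.apiaries_per_sister_group)
                for q, ap in assign.items():
                    state.queens[q].apiary = ap
                cohort = [q for g in groups[role] for q in g]
                survivors = set(apply_mortality(cohort, cfg.mortality_rate,
                                                state.stream("mortality")))
                for q in cohort:
                    if q not in survivors:
                        state.queens[q].alive = False
                state.ledger.append(dict(year=year, event="births", role=role,
                                         n=len(cohort),
                                         survivors=len(survivors)))
        else:
            _produce_cohorts(state, year, dams, sires)
        if year == config.init_end_year:
            break
        # next odd year: phenotype both paths, then the second winter
        _phenotype_cohort(state, BQ, year, year + 1, (True, True),
                          (year + 1, year + 2))
        _phenotype_cohort(state, DPQ, year, year + 1, (True, True),
                          (year + 1, year + 2))
        _second_mortality(state, BQ, year)
        _second_mortality(state, DPQ, year)
        # selection year (year + 2): phenotypic truncation on both paths
        sel_year = year + 2
        dams = _phenotypic_selection(state, state.alive_in_cohort(BQ, year),
                                     config.n_selected_bq)
        sires = _phenotypic_selection(state, state.alive_in_cohort(DPQ, year),
                                      config.n_selected_dpq)
        state.selected[(BQ, sel_year)] = dams
        state.selected[(DPQ, sel_year)] = sires
        for role, sel in ((BQ, dams), (DPQ, sires)):
            state.ledger.append(dict(
                year=sel_year, event="selection", role=role,
                n=len(state.alive_in_cohort(role, year)), survivors=len(sel)))
    state.year = config.init_end_year
    return state


def _summarize(state: PopulationState, dam_generations: int,
               sire_generations: int) -> ReplicateResult:
    rows = []
    years = sorted({y for (r, y) in state.cohorts if r == BQ})
    for y in years:
        ids = state.cohorts[(BQ, y)]
        bvs = np.array([state.bv[q] for q in ids])
        fs = np.array([state.pedigree.inbreeding(q) for q in ids])
        rows.append(dict(birth_year=y, mean_W1=bvs[:, qg.W1].mean(),
                         mean_Q1=bvs[:, qg.Q1].mean(),
                         mean_W2=bvs[:, qg.W2].mean(),
                         mean_Q2=bvs[:, qg.Q2].mean(),
                         mean_F=fs.mean(), n=len(ids)))
    w = state.config.weights
    tr = pd.DataFrame(rows)
    tr["mean_H"] = w[0] * (tr.mean_W1 + tr.mean_Q1) + \
        w[1] * (tr.mean_W2 + tr.mean_Q2)
    # average of the realized dam- and sire-path generation intervals
    span = state.config.end_year - state.config.init_end_year
    mean_L = 0.5 * (span / dam_generations + span / sire_generations)
    return ReplicateResult(
        branch=state.branch, config=state.config, trajectories=tr,
        accuracy=pd.DataFrame(state.accuracies,
                              columns=["year", "role", "accuracy",
                                       "n_candidates"]),
        ledger=pd.DataFrame(state.ledger),
        reml_log=pd.DataFrame(state.reml_log,
                              columns=["year", "converged", "n_iterations"]),
        dam_generations=dam_generations, sire_generations=sire_generations,
        mean_generation_interval=mean_L)


def run_base(state: PopulationState) -> ReplicateResult:
    """Base scheme: biennial EBV selection of 2-year-old dams and sires with
    complete phenotyping, from the first selection in year 12 to the last
    births in year 30 (10 dam generations)."""
    if state.branch == "init":
        state = state.fork("base")
    cfg = state.config
    first = cfg.init_end_year + 2
    for year in range(first, cfg.end_year + 1, 2):
        born = year - 2
        _phenotype_cohort(state, BQ, born, year - 1, (True, True),
                          (year - 1, year))
        _phenotype_cohort(state, DPQ, born, year - 1, (True, True),
                          (year - 1, year))
        _second_mortality(state, BQ, born)
        _second_mortality(state, DPQ, born)
        table = _evaluate(state, year)
        dams = _ebv_selection(state, table, year,
                              state.alive_in_cohort(BQ, born),
                              cfg.n_selected_bq, BQ)
        sires = _ebv_selection(state, table, year,
                               state.alive_in_cohort(DPQ, born),
                               cfg.n_selected_dpq, DPQ)
        state.selected[(BQ, year)] = dams
        state.selected[(DPQ, year)] = sires
        _produce_cohorts(state, year, dams, sires)
    state.year = cfg.end_year
    n_gen = (cfg.end_year - cfg.init_end_year) // 2
    return _summarize(state, n_gen, n_gen)


def run_alt(state: PopulationState) -> ReplicateResult:
    """Alt scheme: annual dam cycles (selection at 1 year old on the early
    trait only, 324 candidates) with sires kept on 2-year complete
    phenotyping; the transition year reuses the Initialization's last
    selected DPQ pool, after which dams are always mated to 2-year-old
    DPQs.  20 dam generations by the last births in year 30."""
    if state.branch == "init":
        state = state.fork("alt")
    cfg = state.config
    t0 = cfg.init_end_year + 1
    for year in range(t0, cfg.end_year + 1):
        # early phenotypes of 1-year-old candidate dams, usable immediately
        _phenotype_cohort(state, BQ, year - 1, year, (True, False),
                          (year, 10**9))
        table = _evaluate(state, year)
        dams = _ebv_selection(state, table, year,
                              state.alive_in_cohort(BQ, year - 1),
                              cfg.n_selected_bq, BQ)
        if year == t0:
            # no DPQs born in init_end_year - 1: reuse the last selected pool
            sires = state.selected[(DPQ, cfg.init_end_year)]
        else:
            _second_mortality(state, DPQ, year - 2)
            sires = _ebv_selection(state, table, year,
                                   state.alive_in_cohort(DPQ, year - 2),
                                   cfg.n_selected_dpq, DPQ)
        state.selected[(BQ, year)] = dams
        state.selected[(DPQ, year)] = sires
        _produce_cohorts(state, year, dams, sires)
        # candidate DPQs born year-1 are phenotyped on both traits this
        # year; early records withheld until they are 2-year-old candidates
        _phenotype_cohort(state, DPQ, year - 1, year, (True, True),
                          (year + 1, year + 1))
    state.year = cfg.end_year
    span = cfg.end_year - cfg.init_end_year
    return _summarize(state, span, span // 2)


def run_replicate_pair(config: SchemeConfig, seed: int | None = None
                       ) -> tuple[ReplicateResult, ReplicateResult]:
    """One paired replicate: shared Initialization, then Base and Alt."""
    init = run_initialization(config, seed)
    base = run_base(init.fork("base"))
    alt = run_alt(init.fork("alt"))
    return base, alt
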