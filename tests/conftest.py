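"""Shared fixtures: toy pedigrees, scaled scheme configs, and the
session-scoped full-design paired runs used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from apisim.pedigree import Pedigree
from apisim.scheme import SchemeConfig, run_alt, run_base, run_initialization


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_pedigree() -> Pedigree:
    """Three generations: founders, an insemination, sisters, a worker
    group, an open mating, and an inbred full-sib mating."""
    ped = Pedigree()
    ped.add_queen(None, None, node_id="dam1")
    ped.add_queen(None, None, node_id="dpq1")
    ped.add_mating("dpq1", node_id="mate1")
    ped.add_queen("dam1", "mate1", node_id="q1")
    ped.add_queen("dam1", "mate1", node_id="q2")
    ped.add_worker_group("q1", "mate1", node_id="w1")
    ped.add_open_mating(node_id="ps1")
    ped.add_queen("q1", "ps1", node_id="q3")
    ped.add_mating("q1", node_id="mate2")
    ped.add_queen("q2", "mate2", node_id="q4")  # dam q2 x drones of q1
    return ped


def random_pedigree(rng: np.random.Generator, n_target: int = 200) -> Pedigree:
    """Random structurally-valid bee pedigree for property tests."""
    ped = Pedigree()
    queens: list[str] = []
    matings: dict[str, str] = {}  # queen -> her mating node

    def mate(q: str) -> str:
        if q not in matings:
            if queens and rng.random() < 0.6:
                dpq = queens[int(rng.integers(len(queens)))]
                matings[q] = ped.add_mating(dpq, node_id=f"M{q}")
            else:
                matings[q] = ped.add_open_mating(node_id=f"P{q}")
        return matings[q]

    for i in range(6):
        q = ped.add_queen(None, None, node_id=f"F{i}")
        queens.append(q)
    k = 0
    while len(ped) < n_target - 2:
        dam = queens[int(rng.integers(len(queens)))]
        m = mate(dam)
        q = ped.add_queen(dam, m, node_id=f"Q{k}")
        if rng.random() < 0.3:
            ped.add_worker_group(q, mate(q), node_id=f"W{k}")
        queens.append(q)
        k += 1
    return ped


def scaled_config(**overrides) -> SchemeConfig:
    """Small but structurally complete design for fast scheme tests."""
    kwargs = dict(weights=(0.5, 0.5), n_selected_bq=6, n_selected_dpq=6,
                  offspring_per_dam_bq=12, offspring_per_dam_dpq=12,
                  n_apiaries=6, init_end_year=6, end_year=14,
                  evaluation_mode="known", seed=1)
    kwargs.update(overrides)
    return SchemeConfig(**kwargs)


def _paired(weights, seed, **overrides):
    cfg = SchemeConfig(weights=weights, evaluation_mode="known", seed=seed,
                       **overrides)
    init = run_initialization(cfg)
    return run_base(init.fork("base")), run_alt(init.fork("alt"))


@pytest.fixture(scope="session")
def paired_full_runs():
    """Full-design paired Base/Alt replicates (known-variance mode) for the
    two single-trait breeding goals and the equal-weight goal.

    Replicate counts are kept small (3/3/2) so the whole set runs in a few
    minutes; the comparison tolerances in the tests account for the
    resulting Monte-Carlo error explicitly.
    """
    runs = {}
    for name, weights, seeds in (("H10", (1.0, 0.0), (11, 12, 13)),
                                 ("H01", (0.0, 1.0), (11, 12, 13)),
                                 ("H55", (0.5, 0.5), (11, 12))):
        base_list, alt_list = [], []
        for seed in seeds:
            b, a = _paired(weights, seed)
            base_list.append(b)
            alt_list.append(a)
        runs[name] = (base_list, alt_list)
    return runs
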