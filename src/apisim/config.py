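"""Scenario grids, run manifests, and batch execution.

A scenario is a point on the study grid: breeding-goal weights x
between-trait genetic correlation x worker-queen correlation x parent
number variant (24 or 36 selected per path).  A manifest expands the grid,
derives a reproducible seed per scenario x replicate, and runs paired
Base/Alt replicates, re-drawing any replicate whose in-loop REML fails.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from apisim.quantgen import GeneticParams
from apisim.scheme import (REMLFailure, SchemeConfig, run_alt, run_base,
                           run_initialization)
from apisim.summary import compare_replicates

__all__ = ["RunManifest", "validate_config", "expand_grid", "run_grid",
           "aggregate_tables"]

_VARIANTS = {24: dict(n_selected=24, offspring=18),
             36: dict(n_selected=36, offspring=12)}


@dataclass
class RunManifest:
    """Everything needed to reproduce one batch of simulations."""

    scenarios: list[dict] = field(default_factory=list)
    replicates: int = 50
    seed: int = 1
    evaluation_mode: str = "known"
    out_dir: str = "results"
    max_redraws: int = 20
    #: also write per-replicate pedigree, performance-file and event-ledger
    #: CSVs (large at full design size)
    save_details: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        grid = expand_grid(raw)
        kwargs = dict(scenarios=grid)
        for key in ("replicates", "seed", "evaluation_mode", "out_dir",
                    "max_redraws", "save_details"):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


_SCHEME_KEYS = ("n_selected_bq", "n_selected_dpq", "offspring_per_dam_bq",
                "offspring_per_dam_dpq", "mortality_rate", "n_apiaries",
                "apiaries_per_sister_group", "init_end_year", "end_year")


def expand_grid(raw: dict) -> list[dict]:
    """Cartesian grid over weights, r_T1T2, r_WQ and parent variant.

    Design constants given at the top level (cohort sizes, apiaries, years)
    apply to every scenario in the grid.
    """
    def aslist(x, default):
        v = raw.get(x, default)
        return v if isinstance(v, list) else [v]

    weights = aslist("weights", [[0.5, 0.5]])
    r_t = aslist("r_T1T2", [0.0])
    r_wq = aslist("r_WQ", [0.0])
    variants = aslist("variant", [24])
    shared = {k: raw[k] for k in _SCHEME_KEYS if k in raw}
    out = []
    for w in weights:
        for rt in r_t:
            for rwq in r_wq:
                for var in variants:
                    out.append(dict(weights=tuple(w), r_T1T2=float(rt),
                                    r_WQ=float(rwq), variant=int(var),
                                    **shared))
    return out


def validate_config(raw: dict) -> SchemeConfig:
    """Build and validate a SchemeConfig from a raw scenario dict.

    Range/divisibility violations raise an aggregated error; values that
    are merely off the study grid (weights, correlations) warn.
    """
    variant = int(raw.get("variant", 24))
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be 24 or 36, got {variant}")
    v = _VARIANTS[variant]
    genetics = GeneticParams(r_T1T2=float(raw.get("r_T1T2", 0.0)),
                             r_WQ=float(raw.get("r_WQ", 0.0)))
    cfg = SchemeConfig(
        weights=tuple(raw.get("weights", (0.5, 0.5))),
        genetics=genetics,
        n_selected_bq=raw.get("n_selected_bq", v["n_selected"]),
        n_selected_dpq=raw.get("n_selected_dpq", v["n_selected"]),
        offspring_per_dam_bq=raw.get("offspring_per_dam_bq", v["offspring"]),
        offspring_per_dam_dpq=raw.get("offspring_per_dam_dpq", v["offspring"]),
        mortality_rate=float(raw.get("mortality_rate", 0.25)),
        n_apiaries=int(raw.get("n_apiaries", 18)),
        apiaries_per_sister_group=int(raw.get("apiaries_per_sister_group", 3)),
        init_end_year=int(raw.get("init_end_year", 10)),
        end_year=int(raw.get("end_year", 30)),
        evaluation_mode=raw.get("evaluation_mode", "known"),
        seed=int(raw.get("seed", 0)))
    cfg.validate()
    w = tuple(round(float(x), 4) for x in cfg.weights)
    if w not in {(1.0, 0.0), (0.75, 0.25), (0.5, 0.5), (0.25, 0.75),
                 (0.0, 1.0), (0.0, 0.0)}:
        warnings.warn(f"weights {w} are off the study grid", stacklevel=2)
    return cfg


def _replicate_seed(master: int, scenario_idx: int, attempt: int) -> int:
    ss = np.random.SeedSequence((master, scenario_idx, attempt))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _scenario_name(s: dict) -> str:
    w = s["weights"]
    return (f"H{w[0]:g}-{w[1]:g}_rt{s['r_T1T2']:g}_rwq{s['r_WQ']:g}"
            f"_v{s['variant']}")


def run_grid(manifest: RunManifest, progress: bool = False) -> pd.DataFrame:
    """Run every scenario x replicate (paired Base+Alt) and persist results.

    Writes, under ``out_dir``: the manifest, one tidy trajectory CSV and
    one gains CSV per scenario, a REML-failure log, and an aggregate
    comparison table.  Returns the aggregate table.
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_json(out / "manifest.json")
    all_rows = []
    fail_rows = []
    for si, scen in enumerate(manifest.scenarios):
        name = _scenario_name(scen)
        base_results, alt_results = [], []
        tidy = []
        attempt = 0
        while len(base_results) < manifest.replicates:
            if attempt >= manifest.replicates + manifest.max_redraws:
                raise RuntimeError(f"too many REML failures in {name}")
            seed = _replicate_seed(manifest.seed, si, attempt)
            cfg = validate_config({**scen, "seed": seed,
                                   "evaluation_mode": manifest.evaluation_mode})
            attempt += 1
            try:
                init = run_initialization(cfg)
                base_state = init.fork("base")
                base = run_base(base_state)
                alt_state = init.fork("alt")
                alt = run_alt(alt_state)
            except REMLFailure as exc:
                fail_rows.append(dict(scenario=name, attempt=attempt - 1,
                                      seed=seed, error=str(exc)))
                continue
            rep = len(base_results)
            base_results.append(base)
            alt_results.append(alt)
            if manifest.save_details:
                for tag, st, res in (("base", base_state, base),
                                     ("alt", alt_state, alt)):
                    stem = f"{name}_rep{rep}_{tag}"
                    st.pedigree.to_csv(out / f"pedigree_{stem}.csv")
                    st.performance_file(cfg.end_year + 2).to_csv(
                        out / f"performance_{stem}.csv")
                    res.ledger.to_csv(out / f"ledger_{stem}.csv", index=False)
            for res in (base, alt):
                tr = res.trajectories.copy()
                tr.insert(0, "scenario", name)
                tr.insert(1, "replicate", rep)
                tr.insert(2, "branch", res.branch)
                tidy.append(tr)
            if progress:
                print(f"{name}: replicate {rep + 1}/{manifest.replicates}",
                      flush=True)
        pd.concat(tidy).to_csv(out / f"trajectories_{name}.csv", index=False)
        comp = compare_replicates(base_results, alt_results,
                                  weights=tuple(scen["weights"]))
        tab = comp.metrics.copy()
        tab.insert(0, "scenario", name)
        for key in ("weights", "r_T1T2", "r_WQ", "variant"):
            tab[key] = [str(scen[key])] * len(tab)
        all_rows.append(tab)
    table = pd.concat(all_rows, ignore_index=True)
    table.to_csv(out / "comparison.csv", index=False)
    pd.DataFrame(fail_rows,
                 columns=["scenario", "attempt", "seed", "error"]
                 ).to_csv(out / "reml_failures.csv", index=False)
    return table


def aggregate_tables(result_dir) -> pd.DataFrame:
    """Re-aggregate the per-scenario trajectory CSVs in a results directory."""
    out = Path(result_dir)
    files = sorted(out.glob("trajectories_*.csv"))
    if not files:
        raise FileNotFoundError(f"no trajectory CSVs under {out}")
    frames = [pd.read_csv(f) for f in files]
    df = pd.concat(frames, ignore_index=True)
    first = df.groupby(["scenario", "replicate", "branch"]).birth_year.min()
    rows = []
    for (scen, rep, branch), sub in df.groupby(
            ["scenario", "replicate", "branch"]):
        sub = sub.set_index("birth_year")
        y0, y1 = 10, int(sub.index.max())
        rows.append(dict(scenario=scen, replicate=rep, branch=branch,
                         gain_H=sub.mean_H.loc[y1] - sub.mean_H.loc[y0],
                         added_F_pct=100 * (sub.mean_F.loc[y1]
                                            - sub.mean_F.loc[y0])))
    return pd.DataFrame(rows)
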