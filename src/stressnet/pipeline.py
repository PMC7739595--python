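"""End-to-end orchestration of the two network analyses.

``run_first_network`` chains imputation, life-event accumulation and
log scaling, median-split discretisation, the two-slice layout,
constraint generation, bootstrap structure averaging and the injury
queries.  ``run_second_network`` does the same for the change-score
(hybrid) analysis, ending in the evidence grid and the Bayesian
regression of the fear-system change on its two drivers.

Every stochastic stage receives a child seed spawned from the config
seed, so a run is reproducible end to end, and each bundle carries a
run log with all seeds, thresholds and constraint rules applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from stressnet.bn.bootstrap import ArcStrengthTable, average_network, bootstrap_strength
from stressnet.bn.constraints import first_network_constraints, second_network_constraints
from stressnet.bn.fit import fit_parameters
from stressnet.bn.search import SearchParams
from stressnet.cohort import CohortSpec, default_ground_truth, sample_cohort, inject_missingness
from stressnet.inference import (
    EvidenceQuery,
    blanket_query_table,
    bayes_linreg,
    cpquery_lw,
    markov_blanket,
    sample_conditional,
)
from stressnet.prep import (
    CHANGE_VARS,
    EXPLANATORY,
    SLICE_VARS,
    build_2tbn_table,
    build_change_table,
    discretise_first,
    impute_bagged_trees,
    save_maps,
    transform_life_events,
)

MEASURE_TIMES = ("T1", "T2", "T3")


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    cohort_path: str | None = None      # CSV; when None, a cohort is simulated
    out_dir: str = "artifacts"
    seed: int = 17
    n_bootstrap: int = 1000
    inclusion: float = 0.3
    significance: float = 0.5
    n_query_samples: int = 100_000
    effect_scale: float = 1.0           # simulation only
    n_recruited: int = 351
    n_t1_only: int = 94
    impute_trees: int = 25

    def search_params(self, seed: int) -> SearchParams:
        return SearchParams(
            n_bootstrap=self.n_bootstrap,
            inclusion=self.inclusion,
            significance=self.significance,
            seed=seed,
        )


def _child_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, ss.spawn(len(names)))}


def _load_or_simulate(config: PipelineConfig, seed: int) -> pd.DataFrame:
    if config.cohort_path is not None:
        return pd.read_csv(config.cohort_path)
    model = default_ground_truth(config.effect_scale)
    spec = CohortSpec(
        n_recruited=config.n_recruited,
        n_t1_only=config.n_t1_only,
        seed=seed,
    )
    return inject_missingness(sample_cohort(model, spec), spec)


def impute_cohort(cohort: pd.DataFrame, n_trees: int, seed: int) -> pd.DataFrame:
    """Impute missing continuous measures on the measurement rows only."""
    out = cohort.copy()
    mrows = out["time"].isin(MEASURE_TIMES)
    block = out.loc[mrows].drop(
        columns=[c for c in ("injured", "participant", "time") if c in out.columns]
        + [c for c in out.columns if c.endswith("_missing")],
        errors="ignore",
    )
    if block.select_dtypes("number").isna().any().any():
        imputed = impute_bagged_trees(block, n_trees=n_trees, seed=seed)
        num_cols = imputed.select_dtypes("number").columns
        out.loc[mrows, num_cols] = imputed[num_cols]
    return out


def run_first_network(config: PipelineConfig) -> dict:
    """Discretised two-slice analysis; returns the artifact bundle."""
    seeds = _child_seeds(config.seed, ("cohort", "impute", "bootstrap", "queries"))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = _load_or_simulate(config, seeds["cohort"])
    cohort = impute_cohort(cohort, config.impute_trees, seeds["impute"])
    transformed = transform_life_events(cohort)
    disc, maps = discretise_first(transformed)
    two_slice = build_2tbn_table(disc)
    learn = two_slice.drop(columns=["participant", "pair"]).dropna().reset_index(drop=True)

    constraints = first_network_constraints(EXPLANATORY, SLICE_VARS)
    params = config.search_params(seeds["bootstrap"])
    strengths = bootstrap_strength(learn, constraints, params)
    dag, labels = average_network(
        strengths, config.inclusion, config.significance, nodes=tuple(learn.columns)
    )
    net = fit_parameters(dag, learn, smoothing=params.smoothing)

    qseed = seeds["queries"]
    blankets, single_tables, full_tables = {}, {}, {}
    for i, target in enumerate(("injured_1", "injured_2")):
        mb = sorted(markov_blanket(dag, target))
        blankets[target] = mb
        rows = []
        for var in mb:
            for state in net.states[var]:
                res = cpquery_lw(
                    net,
                    EvidenceQuery(
                        event={target: "injured"},
                        evidence={var: state},
                        n_samples=config.n_query_samples,
                        seed=qseed + 7 * i,
                    ),
                )
                rows.append({"variable": var, "state": state, "probability": res.probability,
                             "std_error": res.std_error})
        single_tables[target] = pd.DataFrame(rows)
        full_tables[target] = blanket_query_table(
            net, (target, "injured"), tuple(mb),
            n_samples=config.n_query_samples, seed=qseed + 100 + i,
        )

    # artifacts
    two_slice.to_csv(out_dir / "two_slice_table.csv", index=False)
    strengths.to_csv(out_dir / "first_strengths.csv")
    (out_dir / "first_network.json").write_text(dag.to_json())
    (out_dir / "first_network.dot").write_text(
        dag.to_dot({a: f"{strengths.strength_of(*a):.2f}" for a in dag.arcs})
    )
    save_maps(maps, out_dir / "discretisation_maps.json")
    for target in blankets:
        single_tables[target].to_csv(out_dir / f"{target}_single_queries.csv", index=False)
        full_tables[target].to_csv(out_dir / f"{target}_blanket_table.csv", index=False)
    log = {
        "analysis": "first_network",
        "seed": config.seed,
        "child_seeds": seeds,
        "n_bootstrap": config.n_bootstrap,
        "inclusion": config.inclusion,
        "significance": config.significance,
        "blacklist": sorted(map(list, first_network_constraints(EXPLANATORY, SLICE_VARS).blacklist)),
        "whitelist": sorted(map(list, first_network_constraints(EXPLANATORY, SLICE_VARS).whitelist)),
        "discretisation": {k: m.to_dict() for k, m in maps.items()},
        "markov_blankets": blankets,
        "arc_labels": {f"{u}->{v}": lab for (u, v), lab in labels.items()},
        "n_rows": int(len(learn)),
    }
    (out_dir / "first_run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "cohort": cohort,
        "two_slice": two_slice,
        "strengths": strengths,
        "dag": dag,
        "labels": labels,
        "net": net,
        "blankets": blankets,
        "single_tables": single_tables,
        "full_tables": full_tables,
        "maps": maps,
        "log": log,
    }


def run_second_network(config: PipelineConfig) -> dict:
    """Change-score (hybrid) analysis; returns the artifact bundle."""
    seeds = _child_seeds(config.seed, ("cohort", "impute", "bootstrap", "queries", "samples", "regression"))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = _load_or_simulate(config, seeds["cohort"])
    cohort = impute_cohort(cohort, config.impute_trees, seeds["impute"])
    change = build_change_table(cohort)
    learn = change.drop(columns=["participant", "interval"]).reset_index(drop=True)

    explanatory = ("gender", "sport_type", "comp_level", "prev_injury", "training_hours")
    change_cols = tuple(f"d_{v}" for v in CHANGE_VARS)
    constraints = second_network_constraints(explanatory, change_cols)
    params = config.search_params(seeds["bootstrap"])
    strengths = bootstrap_strength(learn, constraints, params)
    dag, labels = average_network(
        strengths, config.inclusion, config.significance, nodes=tuple(learn.columns)
    )
    net = fit_parameters(dag, learn, smoothing=params.smoothing)

    mb = sorted(markov_blanket(dag, "injured"))
    grid_vars = [v for v in ("d_nle", "d_stiffness") if v in dag.nodes]
    grid = blanket_query_table(
        net, ("injured", "injured"), tuple(grid_vars),
        n_samples=config.n_query_samples, seed=seeds["queries"],
    )
    full_grid = blanket_query_table(
        net, ("injured", "injured"), tuple(mb),
        n_samples=config.n_query_samples, seed=seeds["queries"] + 1,
    )

    draws = sample_conditional(net, ["d_bis", "d_hrv", "d_fffs"], n=10_000, seed=seeds["samples"])
    X = np.column_stack(
        [draws["d_bis"], draws["d_hrv"], draws["d_bis"] * draws["d_hrv"]]
    )
    posterior = bayes_linreg(
        draws["d_fffs"].to_numpy(), X,
        prior_sd=5.0, names=["d_bis", "d_hrv", "d_bis:d_hrv"], seed=seeds["regression"],
    )

    change.to_csv(out_dir / "change_table.csv", index=False)
    strengths.to_csv(out_dir / "second_strengths.csv")
    (out_dir / "second_network.json").write_text(dag.to_json())
    (out_dir / "second_network.dot").write_text(
        dag.to_dot({a: f"{strengths.strength_of(*a):.2f}" for a in dag.arcs})
    )
    grid.to_csv(out_dir / "injury_grid.csv", index=False)
    full_grid.to_csv(out_dir / "injured_blanket_table.csv", index=False)
    posterior.frame.to_csv(out_dir / "fffs_regression.csv", index=False)
    log = {
        "analysis": "second_network",
        "seed": config.seed,
        "child_seeds": seeds,
        "n_bootstrap": config.n_bootstrap,
        "inclusion": config.inclusion,
        "significance": config.significance,
        "blacklist": sorted(map(list, constraints.blacklist)),
        "whitelist": sorted(map(list, constraints.whitelist)),
        "markov_blanket_injured": mb,
        "arc_labels": {f"{u}->{v}": lab for (u, v), lab in labels.items()},
        "n_rows": int(len(learn)),
    }
    (out_dir / "second_run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "cohort": cohort,
        "change": change,
        "strengths": strengths,
        "dag": dag,
        "labels": labels,
        "net": net,
        "blanket": mb,
        "grid": grid,
        "full_grid": full_grid,
        "posterior": posterior,
        "log": log,
    }


def render_report(out_dir: str | Path) -> str:
    """Plain-markdown summary of a completed artifact directory."""
    out_dir = Path(out_dir)
    lines = ["# Analysis report", ""]
    for name, title in (
        ("first_run_log.json", "First network (two-time-slice)"),
        ("second_run_log.json", "Second network (change scores)"),
    ):
        p = out_dir / name
        if not p.exists():
            continue
        log = json.loads(p.read_text())
        lines += [f"## {title}", "",
                  f"- rows: {log['n_rows']}, bootstraps: {log['n_bootstrap']}, "
                  f"thresholds: {log['inclusion']}/{log['significance']}, seed: {log['seed']}"]
        if "markov_blankets" in log:
            for t, mb in log["markov_blankets"].items():
                lines.append(f"- Markov blanket of `{t}`: {', '.join(mb) or '(empty)'}")
        if "markov_blanket_injured" in log:
            lines.append(f"- Markov blanket of `injured`: {', '.join(log['markov_blanket_injured']) or '(empty)'}")
        sig = [a for a, lab in log["arc_labels"].items() if lab == "significant"]
        lines.append(f"- significant arcs ({len(sig)}): {', '.join(sorted(sig))}")
        lines.append("")
    for csv_name, title in (
        ("first_strengths.csv", "First-network arc strengths"),
        ("second_strengths.csv", "Second-network arc strengths"),
        ("injury_grid.csv", "Injury probability grid"),
        ("fffs_regression.csv", "Regression summary"),
    ):
        p = out_dir / csv_name
        if not p.exists():
            continue
        df = pd.read_csv(p)
        lines += [f"## {title}", "", "```", df.to_string(index=False), "```", ""]
    return "\n".join(lines)
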