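"""Replication engine: rerun the simulation study at configurable scale.

For each replication a (training, validation) pair is simulated, every
configured method selects interactions on the standardized training set,
selections are scored against the truth, and the signature strength (Delta C)
is computed on both sets.  Aggregation yields one summary row per
method x scenario with Monte-Carlo standard errors.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import delta_c, selection_metrics
from .selection_methods import METHOD_REGISTRY, run_method
from .simulator import make_scenario, simulate_pair
from .trial_data import standardize

log = logging.getLogger("predmod")

__all__ = ["ExperimentConfig", "run_experiment", "run_replication",
           "summarize", "summarize_to_csv", "plot_fdr_fnr", "plot_delta_c"]


@dataclass
class ExperimentConfig:
    scenarios: list
    methods: list = field(default_factory=lambda: ["univariate", "full_lasso"])
    replications: int = 50
    seed: int = 0
    n_workers: int = 1
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("need at least one replication")
        unknown = set(self.methods) - set(METHOD_REGISTRY)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _child_seed(root_seed, scenario_index, rep):
    """Deterministic per-replication seed, independent of execution order."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(scenario_index, rep))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def run_replication(scenario_name, methods, seed, overrides=None):
    """One replication: simulate, select with each method, evaluate.

    Returns a list of per-method result dicts (rows of `replications.csv`).
    """
    spec = make_scenario(scenario_name, seed=seed, **(overrides or {}))
    rng = np.random.default_rng(seed)
    train, valid = simulate_pair(spec, rng)
    train_std, scaler = standardize(train)
    valid_std, _ = standardize(valid, scaler=scaler)
    rows = []
    for method in methods:
        t0 = _time.perf_counter()
        row = {"scenario": scenario_name, "method": method, "seed": seed,
               "failed": False}
        try:
            sel = run_method(method, train_std, seed=seed)
            m = selection_metrics(sel, train.truth)
            dc_tr = delta_c(sel, train_std, which="training")
            dc_va = delta_c(sel, valid_std, which="validation")
            row.update(TP=m.TP, FP=m.FP, pFP=m.pFP, FN=m.FN, FDR=m.FDR,
                       FNR=m.FNR, AUPRC=m.AUPRC, rejected=m.rejected,
                       n_selected=m.n_selected,
                       delta_c_train=dc_tr.delta_c,
                       delta_c_valid=dc_va.delta_c)
        except Exception as exc:            # recorded, excluded from means
            log.warning("method %s failed on %s (seed %d): %s",
                        method, scenario_name, seed, exc)
            row["failed"] = True
            row["error"] = str(exc)
        row["runtime_s"] = _time.perf_counter() - t0
        rows.append(row)
    return rows


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run all scenario x replication cells; returns the per-replication table.

    Results are deterministic given the root seed and independent of the
    worker count (each replication derives its own child seed).
    """
    tasks = [(s_i, name, rep)
             for s_i, name in enumerate(config.scenarios)
             for rep in range(config.replications)]

    def one(task):
        s_i, name, rep = task
        seed = _child_seed(config.seed, s_i, rep)
        return run_replication(name, config.methods, seed,
                               config.scenario_overrides.get(name))

    if config.n_workers > 1:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=config.n_workers)(
            delayed(one)(t) for t in tasks)
    else:
        chunks = [one(t) for t in tasks]
    rows = [r for chunk in chunks for r in chunk]
    return pd.DataFrame(rows)


_AGG_COLS = ["rejected", "n_selected", "TP", "FP", "pFP", "FDR", "FNR",
             "AUPRC", "delta_c_train", "delta_c_valid"]


def summarize(replications: pd.DataFrame) -> pd.DataFrame:
    """Per method x scenario means with Monte-Carlo standard errors."""
    out = []
    for (scen, meth), cell in replications.groupby(["scenario", "method"],
                                                   sort=True):
        g = cell[~cell["failed"]]
        row = {"scenario": scen, "method": meth, "n_replications": len(g),
               "n_failed": int(cell["failed"].sum())}
        for col in _AGG_COLS:
            vals = (pd.to_numeric(g[col], errors="coerce").dropna()
                    if col in g.columns else pd.Series(dtype=float))
            if len(vals):
                row[col] = float(vals.mean())
                row[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))
                                         if len(vals) > 1 else 0.0)
            else:
                row[col] = np.nan
                row[f"{col}_se"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def summarize_to_csv(table: pd.DataFrame, path):
    if table.empty:
        raise ValueError("empty summary table")
    table.to_csv(path, index=False)


def plot_fdr_fnr(table: pd.DataFrame, path=None):
    """FNR against FDR, one point per method, one panel per scenario."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    scens = sorted(table["scenario"].unique())
    fig, axes = plt.subplots(1, len(scens), figsize=(4 * len(scens), 4),
                             squeeze=False)
    for ax, scen in zip(axes[0], scens):
        sub = table[table["scenario"] == scen]
        ax.scatter(sub["FDR"], sub["FNR"])
        for _, r in sub.iterrows():
            ax.annotate(r["method"], (r["FDR"], r["FNR"]), fontsize=7)
        ax.set(xlim=(-0.02, 1.02), ylim=(-0.02, 1.02), xlabel="FDR",
               ylabel="FNR", title=scen)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_delta_c(table: pd.DataFrame, path=None):
    """Paired training/validation Delta C per method and scenario."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    scens = sorted(table["scenario"].unique())
    fig, axes = plt.subplots(1, len(scens), figsize=(4 * len(scens), 4),
                             squeeze=False)
    for ax, scen in zip(axes[0], scens):
        sub = table[table["scenario"] == scen].reset_index(drop=True)
        x = np.arange(len(sub))
        ax.vlines(x, sub["delta_c_valid"], sub["delta_c_train"], color="0.6")
        ax.plot(x, sub["delta_c_train"], "o", label="training")
        ax.plot(x, sub["delta_c_valid"], "s", label="validation")
        ax.set_xticks(x, sub["method"], rotation=60, fontsize=7)
        ax.set(ylabel=r"$\Delta$C", title=scen)
        ax.axhline(0, color="k", lw=0.5)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
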