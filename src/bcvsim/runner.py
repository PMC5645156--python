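"""Execute a RunConfig: dispatch to a driver, write CSV + manifest + log."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .engine import EngineConfig
from .experiments import GridSpec, run_binary_scan, run_compromise, \
    run_decoy_grid, run_trinary_scan
from .hierarchy import ContextScenario, HierarchicalContextModel, \
    hierarchical_factors, hierarchical_value, magnitude_scenario, \
    scenario_predictions, two_level_scenario, variance_scenario

__all__ = ["run_and_write", "run_experiment"]

log = logging.getLogger("bcvsim")

_SCENARIOS = {"magnitude": magnitude_scenario, "variance": variance_scenario,
              "two-level": two_level_scenario}


def _as_list(x):
    return list(x) if isinstance(x, (list, tuple)) else [x]


def _engine_config(config: RunConfig) -> EngineConfig | None:
    if config.mode == "exact":
        return None
    return EngineConfig(n_trials=config.n_trials, seed=config.seed)


def run_experiment(config: RunConfig) -> pd.DataFrame:
    """Run the configured experiment and return its tidy results table."""
    o = config.options
    ec = _engine_config(config)
    if config.experiment == "binary-scan":
        return run_binary_scan(
            R_H=o["R_H"], R_L=o["R_L"],
            mu_grid=GridSpec.linspace("mu_C", o["mu_min"], o["mu_max"], o["mu_step"]),
            reward_vars=_as_list(o["sigma_R2"]), sigma_C2=o["sigma_C2"],
            beta=o["beta"], config=ec)
    if config.experiment == "trinary-scan":
        frames = [run_trinary_scan(
            R_H=o["R_H"], R_L=o["R_L"],
            r3_grid=GridSpec.linspace("R_3", o["r3_min"], o["r3_max"], o["r3_step"]),
            mu_grid=GridSpec("mu_C", sorted(_as_list(o["mu_C"]))),
            reward_var=sr2, sigma_C2=o["sigma_C2"], beta=o["beta"], config=ec)
            for sr2 in _as_list(o["sigma_R2"])]
        return pd.concat(frames, ignore_index=True)
    if config.experiment == "decoy-grid":
        k_grid = lambda name: GridSpec.linspace(name, o["k_min"], o["k_max"], o["k_step"])
        frames = [run_decoy_grid(
            A=o["A"], B=o["B"], k_p_grid=k_grid("R_p_K"), k_q_grid=k_grid("R_q_K"),
            mu_C=mu, reward_var=sr2, sigma_C2=o["sigma_C2"], beta=o["beta"], config=ec)
            for mu in _as_list(o["mu_C"]) for sr2 in _as_list(o["sigma_R2"])]
        return pd.concat(frames, ignore_index=True)
    if config.experiment == "compromise":
        return run_compromise(
            d_grid=GridSpec.linspace("d", o["d_min"], o["d_max"], o["d_step"]),
            reward_vars=_as_list(o["sigma_R2"]), mu_values=_as_list(o["mu_C"]),
            include_binary=bool(o["include_binary"]),
            sigma_C2=o["sigma_C2"], beta=o["beta"], config=ec)
    if config.experiment == "hierarchy":
        model = HierarchicalContextModel(o["var_HC"], o["var_HO"], o["var_LC"],
                                         o["var_LO"], o["var_R"])
        factors = hierarchical_factors(model)
        grid = GridSpec.linspace("R", o["r_min"], o["r_max"], o["r_step"])
        rows = [dict(R=r, HO=o["HO"], LO=o["LO"],
                     value=hierarchical_value(o["HO"], o["LO"], r, model),
                     tau_LO=factors.tau_lo, tau_HO=factors.tau_ho, K=factors.k)
                for r in grid.values]
        return pd.DataFrame(rows)
    if config.experiment == "scenario":
        name = o["name"]
        if name in _SCENARIOS:
            scenario = _SCENARIOS[name](base=o["base"])
        else:
            raise ValueError(
                f"unknown scenario '{name}'; choose from {sorted(_SCENARIOS)}")
        return scenario_predictions(scenario, prior_var=o["prior_var"],
                                    obs_var=o["obs_var"],
                                    reward_var_floor=o["reward_var_floor"])
    raise ValueError(f"unknown experiment '{config.experiment}'")


def _quicklook(df: pd.DataFrame, config: RunConfig, out: Path) -> Path | None:
    """Optional quick-look plot; requires matplotlib (the 'plot' extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    exp = config.experiment
    if exp == "binary-scan":
        for sr2, sub in df.groupby("sigma_R2"):
            ax.plot(sub["mu_C"], sub["value"], label=f"$\\sigma_R^2$={sr2}")
        ax.set_xlabel("prior mean"); ax.set_ylabel("P[H]/P[L]"); ax.legend()
    elif exp == "trinary-scan":
        for (mu, sr2), sub in df.groupby(["mu_C", "sigma_R2"]):
            ax.plot(sub["R_3"], sub["value"], label=f"mu={mu}, $\\sigma_R^2$={sr2}")
        ax.set_xlabel("R_3"); ax.set_ylabel("P[H]/P[L]"); ax.legend(fontsize=6)
    elif exp == "decoy-grid":
        sub = df[(df.mu_C == df.mu_C.iloc[0]) & (df.sigma_R2 == df.sigma_R2.iloc[0])]
        pivot = sub.pivot(index="R_p_K", columns="R_q_K", values="value")
        im = ax.imshow(pivot.values, origin="lower", cmap="RdBu_r",
                       extent=[pivot.columns.min(), pivot.columns.max(),
                               pivot.index.min(), pivot.index.max()])
        fig.colorbar(im, ax=ax, label="P[A]-P[B]")
        ax.set_xlabel("R_q_K"); ax.set_ylabel("R_p_K")
    elif exp == "compromise":
        sub = df[df.metric == "trinary_difference"]
        for (mu, sr2), g in sub.groupby(["mu_C", "sigma_R2"]):
            ax.plot(g["d"], g["value"], label=f"mu={mu}, $\\sigma_R^2$={sr2}")
        ax.set_xlabel("d"); ax.set_ylabel("P[K]-P[A]"); ax.legend(fontsize=6)
    elif exp == "hierarchy":
        ax.plot(df["R"], df["value"])
        ax.set_xlabel("R"); ax.set_ylabel("incentive value")
    else:  # scenario
        labels = df["context"] + df["hl_context"].fillna("").radd("/").str.rstrip("/")
        ax.bar(range(len(df)), df["value"])
        ax.set_xticks(range(len(df)))
        ax.set_xticklabels(labels + " " + df["reward"].round(2).astype(str),
                           rotation=90, fontsize=6)
        ax.set_ylabel("incentive value")
    fig.tight_layout()
    path = out / "quicklook.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def run_and_write(config: RunConfig) -> dict[str, Path]:
    """Run the experiment and write results.csv, manifest.json and run.log.

    The manifest records the full resolved configuration, the seed and the
    package version, which is sufficient to reproduce the CSV bitwise
    (enumeration is deterministic; MC is deterministic given the seed).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        log.info("starting experiment %s (mode=%s, seed=%d)",
                 config.experiment, config.mode, config.seed)
        df = run_experiment(config)
        csv_path = out / "results.csv"
        df.to_csv(csv_path, index=False)
        paths = {"results": csv_path, "log": log_path}
        if config.plot:
            png = _quicklook(df, config, out)
            if png is not None:
                paths["plot"] = png
        manifest = dict(config=config.to_dict(), version=__version__,
                        n_rows=int(len(df)),
                        wall_time_s=round(time.perf_counter() - t0, 3))
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = manifest_path
        log.info("wrote %d rows to %s", len(df), csv_path)
        return paths
    except Exception:
        log.exception("experiment %s failed", config.experiment)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
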