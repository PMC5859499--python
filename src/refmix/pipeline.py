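"""Orchestration of the two-phase reference-sample workflow.

``run_pipeline`` composes the library stages — simulate (or load), collapse,
in-silico prediction, design search, ΔCq summaries, variance decomposition,
Bayesian bias assessment — and writes every table as CSV, a machine-readable
summary as JSON, and Bland-Altman / likelihood-curve / variance plots.
Every artifact is stamped with the configuration hash and seed, and all
randomness flows from the configured seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from refmix import anova as anova_mod
from refmix import bayes as bayes_mod
from refmix import dcq as dcq_mod
from refmix import design_search as ds_mod
from refmix.data_model import collapse_wells, read_cq_table, write_cq_table
from refmix.mixture import bland_altman, mean_profile, predict_pair_profiles
from refmix.simulate import (
    CONTROL_ANALYTE,
    SimulationConfig,
    TARGET_ANALYTES,
    simulate_mixture_phase,
    simulate_profiling_phase,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str = "refmix-out"
    seed: int = 0
    profiling_csv: str | None = None   # None: simulate
    mixture_csv: str | None = None     # None: simulate
    dialect: str | None = None
    max_abs_dcq: float = 1.0
    ratio_values: tuple[float, ...] = (1.0, 3.0)
    bayes_analytes: tuple[str, ...] = ("MIR-21",)
    bayes_variants: tuple[int, ...] = (1, 2, 3)
    n_chains: int = 2
    n_iter: int = 1500
    burn_in: int = 500
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def config_hash(self) -> str:
        def convert(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return convert(dataclasses.asdict(o))
            if isinstance(o, dict):
                return {str(k): convert(v) for k, v in o.items()}
            if isinstance(o, (list, tuple, set)):
                return [convert(v) for v in o]
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)

        blob = json.dumps(convert(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(path: Path, config: RunConfig) -> None:
    (path / "run_stamp.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed}, indent=2)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _stamp(out, config)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)

    # --- profiling data -------------------------------------------------
    stage("profile")
    try:
        if config.profiling_csv:
            prof_wells = read_cq_table(config.profiling_csv, dialect=config.dialect)
        else:
            prof_wells = simulate_profiling_phase(config.simulation, seed=config.seed)
        profiles = collapse_wells(prof_wells.drop(columns="at_ceiling", errors="ignore"))
        write_cq_table(profiles, out / "profiles.csv")
        summary["stages"]["profile"] = {"n_wells": len(prof_wells), "n_profiles": len(profiles)}
    except Exception as exc:
        raise RuntimeError(f"stage 'profile' failed: {exc}") from exc

    # --- design search ---------------------------------------------------
    stage("design")
    try:
        targets = [a for a in profiles["analyte"].unique() if a != CONTROL_ANALYTE]
        grid = ds_mod.ratio_grid(3, config.ratio_values)
        components = sorted(profiles["sample"].unique())
        pairs = ds_mod.enumerate_designs(components, grid)
        cands = [
            ds_mod.score_design_pair(
                ds_mod.DesignCandidate(pair=p), profiles,
                max_abs_dcq=config.max_abs_dcq, target_analytes=targets,
            )
            for p in pairs
        ]
        ranked = ds_mod.rank_designs(cands)
        ds_mod.candidates_to_frame(ranked).to_csv(out / "designs.csv", index=False)
        summary["stages"]["design"] = {
            "n_candidates": len(cands),
            "n_feasible": len(ranked),
            "best": ds_mod.candidates_to_frame(ranked[:1]).to_dict("records"),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'design' failed: {exc}") from exc

    # --- in-silico prediction -------------------------------------------
    stage("predict")
    try:
        designs = list(config.simulation.designs)
        preds = predict_pair_profiles(profiles, designs)
        write_cq_table(preds.drop(columns="at_ceiling"), out / "predictions.csv")
        prof1 = mean_profile(preds, designs[0].name)
        prof2 = mean_profile(preds, designs[1].name)
        ba = bland_altman(
            {a: v for a, v in prof1.items() if a != CONTROL_ANALYTE},
            {a: v for a, v in prof2.items() if a != CONTROL_ANALYTE},
        )
        ba.to_csv(out / "bland_altman.csv", index=False)
        _plot_bland_altman(ba, out / "bland_altman.png")
        summary["stages"]["predict"] = {"n_predictions": len(preds)}
    except Exception as exc:
        raise RuntimeError(f"stage 'predict' failed: {exc}") from exc

    # --- mixture measurements and ΔCq ------------------------------------
    stage("deltacq")
    try:
        if config.mixture_csv:
            mix_wells = read_cq_table(config.mixture_csv, dialect=config.dialect)
        else:
            mix_wells = simulate_mixture_phase(
                config.simulation, "rna_mixture", seed=config.seed + 1
            )
        mixtures = collapse_wells(mix_wells.drop(columns="at_ceiling", errors="ignore"))
        write_cq_table(mixtures, out / "mixtures.csv")
        dcq = dcq_mod.delta_cq(mixtures)
        summ = dcq_mod.summarize_dcq(dcq, grouping="by_isolation")
        dcq.to_csv(out / "dcq.csv", index=False)
        summ.to_csv(out / "dcq_summary.csv", index=False)
        summary["stages"]["deltacq"] = {
            "n_pairs": len(dcq),
            "mean_dcq_by_analyte": dcq.groupby("analyte")["dcq"].mean().round(4).to_dict(),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'deltacq' failed: {exc}") from exc

    # --- variance decomposition ------------------------------------------
    stage("anova")
    try:
        table = anova_mod.factorial_anova(
            profiles,
            ["analyte", "sample", "isolation_lab", "isolation_rep", "pcr_lab"],
            response="cq",
        )
        table.to_csv(out / "anova.csv", index=False)
        _plot_variance(anova_mod.filter_report(table, 1e-6), out / "anova.png")
        summary["stages"]["anova"] = {
            "top_terms": table.head(3)["term"].tolist(),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'anova' failed: {exc}") from exc

    # --- Bayesian bias assessment ----------------------------------------
    stage("bayes")
    try:
        bayes_out = {}
        curve_rows = []
        for analyte in config.bayes_analytes:
            weights = bayes_mod.contrast_weights(
                bayes_mod.dcq_weights("RNA_MIXTURE", "BRL", "BDL"),
                bayes_mod.dcq_weights("RNA_MIXTURE", "BRL", "BRL"),
            )
            res = bayes_mod.run_variants(
                mixtures, analyte, weights,
                variants=config.bayes_variants, seed=config.seed,
                label=f"{analyte} PCR-lab effect on avg dCq",
                n_chains=config.n_chains, n_iter=config.n_iter, burn_in=config.burn_in,
            )
            bayes_out[analyte] = {"peaks": res["peaks"], "peak_spread": res["peak_spread"]}
            for v, c in res["curves"].items():
                for g, l in zip(c.grid, c.likelihood):
                    curve_rows.append(
                        {"analyte": analyte, "variant": v, "grid": g, "likelihood": l}
                    )
            _plot_curves(res["curves"], out / f"curves_{analyte}.png")
        pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
        (out / "bayes_report.json").write_text(json.dumps(bayes_out, indent=2))
        summary["stages"]["bayes"] = bayes_out
    except Exception as exc:
        raise RuntimeError(f"stage 'bayes' failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _plot_bland_altman(ba: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["mean_cq"], ba["delta_cq"])
    for _, r in ba.iterrows():
        ax.annotate(r["analyte"], (r["mean_cq"], r["delta_cq"]), fontsize=7)
    ax.axhline(0.0, color="grey", lw=0.5)
    # reversed axes: left/up = more abundant
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("mean Cq (Mix1, Mix2)")
    ax.set_ylabel("ΔCq = Mix1 − Mix2")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_variance(table: pd.DataFrame, path: Path) -> None:
    terms = table[table["term"] != "residual"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(terms["term"], terms["ms"])
    ax.set_yscale("log")
    ax.set_ylabel("mean square (Cq²)")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_curves(curves: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {1: "black", 2: "red", 3: "blue"}
    for v, c in curves.items():
        ax.plot(c.grid, c.likelihood, color=colors.get(v, None), label=f"variant {v}")
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("parameter of interest (Cq)")
    ax.set_ylabel("marginal likelihood (max = 1)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
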