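"""End-to-end pipeline: simulate -> validate -> centre -> design -> fit -> report.

``run_pipeline`` executes every stage for each testing domain, writes the
coefficient tables, predicted margins, diagnostics sidecars and trend
plots under one output directory, and finishes with a manifest listing a
SHA-256 content hash for every file produced. A master seed
deterministically derives the simulation seed and one MCMC seed per
domain (via ``numpy.random.SeedSequence`` spawning), so identical config
plus seed reproduces identical artifacts. The numbered scripts under
``analysis/`` are thin drivers over this module.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .design import build_design
from .model import McmcConfig, PriorSpec, fit_model, predicted_margins, summarize
from .preprocess import center_scores, validate_tables

GROUP_ORDER = ("no_low", "moderate", "high")


@dataclass
class RunConfig:
    """One pipeline run: either simulate inputs or point at CSVs on disk."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    domains: tuple = tuple(sim.DOMAINS)
    event_year: int = 2014
    simulation: sim.SimulationConfig | None = None
    observations_path: str | None = None
    profiles_path: str | None = None
    reference_path: str | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    make_plots: bool = True

    def validate(self) -> None:
        if not self.domains:
            raise ValueError("domain list must be non-empty")
        external = (self.observations_path, self.profiles_path, self.reference_path)
        if self.simulation is None and not all(external):
            raise ValueError(
                "either a simulation config or all three input table paths "
                "(observations, profiles, reference) must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "mcmc" in raw:
            raw["mcmc"] = McmcConfig(**raw["mcmc"])
        if "priors" in raw:
            raw["priors"] = PriorSpec(**raw["priors"])
        if "simulation" in raw:
            simc = raw["simulation"]
            if "truth" in simc:
                simc["truth"] = sim.SimulationTruth(**simc["truth"])
            raw["simulation"] = sim.SimulationConfig(**simc)
        if "domains" in raw:
            raw["domains"] = tuple(raw["domains"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seeds(master: int, n_domains: int) -> dict:
    """Per-stage integer seeds spawned deterministically from the master."""
    children = np.random.SeedSequence(master).spawn(1 + n_domains)
    ints = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return {"simulate": ints[0], "fit": ints[1:]}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed, len(config.domains))
    written: list[Path] = []

    if config.simulation is not None:
        sim_config = sim.SimulationConfig(
            **{**vars(config.simulation), "seed": seeds["simulate"]}
        )
        observations, profiles, reference, truth = sim.generate_study(sim_config)
        paths = sim.write_study(out / "study", observations, profiles, reference, truth)
        written.extend(Path(p) for p in paths.values())
    else:
        observations = pd.read_csv(config.observations_path)
        profiles = pd.read_csv(config.profiles_path)
        reference = pd.read_csv(config.reference_path)

    report = validate_tables(observations, profiles, drop=True)
    (out / "validation.json").write_text(json.dumps(report.counts, indent=2))
    written.append(out / "validation.json")
    observations = report.observations

    centred = center_scores(observations, reference)
    centred.to_csv(out / "centred.csv", index=False)
    written.append(out / "centred.csv")

    years = sorted(centred["year"].unique())
    for domain, fit_seed in zip(config.domains, seeds["fit"]):
        design = build_design(centred, profiles, domain, config.event_year)
        mcmc = McmcConfig(
            chains=config.mcmc.chains,
            iterations=config.mcmc.iterations,
            warmup=config.mcmc.warmup,
            seed=fit_seed,
        )
        fit = fit_model(design, config.priors, mcmc)
        table = summarize(fit)
        margins = predicted_margins(fit, years)

        table.to_csv(out / f"coefficients_{domain}.csv")
        margins.to_csv(out / f"margins_{domain}.csv", index=False)
        (out / f"diagnostics_{domain}.json").write_text(
            json.dumps(
                {
                    "domain": domain,
                    "seed": fit_seed,
                    "design_hash": fit.design_hash,
                    "max_rhat": fit.diagnostics.get("max_rhat"),
                    "min_ess": fit.diagnostics.get("min_ess"),
                    "divergences": fit.diagnostics.get("divergences"),
                    "warnings": fit.diagnostics.get("warnings"),
                },
                indent=2,
            )
        )
        written.extend(
            [out / f"coefficients_{domain}.csv", out / f"margins_{domain}.csv",
             out / f"diagnostics_{domain}.json"]
        )
        if config.make_plots:
            fig_path = out / f"trends_{domain}.png"
            plot_trends(margins, config.event_year, domain, fig_path)
            written.append(fig_path)

    manifest = {
        "seed": config.seed,
        "derived_seeds": seeds,
        "domains": list(config.domains),
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def plot_trends(
    margins: pd.DataFrame, event_year: int, domain: str, path: str | Path
) -> None:
    """Line plot of predicted centred scores per exposure group with 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [g for g in GROUP_ORDER if g in set(margins["exposure_group"])]
    missing = set(margins["exposure_group"]) - set(GROUP_ORDER)
    if missing:
        raise ValueError(f"unknown exposure group(s) in margins: {sorted(missing)}")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for group in groups:
        sub = margins.loc[margins["exposure_group"] == group].sort_values("year")
        err = np.vstack([sub["mean"] - sub["ci_2.5"], sub["ci_97.5"] - sub["mean"]])
        ax.errorbar(sub["year"], sub["mean"], yerr=err, marker="o",
                    capsize=3, label=group.replace("_", "/"))
    ax.axvline(event_year - 0.5, color="grey", linestyle="--", linewidth=1)
    ax.axhline(0.0, color="black", linewidth=0.5)
    ax.set_xlabel("year")
    ax.set_ylabel("predicted centred score")
    ax.set_title(f"Predicted centred scores — {domain}")
    ax.legend(title="exposure")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pre_post_boxes(
    centred: pd.DataFrame, profiles: pd.DataFrame, event_year: int, path: str | Path
) -> None:
    """Convenience descriptive plot: centred scores pre vs post event by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = profiles[["school_id", "exposure_group"]].drop_duplicates("school_id")
    merged = centred.merge(groups, on="school_id")
    merged["period"] = np.where(merged["year"] < event_year, "pre", "post")
    fig, axes = plt.subplots(1, len(GROUP_ORDER), figsize=(10, 4), sharey=True)
    for ax, group in zip(np.atleast_1d(axes), GROUP_ORDER):
        sub = merged.loc[merged["exposure_group"] == group]
        data = [sub.loc[sub["period"] == p, "mean"] for p in ("pre", "post")]
        ax.boxplot(data, tick_labels=["pre", "post"])
        ax.set_title(group.replace("_", "/"))
        ax.axhline(0.0, color="black", linewidth=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
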