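"""End-to-end orchestration: simulate/load -> profile -> randomize ->
reconstruct -> degeneracy -> transitions, with seeds, per-stage timing and a
JSON run manifest that allows exact regeneration."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from carocontrol import __version__
from carocontrol.ancestral import assemble_ancestral_networks
from carocontrol.controllability import classify_category, control_profile
from carocontrol.core_model import (
    CarotenoidNetwork,
    Phylogeny,
    networks_to_character_matrix,
    read_network,
    write_network,
)
from carocontrol.degeneracy import compound_redundancy, gain_loss_regression, occupancy_rates, pathway_length
from carocontrol.macroevolution import category_history, ctmc_fit, trajectory_binning
from carocontrol.randomization import randomize_and_compare
from carocontrol.synthetic_data import SyntheticConfig, simulate_dataset
from carocontrol.trees import _as_arrays

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "profile", "randomize", "reconstruct", "degeneracy", "transitions")
_KNOWN_KEYS = {"seed", "output_dir", "inputs", *_STAGES}


@dataclass
class RunConfig:
    """Validated pipeline configuration (one YAML file, per-stage sections)."""

    seed: int = 0
    output_dir: str = "carocontrol_out"
    inputs: dict[str, Any] = field(default_factory=dict)
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = {}
        for name in _STAGES:
            section = dict(raw.get(name, {}) or {})
            section.setdefault("enabled", name != "randomize" or True)
            stages[name] = section
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "carocontrol_out")),
            inputs=dict(raw.get("inputs", {}) or {}),
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def stage(self, name: str) -> dict[str, Any]:
        return self.stages.get(name, {"enabled": True})


def _profile_row(label: str, network: CarotenoidNetwork) -> dict[str, Any]:
    oriented = network if network.is_oriented else network.oriented()
    prof = control_profile(oriented)
    return {
        "label": label,
        "N": prof.N,
        "r": network.n_reactions,
        "Nc": prof.Nc,
        "Ns": prof.Ns,
        "Ni": prof.Ni,
        "Ne": prof.Ne,
        "eta_s": prof.eta_s,
        "eta_i": prof.eta_i,
        "eta_e": prof.eta_e,
        "category": classify_category(prof, oriented),
        "pathway_length": pathway_length(network),
    }


def run_pipeline(config: "RunConfig | Mapping[str, Any] | str | Path") -> dict[str, Any]:
    """Execute the configured stages in dependency order; returns the run
    manifest (also written to <output_dir>/manifest.json).

    On stage failure a FAILED marker naming the stage is written next to any
    partial outputs and the exception propagates.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    current = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        sim_cfg = config.stage("simulate")
        if sim_cfg.get("enabled", True) and not config.inputs:
            current = "simulate"
            t0 = time.perf_counter()
            params = {k: v for k, v in sim_cfg.items() if k != "enabled"}
            params.setdefault("seed", config.seed)
            scfg = SyntheticConfig(**params)
            ds = simulate_dataset(scfg)
            master, phylo = ds.master, ds.phylogeny
            tip_networks, matrix = ds.tip_networks, ds.matrix
            (out / "networks").mkdir(exist_ok=True)
            write_network(master, out / "networks" / "master.nodes.tsv",
                          out / "networks" / "master.edges.tsv")
            (out / "tree.nwk").write_text(phylo.to_newick() + "\n")
            matrix.to_csv(out / "characters.csv")
            ds.truth.states.to_csv(out / "truth_states.csv")
            ds.truth.events.to_csv(out / "truth_events.csv", index=False)
            manifest["stages"]["simulate"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "config": scfg.manifest(),
            }
        else:
            current = "load-inputs"
            master = read_network(
                config.inputs["master_nodes"], config.inputs["master_edges"],
                label="master",
            )
            phylo = Phylogeny.from_newick(config.inputs["tree"])
            tip_networks = {}
            for label, paths in config.inputs["species"].items():
                tip_networks[label] = read_network(
                    paths["nodes"], paths["edges"], label=label
                )
            matrix = networks_to_character_matrix(list(tip_networks.values()), master)

        arrays = _as_arrays(phylo)

        # ---- profile ----------------------------------------------------
        if config.stage("profile").get("enabled", True):
            current = "profile"
            t0 = time.perf_counter()
            rows = [_profile_row(lab, net) for lab, net in sorted(tip_networks.items())]
            pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)
            manifest["stages"]["profile"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_networks": len(rows),
            }

        # ---- randomize --------------------------------------------------
        rand_cfg = config.stage("randomize")
        if rand_cfg.get("enabled", True):
            current = "randomize"
            t0 = time.perf_counter()
            k = int(rand_cfg.get("replicates", 10))
            rows = []
            for i, (lab, net) in enumerate(sorted(tip_networks.items())):
                report = randomize_and_compare(net, k=k, rng_seed=config.seed + i)
                for name, stats in report.summary().items():
                    rows.append({"label": lab, "statistic": name, **stats})
            pd.DataFrame(rows).to_csv(out / "randomization.csv", index=False)
            manifest["stages"]["randomize"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "replicates": k,
            }

        # ---- reconstruct ------------------------------------------------
        anc = None
        if config.stage("reconstruct").get("enabled", True):
            current = "reconstruct"
            t0 = time.perf_counter()
            anc = assemble_ancestral_networks(arrays, matrix, master)
            anc.fits_table().to_csv(out / "character_fits.csv")
            anc.states.to_csv(out / "ancestral_states.csv")
            manifest["stages"]["reconstruct"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_internal_nodes": len(anc.networks),
                "n_filtered_reactions": len(anc.filter_log),
            }

        # ---- degeneracy -------------------------------------------------
        if config.stage("degeneracy").get("enabled", True):
            current = "degeneracy"
            t0 = time.perf_counter()
            records = [
                compound_redundancy(master, c) for c in master.derived_ids
            ]
            deg_df = pd.DataFrame(
                {
                    "compound": r.compound,
                    "n_paths": r.n_paths,
                    "mean_L": r.mean_L,
                    **{f"paths_from_{d}": n for d, n in r.per_dietary.items()},
                }
                for r in records
            )
            deg_df.to_csv(out / "degeneracy.csv", index=False)
            extras: dict[str, Any] = {}
            if anc is not None:
                occ, class_table = occupancy_rates(anc, arrays, master, matrix)
                class_table.to_csv(out / "occupancy_by_class.csv")
                responses = {
                    r.character[2:]: r.gain_rate - r.loss_rate
                    for r in occ
                    if not r.character.startswith("R:")
                    and master.compounds[r.character[2:]].role == "derived"
                }
                try:
                    reg = gain_loss_regression(responses, records)
                    extras["gain_loss_coefficients"] = reg.params.to_dict()
                    extras["gain_loss_r2"] = reg.r_squared
                except ValueError as exc:
                    extras["gain_loss_regression"] = f"skipped: {exc}"
            manifest["stages"]["degeneracy"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_compounds": len(records),
                **extras,
            }

        # ---- transitions ------------------------------------------------
        trans_cfg = config.stage("transitions")
        if trans_cfg.get("enabled", True) and anc is not None:
            current = "transitions"
            t0 = time.perf_counter()
            networks_all = dict(anc.networks)
            networks_all.update(tip_networks)
            history = category_history(networks_all, arrays)
            pd.Series(history.categories).rename("category").to_csv(
                out / "categories.csv", index_label="node"
            )
            history.event_table().to_csv(out / "category_events.csv", index=False)
            info: dict[str, Any] = {
                "n_category_changes": history.n_category_changes,
                "n_control_count_changes": history.n_control_count_changes,
            }
            tip_cats = {t: history.categories[t] for t in arrays.tip_labels}
            if len(set(tip_cats.values())) >= 2 and trans_cfg.get("mcmc", True):
                model = ctmc_fit(
                    arrays, tip_cats, seed=config.seed,
                    mcmc_iterations=int(trans_cfg.get("iterations", 40_000)),
                    mcmc_burnin=int(trans_cfg.get("burnin", 1_000)),
                    mcmc_thin=int(trans_cfg.get("thin", 20)),
                )
                model.rates.to_csv(out / "transition_rates.csv")
                info["ctmc_lnL"] = model.lnL
            traj = trajectory_binning(
                anc, arrays,
                bin_width=float(trans_cfg.get("bin_width", 10.0)),
                max_age=float(trans_cfg.get("max_age", 45.0)),
            )
            traj.bins.to_csv(out / "trajectory_bins.csv")
            traj.ternary_coordinates().to_csv(out / "ternary_coordinates.csv")
            info["cycle_amplitude"] = traj.cycle_amplitude.to_dict()
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"]["transitions"] = info
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current}: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", current, exc)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
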