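"""End-to-end pipeline orchestration: simulate -> filter -> networks ->
coupling -> train/evaluate, with seed management and a consolidated report.

A single global seed fans out to per-stage seeds by hashing the stage name,
so stages are independently reproducible. Every text artifact embeds the
configuration hash and seed; the report records a digest over all artifacts
so identical config + seed yields an identical digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from coevoscreen import coevolution_networks as nets
from coevoscreen import library_design as libdesign
from coevoscreen.coupling_analysis import compute_couplings
from coevoscreen.interaction_model import (
    ModelConfig,
    PhysicochemicalEmbedder,
    assemble_dataset,
    evaluate,
    train_model,
)
from coevoscreen.pair_enrichment import filter_pairs
from coevoscreen.screen_simulator import (
    SelectionConfig,
    build_landscape,
    simulate_screen,
    write_tables,
)

log = logging.getLogger("coevoscreen")

ALL_STAGES = ["simulate", "filter", "network", "coupling", "train"]


class ConfigError(ValueError):
    """A missing or invalid pipeline configuration key."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``default_config`` for the shape)."""

    raw: dict
    path: Path | None = None

    REQUIRED = [
        "seed",
        "output_dir",
        "design.preset",
        "simulator.n_rounds",
        "simulator.naive_diversity",
        "simulator.sequencing_depth",
        "enrichment.alpha",
        "enrichment.rounds",
        "network.edit_threshold",
        "coupling.alpha",
        "coupling.ridge",
    ]

    def __post_init__(self) -> None:
        for dotted in self.REQUIRED:
            node: Any = self.raw
            for part in dotted.split("."):
                if not isinstance(node, dict) or part not in node:
                    raise ConfigError(f"missing config key: {dotted}")
                node = node[part]
        if self.raw["design"]["preset"] not in ("LL1", "LL2") and not Path(
            str(self.raw["design"].get("file", ""))
        ).exists():
            raise ConfigError("design.preset must be LL1/LL2 or design.file must exist")

    def __getitem__(self, dotted: str) -> Any:
        node: Any = self.raw
        for part in dotted.split("."):
            node = node[part]
        return node

    def get(self, dotted: str, default: Any = None) -> Any:
        try:
            return self[dotted]
        except (KeyError, TypeError):
            return default

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        return cls(yaml.safe_load(path.read_text()), path)

    def sha(self) -> str:
        """Hash of all settings except the output location."""
        scrubbed = {k: v for k, v in self.raw.items() if k != "output_dir"}
        blob = json.dumps(scrubbed, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(output_dir: str, seed: int = 0) -> dict:
    """A small complete configuration (expanded-alphabet design, modest
    depth, test embedder) suitable for an end-to-end run in minutes."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "design": {"preset": "LL2"},
        "simulator": {
            "n_rounds": 4,
            "naive_diversity": 3000,
            "cells_per_round": 30000,
            "sequencing_depth": 10000,
            "m": 0.25,
            "p0": 6.0,
            "planted": [[2, 4, 2.0]],
            "h_sd": 0.5,
            "pkd0": 7.0,
            "scale": 1.0,
        },
        "enrichment": {"alpha": 0.05, "rounds": ["round3", "round4"]},
        "network": {"edit_threshold": 1, "min_shared": 1, "sample_n": 100},
        "coupling": {"weighting": "count", "alpha": "auto", "ridge": 1e-3,
                     "pseudocount": 0.0},
        "model": {
            "embed_dim": 32, "channels": [4, 8, 16], "epochs": 5,
            "batch_size": 64, "lr": 1e-3,
        },
        "stages": ALL_STAGES,
    }


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _provenance(config: PipelineConfig) -> str:
    return f"# config_sha={config.sha()}\n# seed={config['seed']}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", **kwargs)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> Path:
    """Execute the configured stages in order; return the report directory.

    Artifacts are written per stage as TSV/GraphML; a summary ``report.json``
    collects stage summaries, effective settings, and a digest over all
    artifact files. Stage failures abort with the stage name; partial
    artifacts are left in place.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.load(config)
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ALL_STAGES)
    report: dict[str, Any] = {
        "config_sha": config.sha(),
        "seed": config["seed"],
        "effective_config": config.raw,
        "stages": {},
    }

    preset = config["design.preset"]
    if preset == "LL1":
        design = libdesign.ll1_design()
    elif preset == "LL2":
        design = libdesign.ll2_design()
    else:
        design = libdesign.LibraryDesign.load(config["design.file"])
    design.save(outdir / "design.yaml")

    tables = None
    enriched = None
    current = "(setup)"
    try:
        if "simulate" in stages:
            current = "simulate"
            sim = config.raw["simulator"]
            planted = {(int(i), int(j)): float(m)
                       for i, j, m in sim.get("planted", [])}
            landscape = build_landscape(
                design, planted, seed=stage_seed(config["seed"], "landscape"),
                h_sd=float(sim.get("h_sd", 0.5)), pkd0=float(sim.get("pkd0", 7.0)),
                scale=float(sim.get("scale", 1.0)),
            )
            sel = SelectionConfig(
                n_rounds=int(sim["n_rounds"]),
                naive_diversity=int(sim["naive_diversity"]),
                cells_per_round=int(sim.get("cells_per_round", 50000)),
                sequencing_depth=int(sim["sequencing_depth"]),
                m=float(sim.get("m", 0.25)), p0=float(sim.get("p0", 6.0)),
                seed=stage_seed(config["seed"], "simulate"),
            )
            tables = simulate_screen(design, landscape, sel)
            write_tables(tables, outdir / "counts.tsv")
            report["stages"]["simulate"] = {
                "rounds": [t.round_label for t in tables],
                "n_pairs_naive": len(tables[0].df),
                "n_pairs_final": len(tables[-1].df),
                "depth": sel.sequencing_depth,
            }
            log.info("simulate: %d rounds, %d naive pairs -> %d final pairs",
                     sel.n_rounds, len(tables[0].df), len(tables[-1].df))

        if "filter" in stages:
            current = "filter"
            if tables is None:
                from coevoscreen.screen_simulator import read_tables
                tables = read_tables(outdir / "counts.tsv")
            enriched = filter_pairs(
                tables, [str(r) for r in config["enrichment.rounds"]],
                alpha=float(config["enrichment.alpha"]),
            )
            enriched.write_tsv(outdir / "enriched.tsv")
            report["stages"]["filter"] = {
                "rounds": enriched.rounds, "alpha": enriched.alpha,
                "n_tested": len(enriched.all_pairs),
                "n_enriched": len(enriched.df),
            }
            log.info("filter: %d pairs tested -> %d enriched at p<%g",
                     len(enriched.all_pairs), len(enriched.df), enriched.alpha)

        if "network" in stages and enriched is not None:
            current = "network"
            threshold = int(config["network.edit_threshold"])
            ssn = nets.build_ssn(enriched, threshold=threshold)
            cg = nets.cluster_graph(ssn)
            spsn = nets.build_spsn(enriched,
                                   min_shared=int(config.get("network.min_shared", 1)))
            for g, name in ((ssn, "ssn"), (cg, "cluster_graph"), (spsn, "spsn")):
                g.graph["config_sha"] = config.sha()
                g.graph["seed"] = config["seed"]
                nets.write_graphml(g, outdir / f"{name}.graphml")
                nets.write_edge_list(g, outdir / f"{name}_edges.tsv")
            sample_n = min(int(config.get("network.sample_n", 100)), len(enriched.df))
            profile, sample = nets.cross_reactivity_profile(
                enriched, sample_n=sample_n,
                seed=stage_seed(config["seed"], "network"),
            )
            _write_tsv(profile.df, outdir / "cross_reactivity.tsv", config, index=False)
            _write_tsv(nets.chord_table(sample), outdir / "chord.tsv", config,
                       index=False)
            comp_sizes = sorted((d["size"] for _, d in cg.nodes(data=True)),
                                reverse=True)
            report["stages"]["network"] = {
                "ssn_nodes": ssn.number_of_nodes(), "ssn_edges": ssn.number_of_edges(),
                "n_clusters": cg.number_of_nodes(),
                "largest_clusters": comp_sizes[:5],
                "spsn_edges": spsn.number_of_edges(),
            }
            log.info("network: %d nodes, %d edges, %d clusters",
                     ssn.number_of_nodes(), ssn.number_of_edges(),
                     cg.number_of_nodes())

        if "coupling" in stages and tables is not None:
            current = "coupling"
            source = tables[-1] if config.get("coupling.source", "final") == "final" \
                else enriched
            dca_alpha = config["coupling.alpha"]
            if dca_alpha != "auto":
                dca_alpha = float(dca_alpha)
            result = compute_couplings(
                source,
                weighting=str(config.get("coupling.weighting", "count")),
                alpha=dca_alpha,
                ridge=float(config["coupling.ridge"]),
                pseudocount=float(config.get("coupling.pseudocount", 0.0)),
            )
            _write_tsv(result.mi_inter_chain(), outdir / "mi.tsv", config)
            _write_tsv(result.scores, outdir / "dca_scores.tsv", config)
            _write_tsv(pd.DataFrame(result.s), outdir / "covariance.tsv", config,
                       index=False, header=False)
            _write_tsv(pd.DataFrame(result.theta), outdir / "theta.tsv", config,
                       index=False, header=False)
            _write_tsv(
                pd.DataFrame(result.index_map, columns=["position", "amino_acid"]),
                outdir / "index_map.tsv", config, index=False,
            )
            mi_ic = result.mi_inter_chain()
            top_mi = mi_ic.stack().idxmax()
            report["stages"]["coupling"] = {
                "top_mi_pair": list(top_mi),
                "top_dca_pair": list(result.scores.stack().idxmax()),
                "theta_l1": float(np.abs(result.theta).sum()),
            }
            log.info("coupling: top MI pair %s, top DCA pair %s",
                     top_mi, report["stages"]["coupling"]["top_dca_pair"])

        if "train" in stages and tables is not None and enriched is not None:
            current = "train"
            mdl = config.raw.get("model", {})
            enriched_round_tables = [
                t for t in tables if t.round_label in enriched.rounds
            ]
            present = set()
            for t in enriched_round_tables:
                present.update(zip(t.df["seq_a"], t.df["seq_b"]))
            n_eligible = sum(
                (a, b) not in present
                for a, b in zip(tables[0].df["seq_a"], tables[0].df["seq_b"])
            )
            dataset = assemble_dataset(
                tables[0], enriched, enriched_round_tables,
                seed=stage_seed(config["seed"], "dataset"),
                max_positives=min(
                    int(mdl.get("max_positives", n_eligible)), n_eligible
                ),
            )
            _write_tsv(dataset.df, outdir / "dataset.tsv", config, index=False)
            embedder = PhysicochemicalEmbedder(dim=int(mdl.get("embed_dim", 32)))
            mconfig = ModelConfig(
                channels=tuple(mdl.get("channels", (4, 8, 16))),
                epochs=int(mdl.get("epochs", 5)),
                batch_size=int(mdl.get("batch_size", 64)),
                lr=float(mdl.get("lr", 1e-3)),
                seed=stage_seed(config["seed"], "train"),
            )
            bundle = train_model(dataset, embedder, mconfig, design)
            _write_tsv(bundle.history, outdir / "training_history.tsv", config,
                       index=False)
            val = dataset.subset("val")
            rep = evaluate(bundle, val, embedder, design,
                           per_round_tables=tables)
            if rep.round_means is not None:
                _write_tsv(rep.round_means, outdir / "round_scores.tsv", config,
                           index=False)
            report["stages"]["train"] = {
                "n_train": int((dataset.df["split"] == "train").sum()),
                "n_val": int((dataset.df["split"] == "val").sum()),
                "best_epoch": bundle.best_epoch,
                "best_val_loss": float(bundle.history["val_loss"].min()),
                "val_auc": rep.auc,
                "val_ap": rep.ap,
            }
            log.info("train: best val loss %.4f (epoch %d), val AUC %s",
                     report["stages"]["train"]["best_val_loss"],
                     bundle.best_epoch, rep.auc)
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    report["digest"] = report_digest(outdir)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("report written to %s (digest %s)", outdir, report["digest"])
    return outdir


def report_digest(outdir: Path) -> str:
    """SHA-256 over all artifact files (sorted by name, report excluded)."""
    h = hashlib.sha256()
    for path in sorted(Path(outdir).rglob("*")):
        if path.is_file() and path.name != "report.json":
            h.update(path.relative_to(outdir).as_posix().encode())
            h.update(path.read_bytes())
    return h.hexdigest()
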