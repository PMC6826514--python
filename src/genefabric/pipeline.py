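"""End-to-end orchestration: filter -> normalize -> REV -> coordination ->
PWR -> networks, with a manifest recording configuration and conventions.

The pipeline is deterministic for fixed inputs, writes every stage's output
as TSV/JSON/GraphML under one output directory, and stamps each run with a
hash of its configuration so downstream artifacts are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coordination as coord
from . import expression_stats as es
from . import fabric_pwr as fp
from . import io_preprocess as iop
from . import networks as nets
from . import synthetic

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML via :func:`load_config`."""

    input_table: str | None = None  # raw spot TSV; None -> simulate
    dialect_kind: str = "two_channel"
    channel_rule: str = "single"
    snr_factor: float = 2.0
    tolerance: float = 0.05
    max_iterations: int = 100
    rev: es.REVConfig = field(default_factory=es.REVConfig)
    classification: coord.ClassificationConfig = field(default_factory=coord.ClassificationConfig)
    genesets: dict[str, list[str]] = field(default_factory=dict)
    reference_condition: str | None = None
    pwr_cross: tuple[str, str] | None = None  # (set A name, set B name)
    top_k: int = 4
    simulation: synthetic.SimulationConfig | None = None
    all_pairs: bool = False  # transcriptome-wide pairs (quadratic; off by default)
    seed: int = 0


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "rev" in raw:
        cfg.rev = es.REVConfig(**raw.pop("rev"))
    if "classification" in raw:
        cfg.classification = coord.ClassificationConfig(**raw.pop("classification"))
    if "simulation" in raw:
        sim = raw.pop("simulation")
        modules = [synthetic.LatentModule(**m) for m in sim.pop("modules", [])]
        cfg.simulation = synthetic.SimulationConfig(modules=modules, **sim)
    if "pwr_cross" in raw:
        pc = raw.pop("pwr_cross")
        cfg.pwr_cross = tuple(pc) if pc else None
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        setattr(cfg, key, val)
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(repr(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages and return the manifest (also written as JSON).

    Input is either ``config.input_table`` or a fresh simulation from
    ``config.simulation`` (whose truth tables are then written alongside,
    enabling recovery scoring).  Aborts with the failing stage's name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "conventions": {
            "rev_quantile_convention": config.rev.quantile_convention,
            "independence_threshold": config.classification.independence_threshold,
            "unequal_redundancy_rule": config.classification.unequal_redundancy_rule,
            "use_log2": config.classification.use_log2,
            "regulation_method": "surrogate",
        },
        "stages": {},
    }
    stage = "input"
    try:
        if config.input_table:
            dialect = iop.TableDialect(
                kind=config.dialect_kind, channel_rule=config.channel_rule
            )
            table = iop.read_spot_table(config.input_table, dialect)
        else:
            sim_cfg = config.simulation or synthetic.SimulationConfig(seed=config.seed)
            dataset = synthetic.simulate_dataset(sim_cfg)
            table = dataset.raw
            truth_paths = synthetic.ground_truth_report(dataset, outdir / "truth")
            manifest["stages"]["simulate"] = truth_paths
            dialect = iop.TableDialect(kind="two_channel", channel_rule="single")

        stage = "filter"
        valid, report = iop.filter_spots(table, snr_factor=config.snr_factor)
        (outdir / "filter_report.json").write_text(json.dumps(report.as_dict(), indent=2))
        manifest["stages"]["filter"] = {"path": str(outdir / "filter_report.json"), **report.as_dict()}

        stage = "normalize"
        expr = iop.to_expression(valid, dialect)
        norm = iop.normalize_iterative(expr, config.tolerance, config.max_iterations)
        iop.write_normalized_tsv(norm, outdir / "normalized.tsv")
        manifest["stages"]["normalize"] = {
            "path": str(outdir / "normalized.tsv"),
            "iterations": norm.iterations,
            "final_error": norm.final_error,
        }

        stage = "rev"
        summaries = es.summarize_all(norm.values, config.rev)
        frame = es.summaries_to_frame(summaries)
        frame.to_csv(outdir / "rev.tsv", sep="\t", index=False)
        manifest["stages"]["rev"] = {"path": str(outdir / "rev.tsv"), "n": len(frame)}

        conditions = sorted(frame["condition"].unique())
        genesets = config.genesets or {
            "all": sorted(frame["transcript_id"].unique())
        }

        stage = "regulation"
        regulation: dict[str, list[es.RegulationCall]] = {}
        ref = config.reference_condition
        if ref and ref in conditions:
            reg_rows = []
            for cond in conditions:
                if cond == ref:
                    continue
                calls = []
                for tid in frame["transcript_id"].unique():
                    sc = summaries.get((tid, cond))
                    sr = summaries.get((tid, ref))
                    if sc is None or sr is None:
                        continue
                    calls.append(es.regulation_call(sc, sr))
                regulation[cond] = calls
                reg_rows += [
                    {"condition": cond, "transcript_id": c.transcript_id,
                     "fold_change": c.fold_change, "p_value": c.p_value,
                     "corrected_p": c.corrected_p, "status": c.status,
                     "method": c.method}
                    for c in calls
                ]
            pd.DataFrame(reg_rows).to_csv(outdir / "regulation.tsv", sep="\t", index=False)
            manifest["stages"]["regulation"] = {"path": str(outdir / "regulation.tsv")}

        stage = "coordinate"
        records: dict[tuple[str, str], list[coord.CorrelationRecord]] = {}
        profiles_json = {}
        for cond in conditions:
            prof, redundancy = coord.replicate_profiles(
                norm.values, cond, use_log2=config.classification.use_log2
            )
            for set_name, genes in genesets.items():
                pairs, count = coord.enumerate_pairs(genes)
                recs = coord.correlate_pairs(
                    prof, redundancy, pairs, cond, config.classification
                )
                assert len(recs) == count
                records[(set_name, cond)] = recs
                profiles_json[f"{set_name}|{cond}"] = coord.coordination_profile(recs)
                coord.records_to_frame(recs).to_csv(
                    outdir / f"coordination_{set_name}_{_slug(cond)}.tsv",
                    sep="\t",
                    index=False,
                )
        (outdir / "coordination_profiles.json").write_text(
            json.dumps(profiles_json, indent=2)
        )
        manifest["stages"]["coordinate"] = {
            "path": str(outdir / "coordination_profiles.json"),
            "n_sets": len(genesets),
        }

        stage = "reversals"
        rev_frames = []
        for set_name in genesets:
            for i, ca in enumerate(conditions):
                for cb in conditions[i + 1 :]:
                    d = coord.detect_reversals(records[(set_name, ca)], records[(set_name, cb)])
                    if len(d):
                        d.insert(0, "geneset", set_name)
                        rev_frames.append(d)
        reversals = (
            pd.concat(rev_frames, ignore_index=True)
            if rev_frames
            else pd.DataFrame(
                columns=["geneset", "gene_a", "gene_b", "condition_a", "condition_b", "rho_a", "rho_b"]
            )
        )
        reversals.to_csv(outdir / "reversals.tsv", sep="\t", index=False)
        manifest["stages"]["reversals"] = {
            "path": str(outdir / "reversals.tsv"),
            "n": len(reversals),
        }

        stage = "pwr"
        pwr_paths = {}
        for cond in conditions:
            fabric = es.fabric_summary(list(summaries.values()), cond)
            if config.pwr_cross:
                name_a, name_b = config.pwr_cross
                set_a, set_b = genesets[name_a], genesets[name_b]
                pairs, _ = coord.enumerate_pairs(set_a, set_b)
                rec_pool = records.get((name_a, cond), []) + records.get((name_b, cond), [])
                prof, redundancy = coord.replicate_profiles(
                    norm.values, cond, use_log2=config.classification.use_log2
                )
                cross = coord.correlate_pairs(
                    prof, redundancy, pairs, cond, config.classification
                )
                rho_map = {r.pair: r.rho for r in cross}
                pairs, _ = coord.enumerate_pairs(set_a, set_b)
            else:
                set_name = next(iter(genesets))
                set_a = set_b = None
                recs = records[(set_name, cond)]
                rho_map = {r.pair: r.rho for r in recs}
                pairs = [(r.gene_a, r.gene_b) for r in recs]
            pwr_recs = fp.pwr_records(summaries, rho_map, pairs, fabric)
            top = fp.top_pairs(pwr_recs, config.top_k)
            path = outdir / f"pwr_{_slug(cond)}.tsv"
            pd.DataFrame(
                [
                    {"gene_a": r.gene_a, "gene_b": r.gene_b, "pwr": r.pwr,
                     "expression_term": r.factors[0], "correlation_term": r.factors[1],
                     "control_term": r.factors[2]}
                    for r in pwr_recs
                ]
            ).to_csv(path, sep="\t", index=False)
            if set_a is not None:
                fp.pwr_landscape(pwr_recs, set_a, set_b).to_csv(
                    outdir / f"pwr_landscape_{_slug(cond)}.tsv", sep="\t"
                )
            pwr_paths[cond] = {
                "path": str(path),
                "medallion": [
                    {"pair": f"{r.gene_a}-{r.gene_b}", "pwr": r.pwr} for r in top
                ],
            }
        (outdir / "pwr_top_pairs.json").write_text(json.dumps(pwr_paths, indent=2))
        manifest["stages"]["pwr"] = {"path": str(outdir / "pwr_top_pairs.json")}

        stage = "network"
        for set_name, genes in genesets.items():
            for cond in conditions:
                g = nets.build_network(
                    records[(set_name, cond)], genes, cond, regulation.get(cond)
                )
                nets.export_graph(
                    g, outdir / f"network_{set_name}_{_slug(cond)}.graphml", "graphml"
                )
        manifest["stages"]["network"] = {"n_graphs": len(genesets) * len(conditions)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for entry in manifest["stages"].values():
        if isinstance(entry, dict):
            entry["config_hash"] = manifest["config_hash"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _slug(condition: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in condition)
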