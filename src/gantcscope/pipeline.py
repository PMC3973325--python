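"""End-to-end orchestration: simulate a study bundle, run all stages.

A run is driven by a flat key = value config; stages whose inputs are
absent are skipped with a logged notice. All numeric TSV output uses 6
significant digits, so re-running on identical inputs reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .enrichment import (
    candidate_direct_targets,
    classify_de,
    enrichment_battery,
    simple_de,
)
from .genome import GenomeRecord
from .methylome import (
    calibrate,
    call_sites,
    call_strands,
    origin_gradient_stat,
    site_class_tally,
    smooth_profile,
    window_profile,
)
from .motifs import GANTC, enumerate_gantc_like, partition_counts, scan_motif
from .promoters import conservation_counts, promoter_motif_flags
from .synthetic import (
    SyntheticPlan,
    generate_expression_dataset,
    generate_gene_sets,
    generate_genome,
    generate_ipd_dataset,
    generate_methylation_plan,
    generate_ortholog_panel,
)

logger = logging.getLogger("gantcscope")

DEFAULTS = {
    "pattern": GANTC,
    "window": 20000,
    "tau": 2.4,
    "span": 0.75,
    "min_coverage": 5,
    "promoter_length": 200,
    "alpha": 0.01,
    "strong_fold": 2.0,
    "min_conservation": 2,
    "origin_position": 0,
    "seed": 0,
    "all_24": False,
    "circular": True,
}

_PARAM_TYPES = {
    "window": int, "min_coverage": int, "promoter_length": int,
    "min_conservation": int, "origin_position": int, "seed": int,
    "tau": float, "span": float, "alpha": float, "strong_fold": float,
    "pattern": str,
}


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = ""

    def to_json(self, indent: int = 2) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), indent=indent, default=_default, sort_keys=True)


def _coerce(config: dict) -> dict:
    params = dict(DEFAULTS)
    for key, value in config.items():
        if key in _PARAM_TYPES:
            params[key] = _PARAM_TYPES[key](value)
        elif key in ("all_24", "circular"):
            params[key] = str(value).strip().lower() in ("1", "true", "yes")
        else:
            params[key] = value
    return params


def _round6(x) -> float:
    return float(f"{float(x):.6g}")


def run_pipeline(config: dict, outdir) -> RunReport:
    """Execute motif stats -> methylome -> promoters -> enrichment.

    ``config`` maps path keys (genome, annotation, kinetics,
    reference_kinetics, expression or stats, catalog, panel, essential_set)
    and stage parameters; any stage whose input paths are missing is
    skipped. Raises on malformed inputs.
    """
    params = _coerce(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    report = RunReport(config={k: str(v) for k, v in params.items()}, version=__version__)

    def has(*keys):
        return all(params.get(k) and Path(params[k]).exists() for k in keys)

    genome = features = None
    if has("genome"):
        genome = io.read_fasta(params["genome"], circular=params["circular"])
    if has("annotation"):
        features = io.read_gff3(params["annotation"])

    # ---- motif statistics -------------------------------------------------
    if genome is not None and features is not None:
        patterns = enumerate_gantc_like() if params["all_24"] else [params["pattern"]]
        frames = [partition_counts(genome, features, p).to_frame() for p in patterns]
        stats_tbl = pd.concat(frames, ignore_index=True)
        io.write_table(stats_tbl, outdir / "motif_stats.tsv")
        head = stats_tbl[stats_tbl["pattern"] == params["pattern"]]
        report.stages["motif_statistics"] = {
            "patterns": len(patterns),
            "ratios": {
                row.partition: _round6(row.obs_exp_ratio) for row in head.itertuples()
            },
            "observed_genome": int(head.loc[head["partition"] == "genome", "observed"].iloc[0]),
        }
    else:
        logger.info("motif_statistics skipped: genome or annotation missing")
        report.stages["motif_statistics"] = {"skipped": True}

    # ---- methylome --------------------------------------------------------
    sites = None
    if genome is not None:
        sites = np.asarray(scan_motif(genome.sequence, params["pattern"], genome.circular))
    if genome is not None and has("kinetics", "reference_kinetics") and sites is not None and sites.size:
        ref_obs = io.read_kinetics(params["reference_kinetics"])
        obs = io.read_kinetics(params["kinetics"])
        model = calibrate(ref_obs, min_coverage=params["min_coverage"], tau=params["tau"])
        strand_calls = call_strands(obs, model, min_coverage=params["min_coverage"])
        calls = call_sites(sites, strand_calls, genome.length, genome.circular)
        tally = site_class_tally(calls)
        profile = window_profile(obs, model, window=params["window"], chrom_length=genome.length)
        try:
            profile = smooth_profile(profile, span=params["span"], circular=genome.circular,
                                     chrom_length=genome.length)
        except ValueError as exc:
            logger.warning("profile smoothing skipped: %s", exc)
            report.warnings.append(f"ipd_methylome: {exc}")
        f_site = calls[["plus_f", "minus_f"]].mean(axis=1)
        rho, p_perm = origin_gradient_stat(
            calls["site"], f_site, params["origin_position"], genome.length,
            seed=params["seed"],
        )
        io.write_table(calls, outdir / "site_calls.tsv")
        io.write_table(profile, outdir / "window_profile.tsv")
        summary = {
            "r_full": _round6(model.r_full),
            "r_hemi": _round6(model.r_hemi),
            "tau": params["tau"],
            "tally": tally,
            "gradient_rho": _round6(rho),
            "gradient_p": _round6(p_perm),
            "n_sites": int(sites.size),
        }
        (outdir / "methylome_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        report.stages["ipd_methylome"] = summary
    else:
        logger.info("ipd_methylome skipped: kinetics inputs missing")
        report.stages["ipd_methylome"] = {"skipped": True}

    # ---- promoters --------------------------------------------------------
    flags_df = conservation = None
    if genome is not None and features is not None:
        flags_df = promoter_motif_flags(
            features, genome, params["pattern"], params["promoter_length"]
        )
        if has("panel"):
            panel = io.read_panel(params["panel"])
            focal = flags_df.set_index("gene_id")["has_motif"]
            cons_df = conservation_counts(focal.reindex(panel.index).fillna(False), panel)
            conservation = cons_df["conservation_count"]
            flags_df = flags_df.merge(
                cons_df["conservation_count"].rename_axis("gene_id").reset_index(),
                on="gene_id", how="left",
            )
        io.write_table(flags_df, outdir / "promoters.tsv")
        report.stages["promoter_conservation"] = {
            "n_genes": int(len(flags_df)),
            "n_with_motif": int(flags_df["has_motif"].sum()),
            "promoter_length": params["promoter_length"],
        }
    else:
        logger.info("promoter_conservation skipped: genome or annotation missing")
        report.stages["promoter_conservation"] = {"skipped": True}

    # ---- differential expression + enrichment ----------------------------
    stats_df = None
    if has("stats"):
        stats_df = io.read_gene_stats(params["stats"])
    elif has("expression"):
        matrix = io.read_expression_matrix(params["expression"])
        labels = ["mut" if c.startswith("mut") else "wt" for c in matrix.columns]
        stats_df = simple_de(matrix, labels)
    if stats_df is not None:
        classification = classify_de(stats_df, alpha=params["alpha"], strong_fold=params["strong_fold"])
        catalog = io.read_catalog(params["catalog"]) if has("catalog") else None
        flags = (
            flags_df.set_index("gene_id")["has_motif"] if flags_df is not None else None
        )
        battery = enrichment_battery(
            classification, catalog=catalog, promoter_flags=flags, conservation=conservation
        )
        io.write_table(stats_df, outdir / "gene_stats.tsv")
        io.write_table(battery, outdir / "enrichment.tsv")
        stage = {
            "n_universe": len(classification.universe),
            "n_significant": len(classification.significant),
            "n_up": len(classification.up),
            "n_down": len(classification.down),
            "n_strong": len(classification.strong),
            "n_tests": int(len(battery)),
        }
        if flags is not None and conservation is not None:
            essential = (catalog or {}).get("essential", set())
            candidates = candidate_direct_targets(
                classification, flags, conservation, essential,
                min_conservation=params["min_conservation"],
            )
            io.write_table(candidates, outdir / "candidates.tsv")
            stage["n_candidates"] = int(len(candidates))
        report.stages["de_enrichment"] = stage
    else:
        logger.info("de_enrichment skipped: no stats or expression input")
        report.stages["de_enrichment"] = {"skipped": True}

    (outdir / "report.json").write_text(report.to_json())
    return report


def simulate(plan: SyntheticPlan, outdir, conservation_probs=(0.8, 0.1)) -> Path:
    """Write a full synthetic study bundle plus a ready-made run config.

    ``conservation_probs`` gives the per-gene ortholog-promoter-motif
    propensity for genes with / without a focal promoter motif, coupling
    conservation counts to real promoter content. Returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, features, sites = generate_genome(plan)
    methylation = generate_methylation_plan(plan, sites["site"].to_numpy())
    obs = generate_ipd_dataset(genome, methylation, plan)
    ref = generate_ipd_dataset(genome, methylation, plan, reference=True)
    flags_df = promoter_motif_flags(features, genome, GANTC, DEFAULTS["promoter_length"])
    flags = flags_df.set_index("gene_id")["has_motif"]
    matrix, truth = generate_expression_dataset(features, flags, plan)
    catalog, cog = generate_gene_sets(features, truth, plan)
    p_hi, p_lo = conservation_probs
    panel = generate_ortholog_panel(
        features, plan, n_species=5,
        conservation_probs=np.where(flags.reindex(features["feature_id"]).fillna(False), p_hi, p_lo),
    )

    io.write_fasta(genome, outdir / "genome.fna")
    io.write_gff3(features, outdir / "annotation.gff3", {genome.contig_id: genome.length})
    io.write_kinetics(obs, outdir / "kinetics_wt.tsv")
    io.write_kinetics(ref, outdir / "kinetics_reference.tsv")
    io.write_expression_matrix(matrix, outdir / "expression.tsv")
    io.write_catalog(catalog, outdir / "catalog.tsv")
    io.write_table(panel.reset_index(), outdir / "panel.tsv")
    io.write_table(sites, outdir / "truth_sites.tsv")
    io.write_table(methylation, outdir / "truth_methylation.tsv")
    io.write_table(truth, outdir / "truth_expression.tsv")
    io.write_table(cog.rename_axis("gene_id").reset_index(), outdir / "truth_cog.tsv")

    config = {
        "genome": outdir / "genome.fna",
        "annotation": outdir / "annotation.gff3",
        "kinetics": outdir / "kinetics_wt.tsv",
        "reference_kinetics": outdir / "kinetics_reference.tsv",
        "expression": outdir / "expression.tsv",
        "catalog": outdir / "catalog.tsv",
        "panel": outdir / "panel.tsv",
        "origin_position": plan.origin_position,
        "seed": plan.seed,
    }
    config_path = outdir / "pipeline.cfg"
    io.write_config({k: str(v) for k, v in config.items()}, config_path)
    return config_path
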