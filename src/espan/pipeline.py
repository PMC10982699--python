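"""End-to-end orchestration: simulate -> coverage -> filter -> bias -> density.

A run is configured by a flat YAML file (see ``examples/wt_vs_mutants.yaml``)
and is a pure function of that config: rerunning with the same config and
seed reproduces byte-identical TSV outputs. One master seed drives
label-addressed per-sample substreams, so adding a genotype never perturbs
another sample's draws.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import espan_bias, histone_density, origin_filter
from .formats_io import (
    PARENTAL_MARKS,
    ConfigError,
    GenomeSpec,
    OriginSet,
    read_fragments,
    read_origins,
)
from .strand_coverage import coverage_from_fragments
from .synthetic_data import (
    GENOTYPE_PRESETS,
    GenotypeParams,
    SimulationConfig,
    default_genome,
    simulate_experiment,
)

logger = logging.getLogger("espan")

ANALYSIS_DEFAULTS = {
    "radius": 10000,
    "window": 100,
    "step": 10,
    "exclusion_radius": 300,
    "density_halfwidth": 2500,
    "density_bin": 100,
    "origin_threshold": 2.0,
    "origin_halfwidth": 1000,
    "reference": "WT",
    "normalization": "brdu-matched",
}

SIMULATION_DEFAULTS = {
    "n_origins": 200,
    "replicated_halfwidth": 5000,
    "nucleosome_spacing": 160,
    "fragment_length_mean": 150.0,
    "fragment_length_sd": 15.0,
    "reads_per_nucleosome": 400.0,
    "brdu_reads_per_bp": 2.5,
    "cells_per_locus": 1000,
    "strand_recovery_w": 1.0,
    "marks": ["H3K4me3", "H3K56ac"],
}


def _resolve_genotypes(entries) -> list[GenotypeParams]:
    out = []
    for e in entries:
        if isinstance(e, str):
            if e not in GENOTYPE_PRESETS:
                raise ConfigError(f"unknown genotype preset {e!r}; presets: "
                                  f"{sorted(GENOTYPE_PRESETS)}")
            out.append(GENOTYPE_PRESETS[e])
        else:
            out.append(GenotypeParams(**e))
    return out


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = {
        "seed": int(raw.get("seed", 0)),
        "outdir": raw.get("outdir", "espan_run"),
        "write_coverage": bool(raw.get("write_coverage", False)),
        "write_fragments": bool(raw.get("write_fragments", False)),
        "analysis": {**ANALYSIS_DEFAULTS, **(raw.get("analysis") or {})},
        "simulation": None,
        "samples": raw.get("samples"),
        "genome": raw.get("genome"),
        "origins": raw.get("origins"),
    }
    if "simulation" in raw and raw["simulation"] is not None:
        cfg["simulation"] = {**SIMULATION_DEFAULTS, **raw["simulation"]}
    a = cfg["analysis"]
    for key in ("radius", "window", "step", "density_halfwidth", "density_bin",
                "origin_halfwidth"):
        if a[key] <= 0:
            raise ConfigError(f"analysis.{key} must be positive, got {a[key]}")
    if a["exclusion_radius"] < 0 or a["origin_threshold"] < 0:
        raise ConfigError("exclusion_radius and origin_threshold must be >= 0")
    if cfg["simulation"] is None and not cfg["samples"]:
        raise ConfigError("config needs either a 'simulation' or a 'samples' section")
    return cfg


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute all stages; returns the output directory.

    Artifacts: ``genome.sizes``, ``origins.bed`` / ``origins.filtered.bed``,
    per-sample BED6 (simulation mode), ``manifest.tsv`` (ground truth),
    ``origin_usage.tsv``, per (genotype, mark) ``<g>.<mark>.bias.tsv`` /
    ``.aggregate.tsv`` / ``.folded.tsv``, ``density.tsv``, ``fold_changes.tsv``,
    ``tests.tsv``, plus ``effective_config.yaml`` and ``run.log``.
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: dict, out: Path) -> Path:
    a = cfg["analysis"]
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    # ---- stage: inputs (simulate or load) ----
    if cfg["simulation"] is not None:
        s = dict(cfg["simulation"])
        marks = tuple(s.pop("marks"))
        genotype_entries = s.pop("genotypes", list(GENOTYPE_PRESETS))
        genome, origins = default_genome(n_origins=int(s.pop("n_origins")))
        sim_config = SimulationConfig(
            genome=genome, origins=origins, seed=cfg["seed"],
            analysis_radius=a["radius"], **s,
        )
        genotypes = _resolve_genotypes(genotype_entries)
        logger.info("simulating %d genotypes x %d marks, %d origins",
                    len(genotypes), len(marks), len(origins))
        result = simulate_experiment(sim_config, genotypes, marks)
        result.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        fragment_sets = result.samples
        if cfg.get("write_fragments"):
            for (g, m), fs in fragment_sets.items():
                fs.to_bed(out / f"{g}.{m}.bed")
        genotype_labels = [g.label for g in genotypes]
    else:
        genome = GenomeSpec.from_file(cfg["genome"])
        origins = read_origins(cfg["origins"], genome)
        manifest = pd.read_csv(cfg["samples"], sep="\t")
        fragment_sets = {}
        for _, row in manifest.iterrows():
            fs = read_fragments(
                row["path"], genome, sample_id=f'{row["genotype"]}_{row["mark"]}',
                genotype_label=row["genotype"], mark=row["mark"],
            )
            fragment_sets[(row["genotype"], row["mark"])] = fs
        genotype_labels = sorted({g for g, _ in fragment_sets})
        marks = tuple(sorted({m for _, m in fragment_sets if m != "BrdU"}))
    genome.to_file(out / "genome.sizes")
    origins.to_bed(out / "origins.bed")

    # ---- stage: coverage ----
    coverages = {key: coverage_from_fragments(fs, genome) for key, fs in fragment_sets.items()}
    if cfg.get("write_coverage"):
        from .formats_io import write_bedgraph

        for (g, m), cov in coverages.items():
            write_bedgraph(cov, out / f"{g}.{m}.watson.bedgraph", out / f"{g}.{m}.crick.bedgraph")

    # ---- stage: origin filter (reference-genotype BrdU) ----
    reference = a["reference"]
    ref_brdu = [coverages[k] for k in coverages if k[0] == reference and k[1] == "BrdU"]
    if not ref_brdu:
        raise ConfigError(f"no BrdU sample for reference genotype {reference!r}")
    filtered, report = origin_filter.filter_origins(
        origins, ref_brdu, halfwidth=a["origin_halfwidth"], threshold=a["origin_threshold"]
    )
    report.to_csv(out / "origin_usage.tsv", sep="\t", index=False)
    filtered.to_bed(out / "origins.filtered.bed")

    # ---- stage: bias profiles ----
    for g in genotype_labels:
        brdu_cov = coverages.get((g, "BrdU"))
        for m in marks:
            key = (g, m)
            if key not in coverages:
                continue
            profile = espan_bias.compute_bias_profile(
                coverages[key], brdu_cov, filtered,
                radius=a["radius"], window=a["window"], step=a["step"],
            )
            prefix = out / f"{g}.{m}"
            espan_bias.bias_heatmap_matrix(profile, f"{prefix}.bias.tsv",
                                           exclude=a["exclusion_radius"])
            espan_bias.aggregate_table(profile).to_csv(
                f"{prefix}.aggregate.tsv", sep="\t", index=False, na_rep="nan",
                float_format="%.10g",
            )
            folded = espan_bias.side_resolved_bias(
                profile.effective_matrix, profile.bin_centers, profile.origin_ids,
                exclude=a["exclusion_radius"],
            )
            folded.to_csv(f"{prefix}.folded.tsv", sep="\t", index=False,
                          na_rep="nan", float_format="%.10g")

    # ---- stage: density (parental marks) ----
    parental = [m for m in marks if m in PARENTAL_MARKS]
    for m in parental:
        pairs = [
            histone_density.GenotypeSamplePair(g, coverages[(g, m)], coverages[(g, "BrdU")])
            for g in genotype_labels
            if (g, m) in coverages and (g, "BrdU") in coverages
        ]
        if len(pairs) < 1:
            continue
        table = histone_density.density_table(
            pairs, filtered, halfwidth=a["density_halfwidth"], bin_size=a["density_bin"],
            exclude=a["exclusion_radius"], normalization=a["normalization"],
        )
        if reference in {p.genotype for p in pairs}:
            table = histone_density.fold_change(table, reference)
            tests = histone_density.all_pairwise_tests(table, reference)
            tests.to_csv(out / f"tests.{m}.tsv", sep="\t", index=False,
                         na_rep="nan", float_format="%.10g")
            histone_density.fold_change_summary(table).to_csv(
                out / f"fold_changes.{m}.tsv", sep="\t", index=False,
                na_rep="nan", float_format="%.10g",
            )
        histone_density.density_violin_export(table, out / f"density.{m}.tsv")

    logger.info("pipeline complete: %s", out)
    return out
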