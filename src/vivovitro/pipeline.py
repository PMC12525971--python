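"""End-to-end orchestration behind a single configuration mapping.

A pipeline run either simulates a study bundle or ingests one from
files, then executes every analysis stage — feed formulation,
community metrics, ordination, the lag-window scan, the divergence
model and the correlation report — writing machine-readable CSV/JSON
outputs plus a manifest with the configuration hash and per-file
checksums, so that a run is fully auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import correlation_report, environment_diversity_test
from .community_metrics import alpha_diversity, fb_ratio
from .divergence_model import build_model_frame, fit_type3_anova
from .feed_formulation import ConversionSpec, formulate_series
from .lag_window import window_sweep
from .ordination import pcoa_jaccard
from .synthetic_data import SimulationConfig, generate_study
from .tables_io import (
    IN_VITRO,
    IN_VIVO,
    StudyBundle,
    ValidationError,
    assemble_bundle,
    read_abundance_table,
    read_diet_diary,
    read_metadata,
    write_abundance_table,
    write_diet_diary,
    write_metadata,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "exclusions": [],
    "pseudocount": 0.5,
    "w_min": 1,
    "w_max": 14,
    "rho_threshold": 0.7,
    "level": "genus",
    "adjustment": "bh",
    "use_clr": True,
    "min_prevalence": None,
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {**DEFAULT_CONFIG, **cfg}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_bundle_from_config(config: dict) -> tuple[StudyBundle, dict | None]:
    """Build the study bundle a config describes (simulate or ingest)."""
    exclusions = list(config.get("exclusions") or [])
    if "simulate" in config:
        overrides = dict(config["simulate"] or {})
        if "responders" in overrides:
            from .synthetic_data import Responder

            overrides["responders"] = tuple(Responder(**r) for r in overrides["responders"])
        overrides.setdefault("seed", config.get("seed", 0))
        sim = SimulationConfig(**overrides)
        bundle, truth = generate_study(sim)
        bundle = assemble_bundle(bundle.abundance, bundle.metadata, bundle.diets, exclusions)
        truth_dict = {
            "responders": [dataclasses.asdict(r) for r in truth.responders],
            "env_offsets": truth.env_offsets.round(6).to_dict(),
            "probiotic_taxon": truth.probiotic_taxon,
            "probiotic_boost": truth.probiotic_boost,
            "planted_lags": truth.planted_lags,
        }
        return bundle, truth_dict
    paths = config.get("paths")
    if not paths:
        raise ValidationError("config needs either a 'simulate' or a 'paths' section")
    for key in ("abundance", "metadata", "diet_in_vivo", "diet_in_vitro"):
        if key not in paths:
            raise ValidationError(f"paths section missing {key!r}")
        if not Path(paths[key]).exists():
            raise ValidationError(f"input file not found: {paths[key]}")
    abundance = read_abundance_table(paths["abundance"])
    metadata = read_metadata(paths["metadata"])
    diets = {
        IN_VIVO: read_diet_diary(paths["diet_in_vivo"], units="g_per_day"),
        IN_VITRO: read_diet_diary(paths["diet_in_vitro"], units="g_per_l"),
    }
    return assemble_bundle(abundance, metadata, diets, exclusions), None


def run_pipeline(config: dict, out_dir) -> Path:
    """Run every stage and write outputs + manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        bundle, truth = load_bundle_from_config(config)
        write_abundance_table(bundle.abundance, out / "abundance.tsv")
        write_metadata(bundle.metadata, out / "metadata.csv")
        for env, diary in bundle.diets.items():
            write_diet_diary(diary, out / f"diet_{env}.csv")
        if truth is not None:
            (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

        stage = "formulate"
        recipes, summary = formulate_series(bundle.diets[IN_VIVO], ConversionSpec())
        recipes.round(6).to_csv(out / "recipes.csv")
        summary.round(6).to_csv(out / "recipe_summary.csv")

        stage = "metrics"
        alpha_diversity(bundle.abundance.select_samples(bundle.retained_samples())).round(6).to_csv(
            out / "diversity.csv"
        )
        fb_ratio(bundle.abundance).round(6).to_csv(out / "fb_ratio.csv", header=True)
        w_chao, p_chao, n_pairs = environment_diversity_test(bundle, "chao1")

        stage = "ordinate"
        retained = bundle.abundance.select_samples(bundle.retained_samples())
        pcoa = pcoa_jaccard(retained)
        pcoa.coordinates.round(6).to_csv(out / "pcoa_coordinates.csv")
        pd.DataFrame(
            {"eigenvalue": pcoa.eigenvalues, "proportion": pcoa.proportion_explained}
        ).round(6).to_csv(out / "pcoa_eigenvalues.csv")

        stage = "lagscan"
        sweep = window_sweep(
            bundle,
            w_range=range(int(config["w_min"]), int(config["w_max"]) + 1),
            threshold=float(config["rho_threshold"]),
            use_clr=bool(config["use_clr"]),
            pseudocount=float(config["pseudocount"]),
            min_prevalence=config.get("min_prevalence"),
        )
        sweep.counts.to_csv(out / "lag_sweep.csv")
        (out / "optimal_windows.json").write_text(json.dumps(sweep.optimal, sort_keys=True))

        stage = "model"
        frame = build_model_frame(
            bundle,
            diet_windows=sweep.optimal,
            level=config["level"],
            pseudocount=float(config["pseudocount"]),
            min_prevalence=config.get("min_prevalence"),
        )
        for response in ("PC1_micro", "PC2_micro"):
            report = fit_type3_anova(frame, response)
            report.table.round(6).rename_axis("term").to_csv(out / f"anova_{response}.csv")

        stage = "correlate"
        corr = correlation_report(
            bundle,
            windows=sweep.optimal,
            method=config["adjustment"],
            use_clr=bool(config["use_clr"]),
            pseudocount=float(config["pseudocount"]),
            min_prevalence=config.get("min_prevalence"),
        )
        corr.table.round(6).to_csv(out / "correlations.csv", index=False)

        stage = "manifest"
        files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "version": __version__,
            "config": config,
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "n_samples": len(bundle.metadata),
            "n_retained": bundle.n_retained,
            "optimal_windows": sweep.optimal,
            "chao1_wilcoxon": {"W": w_chao, "p": p_chao, "n_pairs": n_pairs},
            "checksums": {name: _sha256(out / name) for name in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("pipeline complete: %s", out)
    return out
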