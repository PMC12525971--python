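"""Simulation studies validating the pipeline against planted truth.

Each function runs the generator over many seeds and measures how often
a downstream stage recovers what was planted (or, under a null
configuration, how often it falsely rejects).  These studies double as
the package's calibration evidence: the type-I error of the divergence
model should sit near its nominal level, and the planted environment
effects, diet lags and probiotic enrichment should be recovered at the
rates the study conditions support.

Problem sizes default to what one CPU handles in a few minutes
(100–200 seeds at the study's own sample sizes).
"""

from __future__ import annotations

import numpy as np

from .community_metrics import relative_abundance
from .divergence_model import (
    build_model_frame,
    diet_environment_interaction_test,
    fit_type3_anova,
)
from .lag_window import window_sweep
from .synthetic_data import SimulationConfig, generate_study, with_seed
from .tables_io import IN_VITRO, IN_VIVO

#: Windows used for null-model frames, where no lag is planted and the
#: choice is immaterial; they match the default planted lags.
NULL_WINDOWS = {IN_VIVO: 9, IN_VITRO: 12}


def _seed_range(seed: int, n: int) -> list[int]:
    # offset so different studies under the same base seed do not share
    # generator streams; kept below 2**31
    return [int((seed * 1_000_003 + k) % 2_147_483_647) for k in range(n)]


def environment_type1_error(
    n_seeds: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict[str, float]:
    """False-rejection rates of the divergence model under the null.

    Generates no-effect bundles and fits the full model on PC1_micro;
    reports the fraction of seeds rejecting the Environment main effect
    and the joint diet × Environment interaction at ``alpha``.
    """
    env_rej = 0
    int_rej = 0
    for s in _seed_range(seed, n_seeds):
        bundle, _ = generate_study(SimulationConfig.null(seed=s))
        frame = build_model_frame(bundle, NULL_WINDOWS)
        report = fit_type3_anova(frame, "PC1_micro")
        env_rej += report.table.loc["Environment", "p"] < alpha
        _, p_int = diet_environment_interaction_test(frame, "PC1_micro")
        int_rej += p_int < alpha
    return {
        "environment_rejection_rate": env_rej / n_seeds,
        "interaction_rejection_rate": int_rej / n_seeds,
        "n_seeds": n_seeds,
    }


def planted_effect_recovery(
    n_seeds: int = 100, seed: int = 0, alpha: float = 0.05
) -> dict[str, float]:
    """Recovery of the planted environment and diet-divergence effects.

    Under default study conditions, fits the divergence model using the
    planted lags and reports how often the Environment main effect and
    the joint diet × Environment interaction are significant on
    PC1_micro, and how often Environment carries the largest Type III
    share of all terms.
    """
    env_sig = int_sig = env_largest = 0
    shares = []
    for s in _seed_range(seed, n_seeds):
        bundle, truth = generate_study(with_seed(SimulationConfig(), s))
        frame = build_model_frame(bundle, truth.planted_lags)
        report = fit_type3_anova(frame, "PC1_micro")
        env_sig += report.table.loc["Environment", "p"] < alpha
        _, p_int = diet_environment_interaction_test(frame, "PC1_micro")
        int_sig += p_int < alpha
        terms = report.table["sum_sq"].drop("Residual")
        env_largest += terms.idxmax() == "Environment"
        shares.append(report.table.loc["Environment", "var_share"])
    return {
        "environment_sig_rate": env_sig / n_seeds,
        "interaction_sig_rate": int_sig / n_seeds,
        "environment_largest_rate": env_largest / n_seeds,
        "mean_environment_share": float(np.mean(shares)),
        "n_seeds": n_seeds,
    }


def lag_recovery(
    n_seeds: int = 100, seed: int = 0, tolerance: int = 2
) -> dict[str, float]:
    """How often the window sweep recovers each planted lag within
    ``tolerance`` days."""
    hits = {IN_VIVO: 0, IN_VITRO: 0}
    optima = {IN_VIVO: [], IN_VITRO: []}
    truth = None
    for s in _seed_range(seed, n_seeds):
        bundle, truth = generate_study(with_seed(SimulationConfig(), s))
        sweep = window_sweep(bundle)
        for env in hits:
            w = sweep.optimal[env]
            optima[env].append(w)
            hits[env] += abs(w - truth.planted_lags[env]) <= tolerance
    return {
        "in_vivo_recovery_rate": hits[IN_VIVO] / n_seeds,
        "in_vitro_recovery_rate": hits[IN_VITRO] / n_seeds,
        "in_vivo_planted_lag": truth.planted_lags[IN_VIVO],
        "in_vitro_planted_lag": truth.planted_lags[IN_VITRO],
        "in_vivo_median_optimum": float(np.median(optima[IN_VIVO])),
        "in_vitro_median_optimum": float(np.median(optima[IN_VITRO])),
        "n_seeds": n_seeds,
    }


def probiotic_detection(n_seeds: int = 100, seed: int = 0) -> dict[str, float]:
    """How often the probiotic genus is enriched during supplementation.

    Detection per seed: its mean relative abundance in the in vitro
    samples taken during the probiotic phase exceeds its mean over the
    in vitro baseline samples.  The same contrast in vivo serves as the
    negative control (the genus is not boosted there).
    """
    detected_vitro = enriched_vivo = 0
    for s in _seed_range(seed, n_seeds):
        bundle, truth = generate_study(with_seed(SimulationConfig(), s))
        rel = relative_abundance(bundle.abundance)
        genus_row = rel.index.get_level_values("genus") == truth.probiotic_taxon
        for env, counter in ((IN_VITRO, "v"), (IN_VIVO, "k")):
            meta = bundle.metadata_for(env)
            during = meta.loc[meta["phase"] == "probiotic_plus_diet", "sample_id"]
            before = meta.loc[meta["day"] <= 0, "sample_id"]
            mean_during = float(rel.loc[genus_row, list(during)].mean(axis=1).iloc[0])
            mean_before = float(rel.loc[genus_row, list(before)].mean(axis=1).iloc[0])
            if env == IN_VITRO:
                detected_vitro += mean_during > mean_before
            else:
                enriched_vivo += mean_during > mean_before
    return {
        "in_vitro_detection_rate": detected_vitro / n_seeds,
        "in_vivo_enrichment_rate": enriched_vivo / n_seeds,
        "n_seeds": n_seeds,
    }
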