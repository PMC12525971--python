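"""The environment-divergence linear model.

The central question — does the same microbiota respond to the same
intervention differently in vivo and in vitro? — is answered by
reducing both the community and the diet to their first two principal
components and fitting, by ordinary least squares,

    PC_micro ~ (PC1_diet + PC2_diet + Probiotic) × Environment

with sum-to-zero (±1) coding for the Probiotic and Environment factors.
Each term is then tested with Type III sums of squares: the increase in
residual SS when that term alone is dropped from the otherwise full
model.  Variance explained per term is reported both as the Type III SS
share of the total corrected SS and as partial eta-squared.

Microbiota PCs come from a centred PCA of the CLR-transformed counts of
the genera prevalent in both environments (or of all phyla for the
phylum-level run); diet PCs from a PCA of trailing-window macronutrient
means z-standardised within each environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_metrics import prevalence_filter, shared_taxa
from .exposures import MODEL_EXPOSURES
from .lag_window import default_min_prevalence, windowed_exposures
from .ordination import clr_transform, pca
from .tables_io import (
    IN_VITRO,
    IN_VIVO,
    PHASE_PROBIOTIC,
    StudyBundle,
    ValidationError,
)

MODEL_TERMS = [
    "PC1_diet",
    "PC2_diet",
    "Probiotic",
    "Environment",
    "PC1_diet:Environment",
    "PC2_diet:Environment",
    "Probiotic:Environment",
]


@dataclass(frozen=True)
class ModelFrame:
    """Per-sample scores and factors entering the linear model."""

    data: pd.DataFrame  # PC1_micro, PC2_micro, PC1_diet, PC2_diet, Probiotic, Environment
    taxa: list[tuple[str, str]]
    diet_exposures: list[str]

    def __post_init__(self) -> None:
        required = ["PC1_micro", "PC2_micro", "PC1_diet", "PC2_diet", "Probiotic", "Environment"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"model frame missing columns: {missing}")
        num = self.data[required[:4]].to_numpy(dtype=float)
        if not np.isfinite(num).all():
            raise ValidationError("model frame contains non-finite scores")
        if self.data["Environment"].nunique() < 2:
            raise ValidationError(
                "both environments must be present for the interaction to be estimable"
            )


@dataclass(frozen=True)
class ModelReport:
    """Type III ANOVA table with per-term variance shares.

    ``table`` rows are the seven model terms plus ``Residual``; columns
    are ``sum_sq``, ``df``, ``F``, ``p``, ``var_share`` (Type III SS /
    total corrected SS) and ``partial_eta_sq``.
    """

    response: str
    table: pd.DataFrame
    coefficients: pd.Series
    total_ss: float


def z_standardize_by_environment(diet: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Z-transform each exposure column within each environment.

    ``diet`` is samples × exposures indexed by sample id; ``metadata``
    supplies the environment of each sample.  After the transform every
    column has mean 0 and SD 1 (ddof=1) within each environment, which
    puts g/day and g/L exposures on a common scale.
    """
    env = metadata.set_index("sample_id")["environment"]
    out = diet.copy().astype(float)
    for e, idx in diet.groupby(env.reindex(diet.index)).groups.items():
        sub = diet.loc[idx]
        if len(sub) < 2:
            raise ValidationError(f"environment {e!r} has fewer than 2 samples")
        sd = sub.std(ddof=1)
        const = [str(c) for c in sub.columns[sd == 0]]
        if const:
            raise ValidationError(f"constant exposure within {e!r}: {const}")
        out.loc[idx] = (sub - sub.mean()) / sd
    return out


def build_model_frame(
    bundle: StudyBundle,
    diet_windows: dict[str, int],
    level: str = "genus",
    diet_exposures: list[str] | None = None,
    pseudocount: float = 0.5,
    min_prevalence: dict[str, int] | None = None,
) -> ModelFrame:
    """Assemble PC scores and factors for the divergence model.

    ``diet_windows`` gives the trailing-mean window per environment
    (the optimal windows from the lag scan).  At genus level the
    community PCA uses the genera prevalent in both environments; at
    phylum level, all phyla.
    """
    diet_exposures = diet_exposures or list(MODEL_EXPOSURES)
    metas = {e: bundle.metadata_for(e) for e in (IN_VIVO, IN_VITRO)}
    if any(m.empty for m in metas.values()):
        raise ValidationError("both environments need retained samples")
    sample_ids = [sid for e in (IN_VIVO, IN_VITRO) for sid in metas[e]["sample_id"]]

    if level == "genus":
        filtered = {}
        for e, meta in metas.items():
            tab = bundle.abundance.select_samples(list(meta["sample_id"]))
            cutoff = (min_prevalence or {}).get(e, default_min_prevalence(len(meta)))
            filtered[e] = prevalence_filter(tab, cutoff)
        taxa = shared_taxa(filtered[IN_VIVO], filtered[IN_VITRO])
        if len(taxa) < 3:
            raise ValidationError(f"only {len(taxa)} shared prevalent taxa; need >= 3")
        table = bundle.abundance.select_samples(sample_ids)
    elif level == "phylum":
        table = bundle.abundance.select_samples(sample_ids).by_phylum()
        taxa = table.taxa
    else:
        raise ValidationError(f"level must be 'genus' or 'phylum', got {level!r}")

    # CLR over the full composition, then restrict to the selected taxa
    # (CLR of the subcomposition would distort each genus by the
    # others' swings through the subcomposition geometric mean)
    clr_values = clr_transform(table, pseudocount).values[taxa]
    micro = pca(clr_values, n_components=2)
    diet_rows = []
    for e in (IN_VIVO, IN_VITRO):
        days = pd.Series(metas[e]["day"].to_numpy(), index=metas[e]["sample_id"])
        expo = windowed_exposures(bundle.diets[e], days, diet_windows[e], diet_exposures)
        if expo.isna().any().any():
            bad = list(expo.index[expo.isna().any(axis=1)])
            raise ValidationError(
                f"samples without full {diet_windows[e]}-day diet history in {e}: {bad}"
            )
        diet_rows.append(expo)
    diet = pd.concat(diet_rows)
    meta_all = pd.concat(metas.values(), ignore_index=True)
    diet_z = z_standardize_by_environment(diet, meta_all)
    diet_pcs = pca(diet_z, n_components=2)

    meta_indexed = meta_all.set_index("sample_id").loc[sample_ids]
    frame = pd.DataFrame(
        {
            "PC1_micro": micro.coordinates["PC1"],
            "PC2_micro": micro.coordinates["PC2"],
            "PC1_diet": diet_pcs.coordinates["PC1"].reindex(sample_ids),
            "PC2_diet": diet_pcs.coordinates["PC2"].reindex(sample_ids),
            "Probiotic": (meta_indexed["phase"] == PHASE_PROBIOTIC).astype(int),
            "Environment": meta_indexed["environment"],
        }
    )
    if len(frame) <= len(MODEL_TERMS) + 1:
        raise ValidationError(
            f"{len(frame)} samples cannot identify {len(MODEL_TERMS) + 1} parameters"
        )
    return ModelFrame(data=frame, taxa=list(taxa), diet_exposures=diet_exposures)


def _design_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Full-rank design with sum-to-zero (±1) factor coding."""
    env = data["Environment"].map({IN_VIVO: 1.0, IN_VITRO: -1.0})
    if env.isna().any():
        raise ValidationError("Environment must be in_vivo/in_vitro")
    prob = data["Probiotic"].astype(float) * 2.0 - 1.0
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    X["PC1_diet"] = data["PC1_diet"].astype(float)
    X["PC2_diet"] = data["PC2_diet"].astype(float)
    X["Probiotic"] = prob
    X["Environment"] = env
    X["PC1_diet:Environment"] = X["PC1_diet"] * env
    X["PC2_diet:Environment"] = X["PC2_diet"] * env
    X["Probiotic:Environment"] = prob * env
    return X


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_type3_anova(frame: ModelFrame, response: str = "PC1_micro") -> ModelReport:
    """Fit the divergence model and test each term with Type III SS.

    For every term T, ``SS_T = SSE(model without T) - SSE(full model)``
    with all other terms (including interactions) retained, under
    sum-to-zero coding; ``F = (SS_T / df_T) / (SSE_full / df_res)``.
    """
    if response not in ("PC1_micro", "PC2_micro"):
        raise ValidationError(f"response must be PC1_micro or PC2_micro, got {response!r}")
    data = frame.data
    X = _design_matrix(data)
    y = data[response].to_numpy(dtype=float)
    Xm = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < X.shape[1]:
        aliased = []
        base_rank = 0
        for j, col in enumerate(X.columns):
            r = np.linalg.matrix_rank(Xm[:, : j + 1])
            if r == base_rank:
                aliased.append(col)
            base_rank = r
        raise ValidationError(f"design matrix is rank deficient; aliased terms: {aliased}")
    n, p = Xm.shape
    sse_full = _sse(Xm, y)
    df_res = n - p
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    mse = sse_full / df_res
    total_ss = float(((y - y.mean()) ** 2).sum())
    rows = {}
    for term in MODEL_TERMS:
        keep = [c for c in X.columns if c != term]
        ss = _sse(X[keep].to_numpy(dtype=float), y) - sse_full
        ss = max(ss, 0.0)
        F = (ss / 1.0) / mse if mse > 0 else np.inf
        pval = float(stats.f.sf(F, 1, df_res)) if np.isfinite(F) else 0.0
        rows[term] = dict(
            sum_sq=ss,
            df=1,
            F=F,
            p=pval,
            var_share=ss / total_ss if total_ss > 0 else np.nan,
            partial_eta_sq=ss / (ss + sse_full) if (ss + sse_full) > 0 else np.nan,
        )
    rows["Residual"] = dict(
        sum_sq=sse_full, df=df_res, F=np.nan, p=np.nan,
        var_share=sse_full / total_ss if total_ss > 0 else np.nan,
        partial_eta_sq=np.nan,
    )
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    return ModelReport(
        response=response,
        table=pd.DataFrame.from_dict(rows, orient="index"),
        coefficients=pd.Series(beta, index=X.columns),
        total_ss=total_ss,
    )


def diet_environment_interaction_test(
    frame: ModelFrame, response: str = "PC1_micro"
) -> tuple[float, float]:
    """Joint Type III test of the diet × Environment interaction block.

    The diet signal is summarised in two PCs, and which of them carries
    a planted environment-specific diet response is a rotational
    accident, so "does the diet effect differ by environment?" is
    answered by dropping *both* ``PC_diet:Environment`` columns at once
    (a 2-df F test) rather than per-term.  Returns ``(F, p)``.
    """
    data = frame.data
    X = _design_matrix(data)
    y = data[response].to_numpy(dtype=float)
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    sse_full = _sse(Xm, y)
    df_res = n - p
    keep = [c for c in X.columns if c not in ("PC1_diet:Environment", "PC2_diet:Environment")]
    ss = max(_sse(X[keep].to_numpy(dtype=float), y) - sse_full, 0.0)
    F = (ss / 2.0) / (sse_full / df_res)
    return float(F), float(stats.f.sf(F, 2, df_res))
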