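"""Moving-average sensitivity analysis of diet–microbiota coupling.

Microbial responses to diet can lag behind intake by days, so each
macronutrient exposure is summarised as a trailing mean over a window
of ``w`` days ending the day *before* sampling (the 24-hour analysis is
the ``w = 1`` case).  For each window length, a taxon counts as a
*responder* if its abundance correlates positively (Spearman ρ above a
threshold, default 0.7) with at least one exposure; the optimal window
per environment is the one yielding the most responders, ties going to
the shortest window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import exposures as ex
from .community_metrics import prevalence_filter, relative_abundance
from .ordination import clr_transform
from .tables_io import DietDiary, StudyBundle, ValidationError

DEFAULT_RHO_THRESHOLD = 0.7
DEFAULT_W_RANGE = range(1, 15)


def default_min_prevalence(n_samples: int) -> int:
    """Prevalence cutoff used when none is configured: three quarters of
    the samples, rounded down (9 of 12; 8 of 11)."""
    return max(1, int(np.floor(0.75 * n_samples)))


def trailing_mean(series: pd.Series, w: int, day: int) -> float:
    """Mean of the ``w`` values on days ``day - w`` … ``day - 1``.

    Returns NaN when any of those days is absent from the series, so
    that samples without full diet history are excluded rather than
    averaged over a shortened window.
    """
    if w < 1:
        raise ValidationError(f"window length must be >= 1, got {w}")
    window = series.reindex(range(day - w, day))
    vals = window.to_numpy(dtype=float)
    if np.isnan(vals).any():
        return float("nan")
    return float(vals.mean())


def windowed_exposures(
    diary: DietDiary,
    days: pd.Series,
    w: int,
    exposures: list[str] | None = None,
) -> pd.DataFrame:
    """Trailing means of each exposure for each sample.

    ``days`` maps sample id → sampling day.  Rows are sample ids;
    samples whose window extends before the diary contain NaN.
    """
    exposures = exposures or [c for c in ex.ALL_EXPOSURES if c in diary.exposure_names]
    out = {}
    for exposure in exposures:
        s = diary.series(exposure)
        out[exposure] = [trailing_mean(s, w, int(d)) for d in days]
    return pd.DataFrame(out, index=days.index.copy())


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, x)


def spearman_matrix(abundance: pd.DataFrame, exposures: pd.DataFrame) -> pd.DataFrame:
    """Spearman ρ between every taxon row and every exposure column.

    ``abundance`` is taxa × samples, ``exposures`` samples × exposures,
    over the same samples in the same order.  Pairs involving a
    constant series get NaN.
    """
    a = abundance.to_numpy(dtype=float)
    e = exposures.to_numpy(dtype=float).T
    ra = _rank_rows(a)
    re = _rank_rows(e)
    ra = ra - ra.mean(axis=1, keepdims=True)
    re = re - re.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra**2).sum(axis=1))
    se = np.sqrt((re**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra @ re.T) / np.outer(sa, se)
        rho[~np.isfinite(rho)] = np.nan
    return pd.DataFrame(rho, index=abundance.index, columns=exposures.columns)


def responder_count(
    abundance: pd.DataFrame,
    diary: DietDiary,
    days: pd.Series,
    w: int,
    threshold: float = DEFAULT_RHO_THRESHOLD,
    exposures: list[str] | None = None,
) -> tuple[int, pd.DataFrame]:
    """Count taxa responding to at least one exposure at window ``w``.

    ``abundance`` holds per-sample taxon values (CLR or relative
    abundance) with samples as columns matching ``days``.  Samples
    without full window history are dropped; at least 4 must remain.
    Returns the responder count and the full ρ table.
    """
    expo = windowed_exposures(diary, days, w, exposures)
    usable = expo.dropna().index
    if len(usable) < 4:
        raise ValidationError(
            f"only {len(usable)} samples have full {w}-day diet history; >= 4 required"
        )
    rho = spearman_matrix(abundance[list(usable)], expo.loc[usable])
    with np.errstate(invalid="ignore"):
        best = np.nanmax(np.where(np.isnan(rho.to_numpy()), -np.inf, rho.to_numpy()), axis=1)
    count = int((best > threshold).sum())
    return count, rho


@dataclass
class LagSweepResult:
    """Responder counts per window per environment.

    ``counts`` is indexed by window length with one column per
    environment; ``rho`` maps (environment, w) to the full Spearman
    table; ``optimal`` holds the selected window per environment.
    """

    counts: pd.DataFrame
    rho: dict[tuple[str, int], pd.DataFrame] = field(repr=False)
    optimal: dict[str, int] = field(default_factory=dict)


def select_optimal_window(counts: pd.Series) -> int:
    """Window attaining the maximum responder count; ties → smallest."""
    best = counts.max()
    return int(min(w for w, c in counts.items() if c == best))


def window_sweep(
    bundle: StudyBundle,
    w_range=DEFAULT_W_RANGE,
    threshold: float = DEFAULT_RHO_THRESHOLD,
    use_clr: bool = True,
    pseudocount: float = 0.5,
    min_prevalence: dict[str, int] | None = None,
    include_excluded: bool = False,
) -> LagSweepResult:
    """Run the responder scan over a range of window lengths.

    Taxa tested in each environment are its prevalent genera (detected
    in at least ``min_prevalence[env]`` samples; default three quarters
    of samples).  Abundances enter the correlation as CLR values by
    default, or as relative abundances with ``use_clr=False``.
    """
    w_list = sorted(set(int(w) for w in w_range))
    if not w_list:
        raise ValidationError("w_range is empty")
    counts: dict[str, dict[int, int]] = {}
    rho_tables: dict[tuple[str, int], pd.DataFrame] = {}
    for env, diary in bundle.diets.items():
        meta = bundle.metadata_for(env, include_excluded)
        if meta.empty:
            continue
        table = bundle.abundance.select_samples(list(meta["sample_id"]))
        cutoff = (min_prevalence or {}).get(env, default_min_prevalence(len(meta)))
        table = prevalence_filter(table, cutoff)
        if use_clr:
            values = clr_transform(table, pseudocount).values.T
        else:
            values = relative_abundance(table)
        days = pd.Series(meta["day"].to_numpy(), index=meta["sample_id"])
        counts[env] = {}
        for w in w_list:
            c, rho = responder_count(values, diary, days, w, threshold)
            counts[env][w] = c
            rho_tables[(env, w)] = rho
    count_df = pd.DataFrame(counts).rename_axis("w")
    optimal = {env: select_optimal_window(count_df[env]) for env in count_df.columns}
    return LagSweepResult(counts=count_df, rho=rho_tables, optimal=optimal)
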