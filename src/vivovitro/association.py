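"""Correlation and paired-comparison statistics.

Pairwise Spearman correlations between windowed macronutrient means and
microbiota descriptors (alpha diversity, F/B ratio, prevalent-genus
abundances), with multiple-testing adjustment applied *within* each
descriptor family, and the paired Wilcoxon signed-rank comparison of
diversity between environments.

Small-sample p-values are exact: Spearman uses the full permutation
null for n ≤ 9 and the t approximation beyond; Wilcoxon uses the exact
signed-rank distribution (computed by convolution over sign
assignments, so midranks from ties are handled) for n ≤ 25 and a
continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .community_metrics import alpha_diversity, fb_ratio, prevalence_filter, shared_taxa
from .lag_window import default_min_prevalence, windowed_exposures
from .ordination import clr_transform
from .tables_io import IN_VITRO, IN_VIVO, StudyBundle, ValidationError

SPEARMAN_EXACT_N = 9
WILCOXON_EXACT_N = 25

FAMILY_ALPHA = "alpha_diversity"
FAMILY_FB = "fb_ratio"
FAMILY_GENERA = "genera"


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.intp)


def spearman(x, y, exact_n: int = SPEARMAN_EXACT_N) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ρ is the Pearson correlation of midranks.  For n ≤ ``exact_n`` the
    p-value is exact, from the full permutation distribution of one
    margin's ranks; otherwise the t approximation is used.  Constant
    input raises (ρ undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D series")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("constant series: Spearman rho is undefined")
    rx_c, ry_c = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rho = float((rx_c * ry_c).sum() / denom)
    if n <= exact_n:
        perms = _all_permutations(n)
        # statistic is monotone in Σ rx[i]·ry[π(i)]
        s_obs = (rx_c * ry_c).sum()
        s_all = ry_c[perms] @ rx_c
        tol = 1e-9 * max(1.0, abs(s_obs))
        p = float((np.abs(s_all) >= abs(s_obs) - tol).mean())
    else:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg step-up or Bonferroni adjusted p-values,
    returned in the original order."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise ValidationError(f"unknown adjustment method {method!r}")


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic by enumerating
    the 2^n sign assignments via convolution over doubled ranks."""
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(dist)
        shifted[d:] = dist[: total + 1 - d]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2 * min(lower, upper)))


def wilcoxon_signed_rank(pairs, exact_n: int = WILCOXON_EXACT_N) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (two-sided).

    ``pairs`` is a sequence of (a, b) pairs or an array of differences'
    two columns; zero differences are dropped.  Returns ``(W_plus, p)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        d = arr[:, 0] - arr[:, 1]
    elif arr.ndim == 1:
        d = arr
    else:
        raise ValidationError("pairs must be (n, 2) pairs or a 1-D difference vector")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_n:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4
        t_adj = 0.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        t_adj = (tie_counts**3 - tie_counts).sum() / 48
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - t_adj)
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
        p = float(2 * stats.norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


@dataclass(frozen=True)
class CorrelationReport:
    """Long-format descriptor × exposure Spearman results.

    ``table`` columns: environment, family, descriptor, exposure, rho,
    p, p_adj.  Adjustment is applied separately within each
    (environment, family) group.  ``abundance_scale`` records whether
    genus abundances entered as CLR or relative values.
    """

    table: pd.DataFrame
    method: str
    abundance_scale: str
    windows: dict[str, int]


def correlation_report(
    bundle: StudyBundle,
    windows: dict[str, int],
    method: str = "bh",
    use_clr: bool = True,
    pseudocount: float = 0.5,
    min_prevalence: dict[str, int] | None = None,
) -> CorrelationReport:
    """Correlate windowed exposures with microbiota descriptors.

    Descriptors per environment: the three alpha-diversity indices
    (family ``alpha_diversity``), the F/B ratio (family ``fb_ratio``)
    and the abundances of the genera prevalent in both environments
    (family ``genera``).  The two environments are analysed separately
    and never pooled; p-values are adjusted within each (environment,
    family).
    """
    # shared prevalent genera across environments
    filtered = {}
    for env in (IN_VIVO, IN_VITRO):
        meta = bundle.metadata_for(env)
        tab = bundle.abundance.select_samples(list(meta["sample_id"]))
        cutoff = (min_prevalence or {}).get(env, default_min_prevalence(len(meta)))
        filtered[env] = prevalence_filter(tab, cutoff)
    shared = shared_taxa(filtered[IN_VIVO], filtered[IN_VITRO])

    rows = []
    for env in (IN_VIVO, IN_VITRO):
        meta = bundle.metadata_for(env)
        ids = list(meta["sample_id"])
        table = bundle.abundance.select_samples(ids)
        days = pd.Series(meta["day"].to_numpy(), index=ids)
        expo = windowed_exposures(bundle.diets[env], days, windows[env])
        usable = list(expo.dropna().index)
        expo = expo.loc[usable]
        div = alpha_diversity(table).loc[usable]
        fb = fb_ratio(table).loc[usable]
        if use_clr:
            # CLR over the full composition, then subset: computing CLR
            # within the shared-genus subcomposition would let one
            # responder's swing contaminate every other genus through
            # the subcomposition's geometric mean
            genus_vals = clr_transform(table, pseudocount).values.T.loc[shared]
        else:
            from .community_metrics import relative_abundance

            genus_vals = relative_abundance(table).loc[shared]
        genus_vals = genus_vals[usable]
        descriptors = [(FAMILY_ALPHA, c, div[c]) for c in ("chao1", "shannon", "simpson")]
        descriptors.append((FAMILY_FB, "fb_ratio", fb))
        for taxon in genus_vals.index:
            descriptors.append((FAMILY_GENERA, taxon[1], genus_vals.loc[taxon]))
        for family, name, series in descriptors:
            vals = series.to_numpy(dtype=float)
            for exposure in expo.columns:
                evals = expo[exposure].to_numpy(dtype=float)
                try:
                    rho, p = spearman(vals, evals)
                except ValidationError:
                    rho, p = np.nan, np.nan
                rows.append(
                    dict(environment=env, family=family, descriptor=name,
                         exposure=exposure, rho=rho, p=p)
                )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for (_, _), idx in out.groupby(["environment", "family"]).groups.items():
        sub = out.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            out.loc[sub.index[ok], "p_adj"] = adjust_pvalues(sub.loc[ok, "p"], method)
    return CorrelationReport(
        table=out,
        method=method,
        abundance_scale="clr" if use_clr else "relative",
        windows=dict(windows),
    )


def environment_diversity_test(
    bundle: StudyBundle, index: str = "chao1"
) -> tuple[float, float, int]:
    """Paired Wilcoxon comparison of an alpha-diversity index between
    environments, pairing samples by sampling-day rank within each
    environment.  Returns (W_plus, p, n_pairs)."""
    series = {}
    for env in (IN_VIVO, IN_VITRO):
        meta = bundle.metadata_for(env).sort_values("day")
        div = alpha_diversity(bundle.abundance.select_samples(list(meta["sample_id"])))
        series[env] = div[index].to_numpy()
    n = min(len(series[IN_VIVO]), len(series[IN_VITRO]))
    pairs = np.column_stack([series[IN_VIVO][-n:], series[IN_VITRO][-n:]])
    w, p = wilcoxon_signed_rank(pairs)
    return w, p, n
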