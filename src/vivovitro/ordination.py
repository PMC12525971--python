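"""Compositional transform and unsupervised sample structure.

Count compositions carry only relative information, so genus/phylum
counts are centred log-ratio (CLR) transformed before any Euclidean
analysis: ``clr(x)_j = ln((x_j + c) / g(x + c))`` with pseudocount
``c`` and geometric mean ``g`` per sample.  Sample grouping is explored
with presence/absence Jaccard distances embedded by principal
coordinate analysis (PCoA), and score extraction uses PCA with a fixed
sign convention so results are reproducible across linear-algebra
backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.decomposition import PCA as _PCA

from .tables_io import AbundanceTable, ValidationError


@dataclass(frozen=True)
class CLRMatrix:
    """CLR-transformed abundances (samples × taxa); rows sum to zero."""

    values: pd.DataFrame
    pseudocount: float

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1).to_numpy()
        if len(sums) and np.abs(sums).max() > 1e-9:
            raise ValidationError("CLR rows must sum to 0")


@dataclass(frozen=True)
class OrdinationResult:
    """Coordinates with eigenvalues and per-axis variance proportions.

    ``loadings`` (features × axes, orthonormal columns) is populated by
    PCA only.
    """

    coordinates: pd.DataFrame
    eigenvalues: pd.Series
    proportion_explained: pd.Series
    loadings: pd.DataFrame | None = None


def clr_transform(table: AbundanceTable, pseudocount: float = 0.5) -> CLRMatrix:
    """CLR-transform a count table with a pseudocount for zeros."""
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be positive, got {pseudocount}")
    x = table.counts.to_numpy(dtype=float).T + pseudocount  # samples × taxa
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    values = pd.DataFrame(clr, index=table.samples, columns=table.counts.index)
    return CLRMatrix(values=values, pseudocount=pseudocount)


def jaccard_distances(table: AbundanceTable) -> pd.DataFrame:
    """Presence/absence Jaccard distance matrix between samples."""
    presence = (table.counts.to_numpy() >= 1).T  # samples × taxa
    empty = [s for s, row in zip(table.samples, presence) if not row.any()]
    if empty:
        raise ValidationError(f"samples with empty presence sets: {empty}")
    d = squareform(pdist(presence, metric="jaccard"))
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


def pcoa_jaccard(table: AbundanceTable) -> OrdinationResult:
    """PCoA of presence/absence Jaccard distances.

    Negative eigenvalues (Jaccard is not generally Euclidean-embeddable)
    are reported as-is; coordinates are built from the positive ones.
    """
    if len(table.samples) < 3:
        raise ValidationError("PCoA requires at least 3 samples")
    d = jaccard_distances(table)
    res = _skbio_pcoa(
        DistanceMatrix(d.to_numpy(), ids=table.samples),
        method="eigh",
        number_of_dimensions=len(table.samples),
    )
    coords = res.samples
    coords.index = pd.Index(table.samples, name="sample_id")
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=res.eigvals,
        proportion_explained=res.proportion_explained,
    )


def flag_pcoa_outliers(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    n_mads: float = 3.0,
) -> list[str]:
    """Optional automatic outlier flagger (off by default in configs).

    A sample is flagged when its median PCoA distance to the other
    samples of its own environment exceeds that environment's median of
    such medians by more than ``n_mads`` median absolute deviations.
    The published outliers were identified visually; this rule is a
    reproducible stand-in and is deliberately conservative.
    """
    res = pcoa_jaccard(table)
    coords = res.coordinates.to_numpy()
    d = pd.DataFrame(
        squareform(pdist(coords)), index=table.samples, columns=table.samples
    )
    flagged: list[str] = []
    env = metadata.set_index("sample_id")["environment"]
    for _, ids in env.groupby(env).groups.items():
        ids = [s for s in ids if s in d.index]
        if len(ids) < 3:
            continue
        med = pd.Series(
            {s: d.loc[s, [t for t in ids if t != s]].median() for s in ids}
        )
        center = med.median()
        # floor the MAD so float fuzz on identical medians cannot flag
        mad = max((med - center).abs().median(), 1e-9 * max(center, 1.0))
        flagged.extend(med.index[med > center + n_mads * mad])
    return sorted(flagged)


def pca(data: pd.DataFrame, n_components: int = 2, scale: bool = False) -> OrdinationResult:
    """Centred (optionally unit-scaled) PCA of a samples × features matrix.

    Sign convention: within each component the entry of largest
    absolute loading is made positive, and scores are flipped to match.
    """
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("PCA input must be finite")
    n_components = int(n_components)
    if n_components > min(X.shape):
        raise ValidationError(
            f"n_components {n_components} exceeds min(n_samples, n_features) {min(X.shape)}"
        )
    if scale:
        sd = X.std(axis=0, ddof=1)
        const = [str(c) for c, s in zip(data.columns, sd) if s == 0]
        if const:
            raise ValidationError(f"constant columns cannot be unit-scaled: {const}")
        X = (X - X.mean(axis=0)) / sd
    model = _PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    components = model.components_  # n_components × features
    for k in range(n_components):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    axes = [f"PC{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        coordinates=pd.DataFrame(scores, index=data.index, columns=axes),
        eigenvalues=pd.Series(model.explained_variance_, index=axes),
        proportion_explained=pd.Series(model.explained_variance_ratio_, index=axes),
        loadings=pd.DataFrame(components.T, index=data.columns, columns=axes),
    )
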