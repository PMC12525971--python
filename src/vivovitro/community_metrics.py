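"""Per-sample community descriptors and taxon filters.

Relative abundances, prevalence filtering, shared-genus sets between
the two culture environments, alpha diversity (bias-corrected Chao1,
Shannon entropy in nats, Gini–Simpson), and the Firmicutes-to-
Bacteroidetes (F/B) ratio.

Diversity indices are delegated to scikit-bio's implementations with
the conventions fixed here (natural-log Shannon, bias-corrected Chao1,
Gini–Simpson form).  No rarefaction is applied before diversity by
default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import enspie
from skbio.diversity.alpha import shannon as _shannon
from skbio.diversity.alpha import simpson as _simpson

from .tables_io import AbundanceTable, ValidationError

FIRMICUTES = "Firmicutes"
BACTEROIDETES = "Bacteroidetes"


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Proportion matrix (taxa × samples); every column sums to one."""
    counts = table.counts
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValidationError(f"all-zero samples: {empty}")
    return counts / totals


def prevalence_filter(table: AbundanceTable, min_samples: int) -> AbundanceTable:
    """Retain taxa detected (count ≥ 1) in at least ``min_samples`` samples."""
    n = len(table.samples)
    if not (0 < min_samples <= n):
        raise ValidationError(f"min_samples must be in 1..{n}, got {min_samples}")
    present_in = (table.counts >= 1).sum(axis=1)
    return AbundanceTable(table.counts.loc[present_in >= min_samples])


def shared_taxa(table_a: AbundanceTable, table_b: AbundanceTable) -> list[tuple[str, str]]:
    """(phylum, genus) pairs present in both tables, in ``table_a`` order."""
    in_b = set(table_b.taxa)
    return [t for t in table_a.taxa if t in in_b]


def alpha_diversity(
    table: AbundanceTable,
    simpson_kind: str = "gini",
    rarefy_to: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Chao1, Shannon and Simpson indices per sample.

    Chao1 is the bias-corrected estimator
    ``S_obs + F1(F1 - 1) / (2 (F2 + 1))`` built from singleton (F1) and
    doubleton (F2) counts; Shannon is ``-Σ p ln p`` in nats; Simpson is
    the Gini–Simpson index ``1 - Σ p²`` (or inverse Simpson
    ``1 / Σ p²`` with ``simpson_kind="inverse"``).

    ``rarefy_to`` subsamples every sample to a common depth (without
    replacement, seeded) before computing indices; the default is no
    rarefaction.
    """
    if simpson_kind not in ("gini", "inverse"):
        raise ValidationError(f"simpson_kind must be 'gini' or 'inverse', got {simpson_kind!r}")
    rng = np.random.default_rng(seed)
    rows = {}
    for sample in table.samples:
        counts = table.counts[sample].to_numpy()
        if counts.sum() == 0:
            raise ValidationError(f"sample {sample!r} is empty")
        if rarefy_to is not None:
            if counts.sum() < rarefy_to:
                raise ValidationError(
                    f"sample {sample!r} has fewer than {rarefy_to} reads"
                )
            counts = rng.multivariate_hypergeometric(counts, rarefy_to)
        simpson = _simpson(counts) if simpson_kind == "gini" else enspie(counts)
        rows[sample] = {
            "chao1": float(_chao1(counts, bias_corrected=True)),
            "shannon": float(_shannon(counts, base=np.e)),
            "simpson": float(simpson),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def fb_ratio(
    table: AbundanceTable,
    firmicutes: str = FIRMICUTES,
    bacteroidetes: str = BACTEROIDETES,
) -> pd.Series:
    """Per-sample Firmicutes / Bacteroidetes count ratio.

    Samples with no Bacteroidetes counts get NaN (flagged undefined)
    rather than infinity.
    """
    phyla = table.counts.index.get_level_values("phylum")
    f_tot = table.counts.loc[phyla == firmicutes].sum(axis=0)
    b_tot = table.counts.loc[phyla == bacteroidetes].sum(axis=0)
    ratio = f_tot / b_tot.where(b_tot > 0)
    ratio.name = "fb_ratio"
    return ratio
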