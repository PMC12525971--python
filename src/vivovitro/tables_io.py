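"""Tabular artifacts of the study and their validation.

The pipeline operates on four plain-text artifacts:

* an abundance table — genus-level counts per sample, with phylum
  taxonomy, as a TSV whose first two columns are ``phylum`` and
  ``genus`` and whose remaining columns are sample identifiers;
* a sample metadata table — CSV with ``sample_id``, ``environment``
  (``in_vivo``/``in_vitro``), experimental ``day``, intervention
  ``phase`` and an ``excluded`` flag;
* a diet diary per environment — CSV with a ``day`` column and one
  column per macronutrient exposure (g/day in vivo, g/L in vitro);
* the assembled, cross-validated :class:`StudyBundle`.

All parsing is strict: malformed input raises a typed error rather than
being silently coerced, and write∘read is the identity on valid tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposures import ALL_EXPOSURES

logger = logging.getLogger(__name__)

IN_VIVO = "in_vivo"
IN_VITRO = "in_vitro"
ENVIRONMENTS = (IN_VIVO, IN_VITRO)

PHASE_BASELINE = "baseline"
PHASE_PROBIOTIC = "probiotic_plus_diet"
PHASE_DIET_ONLY = "diet_only"
PHASES = (PHASE_BASELINE, PHASE_PROBIOTIC, PHASE_DIET_ONLY)

METADATA_COLUMNS = ["sample_id", "environment", "day", "phase", "excluded"]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """A structurally well-formed table violates a domain invariant."""


class JoinError(ValidationError):
    """Tables that must be joined do not cover each other."""


def phase_for_day(day: int, probiotic_days: tuple[int, int] = (1, 14)) -> str:
    """Intervention phase implied by an experimental day.

    Days at or before 0 are baseline; days within ``probiotic_days``
    (inclusive) combine the probiotic with the dietary intervention;
    later days continue the diet during probiotic washout.
    """
    lo, hi = probiotic_days
    if day <= 0:
        return PHASE_BASELINE
    if lo <= day <= hi:
        return PHASE_PROBIOTIC
    return PHASE_DIET_ONLY


@dataclass(frozen=True)
class AbundanceTable:
    """Taxon-by-sample count matrix with (phylum, genus) taxonomy.

    ``counts`` is indexed by a (phylum, genus) MultiIndex; columns are
    sample identifiers; cells are non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if not isinstance(c.index, pd.MultiIndex) or c.index.names != ["phylum", "genus"]:
            raise ValidationError("counts must be indexed by (phylum, genus)")
        dup = c.index[c.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate taxa: {sorted(set(dup.tolist()))}")
        dup_s = c.columns[c.columns.duplicated()]
        if len(dup_s):
            raise ValidationError(f"duplicate sample ids: {sorted(set(dup_s))}")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            raise ValidationError("counts must be integers")
        if (c.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        empty = c.columns[c.sum(axis=0) == 0]
        if len(empty):
            raise ValidationError(f"samples with zero total count: {list(empty)}")

    @property
    def taxa(self) -> list[tuple[str, str]]:
        """(phylum, genus) pairs, in table order."""
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genera(self) -> list[str]:
        return list(self.counts.index.get_level_values("genus"))

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        return AbundanceTable(self.counts[sample_ids])

    def select_taxa(self, taxa: list[tuple[str, str]]) -> "AbundanceTable":
        return AbundanceTable(self.counts.loc[taxa])

    def by_phylum(self) -> "AbundanceTable":
        """Aggregate counts to phylum level (genus label = phylum)."""
        agg = self.counts.groupby(level="phylum", sort=False).sum()
        agg.index = pd.MultiIndex.from_arrays(
            [agg.index, agg.index], names=["phylum", "genus"]
        )
        return AbundanceTable(agg)


@dataclass(frozen=True)
class DietDiary:
    """Daily macronutrient exposure series for one environment.

    ``values`` is indexed by integer experimental day (contiguous) with
    one column per exposure; ``units`` is ``g_per_day`` for the
    volunteer's intake diary or ``g_per_l`` for SHIME feed
    concentrations.
    """

    values: pd.DataFrame
    units: str = "g_per_day"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.name != "day":
            raise ValidationError("diary must be indexed by 'day'")
        days = v.index.to_numpy()
        if len(days) == 0:
            raise ValidationError("diary is empty")
        expected = np.arange(days.min(), days.max() + 1)
        missing = sorted(set(expected) - set(days))
        if missing:
            raise ValidationError(f"diary has gaps, missing days: {missing}")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate exposure names")
        arr = v.to_numpy(dtype=float)
        if arr.size and np.nanmin(arr) < 0:
            bad = v.columns[(v < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative exposure values in: {bad}")

    @property
    def days(self) -> list[int]:
        return list(self.values.index)

    @property
    def exposure_names(self) -> list[str]:
        return list(self.values.columns)

    def series(self, exposure: str) -> pd.Series:
        if exposure not in self.values.columns:
            raise ValidationError(
                f"unknown exposure {exposure!r}; known: {self.exposure_names}"
            )
        return self.values[exposure]


@dataclass
class StudyBundle:
    """Joined, validated study artifacts for both environments."""

    abundance: AbundanceTable
    metadata: pd.DataFrame
    diets: dict[str, DietDiary]
    n_retained: int = field(init=False)

    def __post_init__(self) -> None:
        validate_metadata(self.metadata)
        meta_ids = set(self.metadata["sample_id"])
        orphan = [s for s in self.abundance.samples if s not in meta_ids]
        if orphan:
            raise JoinError(f"abundance samples without metadata: {orphan}")
        for env, sub in self.metadata.groupby("environment"):
            if env not in self.diets:
                raise JoinError(f"no diet diary for environment {env!r}")
            days = set(self.diets[env].days)
            uncovered = sorted(set(sub["day"]) - days)
            if uncovered:
                raise JoinError(
                    f"{env} sample days not covered by its diary: {uncovered}"
                )
        self.n_retained = int((~self.metadata["excluded"]).sum())

    def metadata_for(self, environment: str, include_excluded: bool = False) -> pd.DataFrame:
        m = self.metadata[self.metadata["environment"] == environment]
        if not include_excluded:
            m = m[~m["excluded"]]
        return m.reset_index(drop=True)

    def retained_samples(self, environment: str | None = None) -> list[str]:
        m = self.metadata[~self.metadata["excluded"]]
        if environment is not None:
            m = m[m["environment"] == environment]
        return list(m["sample_id"])

    def abundance_for(self, environment: str, include_excluded: bool = False) -> AbundanceTable:
        ids = (
            list(self.metadata_for(environment, include_excluded)["sample_id"])
        )
        return self.abundance.select_samples(ids)

    def day_of(self, sample_id: str) -> int:
        row = self.metadata[self.metadata["sample_id"] == sample_id]
        if row.empty:
            raise JoinError(f"unknown sample {sample_id!r}")
        return int(row["day"].iloc[0])


def validate_metadata(metadata: pd.DataFrame, probiotic_days: tuple[int, int] = (1, 14)) -> None:
    """Check the sample-metadata invariants; raise :class:`ValidationError`."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    dup = metadata["sample_id"][metadata["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample ids: {sorted(set(dup))}")
    bad_env = sorted(set(metadata["environment"]) - set(ENVIRONMENTS))
    if bad_env:
        raise ValidationError(f"unknown environments: {bad_env}")
    for _, row in metadata.iterrows():
        expected = phase_for_day(int(row["day"]), probiotic_days)
        if row["phase"] != expected:
            raise ValidationError(
                f"sample {row['sample_id']}: phase {row['phase']!r} inconsistent "
                f"with day {row['day']} (expected {expected!r})"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path, format: str = "tsv") -> AbundanceTable:
    """Read a genus/phylum count TSV into an :class:`AbundanceTable`."""
    if format != "tsv":
        raise FormatError(f"unsupported format {format!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if list(raw.columns[:2]) != ["phylum", "genus"]:
        raise FormatError(
            f"{path}: first two columns must be 'phylum', 'genus', "
            f"got {list(raw.columns[:2])}"
        )
    taxa = list(zip(raw["phylum"], raw["genus"]))
    seen: set[tuple[str, str]] = set()
    for i, t in enumerate(taxa):
        if t in seen:
            raise FormatError(f"{path}: duplicate taxon {t} at row {i + 2}")
        seen.add(t)
    sample_ids = list(raw.columns[2:])
    data = np.empty((len(raw), len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        for i, cell in enumerate(raw[s]):
            try:
                val = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at row {i + 2}, column {s!r}"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}: negative count {val} at row {i + 2}, column {s!r}"
                )
            data[i, j] = val
    counts = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(taxa, names=["phylum", "genus"]),
        columns=sample_ids,
    )
    return AbundanceTable(counts)


def write_abundance_table(table: AbundanceTable, path) -> None:
    out = table.counts.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    meta = meta[METADATA_COLUMNS].copy()
    meta["day"] = meta["day"].astype(int)
    meta["excluded"] = meta["excluded"].astype(bool)
    validate_metadata(meta)
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata[METADATA_COLUMNS].to_csv(path, index=False)


def read_diet_diary(path, units: str = "g_per_day") -> DietDiary:
    """Read a diet diary CSV (day column + one column per exposure)."""
    raw = pd.read_csv(path)
    if "day" not in raw.columns:
        raise FormatError(f"{path}: diary must have a 'day' column")
    try:
        raw["day"] = raw["day"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer day: {exc}") from None
    values = raw.set_index("day").astype(float)
    unknown = [c for c in values.columns if c not in ALL_EXPOSURES]
    if unknown:
        logger.warning("%s: non-canonical exposure columns %s", path, unknown)
    return DietDiary(values, units=units)


def write_diet_diary(diary: DietDiary, path) -> None:
    diary.values.reset_index().to_csv(path, index=False)


def assemble_bundle(
    abundance: AbundanceTable,
    metadata: pd.DataFrame,
    diets: dict[str, DietDiary],
    exclusions: list[str] | None = None,
) -> StudyBundle:
    """Join the study artifacts, marking the named samples excluded.

    Exclusion ids absent from the data are logged as warnings rather
    than raised: the outlier list is configuration, and a run on a
    subset of samples should not fail because of it.  The number of
    retained samples is reported on the returned bundle.
    """
    meta = metadata.copy().reset_index(drop=True)
    exclusions = exclusions or []
    known = set(meta["sample_id"])
    for sid in exclusions:
        if sid not in known:
            logger.warning("exclusion id %r not found in metadata; ignored", sid)
    meta["excluded"] = meta["excluded"] | meta["sample_id"].isin(exclusions)
    bundle = StudyBundle(abundance=abundance, metadata=meta, diets=diets)
    logger.info(
        "assembled bundle: %d samples, %d retained", len(meta), bundle.n_retained
    )
    return bundle
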