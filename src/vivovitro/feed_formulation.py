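"""Translate dietary intakes into SHIME feed-medium recipes.

The gut simulator is fed a defined medium; to mimic a volunteer's diet,
daily macronutrient intakes (g/day) are converted to feed-ingredient
concentrations (g/L) in four steps:

1. *Residues*: only the fraction of each macronutrient that escapes
   small-intestinal absorption reaches the colon.  Ileostomy-study
   estimates are used: 83% of fibre, 1.1% of sugars/carbohydrate, 16%
   of protein.
2. *Normalisation*: daily residues are rescaled so that the soluble
   fibre reaching the simulated colon matches a fixed target
   concentration (default 7.7 g/L, the standard feed's soluble fibre).
3. *Ingredient conversion*: nutrient-to-ingredient factors map residues
   onto medium ingredients (animal protein → special peptone 1:1,
   non-animal protein → yeast extract 1:1.54, resistant starch →
   starch, pectin → pectin, arabinogalactan + arabinoxylan → xylan +
   gum arabic).
4. *Glucose correction*: yeast extract itself contains 2.9% glucose, so
   the glucose ingredient is the sugars target minus that contribution.

The inverse mapping (:func:`recipe_to_nutrients`) recovers nutrient
targets from a recipe and is used for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import exposures as ex
from .reference import STANDARD_FEED_INGREDIENTS
from .tables_io import DietDiary, ValidationError

logger = logging.getLogger(__name__)

#: Nutrient classes accepted as intake, grouped by residue class.
PROTEIN_CLASSES = (ex.ANIMAL_PROTEIN, ex.NON_ANIMAL_PROTEIN)
FIBER_CLASSES = (ex.ARABINOGALACTAN, ex.ARABINOXYLAN, ex.AG_AX, ex.PECTIN, ex.RESISTANT_STARCH)
SUGAR_CLASSES = (ex.SUGARS,)
KNOWN_NUTRIENTS = PROTEIN_CLASSES + FIBER_CLASSES + SUGAR_CLASSES

INGREDIENTS = ["special_peptone", "yeast_extract", "xylan", "gum_arabic", "pectin", "starch", "glucose"]


def _default_residue_fractions() -> dict[str, float]:
    fr = {n: 0.16 for n in PROTEIN_CLASSES}
    fr.update({n: 0.83 for n in FIBER_CLASSES})
    fr.update({n: 0.011 for n in SUGAR_CLASSES})
    return fr


def _default_ingredient_factors() -> dict[str, tuple[str, float]]:
    return {
        ex.ANIMAL_PROTEIN: ("special_peptone", 1.0),
        ex.NON_ANIMAL_PROTEIN: ("yeast_extract", 1.54),
        ex.AG_AX: ("xylan_gum_arabic", 1.0),
        ex.PECTIN: ("pectin", 1.0),
        ex.RESISTANT_STARCH: ("starch", 1.0),
    }


@dataclass(frozen=True)
class ConversionSpec:
    """Parameters of the diet → feed conversion.

    ``xylan_gum_split`` sets the proportion in which the pooled
    arabinogalactan+arabinoxylan ingredient mass is divided between
    xylan and gum arabic; the default 0.5:1.2 is the standard feed's
    proportion.
    """

    residue_fractions: dict[str, float] = field(default_factory=_default_residue_fractions)
    ingredient_factors: dict[str, tuple[str, float]] = field(default_factory=_default_ingredient_factors)
    yeast_extract_glucose_fraction: float = 0.029
    soluble_fiber_target: float = 7.7
    xylan_gum_split: tuple[float, float] = (0.5, 1.2)

    def __post_init__(self) -> None:
        for n, f in self.residue_fractions.items():
            if not (0 < f <= 1):
                raise ValidationError(f"residue fraction for {n!r} not in (0,1]: {f}")
        for n, (_, f) in self.ingredient_factors.items():
            if f <= 0:
                raise ValidationError(f"ingredient factor for {n!r} not positive: {f}")
        if not (0 <= self.yeast_extract_glucose_fraction < 1):
            raise ValidationError("glucose fraction must be in [0,1)")
        if self.soluble_fiber_target <= 0:
            raise ValidationError("soluble fiber target must be positive")


@dataclass(frozen=True)
class ResidueProfile:
    """Per-nutrient residue mass reaching the colon (g/day)."""

    residues: dict[str, float]

    def __post_init__(self) -> None:
        for n, r in self.residues.items():
            if r < 0:
                raise ValidationError(f"negative residue for {n!r}: {r}")

    @property
    def soluble_fiber(self) -> float:
        """Sum of the fibre-class residues."""
        return float(sum(self.residues.get(n, 0.0) for n in FIBER_CLASSES))

    def scaled(self, k: float) -> "ResidueProfile":
        return ResidueProfile({n: k * r for n, r in self.residues.items()})


@dataclass(frozen=True)
class FeedRecipe:
    """Ingredient concentrations (g/L) of one SHIME feed medium.

    Mucin and L-cysteine are fixed constituents of every medium.
    """

    special_peptone: float = 0.0
    yeast_extract: float = 0.0
    xylan: float = 0.0
    gum_arabic: float = 0.0
    pectin: float = 0.0
    starch: float = 0.0
    glucose: float = 0.0
    mucin: float = 2.0
    l_cysteine: float = 0.5

    def __post_init__(self) -> None:
        for name, val in self.as_dict().items():
            if val < 0:
                raise ValidationError(f"negative ingredient {name!r}: {val}")

    def as_dict(self, constants: bool = True) -> dict[str, float]:
        d = {name: float(getattr(self, name)) for name in INGREDIENTS}
        if constants:
            d["mucin"] = float(self.mucin)
            d["l_cysteine"] = float(self.l_cysteine)
        return d

    @property
    def soluble_fiber_equivalent(self) -> float:
        """Fibre-ingredient sum (xylan + gum arabic + pectin + starch)."""
        return float(self.xylan + self.gum_arabic + self.pectin + self.starch)

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Ingredients at reporting precision (one decimal g/L)."""
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def compute_residues(intake: dict[str, float], spec: ConversionSpec) -> ResidueProfile:
    """Apply residue fractions to daily intakes (g/day → g/day).

    ``intake`` maps base nutrient classes to grams per day.  Derived
    quantities (total protein, soluble fibre, their ratio) are not
    accepted — soluble fibre is always recomputed as the sum of the
    fibre-class residues.  Supplying the pooled
    arabinogalactan+arabinoxylan class together with its individual
    components would double-count fibre and raises an error.
    """
    unknown = sorted(set(intake) - set(KNOWN_NUTRIENTS))
    if unknown:
        raise ValidationError(
            f"unknown nutrient classes {unknown}; known: {sorted(KNOWN_NUTRIENTS)}"
        )
    if ex.AG_AX in intake and (ex.ARABINOGALACTAN in intake or ex.ARABINOXYLAN in intake):
        raise ValidationError(
            "supply either the pooled arabinogalactan+arabinoxylan class or its "
            "components, not both"
        )
    residues = {}
    for nutrient, grams in intake.items():
        if grams < 0:
            raise ValidationError(f"negative intake for {nutrient!r}: {grams}")
        residues[nutrient] = grams * spec.residue_fractions[nutrient]
    return ResidueProfile(residues)


def nutrients_to_ingredients(nutrients: dict[str, float], spec: ConversionSpec) -> FeedRecipe:
    """Map nutrient targets (g/L) onto medium ingredients (g/L).

    The pooled fibre class is split between xylan and gum arabic in the
    configured proportion; glucose is corrected for the glucose content
    of yeast extract and clamped at zero (with a warning) if the
    correction exceeds the sugars target.
    """
    vals = dict(nutrients)
    agax = vals.pop(ex.AG_AX, 0.0)
    agax += vals.pop(ex.ARABINOGALACTAN, 0.0) + vals.pop(ex.ARABINOXYLAN, 0.0)
    sugars = vals.pop(ex.SUGARS, 0.0)
    amounts: dict[str, float] = {i: 0.0 for i in INGREDIENTS}
    for nutrient, target in vals.items():
        if nutrient not in spec.ingredient_factors:
            raise ValidationError(f"no ingredient factor for nutrient {nutrient!r}")
        ingredient, factor = spec.ingredient_factors[nutrient]
        amounts[ingredient] = target * factor
    _, agax_factor = spec.ingredient_factors[ex.AG_AX]
    xs, gs = spec.xylan_gum_split
    total_split = xs + gs
    amounts["xylan"] = agax * agax_factor * xs / total_split
    amounts["gum_arabic"] = agax * agax_factor * gs / total_split
    glucose = sugars - spec.yeast_extract_glucose_fraction * amounts["yeast_extract"]
    if glucose < 0:
        logger.warning(
            "yeast-extract glucose (%.3f g/L) exceeds sugars target (%.3f g/L); "
            "glucose clamped to 0",
            spec.yeast_extract_glucose_fraction * amounts["yeast_extract"],
            sugars,
        )
        glucose = 0.0
    amounts["glucose"] = glucose
    return FeedRecipe(**amounts)


def residues_to_recipe(
    residues: ResidueProfile, spec: ConversionSpec, normalize: bool = True
) -> FeedRecipe:
    """Convert colon residues into a feed recipe.

    With ``normalize=True`` every nutrient residue is first scaled by
    ``k = soluble_fiber_target / soluble-fibre residue`` so the medium's
    fibre-ingredient sum equals the target exactly.
    """
    if normalize:
        sf = residues.soluble_fiber
        if sf <= 0:
            raise ValidationError("cannot normalize: soluble-fibre residue is zero")
        residues = residues.scaled(spec.soluble_fiber_target / sf)
    return nutrients_to_ingredients(residues.residues, spec)


def recipe_to_nutrients(recipe: FeedRecipe, spec: ConversionSpec) -> dict[str, float]:
    """Invert the ingredient mapping: recipe (g/L) → nutrient targets (g/L)."""
    inv = {ing: (n, f) for n, (ing, f) in spec.ingredient_factors.items()}
    out: dict[str, float] = {}
    for ingredient in ("special_peptone", "pectin", "starch"):
        nutrient, factor = inv[ingredient]
        out[nutrient] = getattr(recipe, ingredient) / factor
    nutrient, factor = inv["yeast_extract"]
    out[nutrient] = recipe.yeast_extract / factor
    _, agax_factor = spec.ingredient_factors[ex.AG_AX]
    out[ex.AG_AX] = (recipe.xylan + recipe.gum_arabic) / agax_factor
    out[ex.SUGARS] = recipe.glucose + spec.yeast_extract_glucose_fraction * recipe.yeast_extract
    out[ex.SOLUBLE_FIBER] = (
        out[ex.AG_AX] + out[ex.PECTIN] + out[ex.RESISTANT_STARCH]
    )
    return out


def standard_feed_recipe(spec: ConversionSpec | None = None) -> FeedRecipe:
    """The standard SHIME feed, with glucose recomputed from the sugars
    target (0.5 g/L) and the yeast-extract correction."""
    spec = spec or ConversionSpec()
    ing = {k: v for k, v in STANDARD_FEED_INGREDIENTS.items() if k != "glucose"}
    sugars_target = 0.5  # the standard feed's sugars content, g/L
    glucose = sugars_target - spec.yeast_extract_glucose_fraction * ing["yeast_extract"]
    return FeedRecipe(**ing, glucose=max(glucose, 0.0))


def formulate_series(
    diary: DietDiary, spec: ConversionSpec | None = None, normalize: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Formulate one feed recipe per diary day.

    Returns ``(recipes, summary)``: a day-indexed table of ingredient
    concentrations and a two-row mean/SD summary over days.  The
    summary averages the *daily recipes* — because of the per-day fibre
    normalisation this differs from the recipe of the mean intakes.
    """
    spec = spec or ConversionSpec()
    base = [c for c in diary.exposure_names if c in KNOWN_NUTRIENTS]
    if ex.ARABINOGALACTAN in base or ex.ARABINOXYLAN in base:
        # the pooled class duplicates its components
        base = [c for c in base if c != ex.AG_AX]
    if not base:
        raise ValidationError("diary contains no base nutrient columns")
    rows = {}
    for day in diary.days:
        intake = {n: float(diary.values.loc[day, n]) for n in base}
        recipe = residues_to_recipe(compute_residues(intake, spec), spec, normalize=normalize)
        rows[day] = recipe.as_dict()
    recipes = pd.DataFrame.from_dict(rows, orient="index").rename_axis("day")
    summary = pd.DataFrame({"mean": recipes.mean(), "sd": recipes.std(ddof=1)}).T
    return recipes, summary
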