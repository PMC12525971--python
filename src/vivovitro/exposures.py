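"""Canonical names for the dietary exposures tracked by the pipeline.

The diet diary follows eleven exposures: seven *base* macronutrient
series that are measured (or simulated) directly, plus four *derived*
series that are deterministic sums/ratios of the base ones.  All modules
refer to exposures by the snake_case names defined here.
"""

from __future__ import annotations

import pandas as pd

ANIMAL_PROTEIN = "animal_protein"
NON_ANIMAL_PROTEIN = "non_animal_protein"
ARABINOGALACTAN = "arabinogalactan"
ARABINOXYLAN = "arabinoxylan"
PECTIN = "pectin"
RESISTANT_STARCH = "resistant_starch"
SUGARS = "sugars"

PROTEIN = "protein"
AG_AX = "arabinogalactan_arabinoxylan"
SOLUBLE_FIBER = "soluble_fiber"
PROTEIN_TO_SOLUBLE_RATIO = "protein_to_soluble_ratio"

#: Directly measured macronutrient series.
BASE_EXPOSURES = [
    ANIMAL_PROTEIN,
    NON_ANIMAL_PROTEIN,
    ARABINOGALACTAN,
    ARABINOXYLAN,
    PECTIN,
    RESISTANT_STARCH,
    SUGARS,
]

#: Fibre classes whose sum defines soluble fibre.
FIBER_COMPONENTS = [ARABINOGALACTAN, ARABINOXYLAN, PECTIN, RESISTANT_STARCH]

#: The eleven exposures entering the lag-window correlation scan.
ALL_EXPOSURES = [
    PROTEIN,
    ANIMAL_PROTEIN,
    NON_ANIMAL_PROTEIN,
    ARABINOGALACTAN,
    ARABINOXYLAN,
    AG_AX,
    PECTIN,
    SOLUBLE_FIBER,
    RESISTANT_STARCH,
    SUGARS,
    PROTEIN_TO_SOLUBLE_RATIO,
]

#: The four macronutrients entering the environment-divergence model.
MODEL_EXPOSURES = [SOLUBLE_FIBER, SUGARS, NON_ANIMAL_PROTEIN, ANIMAL_PROTEIN]


def add_derived_exposures(diary: pd.DataFrame) -> pd.DataFrame:
    """Append the four derived exposure columns to a base diary.

    ``protein`` is animal + non-animal protein; the combined
    arabinogalactan/arabinoxylan series is their sum; soluble fibre is
    the sum of all four fibre classes; and the protein-to-soluble ratio
    is total protein divided by soluble fibre (NaN where fibre is zero).
    Existing derived columns are recomputed.
    """
    out = diary.copy()
    out[PROTEIN] = out[ANIMAL_PROTEIN] + out[NON_ANIMAL_PROTEIN]
    out[AG_AX] = out[ARABINOGALACTAN] + out[ARABINOXYLAN]
    out[SOLUBLE_FIBER] = out[list(FIBER_COMPONENTS)].sum(axis=1)
    fiber = out[SOLUBLE_FIBER]
    ratio = out[PROTEIN].where(fiber > 0) / fiber.where(fiber > 0)
    out[PROTEIN_TO_SOLUBLE_RATIO] = ratio
    return out[[c for c in ALL_EXPOSURES if c in out.columns]]
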