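"""Reference values of the case study this pipeline re-analyses.

A single volunteer and a SHIME gut simulator inoculated with the
volunteer's faeces underwent a parallel 28-day dietary intervention,
with a *Lacticaseibacillus rhamnosus* GG supplement during the first
14 days.  These constants record the published study design: the
sampling schedule, the sample ledger, the visually identified outlier
samples, and the mean ± SD macronutrient content of the standard and
experimental diets/feeds.  They parameterise the synthetic-data
generator and the worked examples, and are all overridable.
"""

from __future__ import annotations

from .exposures import (
    AG_AX,
    ANIMAL_PROTEIN,
    NON_ANIMAL_PROTEIN,
    PECTIN,
    RESISTANT_STARCH,
    SUGARS,
)

#: Experimental days on which samples were taken during the
#: intervention; day 0 is the pre-intervention baseline sample.
INTERVENTION_SAMPLING_DAYS = [3, 6, 8, 10, 12, 16, 18, 22, 25, 28]

#: Inclusive day interval of probiotic supplementation.
PROBIOTIC_DAYS = (1, 14)

#: Length of the dietary intervention in days.
STUDY_DAYS = 28

#: Sample identifiers: faeces (K, plus inoculum I and baseline SK) and
#: SHIME distal-colon liquid (L, plus baseline SL).  The inoculum was
#: donated before the simulator's 14-day stabilisation; it is placed at
#: day -7 here (the exact calendar offset is configuration, not data).
IN_VIVO_SAMPLES = {"I": -7, "SK": 0, **{f"K{i}": d for i, d in enumerate(INTERVENTION_SAMPLING_DAYS, 1)}}
IN_VITRO_SAMPLES = {"SL": 0, **{f"L{i}": d for i, d in enumerate(INTERVENTION_SAMPLING_DAYS, 1)}}

#: Samples excluded from the published statistical analyses as
#: ordination outliers (three per environment).
OUTLIER_SAMPLES = ["K3", "K4", "K10", "L3", "L4", "L10"]

#: Prevalence thresholds used to call a genus "prevalent": detected in
#: at least 9 of the 12 faecal samples, or at least 8 of the 11 SHIME
#: samples.
PREVALENCE_MIN_SAMPLES = {"in_vivo": 9, "in_vitro": 8}

#: Volunteer dietary intake, g/day, mean ± SD over 28 days.
#: "Standard" is the pre-intervention habitual diet, "experimental" the
#: intervention diet.
VOLUNTEER_DIET_G_PER_DAY = {
    "standard": {
        ANIMAL_PROTEIN: (34.9, 23.7),
        NON_ANIMAL_PROTEIN: (25.9, 13.5),
        AG_AX: (5.0, 2.8),
        PECTIN: (2.2, 1.6),
        RESISTANT_STARCH: (1.7, 1.6),
        SUGARS: (77.0, 41.8),
    },
    "experimental": {
        ANIMAL_PROTEIN: (46.7, 13.1),
        NON_ANIMAL_PROTEIN: (41.4, 6.5),
        AG_AX: (4.9, 1.3),
        PECTIN: (7.5, 1.6),
        RESISTANT_STARCH: (5.1, 2.4),
        SUGARS: (66.4, 18.6),
    },
}

#: SHIME feed nutrient content, g/L, mean ± SD (SD 0 for the fixed
#: standard feed).
SHIME_FEED_G_PER_L = {
    "standard": {
        ANIMAL_PROTEIN: (1.0, 0.0),
        NON_ANIMAL_PROTEIN: (2.0, 0.0),
        AG_AX: (1.7, 0.0),
        PECTIN: (2.0, 0.0),
        RESISTANT_STARCH: (4.0, 0.0),
        SUGARS: (0.5, 0.0),
    },
    "experimental": {
        ANIMAL_PROTEIN: (3.8, 1.4),
        NON_ANIMAL_PROTEIN: (3.4, 0.8),
        AG_AX: (2.3, 1.1),
        PECTIN: (3.2, 0.7),
        RESISTANT_STARCH: (2.0, 0.8),
        SUGARS: (0.4, 0.1),
    },
}

#: Standard SHIME feed ingredients, g/L.  Glucose 0.4 is the published
#: rounded value of sugars 0.5 minus the glucose carried by 3.0 g/L of
#: yeast extract (2.9%).
STANDARD_FEED_INGREDIENTS = {
    "special_peptone": 1.0,
    "yeast_extract": 3.0,
    "xylan": 0.5,
    "gum_arabic": 1.2,
    "pectin": 2.0,
    "starch": 4.0,
    "glucose": 0.4,
}

#: Experimental SHIME feed ingredients, g/L, mean ± SD.
EXPERIMENTAL_FEED_INGREDIENTS = {
    "special_peptone": (3.8, 1.4),
    "yeast_extract": (5.4, 1.2),
    "xylan": (0.7, 0.3),
    "gum_arabic": (1.7, 0.8),
    "pectin": (3.2, 0.7),
    "starch": (2.0, 0.8),
    "glucose": (0.3, 0.1),
}

#: The eight prevalent genera shared between faecal and SHIME samples,
#: with their phyla (classic names, as used for the F/B ratio).
SHARED_CORE_GENERA = [
    ("Bacteroidetes", "Bacteroides"),
    ("Actinobacteria", "Bifidobacterium"),
    ("Verrucomicrobia", "Akkermansia"),
    ("Bacteroidetes", "Alistipes"),
    ("Proteobacteria", "Sutterella"),
    ("Bacteroidetes", "Parabacteroides"),
    ("Firmicutes", "Phascolarctobacterium"),
    ("Lentisphaerae", "Victivallis"),
]
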