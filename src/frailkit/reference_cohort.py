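"""Shipped calibration defaults: the reference cross-sectional cohort.

The package ships the published covariate-by-severity cross-tabulations of
a cross-sectional cohort of 400 community-dwelling Bangladeshi adults aged
55 and over, scored with the FI-30 instrument.  These counts are the
defaults for the table-faithful synthetic cohort generator and for the
reproduction reports; reference levels below are the ones the cohort's
risk-factor model used.

Each matrix row is (fit, mild, moderate, severe) counts for one covariate
level; every matrix has column sums (34, 120, 145, 101) and grand total 400.
"""

from __future__ import annotations

CATEGORIES: tuple[str, ...] = ("FIT", "MILD", "MODERATE", "SEVERE")

#: Cohort-wide severity counts.
CATEGORY_TOTALS: dict[str, int] = {"FIT": 34, "MILD": 120, "MODERATE": 145, "SEVERE": 101}

COHORT_SIZE: int = 400

#: Observed frailty-index range and mean in the reference cohort.
FI_RANGE: tuple[float, float] = (0.05, 0.71)
FI_MEAN: float = 0.28

#: FI summaries by gender: (n, mean, sd).
FI_BY_GENDER: dict[str, tuple[int, float, float]] = {
    "Male": (229, 0.271, 0.118),
    "Female": (171, 0.303, 0.114),
}

#: Continuous age calibration: mean, sd and admissible range in years.
AGE_MEAN_SD: tuple[float, float] = (63.61, 8.73)
AGE_RANGE: tuple[float, float] = (55.0, 100.0)

#: Covariate level -> (fit, mild, moderate, severe) counts.
REFERENCE_CROSSTABS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "age_group": {
        "55-59": (22, 51, 53, 19),
        "60-64": (4, 21, 40, 25),
        "65-69": (4, 30, 19, 13),
        "70+": (4, 18, 33, 44),
    },
    "gender": {
        "Male": (27, 74, 78, 50),
        "Female": (7, 46, 67, 51),
    },
    "education": {
        "Illiterate": (15, 62, 80, 70),
        "Literate": (19, 58, 65, 31),
    },
    "occupation": {
        "Service": (17, 41, 45, 13),
        "Housewife/Others": (17, 79, 100, 88),
    },
    "marital_status": {
        "Married": (30, 102, 121, 67),
        "Widow/Divorce": (4, 18, 24, 34),
    },
    "smoking": {
        "Non-Smoker": (21, 83, 115, 75),
        "Smoker": (13, 37, 30, 26),
    },
    "income": {
        "<$118.3": (3, 32, 44, 39),
        "$118-$236.6": (16, 41, 51, 31),
        "$236.6-$354.9": (11, 20, 32, 22),
        "$354.9-$473.3": (3, 12, 11, 5),
        ">$473.3": (1, 15, 7, 4),
    },
    "family_type": {
        "Nuclear": (14, 58, 57, 43),
        "Joint/Extended": (20, 62, 88, 58),
    },
    "religion": {
        "Muslim": (27, 110, 132, 87),
        "Non-Muslim": (7, 10, 13, 14),
    },
}

#: Reference level per covariate for the logistic risk-factor model.
REFERENCE_LEVELS: dict[str, str] = {
    "age_group": "55-59",
    "gender": "Male",
    "education": "Illiterate",
    "occupation": "Service",
    "marital_status": "Widow/Divorce",
    "smoking": "Non-Smoker",
    "income": "<$118.3",
    "family_type": "Nuclear",
    "religion": "Muslim",
}

#: Declared level order per covariate (data-dictionary order).
LEVEL_ORDER: dict[str, tuple[str, ...]] = {
    cov: tuple(levels.keys()) for cov, levels in REFERENCE_CROSSTABS.items()
}
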