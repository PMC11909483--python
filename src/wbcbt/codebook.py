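"""Versioned codebook of baseline covariates.

Baseline predictors fall into 11 domains (sociodemographics, university
factors, COVID-era stressors, other stressors, anxiety/depression
characteristics, comorbid disorders, treatment history, physical health,
social networks, personality/resilience, internet literacy and
preferences).  The codebook fixes the covariate names, types, ranges and
domain tags so that the generator, the compliance model and the SHAP
reports all speak the same schema.  The schema is versioned: attribution
outputs reference stable names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

VarKind = Literal["binary", "count", "scale", "categorical"]


@dataclass(frozen=True)
class Covariate:
    name: str
    kind: VarKind
    domain: str
    low: float = 0.0
    high: float = 1.0
    levels: tuple[str, ...] | None = None  # categorical only
    description: str = ""


DOMAINS = (
    "sociodemographics",
    "university",
    "covid_stressors",
    "stressors",
    "anxiety_depression",
    "comorbid_disorders",
    "treatment",
    "physical_health",
    "social_networks",
    "personality",
    "internet_preferences",
)

#: categorical level sets used by the generator and validators
COUNTRIES = ("Colombia", "Mexico")
UNIVERSITIES = ("U1", "U2", "U3", "U4", "U5", "U6", "U7")
CLINIC_STATUS = ("waitlist", "clinic_campus", "no_clinic")
SEXES = ("male", "female")
SEXUAL_ORIENTATIONS = ("heterosexual", "gay_lesbian", "bisexual", "other")
AGE_GROUPS = ("18-19", "20", "21-22", "23+")
ARMS = ("guided", "self-guided", "TAU")


COVARIATES: tuple[Covariate, ...] = (
    # sociodemographics
    Covariate("female", "binary", "sociodemographics"),
    Covariate("age_20", "binary", "sociodemographics"),
    Covariate("age_21_22", "binary", "sociodemographics"),
    Covariate("age_23_plus", "binary", "sociodemographics"),
    Covariate("sexual_minority", "binary", "sociodemographics"),
    Covariate("employed", "binary", "sociodemographics",
              description="currently working any number of hours"),
    # university factors
    Covariate("mexico", "binary", "university"),
    Covariate("first_generation", "binary", "university"),
    Covariate("waitlist_recruited", "binary", "university"),
    Covariate("clinic_campus", "binary", "university"),
    Covariate("unam", "binary", "university",
              description="attends the largest participating university"),
    # COVID-era stressors
    Covariate("covid_financial_stress", "scale", "covid_stressors", 0, 10),
    Covariate("covid_infection_household", "binary", "covid_stressors"),
    # other stressors
    Covariate("sexual_assault_past_year", "binary", "stressors"),
    Covariate("chronic_health_stressors", "scale", "stressors", 0, 10),
    # anxiety/depression characteristics
    Covariate("mde_months_past_year", "count", "anxiety_depression", 0, 12,
              description="months with major depressive episodes, past year"),
    Covariate("high_baseline_score", "binary", "anxiety_depression",
              description="baseline PHQ-ADS >= 20 with PHQ-9 >= 10"),
    Covariate("age_of_onset_early", "binary", "anxiety_depression"),
    # comorbid disorders
    Covariate("work_activity_impairment", "scale", "comorbid_disorders", 0, 10,
              description="30-day work impairment due to mental health"),
    Covariate("sad_situational", "scale", "comorbid_disorders", 0, 16,
              description="situational social-anxiety intensity x frequency"),
    Covariate("social_anxiety_disorder", "binary", "comorbid_disorders"),
    Covariate("phobia_history", "binary", "comorbid_disorders",
              description="lifetime extreme fears of objects/situations"),
    Covariate("lifetime_comorbidity_count", "count", "comorbid_disorders", 0, 6),
    # treatment history
    Covariate("prior_treatment", "binary", "treatment"),
    Covariate("psych_med_current", "binary", "treatment"),
    # physical health
    Covariate("role_impairment_home", "scale", "physical_health", 0, 10,
              description="30-day home-management role impairment"),
    Covariate("role_impairment_relationships", "scale", "physical_health", 0, 10),
    Covariate("underweight", "binary", "physical_health"),
    # social networks
    Covariate("loneliness", "scale", "social_networks", 0, 16,
              description="frequency x severity of loneliness"),
    Covariate("confidant_count", "count", "social_networks", 0, 10),
    # personality / resilience
    Covariate("irritability", "scale", "personality", 0, 10),
    Covariate("alexithymia", "scale", "personality", 0, 10),
    Covariate("negative_urgency", "scale", "personality", 0, 10),
    Covariate("openness", "scale", "personality", 0, 10),
    # internet literacy and preferences
    Covariate("helpfulness_reminders", "scale", "internet_preferences", 0, 3,
              description="perceived helpfulness of reminder features"),
    Covariate("helpfulness_texting", "scale", "internet_preferences", 0, 3,
              description="perceived helpfulness of texting features"),
    Covariate("desire_stress_features", "scale", "internet_preferences", 0, 3),
    Covariate("desire_sleep_features", "scale", "internet_preferences", 0, 3),
)

COVARIATE_NAMES: tuple[str, ...] = tuple(c.name for c in COVARIATES)
DOMAIN_MAP: dict[str, str] = {c.name: c.domain for c in COVARIATES}

# weights of the latent compliance-signal score: which baseline covariates
# carry information about weeks-13-52 platform use, and in which direction
SIGNAL_WEIGHTS: dict[str, float] = {
    "employed": -1.0,
    "work_activity_impairment": 0.8,
    "sad_situational": 0.7,
    "social_anxiety_disorder": 0.5,
    "phobia_history": -0.5,
    "lifetime_comorbidity_count": -0.4,
    "role_impairment_home": 0.5,
    "role_impairment_relationships": 0.4,
    "underweight": 0.3,
    "loneliness": 0.4,
    "confidant_count": 0.3,
    "helpfulness_reminders": 0.5,
    "helpfulness_texting": 0.4,
    "desire_stress_features": -0.4,
    "desire_sleep_features": -0.3,
    "sexual_assault_past_year": 0.4,
    "chronic_health_stressors": -0.3,
    "mde_months_past_year": 0.4,
    "high_baseline_score": -0.4,
    "irritability": -0.4,
    "alexithymia": -0.3,
    "negative_urgency": -0.3,
    "openness": -0.3,
    "unam": 0.5,
}


def validate_covariate_frame(X: pd.DataFrame) -> list[str]:
    """Return a list of schema violations (empty when the frame conforms)."""
    issues: list[str] = []
    for cov in COVARIATES:
        if cov.name not in X.columns:
            issues.append(f"missing covariate column {cov.name!r}")
            continue
        col = X[cov.name]
        if not np.issubdtype(col.dtype, np.number):
            issues.append(f"covariate {cov.name!r} is not numeric")
            continue
        if col.isna().any():
            issues.append(f"covariate {cov.name!r} has missing values")
        finite = col.dropna()
        if len(finite) and (finite.min() < cov.low or finite.max() > cov.high):
            issues.append(
                f"covariate {cov.name!r} outside range [{cov.low}, {cov.high}]"
            )
        if cov.kind == "binary" and len(finite) and not finite.isin((0, 1)).all():
            issues.append(f"binary covariate {cov.name!r} has non-0/1 values")
    return issues


def signal_score(X: pd.DataFrame) -> np.ndarray:
    """Standardized linear combination of the signal-bearing covariates.

    This is the latent score through which baseline covariates predict
    weeks-13-52 platform use in the generator.  Covariates are scaled to
    their codebook range before weighting; the result is centered and
    scaled to unit variance (all-constant input returns zeros).
    """
    s = np.zeros(len(X), dtype=float)
    by_name = {c.name: c for c in COVARIATES}
    for name, w in SIGNAL_WEIGHTS.items():
        cov = by_name[name]
        span = cov.high - cov.low
        s = s + w * (X[name].to_numpy(dtype=float) - cov.low) / span
    sd = s.std()
    if sd == 0:
        return np.zeros(len(X))
    return (s - s.mean()) / sd
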