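"""Configuration objects for the synthetic city generator and pipeline.

A :class:`CityConfig` fully determines a synthetic study region: how many
census-tract-like neighbourhoods to tile, the marginal distribution of
population density, how strongly the social environment index (SEI) tracks
density, how many food establishments open per head of population and how
their mix over outlet categories looks, plus the individual-level survey
layer (sample size, outcome model).  All randomness downstream is driven by
``seed`` alone, so a config + seed pair reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: The eight food outlet categories, in the fixed order used everywhere
#: (tables, category_mix vectors, density columns).
CATEGORIES: tuple[str, ...] = (
    "fruit_vegetable_store",
    "fresh_food_retail",
    "small_food_retail",
    "supermarket",
    "ready_for_consumption",
    "convenience_store",
    "fast_food_chain",
    "candy_ice_cream",
)

#: Mapping of outlet category -> health group ("most_healthy" outlets sell
#: predominantly fresh/minimally processed food; "less_healthy" predominantly
#: ultra-processed or ready-to-eat indulgence food; "mixed" both).
HEALTH_GROUPS: dict[str, str] = {
    "fruit_vegetable_store": "most_healthy",
    "fresh_food_retail": "most_healthy",
    "small_food_retail": "mixed",
    "supermarket": "mixed",
    "ready_for_consumption": "mixed",
    "candy_ice_cream": "less_healthy",
    "fast_food_chain": "less_healthy",
    "convenience_store": "less_healthy",
}

GROUP_ORDER: tuple[str, ...] = ("most_healthy", "mixed", "less_healthy")


class ParameterError(ValueError):
    """Raised when a configuration field fails validation; names the field."""


@dataclass
class OutcomeTruth:
    """Generative truth for the individual non-daily fruit/vegetable outcome.

    The outcome is drawn from a two-level logistic model::

        logit P(non_daily_ij) = intercept + beta_exposure * z(exposure_j)
                                + beta_age * z(age_ij) + beta_male * male_ij
                                + beta_education * low_edu_ij + u_j,
        u_j ~ Normal(0, sigma_u^2)

    All parameters are on the log-odds scale.  ``beta_exposure`` is per 1 SD
    of the chosen neighbourhood density; the default 0.18 corresponds to an
    odds ratio of ~1.20 per SD, the magnitude of the small-food-retail
    association this simulator is designed to let the models module recover.
    The intercept default is calibrated so that the *marginal* non-daily
    prevalence — averaging over the default covariate mix, exposure
    distribution and random intercepts — sits near the observed 17.3%
    (with every beta and sigma_u at 0, ``logit(0.173) = -1.565`` gives the
    same prevalence directly).
    """

    intercept: float = -2.07
    beta_exposure: float = 0.18
    beta_age: float = -0.40
    beta_male: float = 0.60
    beta_education: float = 0.20
    sigma_u: float = 0.5

    def validate(self) -> None:
        if self.sigma_u < 0:
            raise ParameterError("sigma_u must be >= 0")


@dataclass
class CityConfig:
    """Parameters of a synthetic multi-city study region.

    Defaults emulate a three-city Chilean study region: 2,442 neighbourhoods
    split across the cities roughly 1700/386/356, log-normal population
    density with median ~10,400 persons/km2, ~0.008 food establishments per
    capita (~48,000 establishments in total), a heavily ready-for-consumption
    category mix, and a survey layer of ~1,292 respondents of whom a small
    fraction have a missing item.
    """

    n_neighbourhoods: int = 2442
    city_labels: tuple[str, ...] = ("Santiago", "Valparaiso", "Concepcion")
    city_weights: tuple[float, ...] = (1700, 386, 356)
    cell_size_km: float = 0.5
    #: (mu, sigma) of log population density [persons/km2].  mu=9.25 puts the
    #: median near 10,400/km2; sigma=0.7 spreads the quartiles ~5,800-15,200.
    popdens_lognormal_params: tuple[float, float] = (9.25, 0.7)
    sei_dimension_count: int = 4
    #: Correlation between each census dimension score and log popdens.
    sei_popdens_correlation: float = 0.4
    #: ~48,000 establishments for the ~8M people implied by the density
    #: distribution over 2,442 quarter-km2 neighbourhoods.
    establishments_per_capita: float = 0.006
    #: Probability vector over the eight outlet categories (CATEGORIES order).
    #: Defaults follow the observed mix: ready-for-consumption dominant
    #: (~66%), then small food retail, convenience, supermarkets, ...
    category_mix: tuple[float, ...] = (
        0.0104, 0.0220, 0.1109, 0.0719, 0.6806, 0.0770, 0.0099, 0.0173,
    )
    #: Log-linear effect of SEI on establishment intensity; positive values
    #: concentrate outlets in more favourable social environments.
    density_sei_gradient: float = 0.5
    #: Negative-binomial dispersion (size) for per-neighbourhood counts;
    #: smaller = heavier tail (variance = mu + mu^2/size).
    nb_dispersion: float = 1.2
    #: Fraction of establishments given a name with no inventory term and an
    #: uninformative provider label, exercising the unclassified path.
    ambiguous_name_fraction: float = 0.03
    #: Fraction of (non-ambiguous) establishments whose name carries no
    #: inventory term but whose provider label is informative, exercising the
    #: provider-type fallback classification path.
    fallback_name_fraction: float = 0.10
    #: Probability that the provider's primary type label is replaced with a
    #: random other label (provider noise).
    label_noise: float = 0.05
    n_participants: int = 1292
    #: Number of distinct neighbourhoods the survey sample is nested in.
    n_survey_neighbourhoods: int = 319
    #: Probability a respondent record has one required item missing.
    missingness_rate: float = 17 / 1292
    #: Female share and 4-level education mix (<primary, primary, secondary,
    #: university) of the respondent pool.
    female_share: float = 0.616
    education_mix: tuple[float, ...] = (0.107, 0.455, 0.308, 0.130)
    #: Which neighbourhood density column drives the outcome model.
    outcome_exposure: str = "density_total"
    outcome_model: OutcomeTruth = field(default_factory=OutcomeTruth)
    seed: int = 0

    def validate(self) -> None:
        if self.n_neighbourhoods <= 0:
            raise ParameterError("n_neighbourhoods must be positive")
        if self.n_participants < 0:
            raise ParameterError("n_participants must be >= 0")
        if self.cell_size_km <= 0:
            raise ParameterError("cell_size_km must be positive")
        if self.establishments_per_capita < 0:
            raise ParameterError("establishments_per_capita must be >= 0")
        if len(self.city_labels) != len(self.city_weights):
            raise ParameterError("city_weights must match city_labels in length")
        if len(self.category_mix) != len(CATEGORIES):
            raise ParameterError(
                f"category_mix must have {len(CATEGORIES)} entries (one per category)"
            )
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ParameterError("category_mix must sum to 1 within 1e-9")
        if not -1.0 <= self.sei_popdens_correlation <= 1.0:
            raise ParameterError("sei_popdens_correlation must lie in [-1, 1]")
        if not 0.0 <= self.ambiguous_name_fraction <= 1.0:
            raise ParameterError("ambiguous_name_fraction must lie in [0, 1]")
        if not 0.0 <= self.fallback_name_fraction <= 1.0:
            raise ParameterError("fallback_name_fraction must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ParameterError("label_noise must lie in [0, 1]")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ParameterError("missingness_rate must lie in [0, 1]")
        if self.sei_dimension_count < 1:
            raise ParameterError("sei_dimension_count must be >= 1")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be positive")
        if abs(sum(self.education_mix) - 1.0) > 1e-9:
            raise ParameterError("education_mix must sum to 1 within 1e-9")
        self.outcome_model.validate()

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():   # YAML-safe: tuples -> lists
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CityConfig":
        d = dict(d)
        om = d.get("outcome_model")
        if isinstance(om, dict):
            d["outcome_model"] = OutcomeTruth(**om)
        for key in ("city_labels", "city_weights", "popdens_lognormal_params",
                    "category_mix", "education_mix"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CityConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
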