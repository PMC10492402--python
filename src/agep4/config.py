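"""Typed configuration objects and the YAML loader.

All tunable constants of the pipeline live here: the synthetic-herd
generator (:class:`SimulationConfig`), phenotype-derivation constants
(:class:`PhenotypeConfig`), the mixed-model specification
(:class:`ModelSpec`) and the MCMC run length (:class:`MCMCConfig`).
Validation is strict: a malformed config file raises a single
``ValidationError`` listing every violation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "SimulationConfig",
    "PhenotypeConfig",
    "ModelSpec",
    "MCMCConfig",
    "RunConfig",
    "load_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulationConfig(_StrictModel):
    """Parameters of the synthetic seasonal-calving herd study.

    Defaults emulate the field study the pipeline is designed around:
    54 pasture-based herds of 88 ± 45 heifers visited three times at
    mean ages 299/327/354 d (age SD 14.5 d), a sire-structured pedigree
    with ~100 widely used sires, Holstein–Friesian × Jersey admixture,
    and a latent age at first progesterone elevation (AGEP4) with
    additive-genetic, herd and breed components.
    """

    n_herds: int = Field(default=54, ge=1)
    herd_size_mean: float = Field(default=88.0, gt=0)
    herd_size_sd: float = Field(default=45.0, ge=0)
    min_herd_size: int = Field(default=10, ge=1)

    n_sires: int = Field(default=100, ge=1)
    max_dam_uses: int = Field(default=2, ge=1)

    #: mean animal ages (days) at the early/mid/late visits
    visit_target_ages: tuple[int, int, int] = (299, 327, 354)
    #: within-herd SD of animal age at any visit, days
    age_sd: float = Field(default=14.5, ge=0)
    #: SD of the per-herd, per-visit scheduling jitter, days
    herd_date_jitter_sd: float = Field(default=3.0, ge=0)

    #: additive genetic variance of AGEP4, days^2 (h2 = 0.30 of a 30 d SD)
    sigma2_a: float = Field(default=270.0, ge=0)
    #: residual variance of AGEP4, days^2
    sigma2_e: float = Field(default=630.0, ge=0)
    #: SD of the herd environmental effect, days
    herd_effect_sd: float = Field(default=10.0, ge=0)
    #: AGEP4 difference of a pure Jersey relative to a pure Holstein-Friesian, days
    jersey_effect: float = -56.0
    #: population intercept, days; calibrated so ~45% of heifers are
    #: post-pubertal at the mid visit under the default breed mixture
    global_mean: float = 348.0

    #: breed-composition mixture: (weight, low, high) of uniform classes
    breed_mixture: tuple[tuple[float, float, float], ...] = (
        (0.48, 0.0, 0.1),   # predominantly Holstein-Friesian
        (0.50, 0.25, 0.75), # HF x Jersey crossbred
        (0.02, 0.9, 1.0),   # predominantly Jersey
    )

    #: probability a post-pubertal visit reads non-elevated (luteal-phase dip)
    p_false_negative: float = Field(default=0.0, ge=0.0, le=1.0)
    #: forbid two consecutive false negatives per animal (estrous-cycle bound)
    cycle_constraint: bool = False

    seed: int = Field(default=2018, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        a, b, c = self.visit_target_ages
        if not (a < b < c):
            raise ValueError("visit_target_ages must be strictly increasing")
        w = sum(w for w, _, _ in self.breed_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("breed_mixture weights must sum to 1")
        for _, lo, hi in self.breed_mixture:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("breed_mixture bounds must satisfy 0 <= lo <= hi <= 1")
        return self


class PhenotypeConfig(_StrictModel):
    """Constants of the three phenotype-derivation methods."""

    #: days added past the last visit for right-censored AGEVISIT records
    penalty_days: int = Field(default=31, ge=0)
    #: lower bound (days) assigned to left-censored AUG records
    floor_days: int = Field(default=200, ge=1)
    #: upper bound (days) assigned to right-censored AUG records
    ceiling_days: int = Field(default=500, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "PhenotypeConfig":
        if self.floor_days >= self.ceiling_days:
            raise ValueError("floor_days must be < ceiling_days")
        return self


class ModelSpec(_StrictModel):
    """Mixed-model specification y = Xb + Zu + e.

    Fixed effects are always herd (class, absorbing the intercept) and
    jersey fraction (covariate). ``response_mode`` selects how y enters:
    observed (continuous), latent liability behind ordinal scores
    (ordinal), or interval-censored with data augmentation (interval).
    """

    response_mode: Literal["continuous", "ordinal", "interval"] = "continuous"
    random_effect: Literal["animal", "sire"] = "animal"
    #: sire-model covariance: independent sires or pedigree relationships
    sire_covariance: Literal["independent", "pedigree"] = "independent"

    #: ordinal mode: fixed thresholds; None means 0, 1, ..., K-2 for K classes
    thresholds: Optional[tuple[float, ...]] = None
    #: ordinal alternative identification: fix sigma2_e = 1 and sample the
    #: thresholds above the first instead of fixing them
    estimate_thresholds: bool = False

    #: scaled-inverse-chi-square prior degrees of freedom
    nu_genetic: float = Field(default=4.0, gt=0)
    nu_residual: float = Field(default=4.0, gt=0)
    #: prior heritability and phenotypic variance fixing the prior scales
    prior_h2: float = Field(default=0.25, gt=0, lt=1)
    #: prior guess of phenotypic variance on the working scale; None picks
    #: 900 d^2 for continuous/interval responses and 1.0 for liabilities
    prior_phenotypic_variance: Optional[float] = Field(default=None, gt=0)

    #: when False, variances stay at their initial values (oracle testing)
    estimate_variances: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ModelSpec":
        if self.thresholds is not None:
            t = self.thresholds
            if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
                raise ValueError("thresholds must be strictly increasing")
        return self

    def default_phenotypic_variance(self) -> float:
        if self.prior_phenotypic_variance is not None:
            return self.prior_phenotypic_variance
        return 1.0 if self.response_mode == "ordinal" else 900.0


class MCMCConfig(_StrictModel):
    """Gibbs-chain run length; defaults are 100,000 samples with the
    first 50,000 discarded as burn-in and no thinning."""

    n_iterations: int = Field(default=100_000, ge=2)
    burn_in: int = Field(default=50_000, ge=0)
    thin: int = Field(default=1, ge=1)
    seed: int = Field(default=1, ge=0)
    #: keep per-record draws of augmented responses (interval mode)
    store_responses: bool = False

    @model_validator(mode="after")
    def _check(self) -> "MCMCConfig":
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        return self


class RunConfig(_StrictModel):
    """Top-level config grouping every stage (the YAML file layout)."""

    simulation: SimulationConfig = SimulationConfig()
    phenotype: PhenotypeConfig = PhenotypeConfig()
    model: ModelSpec = ModelSpec()
    mcmc: MCMCConfig = MCMCConfig()
    #: minimum daughters (control scenario) for a sire to enter EBV correlations
    min_daughters: int = Field(default=5, ge=1)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; missing keys take defaults.

    Raises ``pydantic.ValidationError`` listing every invalid field, or
    ``ValueError`` for an unparseable file.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.model_validate(raw)
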