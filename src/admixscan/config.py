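"""Simulation configuration for synthetic admixed cohorts.

The defaults describe an African-American admixture study: ~2,189
ancestry-informative markers on 22 autosomes, admixture about six
generations deep (ancestry-switch rate lambda = 6 per Morgan), and a
per-individual European ancestry proportion M ~ Beta(a, b) calibrated so
that African ancestry (1 - M) has median 83.7% with interquartile range
76.2%-88.7%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import InvalidConfigError

# Beta shape parameters for the *European* ancestry proportion, calibrated
# (see calibrate_ancestry_beta) so African ancestry matches the target
# median/IQR above.
DEFAULT_BETA_A = 2.8168
DEFAULT_BETA_B = 12.9517


@dataclass(frozen=True)
class RiskLocus:
    """An optional diabetes risk locus with a per-allele effect.

    psi_true is the multiplicative odds per European-origin allele carried
    at the locus (psi_true > 1: European ancestry increases risk;
    psi_true < 1: African ancestry increases risk).
    """

    chromosome: int
    position: float  # Morgans, on `chromosome`
    psi_true: float


@dataclass(frozen=True)
class CovariateEffects:
    """Log-odds coefficients of the generative diabetes model.

    The linear predictor is
        intercept + ancestry * A + bmi * (BMI - 28) + ses * S
        + age * (age - 55) + sex_male * 1[male]
    with A the African ancestry proportion and S the latent SES score
    (higher = higher SES).
    """

    intercept: float = -2.0
    ancestry: float = 1.6
    bmi: float = 0.08
    ses: float = -0.30
    age: float = 0.04
    sex_male: float = 0.15


@dataclass(frozen=True)
class TraitEffects:
    """Additive generative model for a quantitative trait.

    trait = base + ancestry * A + bmi * (BMI - 28) + ses * S
            + diabetes * 1[diabetic] + Normal(0, sd)
    """

    base: float
    ancestry: float
    bmi: float
    ses: float
    diabetes: float
    sd: float


DEFAULT_TRAIT_EFFECTS: dict[str, TraitEffects] = {
    # HbA1c in %, fasting glucose in mg/dL, fasting insulin in mU/L.
    "hba1c": TraitEffects(base=4.9, ancestry=0.8, bmi=0.02, ses=-0.05, diabetes=1.8, sd=0.55),
    "glucose": TraitEffects(base=85.0, ancestry=12.0, bmi=0.5, ses=-1.5, diabetes=60.0, sd=11.0),
    "insulin": TraitEffects(base=8.0, ancestry=5.0, bmi=0.55, ses=-0.8, diabetes=4.0, sd=5.0),
}


@dataclass
class SimConfig:
    """Full configuration of one synthetic-cohort simulation.

    The seed fully determines every simulated output; each pipeline stage
    draws from a named substream spawned from it.
    """

    n_individuals: int = 7021
    n_markers: int = 2189
    n_chromosomes: int = 22
    chrom_length: float = 1.5  # Morgans per chromosome
    lambda_gen: float = 6.0  # ancestry-switch rate per Morgan (~generations)
    ancestry_beta_a: float = DEFAULT_BETA_A  # European proportion ~ Beta(a, b)
    ancestry_beta_b: float = DEFAULT_BETA_B
    freq_divergence: float = 0.5  # target mean |pE - pA| of the marker panel
    risk_locus: Optional[RiskLocus] = None
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    trait_effects: dict[str, TraitEffects] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_EFFECTS)
    )
    missing_rate: float = 0.02
    treated_fraction: float = 0.6  # fraction of diabetics on treatment
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_individuals <= 0:
            raise InvalidConfigError("n_individuals must be positive")
        if self.n_chromosomes <= 0:
            raise InvalidConfigError("n_chromosomes must be positive")
        if self.n_markers < self.n_chromosomes:
            raise InvalidConfigError("need at least one marker per chromosome")
        if self.chrom_length <= 0:
            raise InvalidConfigError("chrom_length must be positive (Morgans)")
        if self.lambda_gen < 0:
            raise InvalidConfigError("lambda_gen must be >= 0")
        if not (self.ancestry_beta_a > 0 and self.ancestry_beta_b > 0):
            raise InvalidConfigError("ancestry Beta shapes must be positive")
        if not (0.0 <= self.freq_divergence <= 0.95):
            raise InvalidConfigError("freq_divergence must be in [0, 0.95]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.treated_fraction <= 1.0):
            raise InvalidConfigError("treated_fraction must be in [0, 1]")
        if self.risk_locus is not None:
            rl = self.risk_locus
            if rl.psi_true <= 0:
                raise InvalidConfigError("risk locus psi_true must be > 0")
            if not (1 <= rl.chromosome <= self.n_chromosomes):
                raise InvalidConfigError("risk locus chromosome outside the panel")
            if not (0.0 <= rl.position <= self.chrom_length):
                raise InvalidConfigError("risk locus position outside the chromosome")
        for name, eff in self.covariate_effects.__dict__.items():
            if not np.isfinite(eff):
                raise InvalidConfigError(f"covariate effect {name!r} is not finite")
        return self

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("risk_locus") is not None:
            d["risk_locus"] = RiskLocus(**d["risk_locus"])
        if "covariate_effects" in d and isinstance(d["covariate_effects"], dict):
            d["covariate_effects"] = CovariateEffects(**d["covariate_effects"])
        if "trait_effects" in d:
            d["trait_effects"] = {
                k: (TraitEffects(**v) if isinstance(v, dict) else v)
                for k, v in d["trait_effects"].items()
            }
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise InvalidConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)
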