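"""Seed-reproducible synthetic cohorts for the depressive-symptom pipeline.

The restricted study data (a community cohort of ~900 adults with 306 plasma
metabolite features, eight demographic/psychosocial covariates and a CES-D
depressive-symptom score in 0..60) cannot be redistributed, so this module
generates cohorts with the statistical structure the analysis assumes:

* a sparse set of causal metabolites acting on the outcome through nonlinear
  links (quadratic, sine, threshold, linear) — at least one purely even link
  (x^2) so that linear screens provably miss it;
* blocks of mutually correlated "redundant" metabolites, emulating the strong
  within-pathway correlations of real metabolomes;
* mixed continuous/categorical covariates (sex, age, BMI, marital status,
  earthquake house-damage category 0-4, antidepressant use, LSNS-6 social
  network score, social capital score) with their own outcome effects;
* a bounded integer outcome: latent = intercept + covariate effects +
  nonlinear metabolite effects + Gaussian noise, rounded and clipped to
  [0, 60];
* missing / unreliable-answer flags driving listwise exclusion, mirroring the
  original cohort's flow from 1008 enrolled to 897 analyzed subjects.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import CONTINUOUS, CATEGORICAL

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "Cohort",
    "EffectSpec",
    "generate_cohort",
    "apply_exclusions",
    "binarize_outcome",
    "COVARIATE_KINDS",
    "DEFAULT_COVARIATE_EFFECTS",
]


class EmptyCohortError(ValueError):
    """All rows were excluded."""


# The eight covariates of the study design, with their variable kinds.
COVARIATE_KINDS: dict[str, str] = {
    "sex": CATEGORICAL,
    "age": CONTINUOUS,
    "bmi": CONTINUOUS,
    "marital_status": CATEGORICAL,
    "house_damage": CATEGORICAL,
    "antidepressant": CATEGORICAL,
    "lsns6": CONTINUOUS,
    "social_capital": CONTINUOUS,
}

# Linear outcome effect (CES-D points per unit) of each covariate.  Signs
# follow the epidemiology the cohort tables show: less social engagement
# (lower LSNS-6), higher perceived social-capital burden score, heavier house
# damage, female sex and antidepressant use all associate with higher
# depressive-symptom scores.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "sex": 1.2,
    "age": 0.0,
    "bmi": 0.0,
    "marital_status": 0.6,
    "house_damage": 0.7,
    "antidepressant": 6.0,
    "lsns6": -0.35,
    "social_capital": 0.55,
}

_LINKS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda z: z,
    "quadratic": lambda z: z * z,
    "sine": lambda z: np.sin(np.pi * z),
    "threshold": lambda z: (z > 0.5).astype(float),
}

# Default assignment of links to the causal metabolites; a quadratic link is
# always first so the default scenario contains a purely even effect.
_DEFAULT_LINK_CYCLE = ("quadratic", "sine", "threshold", "linear")


@dataclass(frozen=True)
class EffectSpec:
    """One causal metabolite effect: a tagged nonlinear link and its size."""

    link: str
    size: float = 3.0

    def __post_init__(self):
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}; known: {sorted(_LINKS)}")

    def apply(self, z: np.ndarray) -> np.ndarray:
        return self.size * _LINKS[self.link](z)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters; defaults reproduce the study scale.

    ``n_subjects``/``n_metabolites`` default to the analyzed cohort (897
    subjects, 306 metabolite features, 8 covariates).  ``intercept`` is set so
    that the >=16 outcome cutoff splits the default cohort roughly 1:2
    high:low, matching the observed 298/599 prevalence.
    """

    n_subjects: int = 897
    n_metabolites: int = 306
    n_causal: int = 5
    effect_functions: tuple[EffectSpec, ...] | None = None
    n_redundant_blocks: int = 10
    block_size: int = 3
    block_correlation: float = 0.6
    noise_sd: float = 4.0
    intercept: float = 5.5
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    missing_rate: float = 0.0
    unreliable_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_metabolites < 1:
            raise ValueError("n_subjects and n_metabolites must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_metabolites:
            raise ValueError("need 0 <= n_causal <= n_metabolites")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for rate in (self.missing_rate, self.unreliable_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("flag rates must lie in [0, 1)")
        unknown = set(self.covariate_effects) - set(COVARIATE_KINDS)
        if unknown:
            raise ValueError(f"unknown covariates in covariate_effects: {unknown}")

    def resolved_effects(self) -> tuple[EffectSpec, ...]:
        if self.effect_functions is not None:
            if len(self.effect_functions) != self.n_causal:
                raise ValueError("effect_functions length must equal n_causal")
            return tuple(self.effect_functions)
        cycle = _DEFAULT_LINK_CYCLE
        return tuple(
            EffectSpec(link=cycle[i % len(cycle)]) for i in range(self.n_causal)
        )


@dataclass
class Cohort:
    """A subjects-by-features table with outcome, flags and ground truth."""

    features: pd.DataFrame  # n x (p + 8), metabolites then covariates
    feature_kinds: dict[str, str]  # per-column {continuous, categorical}
    covariate_names: list[str]
    outcome_scores: np.ndarray  # integers in [0, 60]
    missing_flag: np.ndarray  # boolean n-vectors
    unreliable_flag: np.ndarray
    causal_feature_ids: list[str] = field(default_factory=list)
    redundant_blocks: list[list[str]] = field(default_factory=list)
    config: CohortConfig | None = None

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def metabolite_names(self) -> list[str]:
        cov = set(self.covariate_names)
        return [c for c in self.features.columns if c not in cov]

    def feature_matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def validate(self) -> None:
        n = self.n
        for arr in (self.outcome_scores, self.missing_flag, self.unreliable_flag):
            if len(arr) != n:
                raise ValueError("row-count mismatch between table and vectors")
        if self.outcome_scores.min() < 0 or self.outcome_scores.max() > 60:
            raise ValueError("outcome scores must lie in [0, 60]")
        if set(self.feature_kinds) != set(self.features.columns):
            raise ValueError("feature_kinds must cover exactly the feature columns")


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate marginals patterned on the cohort's demographic table."""
    damage_p = np.array([179, 338, 120, 110, 150], dtype=float)  # codes 0..4
    marital_p = np.array([736, 59, 37, 65], dtype=float)  # married..single
    return pd.DataFrame(
        {
            "sex": rng.binomial(1, 0.576, n),  # 1 = female
            "age": np.round(rng.normal(57.7, 11.6, n), 1),
            "bmi": np.round(rng.normal(23.5, 3.6, n), 2),
            "marital_status": rng.choice(4, n, p=marital_p / marital_p.sum()),
            "house_damage": rng.choice(5, n, p=damage_p / damage_p.sum()),
            "antidepressant": rng.binomial(1, 0.012, n),
            "lsns6": np.clip(np.round(rng.normal(15.5, 5.6, n)), 0, 30),
            "social_capital": np.clip(np.round(rng.normal(4.9, 2.6, n)), 0, 12),
        }
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort; deterministic given ``config.seed``.

    Metabolites are unit-variance Gaussians.  Redundant blocks share a latent
    factor so that within-block pairwise population correlation equals
    ``block_correlation``.  The first ``n_causal`` metabolites carry the
    outcome effects (they are kept out of the redundancy blocks so that the
    planted signal is unambiguous ground truth).
    """
    cfg = config
    effects = cfg.resolved_effects()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_subjects, cfg.n_metabolites

    X = rng.standard_normal((n, p))
    # carve redundancy blocks out of the non-causal tail of the matrix
    rho = cfg.block_correlation
    block_members: list[list[int]] = []
    start = cfg.n_causal
    for b in range(cfg.n_redundant_blocks):
        cols = list(range(start, min(start + cfg.block_size, p)))
        start += cfg.block_size
        if len(cols) < 2:
            break
        factor = rng.standard_normal(n)
        X[:, cols] = math.sqrt(rho) * factor[:, None] + math.sqrt(1.0 - rho) * X[
            :, cols
        ]
        block_members.append(cols)

    metab_names = [f"metab_{i + 1:03d}" for i in range(p)]
    covariates = _simulate_covariates(n, rng)

    latent = np.full(n, float(cfg.intercept))
    for name, size in cfg.covariate_effects.items():
        latent += size * covariates[name].to_numpy(dtype=float)
    causal_ids = [metab_names[i] for i in range(cfg.n_causal)]
    for i, spec in enumerate(effects):
        latent += spec.apply(X[:, i])
    latent += rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
    outcome = np.clip(np.rint(latent), 0, 60).astype(int)

    missing = rng.random(n) < cfg.missing_rate
    unreliable = rng.random(n) < cfg.unreliable_rate

    features = pd.concat(
        [pd.DataFrame(X, columns=metab_names), covariates], axis=1
    )
    features.index = pd.RangeIndex(n, name="subject")
    kinds = {name: CONTINUOUS for name in metab_names}
    kinds.update(COVARIATE_KINDS)
    cohort = Cohort(
        features=features,
        feature_kinds=kinds,
        covariate_names=list(COVARIATE_KINDS),
        outcome_scores=outcome,
        missing_flag=missing,
        unreliable_flag=unreliable,
        causal_feature_ids=causal_ids,
        redundant_blocks=[[metab_names[i] for i in cols] for cols in block_members],
        config=cfg,
    )
    cohort.validate()
    return cohort


def apply_exclusions(cohort: Cohort) -> Cohort:
    """Listwise deletion of flagged subjects (missing or unreliable outcome).

    A row flagged for both reasons is removed once; the counts removed for
    each reason are logged.
    """
    missing = np.asarray(cohort.missing_flag, dtype=bool)
    unreliable = np.asarray(cohort.unreliable_flag, dtype=bool)
    drop = missing | unreliable
    keep = ~drop
    if not keep.any():
        raise EmptyCohortError("every subject was excluded")
    logger.info(
        "exclusions: %d missing outcome, %d unreliable answers, %d rows removed",
        int(missing.sum()),
        int(unreliable.sum()),
        int(drop.sum()),
    )
    kept_idx = np.flatnonzero(keep)
    out = Cohort(
        features=cohort.features.iloc[kept_idx].reset_index(drop=True),
        feature_kinds=dict(cohort.feature_kinds),
        covariate_names=list(cohort.covariate_names),
        outcome_scores=np.asarray(cohort.outcome_scores)[kept_idx],
        missing_flag=np.zeros(keep.sum(), dtype=bool),
        unreliable_flag=np.zeros(keep.sum(), dtype=bool),
        causal_feature_ids=list(cohort.causal_feature_ids),
        redundant_blocks=[list(b) for b in cohort.redundant_blocks],
        config=cohort.config,
    )
    out.features.index = pd.RangeIndex(out.n, name="subject")
    return out


def binarize_outcome(scores: Sequence[int] | np.ndarray, cutoff: int) -> np.ndarray:
    """Label 1 ("high depressive symptoms") iff score >= cutoff.

    The study's two conventional cutoffs are 16 and 19; any positive integer
    is accepted.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be a positive integer")
    scores = np.asarray(scores)
    return (scores >= cutoff).astype(int)
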