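"""Synthetic rating cohorts with the statistical structure the analysis assumes.

The generator emulates the study design: each participant rates 8 pictures
in each of 6 categories on the −3..+3 Likert scale, with categories chosen
to span the valence axis so both approach (positive) and avoidance
(negative) judgments are populated.

Generative model (discretized clamped Gaussian): participant p carries a
latent affective shift ``delta_p ~ Normal(0, participant_sd)``; for
category c with latent mean valence ``mu_c`` and dispersion ``tau_c``,
each picture rating is ``clip(round(Normal(mu_c + delta_p, tau_c)), -3, 3)``.
This is the simplest mechanism producing graded bivalent Likert data whose
pooled (K, H) cloud is concave-increasing and whose (K, sigma) cloud is
concave-quadratic; it makes no claim to be the behavioral process behind
real ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .rpt_variables import RATING_MAX, RATING_MIN
from .ratings_io import DEFAULT_CATEGORIES

#: latent category mean valences spanning the valence axis
DEFAULT_CATEGORY_MEANS = (-2.2, -1.2, -0.4, 0.4, 1.2, 2.2)

DEFAULT_AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65+")


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 200
    n_categories: int = 6
    n_pictures_per_category: int = 8
    category_means: Sequence[float] = DEFAULT_CATEGORY_MEANS
    category_dispersions: Sequence[float] | float = 1.0
    participant_sd: float = 0.5
    cohort: str = "synthetic"
    categories: Sequence[str] = DEFAULT_CATEGORIES
    age_bands: Sequence[str] = DEFAULT_AGE_BANDS
    age_skew: float = 0.0  # 0 = uniform bands; >0 weights older bands
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if len(self.category_means) != self.n_categories:
            raise ValueError("category_means length must equal n_categories")
        taus = self.dispersions()
        if any(t <= 0 for t in taus):
            raise ValueError("category dispersions must be > 0")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be >= 0")

    def dispersions(self) -> tuple[float, ...]:
        t = self.category_dispersions
        if np.isscalar(t):
            return (float(t),) * self.n_categories
        return tuple(float(x) for x in t)


@dataclass
class SyntheticCohort:
    records: pd.DataFrame
    meta: pd.DataFrame
    truth: GeneratorConfig


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a complete rating cohort; byte-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_p, n_c, n_k = (config.n_participants, config.n_categories,
                     config.n_pictures_per_category)
    taus = np.asarray(config.dispersions())
    mus = np.asarray(config.category_means, dtype=float)
    cats = list(config.categories)[:n_c]
    if len(cats) < n_c:
        cats += [f"category_{i}" for i in range(len(cats), n_c)]

    shifts = rng.normal(0.0, config.participant_sd, size=n_p)
    latent = mus[None, :, None] + shifts[:, None, None]  # (p, c, 1)
    raw = rng.normal(latent, taus[None, :, None], size=(n_p, n_c, n_k))
    ratings = np.clip(np.rint(raw), RATING_MIN, RATING_MAX).astype(int)

    pids = [f"P{i:05d}" for i in range(n_p)]
    records = pd.DataFrame({
        "participant_id": np.repeat(pids, n_c * n_k),
        "cohort": config.cohort,
        "category": np.tile(np.repeat(cats, n_k), n_p),
        "picture_id": np.tile([f"{c}_{j:02d}" for c in cats for j in range(n_k)], n_p),
        "rating": ratings.ravel(),
    })

    bands = list(config.age_bands)
    w = np.exp(config.age_skew * np.arange(len(bands)))
    ages = rng.choice(bands, size=n_p, p=w / w.sum())
    meta = pd.DataFrame({
        "participant_id": pids,
        "age_group": ages,
        "completion_seconds": np.round(rng.normal(1200.0, 250.0, n_p).clip(min=120.0), 1),
        "education_level": rng.choice(
            ["high_school", "some_college", "bachelor", "master"], size=n_p),
        "education_years": np.nan,
        "n_diagnosed_illnesses": rng.poisson(1.0, n_p),
    })
    band_years = {"high_school": 12, "some_college": 14, "bachelor": 16, "master": 18}
    meta["education_years"] = meta["education_level"].map(band_years).astype(float)
    return SyntheticCohort(records=records, meta=meta, truth=config)


def generate_multi_cohort(
    configs: Sequence[GeneratorConfig],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate several cohorts, prefixing participant ids per cohort."""
    recs, metas = [], []
    for cfg in configs:
        cohort = generate_cohort(cfg)
        prefix = cfg.cohort + "-"
        cohort.records["participant_id"] = prefix + cohort.records["participant_id"]
        cohort.meta["participant_id"] = prefix + cohort.meta["participant_id"]
        recs.append(cohort.records)
        metas.append(cohort.meta)
    return (pd.concat(recs, ignore_index=True),
            pd.concat(metas, ignore_index=True))


def fixture_ensembles() -> list[tuple[tuple[int, ...], dict[str, float]]]:
    """Hand-worked ensembles with their exact (K+, sigma+, H+) values.

    Used across the test suite: the uniform nonzero pattern (maximal
    entropy log2(8) = 3 bits), a two-rating pattern with proportions
    (3/4, 1/4), the all-neutral pattern (entropy fixed at 0 by convention),
    and a sign-mirrored pair.
    """
    sqrt87 = float(np.sqrt(8.0 / 7.0))  # SD of (3,1,0,...,0): SS=8, var=8/7
    h_31 = 0.75 * np.log2(4.0 / 3.0) + 0.25 * np.log2(4.0)  # = 0.811278 bits
    uniform_sd = float(np.std([2.0] * 8, ddof=1))
    return [
        ((2,) * 8, {"K_plus": 2.0, "sigma_plus": uniform_sd, "H_plus": 3.0}),
        ((3, 1, 0, 0, 0, 0, 0, 0),
         {"K_plus": 0.5, "sigma_plus": sqrt87, "H_plus": float(h_31)}),
        ((0,) * 8, {"K_plus": 0.0, "sigma_plus": 0.0, "H_plus": 0.0}),
        ((-3, -1, 0, 0, 0, 0, 0, 0),
         {"K_plus": 0.0, "sigma_plus": 0.0, "H_plus": 0.0,
          "K_minus": -0.5, "sigma_minus": sqrt87, "H_minus": float(h_31)}),
    ]
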