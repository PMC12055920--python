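"""Per-category behavioral variables of relative preference theory.

For each participant and picture category, the 8 integer Likert ratings
(−3..+3) are split into an approach part (positive ratings) and an
avoidance part (negative ratings). Three variables summarise each part:

* ``K`` — mean rating intensity across the category's pictures (signed;
  ``K+ >= 0`` for approach, ``K- <= 0`` for avoidance), in Likert points.
* ``sigma`` — sample standard deviation of the same rectified vector.
* ``H`` — Shannon entropy (bits) of the pattern of ratings, computed from
  the relative proportions ``p_i = a_i / sum_j a_j`` of rating magnitudes.
  A category rated all-neutral has no defined proportions; by convention
  its entropy is 0.

The denominator of ``K`` includes all N pictures of the category (zeros
included). The alternative — averaging only over same-valence nonzero
ratings — is available via ``denominator="nonzero"`` for sensitivity
analysis; it forces ``|K| >= 1`` and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

RATING_MIN = -3
RATING_MAX = 3

Valence = Literal["approach", "avoidance"]


@dataclass(frozen=True)
class CategoryEnsemble:
    """One participant's ratings for one picture category."""

    participant_id: str
    category: str
    ratings: tuple[int, ...]

    def __post_init__(self) -> None:
        bad = [r for r in self.ratings if not (RATING_MIN <= r <= RATING_MAX)]
        if bad:
            raise ValueError(f"ratings out of range {RATING_MIN}..{RATING_MAX}: {bad}")
        if len(self.ratings) == 0:
            raise ValueError("empty ensemble")


@dataclass(frozen=True)
class ValenceSummary:
    """(K, sigma, H) for one participant x category x valence."""

    participant_id: str
    category: str
    valence: Valence
    K: float
    sigma: float
    H: float
    n_nonzero: int
    proportions: tuple[float, ...] = field(default=())


def valence_split(ratings: Sequence[int] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectify a rating vector into approach and avoidance parts.

    Returns ``(approach, avoidance)`` where ``approach = max(a, 0)`` and
    ``avoidance = min(a, 0)`` elementwise; their sum reconstructs the input.
    """
    a = np.asarray(ratings, dtype=float)
    return np.maximum(a, 0.0), np.minimum(a, 0.0)


def mean_rating(valence_part: Sequence[float] | np.ndarray, n: int | None = None) -> float:
    """Signed mean rating K over the N category pictures (zeros included)."""
    v = np.asarray(valence_part, dtype=float)
    n = len(v) if n is None else n
    if n == 0:
        raise ValueError("ensemble size N must be positive")
    return float(v.sum() / n)


def rating_sd(valence_part: Sequence[float] | np.ndarray, n: int | None = None) -> float:
    """Sample standard deviation (N-1 denominator) of the rectified vector."""
    v = np.asarray(valence_part, dtype=float)
    n = len(v) if n is None else n
    if n < 2:
        raise ValueError("need N >= 2 for a sample standard deviation")
    return float(np.std(v, ddof=1))


def shannon_entropy(valence_part: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy (bits) of the rating-magnitude pattern.

    Proportions are taken over absolute magnitudes so the avoidance part
    (all entries <= 0) yields positive proportions; zero entries contribute
    0 via the 0*log(1/0)=0 convention; an all-zero part (K = 0) returns 0.
    """
    v = np.asarray(valence_part, dtype=float)
    if v.size and (v.max() > 0) and (v.min() < 0):
        raise ValueError("mixed-sign vector: valence_split before computing entropy")
    mags = np.abs(v)
    total = mags.sum()
    if total == 0:
        return 0.0
    p = mags[mags > 0] / total
    return float(-(p * np.log2(p)).sum())


def proportions(valence_part: Sequence[float] | np.ndarray) -> np.ndarray:
    """Relative proportions p_i over nonzero magnitudes; empty if all zero."""
    mags = np.abs(np.asarray(valence_part, dtype=float))
    total = mags.sum()
    if total == 0:
        return np.empty(0)
    return mags[mags > 0] / total


DenominatorPolicy = Literal["all", "nonzero"]


def category_summary(
    ensemble: CategoryEnsemble,
    denominator: DenominatorPolicy = "all",
) -> tuple[ValenceSummary, ValenceSummary]:
    """Compute (K, sigma, H) for the approach and avoidance parts of a category."""
    pos, neg = valence_split(ensemble.ratings)
    out = []
    for valence, part in (("approach", pos), ("avoidance", neg)):
        nz = int(np.count_nonzero(part))
        if denominator == "all":
            vec, n = part, len(part)
        elif denominator == "nonzero":
            vec = part[part != 0] if nz else part
            n = max(nz, 1)
        else:
            raise ValueError(f"unknown denominator policy: {denominator!r}")
        k = float(np.sum(vec) / n)
        sd = rating_sd(vec, len(vec)) if len(vec) >= 2 else 0.0
        out.append(
            ValenceSummary(
                participant_id=ensemble.participant_id,
                category=ensemble.category,
                valence=valence,  # type: ignore[arg-type]
                K=k,
                sigma=sd,
                H=shannon_entropy(part),
                n_nonzero=nz,
                proportions=tuple(proportions(part)),
            )
        )
    return out[0], out[1]


def summarize_ratings(
    records: pd.DataFrame,
    denominator: DenominatorPolicy = "all",
) -> pd.DataFrame:
    """Long table of (K, sigma, H) per participant x category x valence.

    ``records`` is the canonical long ratings table with columns
    participant_id, category, rating (cohort carried through if present).
    """
    rows = []
    has_cohort = "cohort" in records.columns
    grouped = records.groupby(["participant_id", "category"], sort=True, observed=True)
    for (pid, cat), grp in grouped:
        ens = CategoryEnsemble(str(pid), str(cat), tuple(int(r) for r in grp["rating"]))
        for s in category_summary(ens, denominator=denominator):
            row = {
                "participant_id": s.participant_id,
                "category": s.category,
                "valence": s.valence,
                "K": s.K,
                "sigma": s.sigma,
                "H": s.H,
                "n_nonzero": s.n_nonzero,
            }
            if has_cohort:
                row["cohort"] = grp["cohort"].iloc[0]
            rows.append(row)
    cols = ["participant_id", "category", "valence", "K", "sigma", "H", "n_nonzero"]
    if has_cohort:
        cols = ["cohort"] + cols
    return pd.DataFrame(rows, columns=cols)
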