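"""The 15 judgment features extracted from a participant's fitted curves.

Value-function features (from the (K, H) fits):

* ``LA`` — loss aversion: |slope of (log K-, log H-)| / |slope of
  (log K+, log H+)|, i.e. the ratio of avoidance to approach power-law
  exponents.
* ``RA`` — risk aversion: |H''/H'| of the approach value curve at
  K = 1.5. For the power-law ``H = b*K**a`` this is ``|a - 1| / K``.
* ``LR`` — loss resilience: the same ratio on the avoidance curve at
  |K| = 1.5.
* ``beta_plus`` / ``beta_minus`` — K-axis offsets where the logarithmic
  fit crosses H = 0: ``10**(-b/a)``, re-signed negative for avoidance.

Limit-function features (from the quadratic (K, sigma) fits, vertex
formulas for ``sigma = a*K**2 + b*K + c`` with a < 0):

* ``rho`` — turning point ``-b / (2a)`` (K at maximal sigma);
* ``alpha`` — apex ``c - b**2 / (4a)`` (the maximal sigma);
* ``q`` — quadratic area: the integral of sigma(K) over the region where
  K >= 0 and sigma >= 0, i.e. from max(0, lower root) to the upper root.

Trade-off features (from the (H-, H+) category points): mean and sample SD
of the polar angle (degrees; 0 deg = pure avoidance axis, 90 deg = pure
approach) and of the radial distance to the origin. Origin points carry a
radius of 0 but no defined angle; they are excluded from the angle
statistics and counted.

RA and LR are computed from the POWER-LAW fit: the logarithmic family has
|H''/H'| = 1/K identically — a constant carrying no individual
information — whereas the power-law closed form (1-a)/K varies with the
fitted exponent. Offsets come from the LOGARITHMIC fit, whose H = 0
crossing is well defined. A variant computing RA/LR from the logarithmic
family is exposed via ``ra_family`` for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .curve_fits import CurveFit, iqr_fence_mask

K_EVAL_DEFAULT = 1.5

FEATURE_NAMES = (
    "LA", "RA", "LR", "beta_plus", "beta_minus",
    "alpha_plus", "alpha_minus", "rho_plus", "rho_minus", "q_plus", "q_minus",
    "theta", "sigma_theta", "r", "sigma_r",
)

#: features in dimensionless units, comparable across cohorts without caveat
DIMENSIONLESS = ("LA", "RA", "LR", "theta", "sigma_theta", "r", "sigma_r")


@dataclass(frozen=True)
class FeatureVector:
    participant_id: str
    LA: float = math.nan
    RA: float = math.nan
    LR: float = math.nan
    beta_plus: float = math.nan
    beta_minus: float = math.nan
    alpha_plus: float = math.nan
    alpha_minus: float = math.nan
    rho_plus: float = math.nan
    rho_minus: float = math.nan
    q_plus: float = math.nan
    q_minus: float = math.nan
    theta: float = math.nan
    sigma_theta: float = math.nan
    r: float = math.nan
    sigma_r: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _ok(fit: CurveFit | None) -> bool:
    return fit is not None and fit.valid


def value_features(
    powerlaw_plus: CurveFit | None,
    powerlaw_minus: CurveFit | None,
    log_plus: CurveFit | None,
    log_minus: CurveFit | None,
    k_eval: float = K_EVAL_DEFAULT,
    ra_family: Literal["powerlaw", "logarithmic"] = "powerlaw",
) -> dict[str, float]:
    """LA, RA, LR and the offsets beta+- from the four value-function fits.

    Missing or inadmissible fits yield NaN for the features that depend on
    them; LA is also NaN when the approach exponent is 0.
    """
    out = {k: math.nan for k in ("LA", "RA", "LR", "beta_plus", "beta_minus")}
    if _ok(powerlaw_plus) and _ok(powerlaw_minus) and powerlaw_plus.a != 0:
        out["LA"] = abs(powerlaw_minus.a / powerlaw_plus.a)
    if ra_family == "powerlaw":
        if _ok(powerlaw_plus):
            out["RA"] = abs(powerlaw_plus.a - 1.0) / k_eval
        if _ok(powerlaw_minus):
            out["LR"] = abs(powerlaw_minus.a - 1.0) / k_eval
    else:  # |H''/H'| = 1/K for H = a*log10(K) + b, any a != 0
        if _ok(log_plus) and log_plus.a != 0:
            out["RA"] = 1.0 / k_eval
        if _ok(log_minus) and log_minus.a != 0:
            out["LR"] = 1.0 / k_eval
    if _ok(log_plus) and log_plus.a != 0:
        out["beta_plus"] = 10.0 ** (-log_plus.b / log_plus.a)
    if _ok(log_minus) and log_minus.a != 0:
        out["beta_minus"] = -(10.0 ** (-log_minus.b / log_minus.a))
    return out


def _quadratic_features(fit: CurveFit | None) -> tuple[float, float, float]:
    """(rho, alpha, q) of one concave quadratic fit; NaN when inadmissible."""
    if not _ok(fit):
        return math.nan, math.nan, math.nan
    a, b, c = fit.params
    if a >= 0:
        return math.nan, math.nan, math.nan
    rho = -b / (2.0 * a)
    alpha = c - b * b / (4.0 * a)
    disc = b * b - 4.0 * a * c
    if disc <= 0 or alpha <= 0:  # parabola never rises above the K-axis
        return rho, alpha, 0.0
    sq = math.sqrt(disc)
    lo_root = (-b + sq) / (2.0 * a)  # a < 0: this is the smaller root
    hi_root = (-b - sq) / (2.0 * a)
    lo = max(0.0, lo_root)
    if hi_root <= lo:
        return rho, alpha, 0.0
    anti = lambda k: a * k**3 / 3.0 + b * k**2 / 2.0 + c * k
    return rho, alpha, anti(hi_root) - anti(lo)


def limit_features(
    quad_plus: CurveFit | None, quad_minus: CurveFit | None
) -> dict[str, float]:
    """Vertex and area features of the two quadratic limit-function fits.

    Avoidance is computed in magnitude space (|K-|); rho_minus and q_minus
    are reported as positive magnitudes, matching the cross-cohort tables.
    """
    rp, ap, qp = _quadratic_features(quad_plus)
    rm, am, qm = _quadratic_features(quad_minus)
    return {
        "rho_plus": rp, "alpha_plus": ap, "q_plus": qp,
        "rho_minus": rm, "alpha_minus": am, "q_minus": qm,
    }


def tradeoff_features(points: Iterable[tuple[float, float]]) -> dict[str, float]:
    """theta, sigma_theta, r, sigma_r from a participant's (H-, H+) points.

    Angles are measured from the H- axis (atan2(H+, H-), degrees). A single
    usable point has SD 0 by convention. If every point sits at the origin
    the angle features are NaN and the radial features are 0.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise ValueError("need at least one (H-, H+) point")
    hm, hp = pts[:, 0], pts[:, 1]
    radii = np.sqrt(hm**2 + hp**2)
    usable = radii > 0
    out = {
        "r": float(radii.mean()),
        "sigma_r": float(np.std(radii, ddof=1)) if len(radii) > 1 else 0.0,
    }
    if usable.sum() == 0:
        out["theta"] = math.nan
        out["sigma_theta"] = math.nan
    else:
        ang = np.degrees(np.arctan2(hp[usable], hm[usable]))
        out["theta"] = float(ang.mean())
        out["sigma_theta"] = float(np.std(ang, ddof=1)) if usable.sum() > 1 else 0.0
    return out


def extract_features(
    participant_id: str,
    powerlaw_plus: CurveFit | None,
    powerlaw_minus: CurveFit | None,
    log_plus: CurveFit | None,
    log_minus: CurveFit | None,
    quad_plus: CurveFit | None,
    quad_minus: CurveFit | None,
    tradeoff_points: Iterable[tuple[float, float]],
    k_eval: float = K_EVAL_DEFAULT,
    ra_family: Literal["powerlaw", "logarithmic"] = "powerlaw",
) -> FeatureVector:
    """Assemble the full 15-feature vector for one participant."""
    vals = value_features(powerlaw_plus, powerlaw_minus, log_plus, log_minus,
                          k_eval=k_eval, ra_family=ra_family)
    vals.update(limit_features(quad_plus, quad_minus))
    vals.update(tradeoff_features(tradeoff_points))
    return FeatureVector(participant_id=participant_id, **vals)


# --------------------------------------------------------------------------
# feature-level outlier policies


@dataclass(frozen=True)
class OutlierPolicy:
    """Feature-level exclusion policy.

    ``mode``: "threshold" excludes extreme LA and q+ values (the large-cohort
    screen: LA > 200, q+ > 100); "iqr" applies a 3xIQR fence per feature;
    "none" retains everything.
    """

    mode: Literal["threshold", "iqr", "none"] = "threshold"
    la_threshold: float = 200.0
    q_plus_threshold: float = 100.0
    iqr_multiplier: float = 3.0


def feature_outlier_filter(
    table: pd.DataFrame, policy: OutlierPolicy = OutlierPolicy()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the feature-level outlier policy to a feature table.

    Returns ``(retained, exclusion_log)`` where the log has one row per
    excluded participant with the triggering feature names.
    """
    excluded_reasons: dict[str, list[str]] = {}
    if policy.mode == "threshold":
        for pid, la in zip(table["participant_id"], table["LA"]):
            if np.isfinite(la) and la > policy.la_threshold:
                excluded_reasons.setdefault(str(pid), []).append("LA")
        for pid, qp in zip(table["participant_id"], table["q_plus"]):
            if np.isfinite(qp) and qp > policy.q_plus_threshold:
                excluded_reasons.setdefault(str(pid), []).append("q_plus")
    elif policy.mode == "iqr":
        for name in FEATURE_NAMES:
            col = table[name].to_numpy(dtype=float)
            finite = np.isfinite(col)
            if finite.sum() < 4:
                continue
            mask = np.ones(len(col), bool)
            mask[finite] = iqr_fence_mask(col[finite], policy.iqr_multiplier)
            for pid in table.loc[~mask, "participant_id"]:
                excluded_reasons.setdefault(str(pid), []).append(name)
    elif policy.mode != "none":
        raise ValueError(f"unknown outlier mode: {policy.mode!r}")
    log = pd.DataFrame(
        [{"participant_id": pid, "reasons": ";".join(rs)}
         for pid, rs in sorted(excluded_reasons.items())],
        columns=["participant_id", "reasons"],
    )
    retained = table[~table["participant_id"].astype(str).isin(excluded_reasons)]
    return retained.reset_index(drop=True), log
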