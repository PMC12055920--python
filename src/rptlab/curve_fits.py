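"""Curve families of relative preference theory and their least-squares fits.

Three graphical relationships are fitted, at individual and group level:

* value function (K, H): logarithmic ``H = a*log10(K) + b`` and power-law
  ``H = b*K**a``, both obtained by simple linear regression after the
  appropriate log10 transformation of the axes;
* limit function (K, sigma): quadratic ``sigma = a*K**2 + b*K + c``;
* trade-off function (H-, H+): radial, summarised by the mean radial
  distance ``r = mean(sqrt(H-^2 + H+^2))``.

Avoidance-side fits operate on magnitudes |K-| so that the logarithms are
defined and the fitted curves live in the first quadrant; signs are
restored downstream where a signed quantity (the negative offset) is
reported.

Goodness of fit (R^2, adjusted R^2, F, p) is computed in the regression
space — i.e. on the transformed coordinates the linear regression sees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

Family = Literal["logarithmic", "powerlaw", "quadratic", "radial"]


@dataclass(frozen=True)
class FitQuality:
    r2: float
    r2_adj: float
    f_statistic: float
    p_value: float


@dataclass(frozen=True)
class CurveFit:
    """Parameters and quality of one fitted curve.

    ``params`` holds (a, b) for logarithmic and power-law, (a, b, c) for
    quadratic, and (r_mean,) for radial fits. ``valid`` is False when the
    admissibility preconditions (enough usable points, non-degenerate
    design) were not met; params are then NaN.
    """

    family: Family
    params: tuple[float, ...]
    quality: FitQuality
    n_points: int
    n_dropped: int = 0
    valid: bool = True
    degenerate: bool = False
    scale_invariant: bool | None = None
    radii: tuple[float, ...] = field(default=(), repr=False)

    @property
    def a(self) -> float:
        return self.params[0]

    @property
    def b(self) -> float:
        return self.params[1]

    @property
    def c(self) -> float:
        return self.params[2]

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.family == "logarithmic":
            return self.a * np.log10(x) + self.b
        if self.family == "powerlaw":
            return self.b * x ** self.a
        if self.family == "quadratic":
            a, b, c = self.params
            return a * x**2 + b * x + c
        raise ValueError(f"predict undefined for family {self.family!r}")


_INVALID_Q = FitQuality(math.nan, math.nan, math.nan, math.nan)


def _invalid(family: Family, n_points: int, n_dropped: int) -> CurveFit:
    nparams = {"logarithmic": 2, "powerlaw": 2, "quadratic": 3}.get(family, 1)
    return CurveFit(family, (math.nan,) * nparams, _INVALID_Q, n_points, n_dropped, valid=False)


def _regression_quality(y: np.ndarray, yhat: np.ndarray, n_coef: int) -> tuple[FitQuality, bool]:
    """R^2, adjusted R^2, overall F and p for a least-squares fit.

    ``n_coef`` counts regression coefficients excluding the intercept.
    Degenerate SST=0 is defined as R^2 = 1 if residuals also vanish, else 0.
    """
    n = len(y)
    ssr = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    tiny = np.finfo(float).eps * n * (1.0 + float(np.mean(y**2)))
    degenerate = sst <= tiny
    if degenerate:
        r2 = 1.0 if ssr <= tiny else 0.0
    else:
        r2 = 1.0 - ssr / sst
    dof = n - n_coef - 1
    if dof > 0 and not degenerate:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        if ssr > tiny:
            f = max(0.0, (sst - ssr) / n_coef) / (ssr / dof)
            p = float(stats.f.sf(f, n_coef, dof))
        else:
            f, p = math.inf, 0.0
    else:
        r2_adj, f, p = math.nan, math.nan, math.nan
    return FitQuality(r2, r2_adj, f, p), degenerate


def _as_xy(points: Iterable[tuple[float, float]] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    return arr[:, 0], arr[:, 1]


def fit_logarithmic(points: Iterable[tuple[float, float]], min_points: int = 3) -> CurveFit:
    """OLS of y on log10(x); points with x <= 0 are dropped and counted."""
    x, y = _as_xy(points)
    keep = x > 0
    dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < min_points or np.ptp(x) == 0:
        return _invalid("logarithmic", len(x), dropped)
    lx = np.log10(x)
    slope, intercept = np.polyfit(lx, y, 1)
    quality, degen = _regression_quality(y, slope * lx + intercept, 1)
    return CurveFit("logarithmic", (float(slope), float(intercept)), quality,
                    len(x), dropped, degenerate=degen)


def fit_powerlaw(points: Iterable[tuple[float, float]], min_points: int = 3) -> CurveFit:
    """OLS of log10(y) on log10(x); exponent a = slope, prefactor b = 10**intercept.

    Points with x <= 0 or y <= 0 (e.g. zero-entropy categories) are dropped
    and counted. The ``scale_invariant`` flag records asymptotic behavior,
    0 < a < 1.
    """
    x, y = _as_xy(points)
    keep = (x > 0) & (y > 0)
    dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < min_points or np.ptp(x) == 0:
        return _invalid("powerlaw", len(x), dropped)
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    quality, degen = _regression_quality(ly, slope * lx + intercept, 1)
    return CurveFit("powerlaw", (float(slope), float(10**intercept)), quality,
                    len(x), dropped, degenerate=degen,
                    scale_invariant=bool(0 < slope < 1))


def fit_quadratic(points: Iterable[tuple[float, float]], min_points: int = 3) -> CurveFit:
    """Degree-2 polynomial least squares; concavity is judged downstream (a < 0)."""
    x, y = _as_xy(points)
    if len(x) < min_points or len(np.unique(x)) < 3:
        return _invalid("quadratic", len(x), 0)
    a, b, c = np.polyfit(x, y, 2)
    quality, degen = _regression_quality(y, a * x**2 + b * x + c, 2)
    return CurveFit("quadratic", (float(a), float(b), float(c)), quality,
                    len(x), 0, degenerate=degen)


def fit_radial(points: Iterable[tuple[float, float]]) -> CurveFit:
    """Mean radial distance of (H-, H+) points from the origin."""
    hm, hp = _as_xy(points)
    if len(hm) == 0:
        raise ValueError("radial fit needs at least one point")
    radii = np.sqrt(hm**2 + hp**2)
    return CurveFit("radial", (float(radii.mean()),), _INVALID_Q, len(radii),
                    radii=tuple(float(r) for r in radii))


# --------------------------------------------------------------------------
# admissibility screening


@dataclass(frozen=True)
class AdmissibilityDecision:
    admissible: bool
    checks: dict[str, bool]
    reasons: tuple[str, ...]
    n_fenced: int = 0


def iqr_fence_mask(values: Sequence[float] | np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean mask of values within [Q1 - k*IQR, Q3 + k*IQR]."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - k * iqr) & (v <= q3 + k * iqr)


@dataclass(frozen=True)
class AdmissibilityPolicy:
    iqr_fence: bool = True
    iqr_multiplier: float = 3.0
    min_points: int = 3
    require_coherence: bool = True


def _curve_direction(fit: CurveFit) -> float:
    """Sign-bearing shape parameter: slope for log/power, curvature for quadratic."""
    return fit.params[0]


def fit_admissibility(
    fit: CurveFit,
    points: Iterable[tuple[float, float]],
    group_reference: CurveFit | None = None,
    policy: AdmissibilityPolicy = AdmissibilityPolicy(),
) -> AdmissibilityDecision:
    """Apply the model-fit inclusion criteria to an individual fit.

    Checks: the fit itself is valid (enough usable points, computable R^2);
    optionally no point lies beyond the 3xIQR fence of the y-values; and the
    curve direction (slope or curvature sign) agrees with the group-level
    reference fit.
    """
    x, y = _as_xy(points)
    checks: dict[str, bool] = {}
    n_fenced = 0
    checks["valid_fit"] = bool(fit.valid and np.isfinite(fit.quality.r2))
    checks["enough_points"] = bool(fit.valid and fit.n_points >= policy.min_points)
    if policy.iqr_fence and len(y):
        mask = iqr_fence_mask(y, policy.iqr_multiplier)
        n_fenced = int((~mask).sum())
        checks["iqr_fence"] = n_fenced == 0
    if policy.require_coherence and group_reference is not None and fit.valid:
        if fit.family != group_reference.family:
            raise ValueError("coherence check requires same-family group reference")
        d_i, d_g = _curve_direction(fit), _curve_direction(group_reference)
        checks["coherence"] = bool(np.sign(d_i) == np.sign(d_g) and d_i != 0)
    failed = tuple(name for name, ok in checks.items() if not ok)
    return AdmissibilityDecision(not failed, checks, failed, n_fenced)


# --------------------------------------------------------------------------
# boundary envelopes


@dataclass(frozen=True)
class EnvelopeFit:
    family: Family
    params: tuple[float, ...]
    base_fit: CurveFit
    shift: float
    containment: float

    def predict(self, x: np.ndarray | float):
        shifted = CurveFit(self.family, self.params, _INVALID_Q, self.base_fit.n_points)
        return shifted.predict(x)


def fit_boundary_envelope(
    points: Iterable[tuple[float, float]],
    family: Literal["logarithmic", "powerlaw", "quadratic"],
    quantile: float = 0.95,
    min_points: int = 20,
) -> EnvelopeFit:
    """Outer bound of the fitted family containing >= ``quantile`` of the cloud.

    The family is fitted to the points, then translated upward (along y, in
    the family's natural space) by the ``quantile`` level of the signed
    residuals, so that at least that fraction of points lies on or below the
    envelope. The quantile uses linear interpolation.
    """
    pts = np.asarray(list(points), dtype=float)
    if len(pts) < min_points:
        raise ValueError(f"envelopes are group-level constructs; need >= {min_points} points")
    fitter = {"logarithmic": fit_logarithmic, "powerlaw": fit_powerlaw,
              "quadratic": fit_quadratic}[family]
    base = fitter(pts)
    if not base.valid:
        raise ValueError("base fit invalid; cannot construct envelope")
    x, y = pts[:, 0], pts[:, 1]
    if family == "powerlaw":
        keep = (x > 0) & (y > 0)
        resid = np.log10(y[keep]) - np.log10(np.asarray(base.predict(x[keep])))
        shift = float(np.quantile(resid, quantile))
        params = (base.a, base.b * 10**shift)
    elif family == "logarithmic":
        keep = x > 0
        resid = y[keep] - np.asarray(base.predict(x[keep]))
        shift = float(np.quantile(resid, quantile))
        params = (base.a, base.b + shift)
    else:
        keep = np.ones(len(x), bool)
        resid = y - np.asarray(base.predict(x))
        shift = float(np.quantile(resid, quantile))
        a, b, c = base.params
        params = (a, b, c + shift)
    env = CurveFit(family, params, _INVALID_Q, base.n_points)
    xk, yk = x[keep], y[keep]
    contained = yk <= np.asarray(env.predict(xk)) + 1e-12
    return EnvelopeFit(family, params, base, shift, float(contained.mean()))
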