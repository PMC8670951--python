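"""Log–log allometric machinery.

Major-axis (first principal axis) regression gives per-part allometric
coefficients; a continuous two-phase "hinge" regression with a grid
maximum-likelihood change-point estimate captures abrupt slope changes,
with pairs-bootstrap percentile confidence intervals for the change point.
Change points estimated on CEL or TRL scales can be standardized to the
body-length (BOL) scale through a reference hinge fit, and located within
the observed per-stage size ranges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .data_model import HOLASPID, MERASPID, derived_value

#: Fraction of points required strictly on each side of a candidate threshold.
TRIM_FRACTION = 0.10

#: |beta2| below this (relative to max(1, |beta1|)) means no detectable change.
NO_CHANGE_TOL = 1e-8


# ---------------------------------------------------------------------------
# Major axis regression


@dataclass(frozen=True)
class MAFit:
    """Major-axis regression slope (allometric coefficient) with bootstrap CI."""

    slope: float
    intercept: float
    ci: Tuple[float, float]
    n: int
    response: str = ""
    predictor: str = ""
    period: str = ""


def _ma_slope(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(np.var(x))
    syy = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    if sxy == 0.0:
        if sxx == syy:
            raise ValueError("major-axis slope undefined: isotropic scatter")
        if syy > sxx:
            raise ValueError("major-axis slope undefined: vertical principal axis")
        return 0.0
    return (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)


def ma_fit(x, y, *, boot_reps: int = 1000, seed: int = 0,
           response: str = "", predictor: str = "", period: str = "") -> MAFit:
    """Major-axis regression of ``y`` on ``x`` (both already log scale).

    The slope is the first principal axis of the (x, y) scatter; the 95% CI
    is a seeded pairs-bootstrap percentile interval.  Degenerate bootstrap
    replicates (e.g. a single repeated point) are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 points, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in MA input")
    if np.ptp(x) == 0:
        raise ValueError("all x identical; slope undefined")

    slope = _ma_slope(x, y)
    intercept = float(y.mean() - slope * x.mean())

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(boot_reps):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(_ma_slope(x[idx], y[idx]))
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:  # pragma: no cover - pathological data
        lo = hi = slope
    return MAFit(slope=slope, intercept=intercept, ci=(float(lo), float(hi)),
                 n=n, response=response, predictor=predictor, period=period)


def segment_coefficient_profile(specimens, period: str, *, min_n: int = 3,
                                boot_reps: int = 200, seed: int = 0) -> list:
    """MA allometric coefficients per thoracic segment and cephalic part.

    Fits ln LTS_i ~ ln TRL per segment, ln FAL/PGL/ORL ~ ln CEL, and
    ln CEL / ln TRL ~ ln BOL, restricted to one period.  Parts with fewer
    than ``min_n`` usable specimens are omitted with a warning.
    """
    if period not in (MERASPID, HOLASPID):
        raise ValueError(f"unknown period {period!r}")
    group = [s for s in specimens if s.period == period]
    if not group:
        raise ValueError(f"no {period} specimens")

    max_seg = max((s.n_segments() for s in group), default=0)
    pairs = [(f"LTS{i}", "TRL") for i in range(1, max_seg + 1)]
    pairs += [("FAL", "CEL"), ("PGL", "CEL"), ("ORL", "CEL"),
              ("CEL", "BOL"), ("TRL", "BOL")]

    fits = []
    for resp, pred in pairs:
        xs, ys = [], []
        for s in group:
            yv = derived_value(s, resp)
            xv = derived_value(s, pred)
            if yv is not None and xv is not None:
                xs.append(math.log(xv))
                ys.append(math.log(yv))
        if len(xs) < min_n:
            warnings.warn(
                f"{resp}~{pred} ({period}): only {len(xs)} specimens, omitted",
                stacklevel=2)
            continue
        try:
            fits.append(ma_fit(np.array(xs), np.array(ys),
                               boot_reps=boot_reps, seed=seed, response=resp,
                               predictor=pred, period=period))
        except ValueError as exc:
            warnings.warn(f"{resp}~{pred} ({period}): {exc}; omitted",
                          stacklevel=2)
    return fits


# ---------------------------------------------------------------------------
# Two-phase (hinge) threshold regression


@dataclass
class ThresholdFit:
    """Continuous two-phase log–log regression with an estimated change point.

    ``slope_pre`` (= beta1) and ``slope_post`` (= beta1 + beta2) are the
    allometric coefficients before and after the change point ``tau``
    (ln scale); ``changepoint_mm = exp(tau)``.
    """

    beta0: float
    beta1: float
    beta2: float
    tau: float
    rss: float
    sigma: float
    n: int
    x_range: Tuple[float, float]
    grid: np.ndarray = field(repr=False, default=None)
    grid_rss: np.ndarray = field(repr=False, default=None)
    response: str = ""
    predictor: str = ""
    ci_mm: Optional[Tuple[float, float]] = None

    @property
    def slope_pre(self) -> float:
        return self.beta1

    @property
    def slope_post(self) -> float:
        return self.beta1 + self.beta2

    @property
    def changepoint_mm(self) -> float:
        return math.exp(self.tau)

    @property
    def no_change(self) -> bool:
        """True when the slope shift is numerically indistinguishable from 0."""
        return abs(self.beta2) <= NO_CHANGE_TOL * max(1.0, abs(self.beta1))

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.beta0 + self.beta1 * x + self.beta2 * np.maximum(
            x - self.tau, 0.0)


def _candidate_grid(x: np.ndarray) -> np.ndarray:
    n = len(x)
    need = max(1, math.ceil(TRIM_FRACTION * n))
    uniq = np.unique(x)
    keep = [t for t in uniq
            if np.sum(x < t) >= need and np.sum(x > t) >= need]
    return np.asarray(keep)


def _hinge_rss(x: np.ndarray, y: np.ndarray, tau: float):
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - tau, 0.0)])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def hinge_fit(x, y, *, response: str = "", predictor: str = "") -> ThresholdFit:
    """Grid maximum-likelihood fit of the continuous hinge model.

    Candidate change points are the unique observed x values with at least
    10% of points strictly on each side; for each candidate an OLS fit of
    y on {1, x, (x - tau)_+} is evaluated, and the RSS-minimizing candidate
    is the ML estimate under Gaussian errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError(f"need n >= 8 points for a hinge fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor range")
    grid = _candidate_grid(x)
    if len(grid) < 2:
        raise ValueError(
            f"insufficient span: only {len(grid)} admissible threshold "
            "candidates")

    rss_grid = np.empty(len(grid))
    best = None
    for j, tau in enumerate(grid):
        rss, beta = _hinge_rss(x, y, tau)
        rss_grid[j] = rss
        if best is None or rss < best[0]:
            best = (rss, beta, float(tau))
    rss, beta, tau = best
    return ThresholdFit(
        beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
        tau=tau, rss=rss, sigma=math.sqrt(rss / n), n=n,
        x_range=(float(x.min()), float(x.max())),
        grid=grid, grid_rss=rss_grid, response=response, predictor=predictor)


def hinge_bootstrap_ci(x, y, *, reps: int = 1000, seed: int = 0,
                       max_failure_rate: float = 0.20) -> Tuple[float, float]:
    """Pairs-bootstrap percentile 95% CI for the change point, in mm."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hinge_fit(x, y)  # must succeed on the full data
    rng = np.random.default_rng(seed)
    taus, failures = [], 0
    n = len(x)
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            taus.append(hinge_fit(x[idx], y[idx]).tau)
        except ValueError:
            failures += 1
    if failures > max_failure_rate * reps:
        raise RuntimeError(
            f"hinge bootstrap failed in {failures}/{reps} replicates "
            f"({failures / reps:.0%})")
    lo, hi = np.percentile(taus, [2.5, 97.5])
    return (math.exp(lo), math.exp(hi))


def standardize_changepoint_to_bol(cp_mm: float,
                                   reference_fit: ThresholdFit) -> float:
    """Express a CEL- or TRL-scale change point on the BOL scale.

    ``reference_fit`` must be a hinge fit of ln BOL on the change point's
    own predictor; no extrapolation outside its observed range.
    """
    lx = math.log(cp_mm)
    lo, hi = reference_fit.x_range
    if not lo <= lx <= hi:
        raise ValueError(
            f"change point {cp_mm:.4g} mm outside the reference fit range "
            f"[{math.exp(lo):.4g}, {math.exp(hi):.4g}] mm")
    return math.exp(float(reference_fit.predict(lx)))


# ---------------------------------------------------------------------------
# Stage assignment


def stage_for_size(value: float, variable: str, specimens) -> list:
    """Degrees whose observed [min, max] of ``variable`` contains ``value``."""
    ranges: dict = {}
    for s in specimens:
        if s.period != MERASPID or s.degree is None:
            continue
        v = derived_value(s, variable)
        if v is None:
            continue
        lo, hi = ranges.get(s.degree, (math.inf, -math.inf))
        ranges[s.degree] = (min(lo, v), max(hi, v))
    return sorted(d for d, (lo, hi) in ranges.items() if lo <= value <= hi)


def format_stage_set(degrees: Sequence[int], holaspid: bool = False) -> str:
    """Render a degree set in compact form, e.g. ``"D8-10"`` or ``"H"``."""
    if holaspid or not degrees:
        return "H"
    degrees = sorted(degrees)
    if degrees == list(range(degrees[0], degrees[-1] + 1)) and len(degrees) > 1:
        return f"D{degrees[0]}-{degrees[-1]}"
    if len(degrees) == 1:
        return f"D{degrees[0]}"
    return ",".join(f"D{d}" for d in degrees)
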