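"""Segmental (SG) and trunk (TG) growth-gradient models.

Two model families explain relative thoracic segment lengths across
meraspid ontogeny:

* SG models give each segment an autonomous growth rule once released
  from the pygidium — SG-R keeps the segment/trunk growth-rate ratio
  constant, SG-A keeps the segment-vs-trunk allometric coefficient
  constant.
* TG models treat segment boundaries as landmarks in a continuous trunk
  growth field whose log-linear gradient slope changes per stage, driven
  either by the observed trunk growth rate (TG-T) or by stage (TG-D).

SG models predict relative segment lengths (RLS); TG models natively
predict relative posterior-boundary positions (RPS) and derive RLS by
differencing.  Fitting is nonlinear least squares (Levenberg–Marquardt)
with deterministic multistart; models are compared with AICc, Akaike
weights and evidence ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

SG_MODELS = ("SG-R", "SG-A")
TG_MODELS = ("TG-T", "TG-D")
ALL_MODELS = SG_MODELS + TG_MODELS

#: Number of fitted model parameters per family (AICc adds one for sigma^2).
N_PARAMS = {"SG-R": 3, "SG-A": 3, "TG-T": 4, "TG-D": 4}


# ---------------------------------------------------------------------------
# Point predictions


def sg_r_predict(A: float, B: float, r: float, i, s):
    """SG-R relative segment length: ``A * B**(i-1) * r**(s-i)``.

    Release size declines geometrically with release stage ``i``; after
    release the segment keeps a constant per-stage relative factor ``r``.
    """
    i = np.asarray(i)
    s = np.asarray(s)
    if np.any(i > s):
        raise ValueError("segment index i exceeds stage s (not yet released)")
    if np.any(i < 1):
        raise ValueError("segment index i must be >= 1")
    return A * B ** (i - 1) * r ** (s - i)


def sg_a_predict(A: float, B: float, k: float, i, s,
                 trl_series: Mapping[int, float]):
    """SG-A relative segment length: ``A * B**(i-1) * (TRL_s/TRL_i)**(k-1)``.

    ``k`` is the constant allometric coefficient of a segment with respect
    to the trunk after its release at stage ``i``.
    """
    scalar = np.ndim(i) == 0 and np.ndim(s) == 0
    i = np.atleast_1d(np.asarray(i))
    s = np.atleast_1d(np.asarray(s))
    if np.any(i > s):
        raise ValueError("segment index i exceeds stage s (not yet released)")
    try:
        trl_s = np.asarray([trl_series[int(v)] for v in s])
        trl_i = np.asarray([trl_series[int(v)] for v in i])
    except KeyError as exc:
        raise ValueError(f"missing mean-TRL covariate for stage {exc}") from exc
    out = A * B ** (i - 1.0) * (trl_s / trl_i) ** (k - 1.0)
    return float(out[0]) if scalar else out


def tg_position_map(p, b: float):
    """Relative-coordinate image of a material point under a log-linear field.

    A growth field ``g(p) ∝ exp(b*p)`` along the unit trunk moves a point at
    relative position ``p`` to ``(exp(b*p) - 1) / (exp(b) - 1)``; ``b = 0``
    is the identity map.  Endpoints 0 and 1 are fixed for every ``b``.
    """
    p = np.asarray(p, dtype=float)
    if abs(b) < 1e-12:
        # second-order expansion avoids 0/0 while staying smooth in b
        out = p + 0.5 * b * p * (p - 1.0)
    else:
        out = np.expm1(b * p) / np.expm1(b)
    return out if out.shape else float(out)


def tg_predict(c0: float, c1: float, q0: float, q1: float, *,
               stages: Sequence[int],
               link: str,
               trg_series: Optional[Mapping[int, float]] = None,
               response: str = "RPS") -> dict:
    """Predict RPS (or RLS by differencing) for a TG model.

    A segment's posterior boundary enters the thorax at the
    thorax/pygidium junction, ``RPS(i, i) = 1 - q0*q1**i``, then is carried
    by the growth field: ``RPS(i, s+1) = phi_{b_s}(RPS(i, s))`` where the
    gradient slope is ``b_s = c0 + c1*ln(TRG_s)`` (link ``"trg"``) or
    ``b_s = c0 + c1*s`` (link ``"stage"``).

    Returns a dict keyed by ``(segment, stage)``.
    """
    if link not in ("trg", "stage"):
        raise ValueError(f"unknown link {link!r}")
    stages = sorted(int(s) for s in stages)
    lo, hi = stages[0], stages[-1]

    def slope(s: int) -> float:
        if link == "stage":
            return c0 + c1 * s
        if trg_series is None:
            raise ValueError("TG-T requires a TRG covariate series")
        try:
            return c0 + c1 * math.log(trg_series[s])
        except KeyError as exc:
            raise ValueError(f"missing TRG covariate for stage {exc}") from exc

    rps: dict = {}
    for i in range(1, hi + 1):
        p = 1.0 - q0 * q1 ** i
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"TG initial condition outside (0,1): q0={q0}, q1={q1}, i={i}")
        rps[(i, i)] = p
        for s in range(i, hi):
            p = float(tg_position_map(p, slope(s)))
            rps[(i, s + 1)] = p

    if response == "RPS":
        return {k: v for k, v in rps.items() if k[1] >= lo}
    if response == "RLS":
        out = {}
        for (i, s), v in rps.items():
            if s < lo:
                continue
            prev = rps[(i - 1, s)] if i > 1 else 0.0
            out[(i, s)] = v - prev
        return out
    raise ValueError(f"unknown response {response!r}")


# ---------------------------------------------------------------------------
# Observations container


@dataclass
class GradientObservations:
    """Stage-mean RLS or RPS observations indexed by (segment, stage).

    ``trl_series`` maps stage to mean trunk length (SG-A covariate); TRG
    values for TG-T are derived from it as consecutive ratios.
    """

    index: list
    values: np.ndarray
    response: str
    trl_series: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def trg_series(self) -> dict:
        return {s: self.trl_series[s + 1] / self.trl_series[s]
                for s in self.trl_series if s + 1 in self.trl_series}

    @property
    def stages(self) -> list:
        return sorted({s for _, s in self.index})

    @classmethod
    def from_summaries(cls, summaries, response: str = "RLS",
                       stages: Optional[Sequence[int]] = None
                       ) -> "GradientObservations":
        if response not in ("RLS", "RPS"):
            raise ValueError(f"unknown response {response!r}")
        by_degree = {s.degree: s for s in summaries}
        if stages is None:
            stages = [d for d in sorted(by_degree) if d >= 1]
        index, values, trl = [], [], {}
        for s in stages:
            summ = by_degree.get(s)
            if summ is None:
                continue
            vec = summ.mean_rls if response == "RLS" else summ.mean_rps
            if vec is None:
                continue
            if "TRL" in summ.mean_parts:
                trl[s] = summ.mean_parts["TRL"]
            for i, v in enumerate(vec, start=1):
                index.append((i, s))
                values.append(v)
        return cls(index=index, values=np.asarray(values, dtype=float),
                   response=response, trl_series=trl)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class GradientModelFit:
    """One fitted gradient model with its selection statistics."""

    model: str
    response: str
    params: dict
    rss: float
    tss: float
    n: int
    n_params: int
    aicc: float
    n_starts: int
    n_converged: int
    delta_aicc: Optional[float] = None
    weight: Optional[float] = None

    @property
    def pct_variance(self) -> float:
        return 100.0 * (1.0 - self.rss / self.tss)


def aicc(rss: float, n: int, n_params: int) -> float:
    """Least-squares AICc with the residual variance counted as a parameter."""
    k = n_params + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, K={k}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(scores) -> np.ndarray:
    """Normalized model probabilities from a set of AICc scores."""
    scores = np.asarray(scores, dtype=float)
    delta = scores - scores.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def evidential_ratio(weight_a: float, weight_b: float) -> float:
    """Evidence ratio of model a over model b (ratio of Akaike weights)."""
    return weight_a / weight_b


_PENALTY = 1e6


def _predict(model: str, theta: np.ndarray, obs: GradientObservations
             ) -> np.ndarray:
    seg = np.array([i for i, _ in obs.index])
    stg = np.array([s for _, s in obs.index])
    if model == "SG-R":
        A, B, r = np.exp(theta)
        return np.asarray(sg_r_predict(A, B, r, seg, stg))
    if model == "SG-A":
        A, B = np.exp(theta[:2])
        k = theta[2]
        return np.asarray(sg_a_predict(A, B, k, seg, stg, obs.trl_series))
    c0, c1 = theta[0], theta[1]
    q0, q1 = np.exp(theta[2]), np.exp(theta[3])
    link = "trg" if model == "TG-T" else "stage"
    table = tg_predict(c0, c1, q0, q1, stages=obs.stages, link=link,
                       trg_series=obs.trg_series if link == "trg" else None,
                       response=obs.response)
    return np.array([table[key] for key in obs.index])


def _residuals(model, theta, obs):
    try:
        pred = _predict(model, theta, obs)
    except (ValueError, OverflowError, FloatingPointError):
        return np.full(obs.n, _PENALTY)
    if not np.all(np.isfinite(pred)):
        return np.full(obs.n, _PENALTY)
    return pred - obs.values


def _sg_heuristic_start(model: str, obs: GradientObservations) -> Optional[np.ndarray]:
    """Log-space OLS start; exact at zero noise for RLS observations."""
    if obs.response != "RLS" or np.any(obs.values <= 0):
        return None
    seg = np.array([i for i, _ in obs.index], dtype=float)
    stg = np.array([s for _, s in obs.index], dtype=float)
    y = np.log(obs.values)
    if model == "SG-R":
        X = np.column_stack([np.ones_like(seg), seg - 1, stg - seg])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef  # (lnA, lnB, ln r)
    try:
        ratio = np.array([math.log(obs.trl_series[int(s)] / obs.trl_series[int(i)])
                          for i, s in obs.index])
    except KeyError:
        return None
    X = np.column_stack([np.ones_like(seg), seg - 1, ratio])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return np.array([coef[0], coef[1], coef[2] + 1.0])  # (lnA, lnB, k)


def _tg_q_heuristic(obs: GradientObservations) -> tuple:
    """(ln q0, ln q1) from the pygidial share RPYL(s) = q0 * q1**s."""
    table = {key: v for key, v in zip(obs.index, obs.values)}
    pts = []
    for s in obs.stages:
        if obs.response == "RPS":
            v = table.get((s, s))
            rpyl = None if v is None else 1.0 - v
        else:
            vals = [table.get((i, s)) for i in range(1, s + 1)]
            rpyl = None if any(v is None for v in vals) else 1.0 - sum(vals)
        if rpyl is not None and 0 < rpyl < 1:
            pts.append((s, math.log(rpyl)))
    if len(pts) < 2:
        return (math.log(0.4), math.log(0.9))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(xs, ys, 1)
    return (float(intercept), float(slope))


def _starts(model: str, obs: GradientObservations) -> list:
    """Deterministic multistart list: heuristic first, then a small grid."""
    starts = []
    if model in SG_MODELS:
        h = _sg_heuristic_start(model, obs)
        if h is not None:
            starts.append(h)
        lnA_grid = (math.log(0.03), math.log(0.1), math.log(0.3))
        lnB_grid = (math.log(0.7), 0.0, math.log(1.2))
        third = ((math.log(0.8), 0.0, math.log(1.1)) if model == "SG-R"
                 else (0.5, 1.0, 1.5))
        for a in lnA_grid:
            for b in lnB_grid:
                for t in third:
                    starts.append(np.array([a, b, t]))
    else:
        lnq0, lnq1 = _tg_q_heuristic(obs)
        c0_grid = (0.0, 0.5, 1.0)
        c1_grid = ((-2.0, 0.0, 2.0) if model == "TG-T"
                   else (-0.1, 0.0, 0.1))
        for a in c0_grid:
            for b in c1_grid:
                starts.append(np.array([a, b, lnq0, lnq1]))
                starts.append(np.array([a, b, math.log(0.4), math.log(0.9)]))
    return starts


def _params_dict(model: str, theta: np.ndarray) -> dict:
    if model == "SG-R":
        A, B, r = np.exp(theta)
        return {"A": A, "B": B, "r": r}
    if model == "SG-A":
        return {"A": math.exp(theta[0]), "B": math.exp(theta[1]), "k": theta[2]}
    return {"c0": theta[0], "c1": theta[1],
            "q0": math.exp(theta[2]), "q1": math.exp(theta[3])}


def _valid_params(model: str, theta: np.ndarray, obs: GradientObservations) -> bool:
    p = _params_dict(model, theta)
    if model in TG_MODELS:
        hi = max(obs.stages)
        for i in range(1, hi + 1):
            if not 0.0 < p["q0"] * p["q1"] ** i < 1.0:
                return False
    return all(np.isfinite(v) for v in p.values())


def fit_gradient_model(model: str, obs: GradientObservations,
                       starts: Optional[Sequence] = None) -> GradientModelFit:
    """Levenberg–Marquardt fit of one gradient model from a multistart list.

    Positivity constraints are enforced through log parameterization; TG
    initial-condition admissibility is checked on the converged optimum.
    Ties on RSS keep the first converged start.
    """
    if model not in ALL_MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model in SG_MODELS and obs.response != "RLS":
        raise ValueError(f"{model} is fitted on RLS observations")
    start_list = list(starts) if starts is not None else _starts(model, obs)

    best = None
    n_converged = 0
    diagnostics = []
    for x0 in start_list:
        try:
            res = optimize.least_squares(
                lambda th: _residuals(model, th, obs), np.asarray(x0, float),
                method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000)
        except Exception as exc:  # pragma: no cover - scipy internal failures
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not res.success or not _valid_params(model, res.x, obs):
            diagnostics.append(f"start {np.asarray(x0)}: no valid optimum")
            continue
        n_converged += 1
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0] - 1e-15 * max(1.0, best[0]):
            best = (rss, res.x)
    if best is None:
        raise RuntimeError(
            f"{model}: no start converged to a valid optimum; "
            + "; ".join(diagnostics))

    rss, theta = best
    tss = float(np.sum((obs.values - obs.values.mean()) ** 2))
    return GradientModelFit(
        model=model, response=obs.response, params=_params_dict(model, theta),
        rss=rss, tss=tss, n=obs.n, n_params=N_PARAMS[model],
        aicc=aicc(rss, obs.n, N_PARAMS[model]),
        n_starts=len(start_list), n_converged=n_converged)


def compare_models(fits: Sequence[GradientModelFit]) -> pd.DataFrame:
    """AICc comparison table; annotates each fit with delta and weight.

    All fits must share the response variable and sample size — AICc is not
    comparable across differing responses.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    responses = {f.response for f in fits}
    if len(responses) > 1:
        raise ValueError(
            f"mixed response variables {sorted(responses)}: AICc comparison "
            "requires a common response")
    if len({f.n for f in fits}) > 1:
        raise ValueError("fits have differing numbers of observations")

    scores = np.array([f.aicc for f in fits])
    weights = akaike_weights(scores)
    deltas = scores - scores.min()
    for f, d, w in zip(fits, deltas, weights):
        f.delta_aicc = float(d)
        f.weight = float(w)
    order = np.argsort(scores)
    rows = [{
        "model": fits[j].model,
        "response": fits[j].response,
        "n_par": fits[j].n_params,
        "AICc": fits[j].aicc,
        "dAICc": fits[j].delta_aicc,
        "wAICc": fits[j].weight,
        "RSS": fits[j].rss,
        "pct_variance": fits[j].pct_variance,
    } for j in order]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pygidial stasis


@dataclass(frozen=True)
class StasisTest:
    """OLS of specimen-level PYL on degree with a two-sided slope t-test."""

    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def pyl_stasis_test(specimens, stage_range) -> StasisTest:
    """Test for constant absolute pygidial length over a stage window.

    Degenerate data with zero residual variance are flagged; an exactly
    zero slope then reports p = 1.0 by convention.
    """
    lo, hi = stage_range
    pts = [(s.degree, s.pyl) for s in specimens
           if s.period == "meraspid" and s.degree is not None
           and lo <= s.degree <= hi and s.pyl is not None]
    if len(pts) < 3:
        raise ValueError(f"need >=3 specimens with PYL in D{lo}-D{hi}, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all specimens at a single stage; slope undefined")

    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    rss = float(np.sum(resid ** 2))
    if rss <= 1e-24 * max(1.0, float(np.sum(y ** 2))):
        # zero residual variance: snap slopes at round-off scale to exactly 0
        if abs(slope) * float(np.ptp(x)) <= 1e-12 * float(np.abs(y).mean()):
            slope = 0.0
        p = 1.0 if slope == 0.0 else 0.0
        t = 0.0 if slope == 0.0 else math.inf
        return StasisTest(slope, float(y.mean()), t, p, n, degenerate=True)
    se = math.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return StasisTest(slope, intercept, t, float(p), n)
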