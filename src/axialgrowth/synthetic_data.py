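"""Seeded generator of specimen-level ontogenies.

Emits cross-sectional meraspid series D0–D12 plus holaspides with the
statistical structure the downstream analyses assume: a per-stage trunk
growth rate that decays across ontogeny, a posterior-increasing segmental
growth gradient, a pygidium of constant absolute length through D0–D10,
hinge (two-phase) log–log cephalic allometries, and multiplicative
lognormal individual-size and per-part measurement noise.

At degree 0 the trunk is entirely pygidium, so the D0 trunk length equals
the pygidial length; the configured ``trl0`` anchors the growth schedule
that produces the D1+ stage means.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .data_model import (HOLASPID, HOLASPID_SEGMENTS, MERASPID,
                         SpecimenMeasurement)
from .growth_gradients import sg_r_predict, tg_predict

#: Per-degree meraspid counts D0..D12 (2 M0 specimens, then the D1-D12 series).
DEFAULT_MERASPID_COUNTS = (2, 7, 3, 8, 7, 4, 8, 16, 11, 7, 6, 14, 6)

#: How thoracic/pygidial lengths are allocated within the trunk.
#: "constant" pins stage-mean PYL to the configured schedule and uses the
#: gradient model only for the shape of the thoracic profile; "gradient"
#: takes relative segment lengths verbatim from the model (so model
#: parameters are exactly recoverable) and leaves the pygidium the
#: remainder.
PYGIDIUM_MODES = ("constant", "gradient")


@dataclass
class SimulationConfig:
    """Full generative specification of one synthetic dataset."""

    seed: int = 0
    meraspid_counts: tuple = DEFAULT_MERASPID_COUNTS
    n_holaspides: int = 135

    # trunk growth schedule: TRG_s = 1 + gamma * exp(-delta * s)
    trl0: float = 0.9
    gamma: float = 0.35
    delta: float = 0.12

    # pygidium: constant absolute length through D0-D10, then *rho per stage
    p0: float = 0.55
    rho: float = 0.9
    pygidium_mode: str = "constant"

    # generating gradient model and parameters
    gradient_model: str = "SG-A"
    gradient_params: dict = field(default_factory=lambda: {
        "A": 0.12, "B": 0.8, "k": 0.45, "k_slope": 0.095})

    # hinge allometries (beta0, beta1, beta2, tau) on ln scale:
    # ln CEL ~ ln TRL; ln FAL and ln PGL ~ ln CEL; ORL = CEL - FAL - PGL
    cel_hinge: tuple = (math.log(1.05), 0.54, 0.36, math.log(3.5))
    fal_hinge: tuple = (math.log(0.35), 1.62, -0.63, math.log(1.81))
    pgl_hinge: tuple = (math.log(0.38), 0.83, 0.18, math.log(1.95))

    # holaspid body size: BOL ~ lognormal(mu_h, sigma_h)
    mu_h: float = math.log(14.0)
    sigma_h: float = 0.25

    # multiplicative lognormal noise
    sigma_size: float = 0.08
    sigma_part: float = 0.04

    def __post_init__(self) -> None:
        self.meraspid_counts = tuple(int(c) for c in self.meraspid_counts)
        if len(self.meraspid_counts) != 13:
            raise ValueError("meraspid_counts must list 13 degrees (D0-D12)")
        if any(c < 0 for c in self.meraspid_counts) or self.n_holaspides < 0:
            raise ValueError("specimen counts must be >= 0")
        if self.gamma < 0 or self.delta < 0:
            raise ValueError("gamma and delta must be >= 0")
        if self.p0 <= 0 or not 0 < self.rho <= 1:
            raise ValueError("need P0 > 0 and rho in (0, 1]")
        if self.pygidium_mode not in PYGIDIUM_MODES:
            raise ValueError(f"unknown pygidium_mode {self.pygidium_mode!r}")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from YAML or JSON (YAML is a JSON superset)."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config fields")
        return cls(**data)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))


def trg_schedule(cfg: SimulationConfig, stage: int) -> float:
    """Per-stage trunk growth factor TRG_s = 1 + gamma * exp(-delta * s)."""
    return 1.0 + cfg.gamma * math.exp(-cfg.delta * stage)


def stage_mean_trl(cfg: SimulationConfig, max_stage: int = HOLASPID_SEGMENTS
                   ) -> dict:
    """Stage-mean trunk lengths; degree 0 is pure pygidium (TRL = P0)."""
    out = {0: cfg.p0}
    trl = cfg.trl0
    for s in range(1, max_stage + 1):
        trl *= trg_schedule(cfg, s - 1)
        out[s] = trl
    return out


def stage_mean_pyl(cfg: SimulationConfig, stage: int) -> float:
    """Pygidial schedule: constant P0 through D10, then shrinking by rho."""
    if stage <= 10:
        return cfg.p0
    return cfg.p0 * cfg.rho ** (stage - 10)


def _gradient_rls(cfg: SimulationConfig, stage: int, trl: dict) -> np.ndarray:
    """Model-predicted relative segment lengths (i = 1..stage)."""
    p = cfg.gradient_params
    seg = np.arange(1, stage + 1)
    model = cfg.gradient_model
    if model == "SG-R":
        return np.asarray(sg_r_predict(p["A"], p["B"], p["r"], seg, stage),
                          dtype=float)
    if model == "SG-A":
        k = p["k"] + p.get("k_slope", 0.0) * (seg - 1)
        return (p["A"] * p["B"] ** (seg - 1.0)
                * (trl[stage] / np.array([trl[i] for i in seg])) ** (k - 1.0))
    if model in ("TG-T", "TG-D"):
        link = "trg" if model == "TG-T" else "stage"
        trg = {s: trl[s + 1] / trl[s] for s in range(1, max(trl))}
        table = tg_predict(p["c0"], p["c1"], p["q0"], p["q1"],
                           stages=range(1, stage + 1), link=link,
                           trg_series=trg, response="RLS")
        return np.array([table[(i, stage)] for i in seg])
    raise ValueError(f"unknown gradient model {model!r}")


def stage_mean_parts(cfg: SimulationConfig, stage: int) -> dict:
    """Noise-free stage-mean part lengths for one meraspid degree."""
    trl_series = stage_mean_trl(cfg)
    trl = trl_series[stage]
    if stage == 0:
        lts = np.empty(0)
        pyl = cfg.p0
    else:
        w = _gradient_rls(cfg, stage, trl_series)
        if cfg.pygidium_mode == "constant":
            pyl = stage_mean_pyl(cfg, stage)
            if pyl >= trl:
                raise ValueError(
                    f"stage D{stage}: pygidial schedule {pyl} >= trunk {trl}")
            lts = (trl - pyl) * w / w.sum()
        else:
            if w.sum() >= 1.0 or np.any(w <= 0):
                raise ValueError(
                    f"stage D{stage}: gradient model RLS sum {w.sum():.4f} "
                    "leaves no positive pygidium")
            lts = w * trl
            pyl = trl - lts.sum()
    return {"TRL": trl, "LTS": lts, "PYL": pyl,
            **_cephalic_parts(cfg, trl, stage)}


def _hinge(x: float, params: Sequence[float]) -> float:
    b0, b1, b2, tau = params
    return b0 + b1 * x + b2 * max(x - tau, 0.0)


def _cephalic_parts(cfg: SimulationConfig, trl: float, stage) -> dict:
    cel = math.exp(_hinge(math.log(trl), cfg.cel_hinge))
    fal = math.exp(_hinge(math.log(cel), cfg.fal_hinge))
    pgl = math.exp(_hinge(math.log(cel), cfg.pgl_hinge))
    orl = cel - fal - pgl
    if orl <= 0:
        raise ValueError(
            f"stage {stage}: cephalic hinge config yields ORL = {orl:.4f} <= 0 "
            f"(CEL={cel:.4f}, FAL={fal:.4f}, PGL={pgl:.4f})")
    return {"CEL": cel, "FAL": fal, "PGL": pgl, "ORL": orl}


def holaspid_shares(cfg: SimulationConfig) -> dict:
    """Size-independent trunk shares for holaspides (13 segments).

    Computed from the gradient model extended to a virtual 13-segment
    stage, so holaspid parts scale isometrically with trunk size
    (post-change-point branch behaviour).
    """
    trl_series = stage_mean_trl(cfg, max_stage=HOLASPID_SEGMENTS + 1)
    s = HOLASPID_SEGMENTS
    w = _gradient_rls(cfg, s, trl_series)
    if cfg.pygidium_mode == "constant":
        pyl_share = stage_mean_pyl(cfg, s) / trl_series[s]
        lts_shares = (1.0 - pyl_share) * w / w.sum()
    else:
        lts_shares = w
        pyl_share = 1.0 - w.sum()
        if pyl_share <= 0:
            raise ValueError("gradient model leaves no positive holaspid pygidium")
    return {"LTS": lts_shares, "PYL": pyl_share}


def _solve_trl_for_bol(cfg: SimulationConfig, bol: float) -> float:
    """Invert BOL = TRL + CEL(TRL) for the holaspid branch."""
    from scipy.optimize import brentq
    f = lambda t: t + math.exp(_hinge(math.log(t), cfg.cel_hinge)) - bol
    return brentq(f, 1e-6, bol)


def simulate_ontogeny(cfg: SimulationConfig) -> list:
    """Generate a full synthetic dataset; deterministic given ``cfg.seed``.

    Per-specimen values are stage means multiplied by one lognormal
    individual-size factor and independent lognormal per-part factors.
    """
    rng = np.random.default_rng(cfg.seed)
    specimens = []

    for stage, count in enumerate(cfg.meraspid_counts):
        if count == 0:
            continue
        means = stage_mean_parts(cfg, stage)
        for j in range(count):
            specimens.append(_noisy_specimen(
                cfg, rng, f"SIM-D{stage:02d}-{j + 1:03d}", MERASPID, stage,
                means))

    shares = holaspid_shares(cfg)
    for j in range(cfg.n_holaspides):
        bol = math.exp(rng.normal(cfg.mu_h, cfg.sigma_h))
        trl = _solve_trl_for_bol(cfg, bol)
        means = {"TRL": trl, "LTS": shares["LTS"] * trl,
                 "PYL": shares["PYL"] * trl,
                 **_cephalic_parts(cfg, trl, "holaspid")}
        specimens.append(_noisy_specimen(
            cfg, rng, f"SIM-H-{j + 1:03d}", HOLASPID, None, means))
    return specimens


def _noisy_specimen(cfg, rng, sid, period, degree, means) -> SpecimenMeasurement:
    size = math.exp(rng.normal(0.0, cfg.sigma_size)) if cfg.sigma_size else 1.0

    def part(mean):
        noise = (math.exp(rng.normal(0.0, cfg.sigma_part))
                 if cfg.sigma_part else 1.0)
        return mean * size * noise

    return SpecimenMeasurement(
        specimen_id=sid, period=period, degree=degree,
        fal=part(means["FAL"]), pgl=part(means["PGL"]), orl=part(means["ORL"]),
        lts=tuple(part(v) for v in means["LTS"]), pyl=part(means["PYL"]))


def simulate_hinge_dataset(beta0: float, beta1: float, beta2: float,
                           tau: float, x_range: Sequence[float], n: int,
                           noise_sd: float, seed: int,
                           include_tau: bool = True):
    """Gaussian-noise hinge data ``y = b0 + b1*x + b2*(x - tau)_+``.

    Points are evenly spaced over ``x_range``; with ``include_tau`` the
    break point itself is inserted into the grid so noise-free fits can
    recover it exactly.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 points, got {n}")
    lo, hi = float(x_range[0]), float(x_range[1])
    if not lo < tau < hi:
        raise ValueError(f"tau={tau} outside x range ({lo}, {hi})")
    x = np.linspace(lo, hi, n)
    if include_tau:
        x[np.argmin(np.abs(x - tau))] = tau
    rng = np.random.default_rng(seed)
    y = beta0 + beta1 * x + beta2 * np.maximum(x - tau, 0.0)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return x, y
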