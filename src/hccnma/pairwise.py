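"""Direct (head-to-head) evidence synthesis per design.

Classical inverse-variance pooling of trial-level log hazard ratios within
each treatment pair: a fixed-effect model and the DerSimonian-Laird
random-effects model with the usual moment estimator

    tau^2 = max(0, (Q - (k - 1)) / C),   C = sum(w) - sum(w^2) / sum(w)

where Q is Cochran's heterogeneity statistic under fixed-effect weights
w_i = 1 / se_i^2.  Confidence intervals use the normal 1.96 quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .effects import LogHREstimate, design_contrasts
from .network import EvidenceNetwork

Z975 = 1.959963984540054


@dataclass(frozen=True)
class PooledEstimate:
    """An inverse-variance pooled log hazard ratio for one design."""

    design: tuple[str, str]
    horizon: int
    model: str  # "fixed" | "random"
    loghr: float
    se: float
    k: int
    q_stat: float
    tau2: float

    @property
    def hr(self) -> float:
        return math.exp(self.loghr)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.loghr - Z975 * self.se),
            math.exp(self.loghr + Z975 * self.se),
        )


def _prepare(estimates: list[LogHREstimate]) -> tuple[tuple[str, str], int, list[float], list[float]]:
    if not estimates:
        raise ValueError("no estimates to pool")
    design = estimates[0].design
    horizon = estimates[0].horizon
    ys, vs = [], []
    for est in estimates:
        if est.design != design:
            raise ValueError(f"mixed designs: {est.design} vs {design}")
        if est.horizon != horizon:
            raise ValueError("mixed horizons in one pool")
        est = est.oriented(design[1], design[0])  # later code vs earlier code
        ys.append(est.loghr)
        vs.append(est.se**2)
    return design, horizon, ys, vs


def fixed_effect_pool(estimates: list[LogHREstimate]) -> PooledEstimate:
    """Inverse-variance fixed-effect pool; Q is reported as a by-product."""
    design, horizon, ys, vs = _prepare(estimates)
    ws = [1.0 / v for v in vs]
    sw = sum(ws)
    pooled = sum(w * y for w, y in zip(ws, ys)) / sw
    q = sum(w * (y - pooled) ** 2 for w, y in zip(ws, ys))
    return PooledEstimate(
        design=design,
        horizon=horizon,
        model="fixed",
        loghr=pooled,
        se=sw**-0.5,
        k=len(ys),
        q_stat=q,
        tau2=0.0,
    )


def dersimonian_laird_pool(estimates: list[LogHREstimate]) -> PooledEstimate:
    """DerSimonian-Laird random-effects pool (requires >= 2 estimates)."""
    if len(estimates) < 2:
        raise ValueError("random-effects pooling needs >= 2 estimates")
    design, horizon, ys, vs = _prepare(estimates)
    ws = [1.0 / v for v in vs]
    sw = sum(ws)
    fixed = sum(w * y for w, y in zip(ws, ys)) / sw
    q = sum(w * (y - fixed) ** 2 for w, y in zip(ws, ys))
    c = sw - sum(w * w for w in ws) / sw
    tau2 = max(0.0, (q - (len(ys) - 1)) / c)
    ws_re = [1.0 / (v + tau2) for v in vs]
    sw_re = sum(ws_re)
    pooled = sum(w * y for w, y in zip(ws_re, ys)) / sw_re
    return PooledEstimate(
        design=design,
        horizon=horizon,
        model="random",
        loghr=pooled,
        se=sw_re**-0.5,
        k=len(ys),
        q_stat=q,
        tau2=tau2,
    )


def pool_design(estimates: list[LogHREstimate], model: str = "random") -> PooledEstimate:
    """Pool one design, falling back to fixed-effect when only one trial exists."""
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    if model == "fixed" or len(estimates) < 2:
        pooled = fixed_effect_pool(estimates)
        if model == "random":
            # single-trial design: the random-effects pool degenerates to it
            pooled = PooledEstimate(**{**pooled.__dict__, "model": "random"})
        return pooled
    return dersimonian_laird_pool(estimates)


def pool_all_designs(
    network: EvidenceNetwork, horizon: int, model: str = "random"
) -> list[PooledEstimate]:
    """One pooled estimate per design with direct evidence at ``horizon``."""
    by_design = design_contrasts(network, horizon)
    return [pool_design(ests, model=model) for _, ests in sorted(by_design.items())]


def pooled_to_frame(pooled: list[PooledEstimate]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "treatment": p.design[1],
                "comparator": p.design[0],
                "horizon": p.horizon,
                "model": p.model,
                "k": p.k,
                "hr": p.hr,
                "ci_low": p.ci95[0],
                "ci_high": p.ci95[1],
                "loghr": p.loghr,
                "se": p.se,
                "q_stat": p.q_stat,
                "tau2": p.tau2,
            }
            for p in pooled
        ]
    )
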