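"""Posterior treatment ranking: rank probabilities and SUCRA.

For every posterior draw, treatments are ordered by their basic parameter
(log HR versus the reference; the reference itself sits at 0).  These are
survival hazard ratios, so a lower value means better survival and rank 1 is
"best".  The rank-probability matrix P[t, r] is the empirical frequency with
which treatment t occupies rank r; the surface under the cumulative ranking
curve condenses each row into a single [0, 1] score,

    SUCRA_t = sum_{r=1}^{T-1} P(rank_t <= r) / (T - 1),

equal to 1 for a certainly-best treatment and 0 for a certainly-worst one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nma import NMAPosterior

_DIRECTIONS = ("lower", "higher")


@dataclass
class RankProbabilityMatrix:
    """Doubly stochastic matrix of posterior rank frequencies."""

    probs: pd.DataFrame  # index: treatments, columns: ranks 1..T
    direction: str

    def validate(self, atol: float = 1e-8):
        p = self.probs.to_numpy()
        if (p < -atol).any() or (p > 1 + atol).any():
            raise ValueError("rank probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=atol):
            raise ValueError("rank-probability rows must sum to 1")
        if not np.allclose(p.sum(axis=0), 1.0, atol=atol):
            raise ValueError("rank-probability columns must sum to 1")


@dataclass
class SUCRAResult:
    """Per-treatment SUCRA values and the ordering they induce."""

    values: pd.Series        # index: treatments, SUCRA in [0, 1]
    ordering: list[str]      # best (highest SUCRA) first

    def rank_of(self, treatment: str) -> int:
        """1-based position of a treatment in the SUCRA ordering."""
        return self.ordering.index(treatment) + 1


def rank_probabilities(
    posterior: NMAPosterior,
    direction: str = "lower",
    jitter: float = 1e-12,
    seed: int = 0,
) -> RankProbabilityMatrix:
    """Empirical rank frequencies over posterior draws.

    ``direction="lower"`` ranks smaller log HRs (better survival) first.
    Exact ties are broken by seeded uniform jitter of magnitude ``jitter``.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    D = posterior.d_matrix()
    n_draws, T = D.shape
    rng = np.random.default_rng(seed)
    values = D + rng.uniform(-jitter, jitter, size=D.shape)
    if direction == "higher":
        values = -values
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n_draws)[:, None]
    ranks[rows, order] = np.arange(T)[None, :]
    probs = np.zeros((T, T))
    for t in range(T):
        probs[t] = np.bincount(ranks[:, t], minlength=T) / n_draws
    frame = pd.DataFrame(
        probs, index=posterior.treatments, columns=range(1, T + 1)
    )
    return RankProbabilityMatrix(probs=frame, direction=direction)


def sucra(rank_probs: RankProbabilityMatrix) -> SUCRAResult:
    """Surface under the cumulative ranking curve for every treatment."""
    rank_probs.validate()
    p = rank_probs.probs.to_numpy()
    T = p.shape[0]
    if T < 2:
        raise ValueError("SUCRA needs at least two treatments")
    cum = np.cumsum(p, axis=1)
    values = cum[:, : T - 1].sum(axis=1) / (T - 1)
    series = pd.Series(values, index=rank_probs.probs.index, name="sucra")
    ordering = list(series.sort_values(ascending=False, kind="stable").index)
    return SUCRAResult(values=series, ordering=ordering)


def sucra_from_posterior(
    posterior: NMAPosterior, direction: str = "lower", seed: int = 0
) -> SUCRAResult:
    return sucra(rank_probabilities(posterior, direction=direction, seed=seed))


def ranking_to_frame(rank_probs: RankProbabilityMatrix, result: SUCRAResult) -> pd.DataFrame:
    """Treatment x (SUCRA, r1..rT) table, the tabular twin of a ranking plot."""
    frame = rank_probs.probs.copy()
    frame.columns = [f"r{r}" for r in frame.columns]
    frame.insert(0, "sucra", result.values)
    return frame.sort_values("sucra", ascending=False)
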