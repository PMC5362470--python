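"""Design-level agreement between direct and indirect evidence (net heat).

Each *design* (treatment pair with direct evidence) is condensed into one
fixed-effect pooled log hazard ratio.  A weighted least-squares fit of those
design estimates on the consistency design matrix yields network estimates;
the residual heterogeneity/inconsistency statistic

    Q = sum_d w_d (y_d - yhat_d)^2,    w_d = 1 / se_d^2

decomposes exactly into per-design contributions.  The hat matrix
H = X (X' W X)^+ X' W says how much each design's direct estimate drives each
network estimate (the square sizes of a net heat display), and refitting with
one design's direct evidence detached gives the signed inconsistency changes
(its colors): negative change = inconsistency decreases when the design is
removed, implicating it in the disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .effects import LogHREstimate
from .network import normalize_treatment
from .pairwise import PooledEstimate, pool_design

PINV_RTOL = 1e-10


@dataclass(frozen=True)
class DesignEstimate:
    """Design-level pooled direct evidence: log HR of design[1] vs design[0]."""

    design: tuple[str, str]
    horizon: int
    loghr: float
    se: float
    n_trials: int = 1

    def __post_init__(self):
        if tuple(sorted(self.design)) != tuple(self.design):
            raise ValueError("design must be an ordered (sorted) treatment pair")
        if not self.se > 0:
            raise ValueError("standard error must be positive")

    @property
    def label(self) -> str:
        return f"{self.design[0]}:{self.design[1]}"


def aggregate_by_design(
    contrasts_by_design: dict[tuple[str, str], list[LogHREstimate]],
    horizon: int | None = None,
) -> list[DesignEstimate]:
    """Fixed-effect pool of all trials sharing a design, in sorted design order."""
    out = []
    for design, ests in sorted(contrasts_by_design.items()):
        if horizon is not None:
            ests = [e for e in ests if e.horizon == horizon]
        if not ests:
            continue
        pooled: PooledEstimate = pool_design(ests, model="fixed")
        out.append(
            DesignEstimate(
                design=pooled.design,
                horizon=pooled.horizon,
                loghr=pooled.loghr,
                se=pooled.se,
                n_trials=pooled.k,
            )
        )
    return out


@dataclass
class ConsistencyFitResult:
    """Weighted least-squares consistency fit over design estimates."""

    designs: list[DesignEstimate]
    treatments: list[str]          # reference first
    reference: str
    basic: np.ndarray              # fitted basic parameters (len T-1)
    fitted: np.ndarray             # fitted design effects
    residuals: np.ndarray
    hat: np.ndarray                # H = X (X'WX)^+ X'W
    q_total: float
    q_per_design: dict[str, float]
    df: int


def _design_matrix(
    designs: list[DesignEstimate], treatments: list[str]
) -> np.ndarray:
    index = {t: i - 1 for i, t in enumerate(treatments)}  # reference -> -1
    X = np.zeros((len(designs), len(treatments) - 1))
    for r, d in enumerate(designs):
        a, b = d.design  # effect is b vs a
        if index[b] >= 0:
            X[r, index[b]] = 1.0
        if index[a] >= 0:
            X[r, index[a]] = -1.0
    return X


def consistency_fit(
    designs: list[DesignEstimate], reference: str = "TACE", _strict: bool = True
) -> ConsistencyFitResult:
    """Fit the consistency model to design-level estimates by weighted least squares."""
    reference = normalize_treatment(reference)
    if not designs:
        raise ValueError("no design estimates")
    codes = sorted({t for d in designs for t in d.design})
    if reference not in codes:
        raise ValueError(f"reference {reference} not among the designs")
    g = nx.Graph(d.design for d in designs)
    if _strict and not nx.is_connected(g):
        raise ValueError("design network is disconnected")
    treatments = [reference] + [t for t in codes if t != reference]

    X = _design_matrix(designs, treatments)
    w = np.array([1.0 / d.se**2 for d in designs])
    y = np.array([d.loghr for d in designs])
    XtW = X.T * w
    A = XtW @ X
    A_pinv = np.linalg.pinv(A, rcond=PINV_RTOL)
    basic = A_pinv @ (XtW @ y)
    H = X @ A_pinv @ XtW
    fitted = X @ basic
    resid = y - fitted
    q_per = w * resid**2
    return ConsistencyFitResult(
        designs=list(designs),
        treatments=treatments,
        reference=reference,
        basic=basic,
        fitted=fitted,
        residuals=resid,
        hat=H,
        q_total=float(q_per.sum()),
        q_per_design={d.label: float(q) for d, q in zip(designs, q_per)},
        df=len(designs) - int(np.linalg.matrix_rank(A, tol=PINV_RTOL)),
    )


@dataclass
class QDecomposition:
    """Total inconsistency/heterogeneity Q, its per-design split, and
    the Q remaining after detaching each design's direct evidence."""

    q_total: float
    q_per_design: dict[str, float]
    df: int
    leave_one_out: dict[str, float]


@dataclass
class NetHeatMatrix:
    """Design-by-design contribution sizes and signed inconsistency changes.

    ``contribution[r, c]``: share of design c's direct estimate in design r's
    network estimate (normalized absolute hat-matrix weights; rows sum to 1).
    ``change[r, c]`` for r != c: change in design r's Q contribution when
    design c's direct evidence is detached; the diagonal holds the change in
    total Q.  Negative values (a decrease, drawn warm in heat displays)
    implicate the detached design in the inconsistency.
    """

    labels: list[str]
    contribution: pd.DataFrame
    change: pd.DataFrame


def net_heat(
    designs: list[DesignEstimate], reference: str = "TACE"
) -> tuple[NetHeatMatrix, QDecomposition]:
    """Hat-matrix contributions plus leave-one-design-out inconsistency changes."""
    if len(designs) < 2:
        raise ValueError("net heat needs at least 2 designs")
    base = consistency_fit(designs, reference=reference)
    labels = [d.label for d in designs]
    n = len(designs)

    absH = np.abs(base.hat)
    contribution = absH / absH.sum(axis=1, keepdims=True)

    change = np.zeros((n, n))
    loo_q: dict[str, float] = {}
    for c in range(n):
        rest = designs[:c] + designs[c + 1 :]
        refit = consistency_fit(rest, reference=reference, _strict=False)
        loo_q[labels[c]] = refit.q_total
        change[c, c] = refit.q_total - base.q_total
        for d_est, q_after in zip(rest, [refit.q_per_design[d.label] for d in rest]):
            r = labels.index(d_est.label)
            change[r, c] = q_after - base.q_per_design[d_est.label]

    decomposition = QDecomposition(
        q_total=base.q_total,
        q_per_design=dict(base.q_per_design),
        df=base.df,
        leave_one_out=loo_q,
    )
    matrix = NetHeatMatrix(
        labels=labels,
        contribution=pd.DataFrame(contribution, index=labels, columns=labels),
        change=pd.DataFrame(change, index=labels, columns=labels),
    )
    return matrix, decomposition


def plot_net_heat(matrix: NetHeatMatrix, ax=None):
    """Minimal matrix rendering of a net heat display (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    change = matrix.change.to_numpy()
    vmax = max(np.abs(change).max(), 1e-12)
    ax.imshow(change, cmap="coolwarm_r", vmin=-vmax, vmax=vmax)
    sizes = matrix.contribution.to_numpy()
    n = len(matrix.labels)
    for r in range(n):
        for c in range(n):
            half = 0.45 * np.sqrt(sizes[r, c])
            ax.add_patch(
                plt.Rectangle((c - half, r - half), 2 * half, 2 * half,
                              fill=False, lw=0.8)
            )
    ax.set_xticks(range(n), matrix.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), matrix.labels, fontsize=7)
    return ax
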