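"""Bayesian random-effects network meta-analysis under consistency.

Model
-----
Every treatment k has a basic parameter d_k, the log hazard ratio of k versus
the reference (d_ref = 0); any contrast is a difference of basic parameters
(the consistency assumption).  Trial i contributes its observed contrast
vector y_i (non-baseline arms versus the trial's baseline arm) through a
normal approximate likelihood

    y_i ~ N(X_i d,  S_i + tau^2 R_i)

where S_i is the within-trial sampling covariance of the cloglog contrasts,
tau is the common between-trial standard deviation of contrasts, and R_i is
the random-effects correlation structure: 1 on the diagonal and 1/2 off the
diagonal for contrasts sharing the baseline arm (the standard multi-arm
construction).  Priors are vague: d_k ~ N(0, sd^2) with sd = 10 on the log-HR
scale and tau ~ Uniform(0, upper) with upper = 5.

Sampler
-------
Metropolis-within-Gibbs.  Given tau the model is linear-Gaussian, so the full
conditional of the whole d vector is multivariate normal and is sampled
exactly (one Cholesky per sweep).  tau is updated by a random-walk Metropolis
step whose scale adapts toward a 44% acceptance rate during burn-in only, so
the post-burn-in chain is a valid time-homogeneous Markov chain.  A fixed
seed yields bit-identical draws.  Convergence is summarized by the rank-
normalized split potential scale reduction factor (R-hat, via ArviZ) with a
warning above 1.05.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg

from .effects import ContrastSet
from .network import TREATMENT_ORDER, normalize_treatment

logger = logging.getLogger(__name__)

RHAT_WARN = 1.05


@dataclass
class NMAModelSpec:
    """Sampler and prior settings for the network meta-analysis.

    ``tau_fixed`` pins the heterogeneity sd instead of sampling it.  When the
    network carries no residual degrees of freedom to inform tau (number of
    contrasts <= number of basic parameters), tau is fixed at 0 automatically:
    a uniform prior would otherwise pass straight through to the posterior
    and inflate every credible interval with prior artefact.
    """

    reference: str = "TACE"
    prior_sd: float = 10.0
    tau_upper: float = 5.0
    chains: int = 4
    iterations: int = 20000
    burn_in: int = 5000
    seed: int | None = None
    tau_fixed: float | None = None

    def __post_init__(self):
        self.reference = normalize_treatment(self.reference)
        if not self.tau_upper > 0:
            raise ValueError("tau_upper must be positive")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.iterations < 1000:
            raise ValueError("at least 1000 post burn-in iterations are required")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


def _display_order(codes: set[str], reference: str) -> list[str]:
    known = [t for t in TREATMENT_ORDER if t in codes]
    extra = sorted(codes - set(known))
    ordered = known + extra
    ordered.remove(reference)
    return [reference] + ordered


@dataclass
class NMAModel:
    """Prepared data and design structure for the sampler."""

    treatments: list[str]          # reference first
    reference: str
    # vectorized two-arm blocks: X2 (n2 x K) incidence rows
    X2: np.ndarray
    y2: np.ndarray
    v2: np.ndarray
    # multi-arm blocks: (X, y, S, R) per trial with >= 2 contrasts
    multi: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]

    @property
    def n_params(self) -> int:
        return len(self.treatments) - 1

    @property
    def n_contrasts(self) -> int:
        return len(self.y2) + sum(len(y) for _, y, _, _ in self.multi)

    @property
    def residual_df(self) -> int:
        """Contrasts in excess of basic parameters — what informs tau."""
        return self.n_contrasts - self.n_params


def build_model(
    contrast_sets: list[ContrastSet], reference: str = "TACE"
) -> NMAModel:
    """Map trial contrasts onto basic parameters; verify connectivity."""
    reference = normalize_treatment(reference)
    if not contrast_sets:
        raise ValueError("no contrasts supplied")
    codes: set[str] = set()
    g = nx.Graph()
    for cs in contrast_sets:
        ts = cs.treatments
        codes.update(ts)
        for c in cs.contrasts:
            g.add_edge(c.treatment_a, c.treatment_b)
    if reference not in codes:
        raise ValueError(f"reference {reference} absent from the contrast data")
    if not nx.is_connected(g):
        comp = nx.node_connected_component(g, reference)
        raise ValueError(
            "evidence network is disconnected; outside the reference component: "
            f"{sorted(codes - comp)} (restrict with trial_network.connected_component)"
        )

    treatments = _display_order(codes, reference)
    index = {t: i - 1 for i, t in enumerate(treatments)}  # reference -> -1
    K = len(treatments) - 1

    rows2, y2, v2 = [], [], []
    multi = []
    for cs in contrast_sets:
        if len(cs.contrasts) == 1:
            c = cs.contrasts[0]
            row = np.zeros(K)
            if index[c.treatment_a] >= 0:
                row[index[c.treatment_a]] = 1.0
            if index[c.treatment_b] >= 0:
                row[index[c.treatment_b]] = -1.0
            rows2.append(row)
            y2.append(c.loghr)
            v2.append(float(cs.covariance[0, 0]))
        else:
            m = len(cs.contrasts)
            X = np.zeros((m, K))
            y = np.empty(m)
            for r, c in enumerate(cs.contrasts):
                if index[c.treatment_a] >= 0:
                    X[r, index[c.treatment_a]] = 1.0
                if index[c.treatment_b] >= 0:
                    X[r, index[c.treatment_b]] = -1.0
                y[r] = c.loghr
            R = np.full((m, m), 0.5)
            np.fill_diagonal(R, 1.0)
            multi.append((X, y, np.asarray(cs.covariance, dtype=float), R))
    X2 = np.asarray(rows2, dtype=float).reshape(len(rows2), K)
    return NMAModel(
        treatments=treatments,
        reference=reference,
        X2=X2,
        y2=np.asarray(y2, dtype=float),
        v2=np.asarray(v2, dtype=float),
        multi=multi,
    )


@dataclass
class NMAPosterior:
    """MCMC draws of the basic parameters and heterogeneity."""

    treatments: list[str]          # reference first; d_reference == 0
    reference: str
    d: np.ndarray                  # (chains, draws, n_params)
    tau: np.ndarray                # (chains, draws)
    rhat: dict[str, float]
    accept_rate: float
    spec: NMAModelSpec

    @property
    def n_draws(self) -> int:
        return self.d.shape[0] * self.d.shape[1]

    def d_matrix(self) -> np.ndarray:
        """All draws x all treatments, with the reference's zero column first."""
        flat = self.d.reshape(-1, self.d.shape[-1])
        zeros = np.zeros((flat.shape[0], 1))
        return np.hstack([zeros, flat])

    def tau_flat(self) -> np.ndarray:
        return self.tau.reshape(-1)

    def contrast_draws(self, a: str, b: str) -> np.ndarray:
        """Per-draw log HR of a versus b (exact consistency identity)."""
        D = self.d_matrix()
        ix = {t: i for i, t in enumerate(self.treatments)}
        return D[:, ix[normalize_treatment(a)]] - D[:, ix[normalize_treatment(b)]]

    def summary(self) -> pd.DataFrame:
        D = self.d_matrix()[:, 1:]
        qs = np.quantile(D, [0.025, 0.5, 0.975], axis=0)
        rows = []
        for j, t in enumerate(self.treatments[1:]):
            rows.append(
                {
                    "treatment": t,
                    "mean": D[:, j].mean(),
                    "median": qs[1, j],
                    "cri_low": qs[0, j],
                    "cri_high": qs[2, j],
                    "rhat": self.rhat.get(f"d_{t}", math.nan),
                }
            )
        tau = self.tau_flat()
        rows.append(
            {
                "treatment": "tau",
                "mean": tau.mean(),
                "median": np.quantile(tau, 0.5),
                "cri_low": np.quantile(tau, 0.025),
                "cri_high": np.quantile(tau, 0.975),
                "rhat": self.rhat.get("tau", math.nan),
            }
        )
        return pd.DataFrame(rows)

    def to_arviz(self):
        import arviz as az

        data = {f"d_{t}": self.d[:, :, j] for j, t in enumerate(self.treatments[1:])}
        data["tau"] = self.tau
        return az.from_dict(posterior=data)


def _inv_logdet(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a small SPD matrix (closed form for 2x2)."""
    if V.shape == (2, 2):
        a, b, c, d = V[0, 0], V[0, 1], V[1, 0], V[1, 1]
        det = a * d - b * c
        return np.array([[d, -b], [-c, a]]) / det, math.log(det)
    sign, logdet = np.linalg.slogdet(V)
    return np.linalg.inv(V), logdet


def _loglik_tau(model: NMAModel, resid2: np.ndarray, d: np.ndarray, tau2: float) -> float:
    """Log-likelihood of tau given the current basic parameters.

    ``resid2`` are the residuals of the two-arm contrasts at the current d.
    """
    total = 0.0
    if len(model.y2):
        v = model.v2 + tau2
        total += -0.5 * float(np.sum(np.log(v) + resid2 * resid2 / v))
    for X, y, S, R in model.multi:
        Vi, logdet = _inv_logdet(S + tau2 * R)
        r = y - X @ d
        total += -0.5 * (logdet + float(r @ Vi @ r))
    return total


def run_mcmc(model: NMAModel, spec: NMAModelSpec) -> NMAPosterior:
    """Sample the posterior; deterministic for a fixed ``spec.seed``."""
    K = model.n_params
    if K == 0:
        raise ValueError("model has no basic parameters")
    rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(spec.seed).spawn(spec.chains)
    ]
    prior_prec = 1.0 / spec.prior_sd**2

    tau_fixed = spec.tau_fixed
    if tau_fixed is None and model.residual_df <= 0:
        logger.info(
            "no residual degrees of freedom to inform tau (%d contrasts, "
            "%d basic parameters); fixing tau = 0",
            model.n_contrasts, K,
        )
        tau_fixed = 0.0
    sample_tau = tau_fixed is None

    X2, y2, v2 = model.X2, model.y2, model.v2
    eye_prior = np.eye(K) * prior_prec
    d_out = np.empty((spec.chains, spec.iterations, K))
    tau_out = np.empty((spec.chains, spec.iterations))
    n_accept = 0
    n_prop = 0

    for c, rng in enumerate(rngs):
        d = np.zeros(K)
        tau = min(0.1, spec.tau_upper / 2) if sample_tau else float(tau_fixed)
        step = 0.1
        accepted_batch = 0
        batch = 0
        total = spec.burn_in + spec.iterations
        for it in range(total):
            tau2 = tau * tau
            # --- conjugate joint update of d | tau ---
            b = np.zeros(K)
            if len(y2):
                w = 1.0 / (v2 + tau2)
                XtW = X2.T * w
                Lam = eye_prior + XtW @ X2
                b = XtW @ y2
            else:
                Lam = eye_prior.copy()
            for X, y, S, R in model.multi:
                Vi, _ = _inv_logdet(S + tau2 * R)
                XtVi = X.T @ Vi
                Lam += XtVi @ X
                b = b + XtVi @ y
            L = linalg.cholesky(Lam, lower=True)
            mean = linalg.cho_solve((L, True), b)
            z = rng.standard_normal(K)
            d = mean + linalg.solve_triangular(L, z, lower=True, trans="T")

            # --- random-walk Metropolis update of tau ---
            if sample_tau:
                prop = tau + step * rng.standard_normal()
                logu = math.log(rng.random())
                if 0.0 < prop < spec.tau_upper:
                    resid2 = y2 - X2 @ d if len(y2) else y2
                    ll_cur = _loglik_tau(model, resid2, d, tau2)
                    ll_prop = _loglik_tau(model, resid2, d, prop * prop)
                    if logu < ll_prop - ll_cur:
                        tau = prop
                        accepted_batch += 1
                        if it >= spec.burn_in:
                            n_accept += 1
                if it >= spec.burn_in:
                    n_prop += 1
                elif (it + 1) % 50 == 0:  # adapt during burn-in only
                    batch += 1
                    rate = accepted_batch / 50.0
                    step *= math.exp((rate - 0.44) / math.sqrt(batch))
                    step = min(max(step, 1e-4), spec.tau_upper)
                    accepted_batch = 0
            if it >= spec.burn_in:
                d_out[c, it - spec.burn_in] = d
                tau_out[c, it - spec.burn_in] = tau

    rhat = _compute_rhat(model, d_out, tau_out, sample_tau)
    accept_rate = n_accept / n_prop if n_prop else float("nan")
    if sample_tau and accept_rate == 0.0:
        raise RuntimeError("tau random walk accepted no proposals after adaptation")
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > RHAT_WARN}
    if bad:
        warnings.warn(
            f"potential scale reduction above {RHAT_WARN}: {bad}; "
            "increase iterations or burn-in",
            stacklevel=2,
        )
    return NMAPosterior(
        treatments=model.treatments,
        reference=model.reference,
        d=d_out,
        tau=tau_out,
        rhat=rhat,
        accept_rate=accept_rate,
        spec=spec,
    )


def _compute_rhat(
    model: NMAModel, d: np.ndarray, tau: np.ndarray, sample_tau: bool = True
) -> dict[str, float]:
    import arviz as az

    data = {f"d_{t}": d[:, :, j] for j, t in enumerate(model.treatments[1:])}
    if sample_tau:
        data["tau"] = tau
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(az.from_dict(posterior=data))
    return {k: float(rh[k].values) for k in rh.data_vars}


@dataclass
class LeagueTable:
    """Square matrix of posterior HR summaries: cell (row, col) = HR row vs col."""

    treatments: list[str]
    median: np.ndarray
    low: np.ndarray
    high: np.ndarray

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        n = len(self.treatments)
        cells = []
        for i in range(n):
            row = []
            for j in range(n):
                if i == j:
                    row.append(self.treatments[i])
                else:
                    row.append(
                        f"{self.median[i, j]:.{decimals}f} "
                        f"({self.low[i, j]:.{decimals}f}, {self.high[i, j]:.{decimals}f})"
                    )
            cells.append(row)
        return pd.DataFrame(cells, index=self.treatments, columns=self.treatments)


def league_table(posterior: NMAPosterior, order: list[str] | None = None) -> LeagueTable:
    """Posterior median HR with 95% credible interval for every ordered pair.

    Quantiles are taken on the log scale and exponentiated, so reciprocal
    symmetry (cell(a,b) * cell(b,a) = 1 for medians, low(a,b) = 1/high(b,a))
    holds exactly up to floating point.
    """
    treatments = order or posterior.treatments
    ix = {t: i for i, t in enumerate(posterior.treatments)}
    D = posterior.d_matrix()
    n = len(treatments)
    median = np.ones((n, n))
    low = np.ones((n, n))
    high = np.ones((n, n))
    for i, a in enumerate(treatments):
        for j, b in enumerate(treatments):
            if i == j:
                continue
            diff = D[:, ix[a]] - D[:, ix[b]]
            lo, med, hi = np.quantile(diff, [0.025, 0.5, 0.975])
            median[i, j] = math.exp(med)
            low[i, j] = math.exp(lo)
            high[i, j] = math.exp(hi)
    return LeagueTable(treatments=list(treatments), median=median, low=low, high=high)


class BayesianNMA:
    """Estimator-style front end to the network meta-analysis.

    Parameters mirror :class:`NMAModelSpec`.  After :meth:`fit`, the posterior
    is in ``posterior_``, convergence diagnostics in ``rhat_``, and the
    treatments (reference first) in ``treatments_``.

    Examples
    --------
    >>> nma = BayesianNMA(reference="TACE", chains=2, iterations=2000,
    ...                   burn_in=500, seed=7)
    >>> nma.fit(contrast_sets)            # doctest: +SKIP
    >>> nma.league_table().to_frame()     # doctest: +SKIP
    """

    def __init__(
        self,
        reference: str = "TACE",
        prior_sd: float = 10.0,
        tau_upper: float = 5.0,
        chains: int = 4,
        iterations: int = 20000,
        burn_in: int = 5000,
        seed: int | None = None,
        tau_fixed: float | None = None,
    ):
        self.reference = reference
        self.prior_sd = prior_sd
        self.tau_upper = tau_upper
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.seed = seed
        self.tau_fixed = tau_fixed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "reference": self.reference,
            "prior_sd": self.prior_sd,
            "tau_upper": self.tau_upper,
            "chains": self.chains,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "tau_fixed": self.tau_fixed,
        }

    def set_params(self, **params) -> "BayesianNMA":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _spec(self) -> NMAModelSpec:
        return NMAModelSpec(**self.get_params())

    def fit(self, contrast_sets: list[ContrastSet]) -> "BayesianNMA":
        spec = self._spec()
        self.model_ = build_model(contrast_sets, reference=spec.reference)
        self.posterior_ = run_mcmc(self.model_, spec)
        self.treatments_ = list(self.posterior_.treatments)
        self.rhat_ = dict(self.posterior_.rhat)
        self.tau_mean_ = float(self.posterior_.tau_flat().mean())
        return self

    def league_table(self, order: list[str] | None = None) -> LeagueTable:
        self._check_fitted()
        return league_table(self.posterior_, order=order)

    def summary(self) -> pd.DataFrame:
        self._check_fitted()
        return self.posterior_.summary()

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise RuntimeError("call fit() before requesting results")
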