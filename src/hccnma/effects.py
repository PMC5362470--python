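"""Log hazard-ratio contrasts from per-arm survival proportions.

Trials report the proportion of patients alive at yearly horizons, not
per-study hazard ratios.  Under proportional hazards the cumulative hazard at
horizon t is H(t) = -ln S(t), and the ratio of cumulative hazards between two
arms equals the hazard ratio, so

    log HR(a vs b) = ln(-ln S_a) - ln(-ln S_b)

(the complementary log-log transform of the survival proportions).  The
delta-method variance of ln(-ln S) for S estimated from n patients is

    var = (1 - S) / (n * S * (ln S)^2),

and variances add across independent arms.  Multi-arm trials yield a vector
of contrasts against a common baseline arm whose covariance off-diagonals are
the baseline arm's variance term (the shared-arm construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import EvidenceNetwork, Trial


class DegenerateArmError(ValueError):
    """Survival proportion of 0 or 1 even after continuity correction."""


@dataclass(frozen=True)
class SurvivalRecord:
    """Survivors out of those at risk in one arm at one horizon."""

    arm_id: str
    horizon: int
    survivors: float
    at_risk: float
    corrected: bool = False

    def __post_init__(self):
        if self.at_risk < 1:
            raise ValueError(f"arm {self.arm_id}: at_risk must be >= 1")
        if not 0 <= self.survivors <= self.at_risk:
            raise ValueError(f"arm {self.arm_id}: survivors outside [0, at_risk]")

    @property
    def proportion(self) -> float:
        return self.survivors / self.at_risk


@dataclass(frozen=True)
class LogHREstimate:
    """A trial-level contrast: log hazard ratio of ``treatment_a`` vs ``treatment_b``.

    HR < 1 (loghr < 0) means ``treatment_a`` has the lower hazard, i.e. better
    survival.
    """

    trial_label: str
    treatment_a: str
    treatment_b: str
    horizon: int
    loghr: float
    se: float

    def __post_init__(self):
        if not math.isfinite(self.loghr):
            raise ValueError("log hazard ratio must be finite")
        if not self.se > 0:
            raise ValueError("standard error must be positive")

    def reversed(self) -> "LogHREstimate":
        return LogHREstimate(
            trial_label=self.trial_label,
            treatment_a=self.treatment_b,
            treatment_b=self.treatment_a,
            horizon=self.horizon,
            loghr=-self.loghr,
            se=self.se,
        )

    @property
    def design(self) -> tuple[str, str]:
        return tuple(sorted((self.treatment_a, self.treatment_b)))

    def oriented(self, a: str, b: str) -> "LogHREstimate":
        """This contrast expressed as a-vs-b (flipping the sign if needed)."""
        if (self.treatment_a, self.treatment_b) == (a, b):
            return self
        if (self.treatment_b, self.treatment_a) == (a, b):
            return self.reversed()
        raise ValueError(f"contrast is not between {a} and {b}")


@dataclass
class ContrastSet:
    """All contrasts of one trial versus a common baseline arm, with covariance."""

    trial_label: str
    baseline: str
    contrasts: list[LogHREstimate]
    covariance: np.ndarray

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float)
        m = len(self.contrasts)
        if self.covariance.shape != (m, m):
            raise ValueError("covariance shape does not match contrast count")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")

    @property
    def horizon(self) -> int:
        return self.contrasts[0].horizon

    @property
    def treatments(self) -> list[str]:
        return [self.baseline] + [c.treatment_a for c in self.contrasts]


def continuity_correct(record: SurvivalRecord) -> SurvivalRecord:
    """Pull boundary proportions off 0/1: add 0.5 survivors (or deaths) and 1 at risk."""
    if record.survivors in (0, record.at_risk):
        return SurvivalRecord(
            arm_id=record.arm_id,
            horizon=record.horizon,
            survivors=record.survivors + 0.5,
            at_risk=record.at_risk + 1.0,
            corrected=True,
        )
    return record


def cloglog_variance(record: SurvivalRecord) -> float:
    """Delta-method variance of ln(-ln S) for one arm."""
    s = record.proportion
    if s <= 0.0 or s >= 1.0:
        raise DegenerateArmError(
            f"arm {record.arm_id}: survival proportion {s} is degenerate"
        )
    return (1.0 - s) / (record.at_risk * s * math.log(s) ** 2)


def cloglog_loghr(
    surv_a: SurvivalRecord,
    surv_b: SurvivalRecord,
    treatment_a: str = "A",
    treatment_b: str = "B",
    trial_label: str = "",
) -> LogHREstimate:
    """Log cumulative-hazard (= hazard) ratio of arm a relative to arm b."""
    if surv_a.horizon != surv_b.horizon:
        raise ValueError("survival records must share a horizon")
    surv_a = continuity_correct(surv_a)
    surv_b = continuity_correct(surv_b)
    var = cloglog_variance(surv_a) + cloglog_variance(surv_b)
    loghr = math.log(-math.log(surv_a.proportion)) - math.log(
        -math.log(surv_b.proportion)
    )
    return LogHREstimate(
        trial_label=trial_label,
        treatment_a=treatment_a,
        treatment_b=treatment_b,
        horizon=surv_a.horizon,
        loghr=loghr,
        se=math.sqrt(var),
    )


def _survival_record(trial: Trial, treatment: str, horizon: int) -> SurvivalRecord:
    arm = trial.arm_for(treatment)
    if horizon not in arm.survivors_by_year:
        raise ValueError(
            f"trial {trial.trial_label}: arm {arm.arm_id} has no survivor count "
            f"at year {horizon}"
        )
    return SurvivalRecord(
        arm_id=arm.arm_id,
        horizon=horizon,
        survivors=arm.survivors_by_year[horizon],
        at_risk=arm.n_enrolled,
    )


def trial_contrasts(
    trial: Trial, horizon: int, baseline: str | None = None
) -> ContrastSet:
    """Contrasts of every non-baseline arm versus the baseline arm.

    The baseline defaults to the lexicographically smallest treatment code.
    Covariance off-diagonals equal the baseline arm's cloglog variance (all
    contrasts share that arm's sampling noise).
    """
    if horizon not in trial.reported_outcomes:
        raise ValueError(
            f"trial {trial.trial_label} does not report outcome year {horizon}"
        )
    treatments = list(trial.treatments)
    if baseline is None:
        baseline = treatments[0]
    elif baseline not in treatments:
        raise ValueError(f"baseline {baseline} not in trial {trial.trial_label}")
    others = [t for t in treatments if t != baseline]

    base_rec = continuity_correct(_survival_record(trial, baseline, horizon))
    base_var = cloglog_variance(base_rec)
    contrasts = []
    variances = []
    for t in others:
        rec = continuity_correct(_survival_record(trial, t, horizon))
        est = cloglog_loghr(rec, base_rec, t, baseline, trial.trial_label)
        contrasts.append(est)
        variances.append(cloglog_variance(rec) + base_var)
    m = len(contrasts)
    cov = np.full((m, m), base_var)
    np.fill_diagonal(cov, variances)
    return ContrastSet(
        trial_label=trial.trial_label,
        baseline=baseline,
        contrasts=contrasts,
        covariance=cov,
    )


def network_contrasts(network: EvidenceNetwork, horizon: int) -> list[ContrastSet]:
    """One :class:`ContrastSet` per trial reporting survivor counts at ``horizon``."""
    sets = []
    for trial in network.trials:
        if horizon not in trial.reported_outcomes:
            continue
        sets.append(trial_contrasts(trial, horizon))
    return sets


def design_contrasts(
    network: EvidenceNetwork, horizon: int
) -> dict[tuple[str, str], list[LogHREstimate]]:
    """Per-design direct contrasts, oriented as later-vs-earlier treatment code.

    Multi-arm trials contribute one contrast per pairwise design, computed
    directly from the two arms involved.
    """
    out: dict[tuple[str, str], list[LogHREstimate]] = {}
    for trial in network.trials:
        if horizon not in trial.reported_outcomes:
            continue
        for a, b in sorted(trial.designs):
            rec_a = _survival_record(trial, a, horizon)
            rec_b = _survival_record(trial, b, horizon)
            # orientation: second (later code) vs first, matching league layout
            est = cloglog_loghr(rec_b, rec_a, b, a, trial.trial_label)
            out.setdefault((a, b), []).append(est)
    return dict(sorted(out.items()))


def contrasts_to_frame(sets: list[ContrastSet]):
    """Flatten contrast sets into an audit table."""
    import pandas as pd

    rows = [
        {
            "trial_label": c.trial_label,
            "treatment": c.treatment_a,
            "comparator": c.treatment_b,
            "horizon": c.horizon,
            "loghr": c.loghr,
            "se": c.se,
        }
        for cs in sets
        for c in cs.contrasts
    ]
    return pd.DataFrame(rows)
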