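"""Bundled data: the 42-article HCC evidence network and the published
design-level direct hazard-ratio estimates.

``load_hcc_network`` returns the transcribed trial table (13 therapies,
5,666 patients) as an :class:`~hccnma.network.EvidenceNetwork`.  It carries
arm sizes and outcome-reporting flags only — the source trials' survivor
counts are not published, so effect extraction on this network requires
either user-supplied survivor columns or the synthetic generator.

``load_direct_estimates`` returns the published design-level direct
comparisons (pairwise pooled HR with 95% CI per design and horizon), usable
as contrast inputs for a design-level network meta-analysis.
"""

from __future__ import annotations

import logging
import math
from importlib.resources import files

import numpy as np
import pandas as pd

from .effects import ContrastSet, LogHREstimate
from .network import EvidenceNetwork, load_tables

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


def _data_path(name: str) -> str:
    return str(files("hccnma") / "data" / name)


def load_hcc_network() -> EvidenceNetwork:
    """The packaged 13-treatment, 42-article evidence network."""
    return load_tables(_data_path("hcc_studies.csv"), _data_path("hcc_arms.csv"))


def load_direct_estimates(horizon: int | None = None) -> pd.DataFrame:
    """Published design-level direct HRs (columns: horizon, treatment,
    comparator, hr, ci_low, ci_high, loghr, se).

    The standard error is derived from the CI width on the log scale,
    se = ln(hi/lo) / (2 * 1.96).  One published entry prints a CI that does
    not bracket its point estimate; the point and the CI width are both kept
    as printed, with a log warning.
    """
    df = pd.read_csv(_data_path("direct_estimates.csv"))
    if horizon is not None:
        df = df[df["horizon"] == horizon].reset_index(drop=True)
    df["loghr"] = np.log(df["hr"])
    df["se"] = np.log(df["ci_high"] / df["ci_low"]) / (2 * Z975)
    bad = (df["hr"] < df["ci_low"]) | (df["hr"] > df["ci_high"])
    if bad.any():
        for _, row in df[bad].iterrows():
            logger.warning(
                "direct estimate %s vs %s at OS-%d: point %.2f outside its "
                "printed CI (%.2f, %.2f); keeping both as printed",
                row["treatment"], row["comparator"], row["horizon"],
                row["hr"], row["ci_low"], row["ci_high"],
            )
    return df


def direct_estimate_contrasts(horizon: int) -> list[ContrastSet]:
    """Design-level direct estimates wrapped as single-contrast sets for NMA."""
    df = load_direct_estimates(horizon)
    sets = []
    for _, row in df.iterrows():
        est = LogHREstimate(
            trial_label=f"direct:{row['treatment']}:{row['comparator']}",
            treatment_a=row["treatment"],
            treatment_b=row["comparator"],
            horizon=int(row["horizon"]),
            loghr=float(row["loghr"]),
            se=float(row["se"]),
        )
        sets.append(
            ContrastSet(
                trial_label=est.trial_label,
                baseline=est.treatment_b,
                contrasts=[est],
                covariance=np.array([[est.se**2]]),
            )
        )
    return sets
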