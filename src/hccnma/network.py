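"""Treatment-trial evidence network for the HCC minimally-invasive therapy comparison.

The evidence base is a network of randomized trials, each comparing two or
three of thirteen therapies (TACE alone or combined with an adjuvant, ablative
or radiation modalities, PEI, PAI, RFA, RT, TARE-90Y, DEB-TACE).  Trials report
overall survival at one to four yearly horizons (OS-1..OS-4); every analysis
stage downstream operates on the subnetwork of trials reporting a given
horizon.

Two plain-text tables describe a network:

``studies.csv``
    one row per published comparison row: article, label, region, year, the
    two treatments, the two arm sizes, the reported-outcome string (over
    "1234") and a sub-row key (multi-arm articles print one row per pairwise
    comparison).
``arms.csv``
    the canonical list of patient arms: article, arm id, treatment, enrolled
    count and the sub-rows the arm serves.  Multi-arm articles list each
    physical arm once; arms may optionally carry survivor counts ``s1..s4``.

Trials are reconstructed per article as connected components of the bipartite
sub-row/arm graph: sub-rows sharing an arm describe one multi-arm trial,
disjoint sub-rows (independent randomizations published together) stay
separate trials.  The loader cross-validates every printed comparison row
against the arms table and rejects any mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: The thirteen therapy labels, in conventional display order (reference first).
TREATMENT_ORDER: tuple[str, ...] = (
    "TACE",
    "TACE+EBRT",
    "TACE+HIFU",
    "TACE+PEI",
    "TACE+RFA",
    "TACE+RT",
    "TACE+SOR",
    "TARE-90Y",
    "DEB-TACE",
    "PAI",
    "PEI",
    "RFA",
    "RT",
)

OUTCOME_YEARS = (1, 2, 3, 4)


class NetworkValidationError(ValueError):
    """Raised when the two fixture tables disagree or a row is malformed."""


def normalize_treatment(label: str) -> str:
    """Canonicalize a therapy label: uppercase, '+'-separated, no spaces.

    'TARE-90Y' and 'DEB-TACE' are kept as single hyphenated tokens.
    """
    return label.strip().upper().replace(" ", "")


@dataclass(frozen=True)
class Treatment:
    """A therapy node in the evidence network."""

    code: str
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "code", normalize_treatment(self.code))
        if not self.label:
            object.__setattr__(self, "label", self.code)


@dataclass
class TrialArm:
    """One randomized patient arm.

    ``survivors_by_year`` maps a horizon year (1..4) to the number of patients
    alive at that horizon; absent for networks carrying only arm sizes.
    """

    arm_id: str
    treatment: str
    n_enrolled: int
    survivors_by_year: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.treatment = normalize_treatment(self.treatment)
        if self.n_enrolled < 1:
            raise NetworkValidationError(f"arm {self.arm_id}: n_enrolled must be >= 1")
        prev = self.n_enrolled
        for year in sorted(self.survivors_by_year):
            s = self.survivors_by_year[year]
            if not 0 <= s <= self.n_enrolled:
                raise NetworkValidationError(
                    f"arm {self.arm_id}: survivors at year {year} outside [0, n]"
                )
            if s > prev:
                raise NetworkValidationError(
                    f"arm {self.arm_id}: survivor counts increase at year {year}"
                )
            prev = s


@dataclass
class Trial:
    """A randomized trial: >= 2 arms with distinct treatments, one article."""

    article_id: str
    trial_label: str
    region: str
    year: int
    arms: list[TrialArm]
    reported_outcomes: frozenset[int]

    def __post_init__(self):
        if len({a.treatment for a in self.arms}) < 2:
            raise NetworkValidationError(
                f"trial {self.trial_label}: needs >= 2 distinct treatments"
            )

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(sorted({a.treatment for a in self.arms}))

    @property
    def designs(self) -> set[tuple[str, str]]:
        """All unordered treatment pairs directly compared within this trial."""
        ts = self.treatments
        return {
            tuple(sorted((a, b)))
            for i, a in enumerate(ts)
            for b in ts[i + 1 :]
        }

    def arm_for(self, treatment: str) -> TrialArm:
        for arm in self.arms:
            if arm.treatment == treatment:
                return arm
        raise KeyError(treatment)


@dataclass
class EvidenceNetwork:
    """The treatment-trial graph underlying every analysis stage."""

    treatments: dict[str, Treatment]
    trials: list[Trial]
    horizon: int | None = None

    def __post_init__(self):
        for trial in self.trials:
            for arm in trial.arms:
                if arm.treatment not in self.treatments:
                    raise NetworkValidationError(
                        f"trial {trial.trial_label}: unknown treatment {arm.treatment}"
                    )

    @property
    def article_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.article_id, None)
        return list(seen)

    def at_horizon(self, horizon: int) -> "EvidenceNetwork":
        """Subnetwork of trials reporting the given survival horizon."""
        if horizon not in OUTCOME_YEARS:
            raise ValueError(f"horizon must be in 1..4, got {horizon}")
        trials = [t for t in self.trials if horizon in t.reported_outcomes]
        present = {a.treatment for t in trials for a in t.arms}
        return EvidenceNetwork(
            treatments={c: t for c, t in self.treatments.items() if c in present},
            trials=trials,
            horizon=horizon,
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for trial in self.trials:
            for a, b in trial.designs:
                g.add_edge(a, b)
        return g

    def ordered_treatments(self) -> list[str]:
        """Treatment codes in display order (known labels first)."""
        known = [t for t in TREATMENT_ORDER if t in self.treatments]
        extra = sorted(set(self.treatments) - set(known))
        return known + extra


# ---------------------------------------------------------------------------
# loading and validation

def _read_arm_row(row: pd.Series) -> TrialArm:
    survivors = {}
    for year in OUTCOME_YEARS:
        col = f"s{year}"
        if col in row.index and pd.notna(row[col]) and str(row[col]) != "":
            survivors[year] = int(row[col])
    return TrialArm(
        arm_id=str(row["arm_id"]),
        treatment=str(row["treatment"]),
        n_enrolled=int(row["n_enrolled"]),
        survivors_by_year=survivors,
    )


def _parse_outcomes(value) -> frozenset[int]:
    text = str(value).strip()
    years = frozenset(int(ch) for ch in text if ch in "1234")
    if not years or any(ch not in "1234" for ch in text):
        raise NetworkValidationError(f"malformed outcomes string {text!r}")
    return years


def load_tables(studies_path: str | Path, arms_path: str | Path) -> EvidenceNetwork:
    """Build a validated :class:`EvidenceNetwork` from the two-file CSV schema."""
    studies = pd.read_csv(studies_path, dtype=str)
    arms_df = pd.read_csv(arms_path, dtype=str)
    required_s = {"article_id", "trial_label", "treatment_1", "treatment_2",
                  "size_1", "size_2", "outcomes"}
    if missing := required_s - set(studies.columns):
        raise NetworkValidationError(f"studies table missing columns {sorted(missing)}")
    required_a = {"article_id", "arm_id", "treatment", "n_enrolled"}
    if missing := required_a - set(arms_df.columns):
        raise NetworkValidationError(f"arms table missing columns {sorted(missing)}")

    if "row" not in studies.columns:
        studies = studies.assign(row="main")
    if "rows" not in arms_df.columns:
        arms_df = arms_df.assign(rows="main")

    arms_by_article: dict[str, list[tuple[TrialArm, set[str]]]] = {}
    seen_arm_ids: set[str] = set()
    for _, row in arms_df.iterrows():
        arm = _read_arm_row(row)
        if arm.arm_id in seen_arm_ids:
            raise NetworkValidationError(f"duplicate arm_id {arm.arm_id}")
        seen_arm_ids.add(arm.arm_id)
        keys = {k for k in str(row["rows"]).split("|") if k}
        arms_by_article.setdefault(str(row["article_id"]), []).append((arm, keys))

    treatments: dict[str, Treatment] = {}
    trials: list[Trial] = []
    for article_id, group in studies.groupby("article_id", sort=False):
        arm_entries = arms_by_article.get(article_id)
        if not arm_entries:
            raise NetworkValidationError(f"article {article_id}: no arms listed")

        # validate every printed comparison row against the canonical arms
        row_meta: dict[str, pd.Series] = {}
        for _, srow in group.iterrows():
            key = str(srow["row"])
            row_meta[key] = srow
            serving = [(a, k) for a, k in arm_entries if key in k]
            want = sorted(
                (normalize_treatment(str(srow[f"treatment_{i}"])), int(srow[f"size_{i}"]))
                for i in (1, 2)
            )
            got = sorted((a.treatment, a.n_enrolled) for a, _ in serving)
            if want != got:
                raise NetworkValidationError(
                    f"article {article_id} row {key!r}: printed comparison "
                    f"{want} does not match arms table {got}"
                )

        # trials = connected components of the sub-row/arm sharing graph
        g = nx.Graph()
        for idx, (arm, keys) in enumerate(arm_entries):
            g.add_node(("arm", idx))
            for key in keys:
                g.add_edge(("arm", idx), ("row", key))
        for comp in nx.connected_components(g):
            arm_idx = sorted(i for kind, i in comp if kind == "arm")
            row_keys = sorted(k for kind, k in comp if kind == "row")
            comp_arms = [arm_entries[i][0] for i in arm_idx]
            outcomes = frozenset()
            for k in row_keys:
                outcomes |= _parse_outcomes(row_meta[k]["outcomes"])
            first = row_meta[row_keys[0]]
            label = str(first["trial_label"])
            if len(row_keys) > 1:  # merged multi-arm article: strip the sub-row suffix
                label = label.replace(f"-{row_keys[0]} ", " ")
            trials.append(
                Trial(
                    article_id=str(article_id),
                    trial_label=label,
                    region=str(first.get("region", "")),
                    year=int(first["year"]) if "year" in first else 0,
                    arms=comp_arms,
                    reported_outcomes=outcomes,
                )
            )
            for arm in comp_arms:
                treatments.setdefault(arm.treatment, Treatment(arm.treatment))

    return EvidenceNetwork(treatments=treatments, trials=trials)


def load_fixture() -> EvidenceNetwork:
    """Load the packaged 42-article, 13-treatment HCC evidence network."""
    from importlib.resources import files

    data = files("hccnma") / "data"
    return load_tables(
        str(data / "hcc_studies.csv"), str(data / "hcc_arms.csv")
    )


# ---------------------------------------------------------------------------
# descriptive statistics

def patient_totals(network: EvidenceNetwork) -> tuple[dict[str, int], int]:
    """Patients per treatment and the grand total; each arm counted once."""
    totals: dict[str, int] = {code: 0 for code in network.treatments}
    counted: set[str] = set()
    for trial in network.trials:
        for arm in trial.arms:
            if arm.arm_id in counted:
                continue
            counted.add(arm.arm_id)
            totals[arm.treatment] += arm.n_enrolled
    return totals, sum(totals.values())


def count_designs(
    network: EvidenceNetwork, horizon: int | None = None
) -> tuple[int, list[tuple[str, str]]]:
    """Distinct unordered treatment pairs with >= 1 direct comparison."""
    net = network if horizon is None else network.at_horizon(horizon)
    designs: set[tuple[str, str]] = set()
    for trial in net.trials:
        designs |= trial.designs
    ordered = sorted(designs)
    return len(ordered), ordered


def outcome_coverage(network: EvidenceNetwork) -> dict[int, int]:
    """Number of articles reporting each survival horizon (once per article)."""
    per_article: dict[str, set[int]] = {}
    for trial in network.trials:
        per_article.setdefault(trial.article_id, set()).update(trial.reported_outcomes)
    return {
        year: sum(1 for outs in per_article.values() if year in outs)
        for year in OUTCOME_YEARS
    }


def arm_structure(network: EvidenceNetwork) -> dict[str, int]:
    """Counts of two-arm and three-arm articles.

    Article arity is the number of distinct treatments across all of its arms;
    articles publishing repeated independent two-arm comparisons of the same
    pair count as two-arm.
    """
    per_article: dict[str, set[str]] = {}
    for trial in network.trials:
        per_article.setdefault(trial.article_id, set()).update(trial.treatments)
    counts = {"two_arm": 0, "three_arm": 0}
    for ts in per_article.values():
        if len(ts) == 2:
            counts["two_arm"] += 1
        elif len(ts) == 3:
            counts["three_arm"] += 1
        else:
            counts[f"{len(ts)}_arm"] = counts.get(f"{len(ts)}_arm", 0) + 1
    return counts


def connected_component(
    network: EvidenceNetwork, horizon: int, reference: str
) -> EvidenceNetwork:
    """Maximal connected subnetwork containing ``reference`` at ``horizon``.

    Treatments disconnected from the reference (e.g. therapies whose only
    trial does not report the horizon) are dropped with a log message.
    """
    reference = normalize_treatment(reference)
    if reference not in network.treatments:
        raise KeyError(f"reference {reference} not in network")
    sub = network.at_horizon(horizon)
    if reference not in sub.treatments:
        raise NetworkValidationError(
            f"reference {reference} has no trial reporting horizon {horizon}"
        )
    comp = nx.node_connected_component(sub.graph(), reference)
    dropped = sorted(set(sub.treatments) - comp)
    if dropped:
        logger.info(
            "horizon %d: dropping treatments disconnected from %s: %s",
            horizon, reference, ", ".join(dropped),
        )
    trials = [t for t in sub.trials if set(t.treatments) <= comp]
    return EvidenceNetwork(
        treatments={c: t for c, t in sub.treatments.items() if c in comp},
        trials=trials,
        horizon=horizon,
    )


def describe(network: EvidenceNetwork) -> dict:
    """All descriptive statistics as one JSON-serializable mapping."""
    totals, grand = patient_totals(network)
    n_designs, designs = count_designs(network)
    return {
        "n_articles": len(network.article_ids),
        "n_trials": len(network.trials),
        "n_treatments": len(network.treatments),
        "total_subjects": grand,
        "patients_per_treatment": {
            code: totals[code] for code in network.ordered_treatments()
        },
        "n_designs": n_designs,
        "designs": [list(d) for d in designs],
        "arm_structure": arm_structure(network),
        "outcome_coverage": outcome_coverage(network),
    }
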