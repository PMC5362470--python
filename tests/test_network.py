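"""The trial-network data model and its descriptive statistics."""

import pandas as pd
import pytest

import hccnma as h
from hccnma.network import (
    NetworkValidationError,
    Treatment,
    Trial,
    TrialArm,
    load_tables,
    normalize_treatment,
)


def make_trial(label, pairs, outcomes=frozenset({1, 2, 3, 4}), article=None):
    arms = [
        TrialArm(arm_id=f"{label}:{t}", treatment=t, n_enrolled=n)
        for t, n in pairs
    ]
    return Trial(
        article_id=article or label,
        trial_label=label,
        region="x",
        year=2000,
        arms=arms,
        reported_outcomes=outcomes,
    )


def make_network(trials):
    codes = {a.treatment for t in trials for a in t.arms}
    return h.EvidenceNetwork({c: Treatment(c) for c in codes}, trials)


class TestBundledNetwork:
    def test_thirteen_treatments_and_42_articles(self, hcc_network):
        assert len(hcc_network.treatments) == 13
        assert len(hcc_network.article_ids) == 42

    def test_patient_totals_match_published_counts(self, hcc_network):
        totals, grand = h.patient_totals(hcc_network)
        assert grand == 5666
        expected = {
            "TACE": 2392, "RFA": 891, "TACE+RFA": 438, "PEI": 432,
            "TACE+SOR": 379, "DEB-TACE": 325, "TARE-90Y": 310,
            "TACE+PEI": 174, "TACE+RT": 131, "TACE+HIFU": 68,
            "PAI": 63, "TACE+EBRT": 54, "RT": 9,
        }
        assert totals == expected
        assert round(100 * totals["TACE"] / grand, 2) == 42.22

    def test_sixteen_designs_overall_and_at_year_one(self, hcc_network):
        assert h.count_designs(hcc_network)[0] == 16
        assert h.count_designs(hcc_network, horizon=1)[0] == 16

    def test_outcome_coverage(self, hcc_network):
        assert h.outcome_coverage(hcc_network) == {1: 40, 2: 41, 3: 36, 4: 23}

    def test_arm_structure(self, hcc_network):
        assert h.arm_structure(hcc_network) == {"two_arm": 38, "three_arm": 4}

    def test_three_arm_articles_are_the_known_four(self, hcc_network):
        per_article = {}
        for t in hcc_network.trials:
            per_article.setdefault(t.article_id, set()).update(t.treatments)
        three = {a for a, ts in per_article.items() if len(ts) == 3}
        assert three == {"yang_2009", "cheng_2008", "cheng_2001", "allgaier_1998"}

    def test_year4_component_drops_pai_only(self, hcc_network):
        sub = h.connected_component(hcc_network, 4, "TACE")
        assert len(sub.treatments) == 12
        assert "PAI" not in sub.treatments

    def test_year1_component_keeps_all_thirteen(self, hcc_network):
        sub = h.connected_component(hcc_network, 1, "TACE")
        assert len(sub.treatments) == 13

    def test_removing_articles_never_increases_counts(self, hcc_network):
        base_cov = h.outcome_coverage(hcc_network)
        base_designs = h.count_designs(hcc_network)[0]
        for drop in ("lin_2005", "shibata_2009", "cheng_2008"):
            trials = [t for t in hcc_network.trials if t.article_id != drop]
            net = h.EvidenceNetwork(dict(hcc_network.treatments), trials)
            cov = h.outcome_coverage(net)
            assert all(cov[y] <= base_cov[y] for y in cov)
            assert h.count_designs(net)[0] <= base_designs

    def test_year1_coverage_unaffected_by_studies_lacking_year1(self, hcc_network):
        # the two articles reporting outcomes "234" only
        trials = [
            t for t in hcc_network.trials
            if t.article_id not in ("shibata_2009", "koda_2001")
        ]
        net = h.EvidenceNetwork(dict(hcc_network.treatments), trials)
        assert h.outcome_coverage(net)[1] == 40


class TestLoaderValidation:
    def test_size_mismatch_between_files_rejected(self, tmp_path):
        from importlib.resources import files

        data = files("hccnma") / "data"
        studies = pd.read_csv(str(data / "hcc_studies.csv"))
        arms = pd.read_csv(str(data / "hcc_arms.csv"))
        arms.loc[0, "n_enrolled"] += 1  # disagree with the printed row
        studies.to_csv(tmp_path / "s.csv", index=False)
        arms.to_csv(tmp_path / "a.csv", index=False)
        with pytest.raises(NetworkValidationError, match="does not match"):
            load_tables(tmp_path / "s.csv", tmp_path / "a.csv")

    def test_unknown_columns_rejected(self, tmp_path):
        (tmp_path / "s.csv").write_text("article_id,foo\nx,1\n")
        (tmp_path / "a.csv").write_text("article_id,arm_id,treatment,n_enrolled\n")
        with pytest.raises(NetworkValidationError, match="missing columns"):
            load_tables(tmp_path / "s.csv", tmp_path / "a.csv")

    def test_survivor_counts_must_be_monotone(self):
        with pytest.raises(NetworkValidationError, match="increase"):
            TrialArm("a", "TACE", 50, {1: 20, 2: 30})

    def test_single_treatment_trial_rejected(self):
        with pytest.raises(NetworkValidationError, match="distinct treatments"):
            make_trial("bad", [("A", 10), ("A", 12)])


class TestDescriptiveOperations:
    def test_totals_on_toy_trial(self):
        net = make_network([make_trial("t", [("A", 10), ("B", 20)])])
        totals, grand = h.patient_totals(net)
        assert totals == {"A": 10, "B": 20} and grand == 30

    def test_empty_network_has_zero_designs(self):
        net = h.EvidenceNetwork({}, [])
        assert h.count_designs(net)[0] == 0

    def test_design_count_has_set_semantics(self):
        t1 = make_trial("t1", [("A", 10), ("B", 20)])
        t2 = make_trial("t2", [("B", 15), ("A", 25)])
        net = make_network([t1, t2])
        assert h.count_designs(net)[0] == 1
        # order invariance
        assert h.count_designs(make_network([t2, t1]))[0] == 1

    def test_single_two_arm_trial_structure(self):
        net = make_network([make_trial("t", [("A", 10), ("B", 20)])])
        assert h.arm_structure(net) == {"two_arm": 1, "three_arm": 0}

    def test_connected_component_of_connected_triangle_is_identity(self):
        net = make_network([make_trial("t", [("A", 10), ("B", 20), ("C", 30)])])
        sub = h.connected_component(net, 1, "A")
        assert set(sub.treatments) == {"A", "B", "C"}
        assert len(sub.trials) == 1

    def test_component_drops_disconnected_pair(self):
        trials = [
            make_trial("t1", [("A", 10), ("B", 20)]),
            make_trial("t2", [("C", 10), ("D", 20)]),
        ]
        sub = h.connected_component(make_network(trials), 1, "A")
        assert set(sub.treatments) == {"A", "B"}

    def test_horizon_designs_subset_of_full(self, hcc_network):
        full = set(h.count_designs(hcc_network)[1])
        for year in (1, 2, 3, 4):
            assert set(h.count_designs(hcc_network, year)[1]) <= full

    def test_invalid_horizon_rejected(self, hcc_network):
        with pytest.raises(ValueError):
            h.count_designs(hcc_network, horizon=5)


def test_treatment_label_normalization():
    assert normalize_treatment("tace + rfa") == "TACE+RFA"
    assert normalize_treatment("TARE-90Y") == "TARE-90Y"
    assert normalize_treatment("deb-tace ") == "DEB-TACE"
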