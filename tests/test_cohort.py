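"""Cohort construction, case identification and matched control selection."""

import numpy as np
import pandas as pd
import pytest

from ehrisk.cohort import (
    CohortDefinition, build_cohort, fiscal_year, identify_cases,
    is_suicide_cause, match_controls,
)
from tests.conftest import make_events, make_patients


class TestFiscalYear:
    @pytest.mark.parametrize("date,fy", [
        ("2009-09-30", 2009), ("2009-10-01", 2010), ("2010-09-30", 2010),
        ("2010-10-01", 2011), ("2017-09-30", 2017),
    ])
    def test_boundaries(self, date, fy):
        assert fiscal_year(date) == fy


class TestBuildCohort:
    def test_enrollment_is_first_in_window_visit(self):
        patients = make_patients([{"id": "A"}])
        events = make_events([("A", "outpatient_visit", "2009-05-01"),
                              ("A", "outpatient_visit", "2011-03-02")])
        cohort = build_cohort(patients, events)
        assert list(cohort["id"]) == ["A"]
        assert cohort.loc[0, "enrollment_date"] == pd.Timestamp("2011-03-02")

    def test_out_of_window_patient_excluded(self):
        patients = make_patients([{"id": "A"}, {"id": "B"}])
        events = make_events([("A", "outpatient_visit", "2008-01-01"),
                              ("B", "outpatient_visit", "2012-01-01")])
        cohort = build_cohort(patients, events)
        assert list(cohort["id"]) == ["B"]

    def test_visit_on_fiscal_window_start_enrolls(self):
        patients = make_patients([{"id": "A"}])
        events = make_events([("A", "outpatient_visit", "2009-10-01")])
        cohort = build_cohort(patients, events)
        assert cohort.loc[0, "enrollment_date"] == pd.Timestamp("2009-10-01")
        assert cohort.loc[0, "enrollment_fy"] == 2010


class TestIdentifyCases:
    @pytest.mark.parametrize("cause,death,expected", [
        ("X72", "2015-06-01", True),      # inside X60-84 range
        ("X60", "2015-06-01", True),
        ("X84", "2015-06-01", True),
        ("X85", "2015-06-01", False),     # assault, outside range
        ("X59", "2015-06-01", False),
        ("U03", "2015-06-01", True),
        ("Y87.0", "2015-06-01", True),
        ("Y87.1", "2015-06-01", False),
        ("Y87.0", "2018-03-01", False),   # fails the pre-2018 rule
        ("X72.1", "2015-06-01", True),    # decimal extension matches its root
        ("", None, False),
    ])
    def test_case_rule(self, cause, death, expected):
        patients = make_patients([{
            "id": "A", "underlying_cause": cause, "death_date": death,
            "suicide_death": expected}])
        events = make_events([("A", "outpatient_visit", "2011-01-01")])
        cohort = build_cohort(patients, events)
        assert (identify_cases(cohort) == ["A"]) is expected

    def test_is_suicide_cause_handles_whitespace_and_case(self):
        assert is_suicide_cause(" x72 ")
        assert not is_suicide_cause(None if False else "")


def toy_matching_setup():
    patients = make_patients([
        {"id": "case1", "death_date": "2014-05-01", "underlying_cause": "X72",
         "suicide_death": True},
        {"id": "ctrl1"},
    ])
    events = make_events([
        ("case1", "outpatient_visit", "2012-01-15"),
        ("ctrl1", "outpatient_visit", "2012-02-20"),   # same FY2012 enrollment
        ("ctrl1", "outpatient_visit", "2014-02-03"),   # visits in endpoint FY2014
        ("ctrl1", "outpatient_visit", "2014-09-09"),
    ])
    return patients, events


class TestMatching:
    def test_single_pair_with_first_visit_index(self):
        patients, events = toy_matching_setup()
        cohort = build_cohort(patients, events)
        pairs, unmatched = match_controls(cohort, events, ["case1"], seed=0)
        assert unmatched == []
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["control_id"] == "ctrl1"
        assert row["case_index_date"] == pd.Timestamp("2014-05-01")
        # control index = first outpatient visit of the endpoint year
        assert row["control_index_date"] == pd.Timestamp("2014-02-03")

    def test_exhaustion_without_replacement(self):
        patients = make_patients([
            {"id": "case1", "death_date": "2014-05-01", "underlying_cause": "X72",
             "suicide_death": True},
            {"id": "case2", "death_date": "2014-07-01", "underlying_cause": "X60",
             "suicide_death": True},
            {"id": "ctrl1"},
        ])
        events = make_events([
            ("case1", "outpatient_visit", "2012-01-15"),
            ("case2", "outpatient_visit", "2012-03-15"),
            ("ctrl1", "outpatient_visit", "2012-02-20"),
            ("ctrl1", "outpatient_visit", "2014-02-03"),
        ])
        cohort = build_cohort(patients, events)
        pairs, unmatched = match_controls(cohort, events, ["case1", "case2"], seed=1)
        assert len(pairs) == 1 and len(unmatched) == 1

    def test_empty_pool_yields_unmatched_not_error(self):
        patients = make_patients([
            {"id": "case1", "death_date": "2014-05-01", "underlying_cause": "X72",
             "suicide_death": True}])
        events = make_events([("case1", "outpatient_visit", "2012-01-15")])
        cohort = build_cohort(patients, events)
        pairs, unmatched = match_controls(cohort, events, ["case1"], seed=0)
        assert len(pairs) == 0 and unmatched == ["case1"]

    def test_determinism(self, small_cohort):
        _, patients, events, _ = small_cohort
        cohort = build_cohort(patients, events)
        cases = identify_cases(cohort)
        a, ua = match_controls(cohort, events, cases, seed=5)
        b, ub = match_controls(cohort, events, cases, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert ua == ub

    def test_invariants_on_simulated_cohort(self, small_cohort):
        _, patients, events, _ = small_cohort
        cohort = build_cohort(patients, events)
        cases = identify_cases(cohort)
        pairs, unmatched = match_controls(cohort, events, cases, seed=3)
        # bijectivity
        assert pairs["case_id"].is_unique and pairs["control_id"].is_unique
        assert len(pairs) + len(unmatched) == len(cases)
        # controls are never suicide cases
        assert not set(pairs["control_id"]) & set(cases)
        fy = cohort.set_index("id")["enrollment_fy"]
        definition = CohortDefinition()
        for _, row in pairs.iterrows():
            # stratum conservation
            assert fy[row["case_id"]] == fy[row["control_id"]] == row["enrollment_fy"]
            assert definition.year_of(row["case_index_date"]) == row["endpoint_year"]
            assert definition.year_of(row["control_index_date"]) == row["endpoint_year"]


def random_toy_cohort(rng):
    """A <=8-patient random cohort for maximality checks against brute force."""
    n = int(rng.integers(2, 9))
    rows, events = [], []
    for i in range(n):
        pid = f"p{i}"
        enroll = pd.Timestamp("2010-01-01") + pd.Timedelta(days=int(rng.integers(0, 2000)))
        events.append((pid, "outpatient_visit", enroll))
        is_case = rng.random() < 0.4
        if is_case:
            death = enroll + pd.Timedelta(days=int(rng.integers(30, 1500)))
            rows.append({"id": pid, "death_date": death, "underlying_cause": "X72",
                         "suicide_death": True, "enrollment_date": enroll})
            if death >= pd.Timestamp("2018-01-01"):
                rows[-1]["death_date"] = pd.Timestamp("2017-06-01")
        else:
            rows.append({"id": pid, "enrollment_date": enroll})
            for _ in range(int(rng.integers(0, 4))):
                events.append((pid, "outpatient_visit",
                               enroll + pd.Timedelta(days=int(rng.integers(0, 2500)))))
    return make_patients(rows), make_events(events)


def max_matching_oracle(cohort, events, cases, definition):
    """Maximum-cardinality matching size by networkx (independent route)."""
    import networkx as nx
    from ehrisk.cohort import _outpatient_visits

    suicide = cohort["suicide_death"]
    pool = cohort[~suicide & ~cohort["id"].isin(cases)]
    vis = _outpatient_visits(events)
    vis = vis[vis["patient_id"].isin(pool["id"])].copy()
    vis["year"] = vis["event_date"].map(definition.year_of)
    fy = cohort.set_index("id")["enrollment_fy"]
    g = nx.Graph()
    case_nodes = [f"case::{c}" for c in cases]
    g.add_nodes_from(case_nodes, bipartite=0)
    for c in cases:
        stratum = (fy[c], definition.year_of(cohort.set_index("id").loc[c, "death_date"]))
        for pid in pool["id"]:
            years = set(vis.loc[vis["patient_id"] == pid, "year"])
            if fy[pid] == stratum[0] and stratum[1] in years:
                g.add_edge(f"case::{c}", f"ctrl::{pid}")
    match = nx.bipartite.maximum_matching(g, top_nodes=case_nodes)
    return len(match) // 2


def test_matching_is_cardinality_maximal_on_random_toys():
    """Seeded matching equals brute-force maximum matching on 200 random pools."""
    rng = np.random.default_rng(99)
    definition = CohortDefinition()
    checked = 0
    for trial in range(200):
        patients, events = random_toy_cohort(rng)
        cohort = build_cohort(patients, events, definition)
        if cohort.empty:
            continue
        cases = identify_cases(cohort, definition)
        if not cases:
            continue
        pairs, unmatched = match_controls(cohort, events, cases, definition,
                                          seed=int(rng.integers(2**31)))
        assert len(pairs) == max_matching_oracle(cohort, events, cases, definition)
        assert pairs["control_id"].is_unique
        checked += 1
    assert checked > 50
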