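from __future__ import annotations

import itertools
from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroclaims.codebook import Codebook
from neuroclaims.identify import (
    assign_group,
    classify_dementia,
    classify_parkinsonism,
    identify_cohort,
    incident_counts_by_year,
    is_incident,
    qualifies_repeated,
)
from neuroclaims.records import PrescriptionRecord, build_histories
from tests.conftest import make_history, make_person

AS_OF = date(2021, 12, 31)


def rx_on(days: list[int], atc: str = "N04BA02", year: int = 2021):
    return [(date(year, 1, 1) + timedelta(days=d), atc) for d in days]


class TestQualifiesRepeated:
    def test_two_matching_within_window(self, codebook):
        h = make_history(rx=rx_on([0, 30]))
        ok, first = qualifies_repeated(h.prescriptions, codebook.park_atc, codebook)
        assert ok and first == date(2021, 1, 1)

    def test_single_prescription_fails(self, codebook):
        h = make_history(rx=rx_on([0]))
        ok, first = qualifies_repeated(h.prescriptions, codebook.park_atc, codebook)
        assert not ok and first is None

    def test_two_beyond_window_fail(self, codebook):
        h = make_history(rx=[(date(2020, 1, 1), "N04BA02"), (date(2021, 2, 5), "N04BA02")])
        assert (date(2021, 2, 5) - date(2020, 1, 1)).days == 401
        ok, _ = qualifies_repeated(h.prescriptions, codebook.park_atc, codebook)
        assert not ok

    def test_non_matching_atc_ignored(self, codebook):
        h = make_history(rx=rx_on([0, 10], atc="C09AA05"))
        ok, _ = qualifies_repeated(h.prescriptions, codebook.park_atc, codebook)
        assert not ok

    @settings(max_examples=200, deadline=None)
    @given(
        offsets=st.lists(st.integers(0, 900), min_size=0, max_size=8),
        min_count=st.integers(2, 4),
        window=st.integers(30, 500),
    )
    def test_matches_brute_force_oracle(self, offsets, min_count, window):
        cb = Codebook(repeat_min_count=min_count, repeat_window_days=window)
        rx = [PrescriptionRecord("p1", date(2018, 1, 1) + timedelta(days=d), "N04BA02")
              for d in offsets]
        # oracle: enumerate every subset of size min_count
        dates = sorted(r.dispense_date for r in rx)
        expected_spans = [
            combo[0]
            for combo in itertools.combinations(dates, min_count)
            if (combo[-1] - combo[0]).days <= window
        ]
        ok, first = qualifies_repeated(rx, cb.park_atc, cb)
        assert ok == bool(expected_spans)
        if ok:
            assert first == min(expected_spans)


class TestClassifyParkinsonism:
    def test_exemption_only(self, codebook):
        h = make_history(ex=[(date(2019, 3, 1), "038")])
        c = classify_parkinsonism(h, codebook, AS_OF)
        assert c.is_case and c.criteria == {"park_exemption"}
        assert c.sources == {"exemption"} and c.first_date == date(2019, 3, 1)

    def test_repeated_rx_only(self, codebook):
        h = make_history(rx=rx_on([0, 40], atc="N04BC05"))
        c = classify_parkinsonism(h, codebook, AS_OF)
        assert c.is_case and c.criteria == {"park_rx"}

    def test_single_rx_plus_unrelated_exemption(self, codebook):
        h = make_history(rx=rx_on([0]), ex=[(date(2020, 1, 1), "999")])
        assert not classify_parkinsonism(h, codebook, AS_OF).is_case

    def test_events_after_as_of_ignored(self, codebook):
        h = make_history(rx=rx_on([0, 40], year=2022))
        assert not classify_parkinsonism(h, codebook, AS_OF).is_case
        assert classify_parkinsonism(h, codebook, date(2022, 12, 31)).is_case


class TestClassifyDementia:
    def test_proxy_without_psych_labels(self, codebook):
        # repeated trazodone is accepted as proxy evidence
        h = make_history(rx=rx_on([0, 60], atc="N06AX05"))
        c = classify_dementia(h, codebook, AS_OF)
        assert c.is_case and c.criteria == {"dem_proxy"}
        assert not c.excluded_psychiatric

    def test_proxy_plus_psych_exemption_excluded(self, codebook):
        h = make_history(rx=rx_on([0, 60], atc="N05AH04"), ex=[(date(2018, 1, 1), "044")])
        c = classify_dementia(h, codebook, AS_OF)
        assert not c.is_case and c.excluded_psychiatric

    def test_hdr_overrides_proxy_only_exclusion(self, codebook):
        h = make_history(
            rx=rx_on([0, 60], atc="N05AH04"),
            ex=[(date(2018, 1, 1), "044")],
            hdr=[(date(2019, 5, 2), ["2900"])],
        )
        c = classify_dementia(h, codebook, AS_OF)
        assert c.is_case and "dem_hdr" in c.criteria and not c.excluded_psychiatric

    def test_dementia_icd9_in_any_position(self, codebook):
        h = make_history(hdr=[(date(2020, 1, 1), ["4019", "29410"])])
        assert classify_dementia(h, codebook, AS_OF).is_case

    def test_dotted_icd9_prefix_matching(self, codebook):
        # codebook uses "294.1"; data carries undotted 5-digit codes
        h = make_history(hdr=[(date(2020, 1, 1), ["294.11"])])
        assert classify_dementia(h, codebook, AS_OF).is_case

    @pytest.mark.parametrize(
        "active", list(itertools.product([0, 1], repeat=5)), ids=lambda a: "".join(map(str, a))
    )
    def test_truth_table_enumeration(self, codebook, active):
        """Oracle: case iff any non-proxy criterion, or proxy without psych."""
        dem_rx, hdr, exem, proxy, psych = active
        rx, hdrs, exs = [], [], []
        if dem_rx:
            rx += rx_on([0, 30], atc="N06DA02")
        if proxy:
            rx += rx_on([100, 130], atc="N06AX11")
        if hdr:
            hdrs.append((date(2020, 2, 1), ["3310"]))
        if exem:
            exs.append((date(2020, 3, 1), "011"))
        if psych:
            exs.append((date(2017, 1, 1), "044"))
        h = make_history(rx=rx, hdr=hdrs, ex=exs)
        c = classify_dementia(h, codebook, AS_OF)
        expected = bool(dem_rx or hdr or exem) or (bool(proxy) and not psych)
        assert c.is_case == expected
        expected_excluded = bool(proxy) and bool(psych) and not (dem_rx or hdr or exem)
        assert c.excluded_psychiatric == expected_excluded


class TestAssignGroup:
    @pytest.mark.parametrize(
        "park,dem,expected",
        [(True, True, "both"), (True, False, "parkinsonism"),
         (False, True, "dementia"), (False, False, None)],
    )
    def test_exhaustive(self, park, dem, expected):
        assert assign_group(park, dem) == expected


class TestIsIncident:
    def test_first_ever_event_in_reference_year(self, codebook):
        h = make_history(rx=rx_on([10, 50], year=2021))
        assert is_incident(h, codebook, 2021, 5, 2016)

    def test_old_exemption_blocks_incidence(self, codebook):
        h = make_history(rx=rx_on([10, 50], year=2021), ex=[(date(2018, 6, 1), "038")])
        assert not is_incident(h, codebook, 2021, 5, 2016)

    def test_single_proxy_rx_counts_as_lookback_evidence(self, codebook):
        h = make_history(rx=rx_on([10, 50], year=2021) + rx_on([5], atc="N05AH04", year=2019))
        assert not is_incident(h, codebook, 2021, 5, 2016)

    def test_lookback_truncated_at_study_start(self, codebook):
        # reference 2017 with study start 2016: only 2016 is scanned
        h = make_history(rx=rx_on([10, 50], year=2017))
        assert is_incident(h, codebook, 2017, 5, study_start_year=2016)

    def test_evidence_after_year_violates_contract(self, codebook):
        h = make_history(rx=rx_on([10], year=2022))
        with pytest.raises(ValueError):
            is_incident(h, codebook, 2021, 5, 2016)


def _cohort(histories, codebook, **kw):
    return identify_cohort(histories, codebook, reference_year=2021,
                           lookback_years=5, study_start_year=2016, **kw)


class TestIdentifyCohort:
    def test_group_intersection_identity(self, codebook):
        h_park = make_history(make_person("a"), rx=rx_on([0, 30]))
        h_dem = make_history(make_person("b"), rx=rx_on([0, 30], atc="N06DA02"))
        h_both = make_history(
            make_person("c"), rx=rx_on([0, 30]) + rx_on([5, 35], atc="N06DA02")
        )
        res = _cohort({h.person.person_id: h for h in (h_park, h_dem, h_both)}, codebook)
        groups = {c.person_id: c.group for c in res.cases}
        assert groups == {"a": "parkinsonism", "b": "dementia", "c": "both"}

    def test_sum_of_groups_is_total(self, codebook):
        hists = {}
        for i, atc in enumerate(["N04BA02", "N06DA02", "N05AH04"] * 4):
            p = make_person(f"p{i}")
            hists[p.person_id] = make_history(p, rx=rx_on([0, 30], atc=atc))
        res = _cohort(hists, codebook)
        by = res.by_group()
        assert len(res.cases) == sum(len(v) for v in by.values())

    def test_exemption_only_cases_have_no_prescription_source(self, codebook):
        hists = {
            "a": make_history(make_person("a"), ex=[(date(2020, 1, 1), "038")]),
            "b": make_history(make_person("b"), ex=[(date(2020, 1, 1), "011")]),
        }
        res = _cohort(hists, codebook)
        assert len(res.cases) == 2
        for g in ("parkinsonism", "dementia"):
            assert res.source_breakdown[g]["prescription"] == 0
            assert res.source_breakdown[g]["exemption"] == 1

    def test_dead_before_reference_year_not_counted(self, codebook):
        p = make_person("a", death=date(2019, 7, 1))
        res = _cohort({"a": make_history(p, rx=rx_on([0, 30], year=2018))}, codebook)
        assert res.cases == []

    def test_death_in_reference_year_flagged(self, codebook):
        p = make_person("a", death=date(2021, 7, 1))
        res = _cohort({"a": make_history(p, rx=rx_on([0, 30], year=2018))}, codebook)
        assert len(res.cases) == 1
        assert res.cases[0].died_in_reference_year

    def test_order_invariance(self, codebook):
        p = make_person("a")
        rx = rx_on([40, 0, 90])
        h1 = make_history(p, rx=rx)
        h2 = make_history(p, rx=list(reversed(rx)))
        r1 = _cohort({"a": h1}, codebook)
        r2 = _cohort({"a": h2}, codebook)
        assert r1.cases == r2.cases

    def test_drug_breakdown_subgroups(self, codebook):
        hists = {
            "a": make_history(make_person("a"), rx=rx_on([0, 30], atc="N04BA02")),
            "b": make_history(make_person("b"), rx=rx_on([0, 30], atc="N06AX05")),
        }
        res = _cohort(hists, codebook)
        assert res.drug_breakdown["parkinsonism"] == {"N04BA": 1}
        assert res.drug_breakdown["dementia"] == {"trazodone": 1}


class TestMonotoneProperties:
    def test_psych_label_never_creates_a_case(self, codebook):
        base = make_history(make_person("a"), rx=rx_on([0, 30], atc="N06DA02"))
        with_label = make_history(
            make_person("a"), rx=rx_on([0, 30], atc="N06DA02"),
            ex=[(date(2018, 1, 1), "044")],
        )
        c0 = classify_dementia(base, codebook, AS_OF)
        c1 = classify_dementia(with_label, codebook, AS_OF)
        assert c0.is_case and c1.is_case  # non-proxy criterion survives

    def test_psych_label_removes_only_proxy_only_cases(self, codebook):
        proxy_only = make_history(rx=rx_on([0, 30], atc="N05AH04"))
        labelled = make_history(rx=rx_on([0, 30], atc="N05AH04"),
                                ex=[(date(2018, 1, 1), "044")])
        assert classify_dementia(proxy_only, codebook, AS_OF).is_case
        assert not classify_dementia(labelled, codebook, AS_OF).is_case

    def test_adding_dementia_discharge_never_removes_case(self, codebook):
        for extra_ex in ([], [(date(2018, 1, 1), "044")]):
            h = make_history(rx=rx_on([0, 30], atc="N05AH04"),
                             hdr=[(date(2020, 1, 1), ["2900"])], ex=extra_ex)
            assert classify_dementia(h, codebook, AS_OF).is_case

    def test_incident_cases_are_subset_of_prevalent(self, codebook):
        hists = {}
        for i in range(20):
            p = make_person(f"p{i}")
            year = 2021 if i % 2 else 2018
            hists[p.person_id] = make_history(p, rx=rx_on([0, 30], year=year))
        res = _cohort(hists, codebook)
        incident = {c.person_id for c in res.cases if c.incident}
        prevalent = {c.person_id for c in res.cases}
        assert incident <= prevalent


class TestIncidentCountsByYear:
    def test_counts_by_first_evidence_year(self, codebook):
        hists = {
            "a": make_history(make_person("a"), rx=rx_on([0, 30], year=2019)),
            "b": make_history(make_person("b"), rx=rx_on([0, 30], year=2019)),
            "c": make_history(make_person("c"), rx=rx_on([0, 30], year=2021)),
        }
        counts = incident_counts_by_year(hists, codebook, [2019, 2020, 2021],
                                         study_start_year=2016)
        assert counts[2019]["parkinsonism"] == 2
        assert counts[2020]["parkinsonism"] == 0
        assert counts[2021]["parkinsonism"] == 1

    def test_prior_evidence_blocks(self, codebook):
        h = make_history(rx=rx_on([0], year=2018) + rx_on([0, 30], year=2021))
        counts = incident_counts_by_year({"p1": h}, codebook, [2021], study_start_year=2016)
        assert counts[2021]["parkinsonism"] == 0
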