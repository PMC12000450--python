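"""Descriptive-statistics layer: exact 3-decimal percents, Yates chi-square
convention, median/IQR, domain mapping and patient-level frequency tables.

The regression fixture below freezes a published organ-system summary of
extraintestinal manifestations in a 30,334-patient IBD cohort
(CD n=15,924 / UC n=11,718 / IBDU n=2,692): for every row the printed
percent must be reproduced exactly from its printed count, and the printed
CD-vs-UC p-value must be reproduced by the Yates-corrected chi-square.
"""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibd_diseasome.cohort import CohortLabel
from ibd_diseasome.domains import IBD_INDEX_DOMAIN, UNMAPPED, default_domain_map
from ibd_diseasome.freq import (
    chi_square_2x2,
    frequency_table,
    map_code_to_domain,
    median_iqr,
    percent,
    utilization_rate,
)
from ibd_diseasome.records import EncounterRecord

N_CD, N_UC, N_IBDU = 15924, 11718, 2692
N_TOTAL = N_CD + N_UC + N_IBDU

# (row, count_CD, pct_CD, count_UC, pct_UC, count_IBDU, pct_IBDU,
#  count_total, pct_total, p_UC_vs_CD)
ORGAN_SYSTEM_TABLE = [
    ("Mental", 3095, 19.436, 1869, 15.950, 537, 19.948, 5501, 18.135, 0.00001),
    ("Musculoskeletal", 3142, 19.731, 1767, 15.079, 467, 17.348, 5376, 17.723, 0.00001),
    ("Genitourinary", 2046, 12.849, 1106, 9.438, 279, 10.364, 3431, 11.311, 0.00001),
    ("Cerebrovascular", 1657, 10.406, 1188, 10.138, 310, 11.516, 3155, 10.401, 0.4820),
    ("Circulatory", 1584, 9.947, 1240, 10.582, 322, 11.961, 3146, 10.371, 0.0888),
    ("Respiratory", 1658, 10.412, 1092, 9.319, 276, 10.253, 3026, 9.976, 0.0029),
    ("Symptoms/signs", 1415, 8.886, 916, 7.817, 275, 10.215, 2606, 8.591, 0.0017),
    ("Digestive", 1209, 7.592, 968, 8.261, 290, 10.773, 2467, 8.133, 0.0438),
    ("Blood/immune", 865, 5.432, 461, 3.934, 129, 4.792, 1455, 4.797, 0.00001),
    ("Skin", 794, 4.986, 381, 3.251, 89, 3.306, 1264, 4.167, 0.00001),
    ("Nervous", 640, 4.019, 472, 4.028, 122, 4.532, 1234, 4.068, 0.9950),
    ("Endocrine", 327, 2.054, 286, 2.441, 94, 3.492, 707, 2.331, 0.0341),
    ("Eye", 458, 2.876, 212, 1.809, 37, 1.374, 707, 2.331, 0.00001),
    ("Ear", 244, 1.532, 215, 1.835, 48, 1.783, 507, 1.671, 0.0578),
    ("Any EIM & AID", 9490, 59.596, 6290, 53.678, 1522, 56.538, 17302, 57.038, 0.00001),
]


class TestPercent:
    @pytest.mark.parametrize("row", ORGAN_SYSTEM_TABLE, ids=lambda r: r[0])
    def test_reproduces_printed_percents(self, row):
        _, c_cd, p_cd, c_uc, p_uc, c_ibdu, p_ibdu, c_tot, p_tot, _ = row
        assert percent(c_cd, N_CD) == p_cd
        assert percent(c_uc, N_UC) == p_uc
        assert percent(c_ibdu, N_IBDU) == p_ibdu
        assert percent(c_tot, N_TOTAL) == p_tot

    def test_sex_row_uses_sex_known_denominator(self):
        # 13,911 of the 26,945 patients with known sex are female
        assert percent(13911, 26945) == 51.627

    def test_zero_numerator(self):
        assert percent(0, 10) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(n=st.integers(0, 1000), d=st.integers(1, 1000), step=st.integers(1, 50))
    def test_monotone_in_numerator(self, n, d, step):
        n = min(n, d)
        n2 = min(n + step, d)
        assert percent(n2, d) >= percent(n, d)


class TestChiSquare:
    @pytest.mark.parametrize(
        "row",
        [r for r in ORGAN_SYSTEM_TABLE if r[-1] > 0.0001],
        ids=lambda r: r[0],
    )
    def test_yates_reproduces_printed_p(self, row):
        """Printed p-values reproduce to +/-1 unit in the last printed digit
        with the continuity correction."""
        _, c_cd, _, c_uc, *_, p_printed = row
        _, p = chi_square_2x2(c_cd, N_CD, c_uc, N_UC)
        assert abs(p - p_printed) <= 1.5e-4

    def test_without_correction_does_not_reproduce(self):
        # digestive row: 0.0438 printed; plain Pearson gives ~0.041
        _, p = chi_square_2x2(1209, N_CD, 968, N_UC, yates=False)
        assert abs(p - 0.0438) > 1.5e-4
        # respiratory row: 0.0029 printed; plain Pearson gives ~0.0027
        _, p = chi_square_2x2(1658, N_CD, 1092, N_UC, yates=False)
        assert abs(p - 0.0029) > 1.0e-4

    def test_identical_proportions(self):
        stat, p = chi_square_2x2(50, 100, 50, 100)
        assert stat == 0.0
        assert p == 1.0

    def test_symmetry(self):
        assert chi_square_2x2(1209, N_CD, 968, N_UC) == pytest.approx(
            chi_square_2x2(968, N_UC, 1209, N_CD)
        )

    def test_empty_margin_raises(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 1, 10)

    def test_small_expected_cell_warns_but_returns(self):
        with pytest.warns(UserWarning):
            stat, p = chi_square_2x2(0, 3000, 1, 3000)
        assert 0 <= p <= 1


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values,expected",
        [([5], (5, 0)), ([1, 2, 3, 4], (2.5, 1.5)), ([0, 0, 0, 100], (0, 25.0))],
    )
    def test_examples(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestDomainMapping:
    @pytest.mark.parametrize(
        "code,domain_start",
        [
            ("F32.9", "Mental"),
            ("M45.9", "Diseases of the musculoskeletal"),
            ("N20.0", "Diseases of the genitourinary"),
            ("I80.2", "Cerebrovascular"),
            ("I63.9", "Cerebrovascular"),
            ("I20.9", "Diseases of the circulatory"),
            ("J45.9", "Diseases of the respiratory"),
            ("R53", "Symptoms"),
            ("K90.0", "Diseases of the digestive"),
            ("D84.9", "Diseases of the blood"),
            ("L40.5", "Diseases of the skin"),
            ("G45.9", "Diseases of the nervous"),
            ("E10.9", "Endocrine"),
            ("H20.9", "Diseases of the eye"),
            ("H90.3", "Diseases of the ear"),
        ],
    )
    def test_chapter_assignment(self, code, domain_start):
        assert map_code_to_domain(code).startswith(domain_start)

    def test_ibd_index_codes_are_not_eim(self):
        assert map_code_to_domain("K50.9") == IBD_INDEX_DOMAIN
        assert map_code_to_domain("K51.2") == IBD_INDEX_DOMAIN

    def test_unmapped_falls_through(self):
        assert map_code_to_domain("U07.1") == UNMAPPED

    def test_roundtrip_serialization(self, tmp_path):
        from ibd_diseasome.domains import DomainMap

        dmap = default_domain_map()
        for suffix in (".json", ".yaml"):
            path = tmp_path / f"map{suffix}"
            dmap.save(path)
            assert DomainMap.load(path).to_dict() == dmap.to_dict()


def _mini_cohort():
    return [
        CohortLabel("P1", "CD"), CohortLabel("P2", "CD"),
        CohortLabel("P3", "UC"), CohortLabel("P4", "UC"),
        CohortLabel("P5", "IBDU"), CohortLabel("P6", "excluded"),
    ]


def _rec(pid, code, day=1):
    return EncounterRecord(pid, dt.date(2010, 1, day), code, "physician_claim")


class TestFrequencyTable:
    def test_patient_counted_once_per_domain(self):
        records = [
            _rec("P1", "M45.9"), _rec("P1", "M06.9", 2), _rec("P1", "M79.6", 3),
            _rec("P3", "M45.9"),
        ]
        rows = frequency_table(records, _mini_cohort())
        musculo = next(r for r in rows if r.row_label.startswith("Diseases of the musculo"))
        assert musculo.count_CD == 1  # five distinct M codes still one patient
        assert musculo.count_UC == 1
        assert musculo.pct_CD == 50.0

    def test_ibd_and_unmapped_codes_never_count(self):
        records = [_rec("P1", "K50.9"), _rec("P2", "U07.1")]
        rows = frequency_table(records, _mini_cohort())
        assert all(r.count_total == 0 for r in rows)

    def test_any_row_aggregates_across_domains(self):
        records = [_rec("P1", "M45.9"), _rec("P1", "F32.9", 2), _rec("P3", "H20.9")]
        rows = frequency_table(records, _mini_cohort())
        any_row = rows[-1]
        assert any_row.row_label == "Number of patients with any EIM & AID"
        assert any_row.count_CD == 1 and any_row.count_UC == 1
        assert any_row.count_total == 2

    def test_every_cd_patient_with_f_code_gives_100_percent(self):
        records = [_rec("P1", "F32.9"), _rec("P2", "F41.1")]
        rows = frequency_table(records, _mini_cohort())
        mental = next(r for r in rows if r.row_label.startswith("Mental"))
        assert mental.pct_CD == 100.0

    def test_planted_prevalence_recovered(self, planted_cohort):
        """Domain percents recovered within 3 binomial SEs of the generator's
        expected marginal carry rate."""
        import math

        config, records, truth, cohort = planted_cohort
        rows = frequency_table(records, cohort)
        k = config.n_communities
        # marginal probability a patient carries any one planted code
        p_code = config.p_within / k + config.p_between * (k - 1) / k
        # F-chapter codes in the pool
        f_codes = [c for c in truth.code_communities if c.startswith("F")]
        p_domain = 1 - (1 - p_code) ** len(f_codes)
        mental = next(r for r in rows if r.row_label.startswith("Mental"))
        n_cd = sum(1 for c in cohort if c.label == "CD")
        se = math.sqrt(p_domain * (1 - p_domain) / n_cd)
        assert abs(mental.pct_CD / 100 - p_domain) < 3 * se

    def test_code_list_grouping(self):
        records = [_rec("P1", "M45.9"), _rec("P3", "M45.9"), _rec("P3", "F32.9", 2)]
        rows = frequency_table(records, _mini_cohort(), grouping=["M45.9", "F32.9"])
        by_label = {r.row_label: r for r in rows}
        assert by_label["M45.9"].count_total == 2
        assert by_label["F32.9"].count_UC == 1


class TestUtilization:
    @pytest.mark.parametrize("events,py,expected", [(0, 10, 0.0), (50, 25, 2.0), (7, 3.5, 2.0)])
    def test_rate(self, events, py, expected):
        assert utilization_rate(events, py) == expected

    def test_zero_patient_years_raises(self):
        with pytest.raises(ValueError):
            utilization_rate(5, 0)
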