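"""Disproportionality statistics against hand arithmetic and brute-force
oracles, plus deduplication and sensitivity-filter behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from pvtrigger import pharmacovigilance as pv
from pvtrigger.synthetic import generate_reports
from tests.conftest import TARGET_EVENT, planted_config


def _mini_reports(rows):
    cols = ["CASEID", "FDA_DT", "DRUGNAME", "PT"]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("SEX", "AGE", "WT", "COUNTRY", "OCCP_COD", "OUTC_COD",
              "START_DT", "EVENT_DT"):
        df[c] = ""
    return df


class TestDeduplicate:
    def test_keeps_latest_receipt_and_breaks_ties_by_file_order(self):
        df = _mini_reports([
            ("X", "2020-01-01", "A", "E1"),
            ("X", "2021-06-01", "A", "E2"),
            ("Y", "2020-05-05", "B", "E1"),
            ("Y", "2020-05-05", "B", "E3"),  # tie: last occurrence wins
        ])
        out = pv.deduplicate(df)
        assert len(out) == 2
        assert out.loc[out.CASEID == "X", "PT"].item() == "E2"
        assert out.loc[out.CASEID == "Y", "PT"].item() == "E3"

    def test_no_duplicates_is_identity_and_idempotent(self):
        df = _mini_reports([("A", "2020-01-01", "D", "E"),
                            ("B", "2020-01-02", "D", "E")])
        once = pv.deduplicate(df)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      df.reset_index(drop=True))
        pd.testing.assert_frame_equal(pv.deduplicate(once), once)

    def test_unparseable_dates_are_dropped(self, caplog):
        df = _mini_reports([("A", "not-a-date", "D", "E"),
                            ("B", "2020-01-02", "D", "E")])
        out = pv.deduplicate(df)
        assert list(out.CASEID) == ["B"]

    def test_synthetic_duplicates_collapse_to_n(self, planted_reports):
        out = pv.deduplicate(planted_reports)
        assert len(out) == 20000


class TestContingency:
    def test_single_report_all_cells(self):
        df = _mini_reports([("1", "2020-01-01", "X", "Y")])
        t = pv.build_contingency(df, "X", "Y")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)
        t2 = pv.build_contingency(df, "ABSENT", "Y")
        assert (t2.a, t2.c) == (0, 1)

    def test_multi_drug_report_counts_once_per_drug(self):
        df = _mini_reports([("1", "2020-01-01", "X|Z", "Y"),
                            ("2", "2020-01-01", "W", "Y")])
        assert pv.build_contingency(df, "X", "Y").a == 1
        assert pv.build_contingency(df, "Z", "Y").a == 1

    def test_name_normalisation_merges_variants(self):
        assert pv.normalize_drug_name("CELECOXIB.|CELECOXIB") == ["CELECOXIB"]
        assert pv.normalize_drug_name("Naproxen Sodium ({= 220 MG)") == \
            ["NAPROXEN SODIUM"]
        assert pv.normalize_drug_name("aspirin (oral)") == ["ASPIRIN"]

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            pv.ContingencyTable(0, 0, 0, 0)
        with pytest.raises(ValueError):
            pv.ContingencyTable(-1, 1, 1, 1)


class TestRor:
    def test_hand_arithmetic_value(self):
        est, (lo, hi), corr = pv.ror(pv.ContingencyTable(10, 90, 90, 9810))
        assert est == pytest.approx(98100 / 8100, rel=1e-12)
        se = np.sqrt(1 / 10 + 1 / 90 + 1 / 90 + 1 / 9810)
        assert lo == pytest.approx(np.exp(np.log(est) - 1.96 * se), rel=1e-12)
        assert not corr

    def test_symmetric_table_is_null(self):
        est, (lo, hi), _ = pv.ror(pv.ContingencyTable(25, 25, 25, 25))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_gets_haldane_correction(self):
        est, _, corr = pv.ror(pv.ContingencyTable(5, 0, 3, 10))
        assert corr and np.isfinite(est)


class TestPrrChi2:
    def test_hand_arithmetic_value(self):
        prr, chi2, _ = pv.prr_chi2(pv.ContingencyTable(10, 90, 90, 9810))
        assert prr == pytest.approx(0.1 / (90 / 9900), rel=1e-12)

    def test_proportional_table_is_null(self):
        prr, chi2, _ = pv.prr_chi2(pv.ContingencyTable(20, 80, 200, 800))
        assert prr == pytest.approx(1.0)
        assert 0 <= chi2 < 0.1

    def test_chi2_matches_scipy_yates(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(1, 200, size=4)
            t = pv.ContingencyTable(int(a), int(b), int(c), int(d))
            _, chi2, _ = pv.prr_chi2(t)
            ref = stats.chi2_contingency(np.array([[a, b], [c, d]]),
                                         correction=True)[0]
            assert chi2 == pytest.approx(ref, abs=1e-9)


class TestBcpnn:
    def test_ic025_below_ic_everywhere(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 500, size=4)
            if a + b + c + d == 0:
                continue
            ic, ic025 = pv.bcpnn_ic(pv.ContingencyTable(int(a), int(b),
                                                        int(c), int(d)))
            assert ic025 < ic

    def test_independence_limit_is_zero(self):
        ic, _ = pv.bcpnn_ic(pv.ContingencyTable(20000, 80000, 200000, 800000))
        assert abs(ic) < 0.01

    def test_large_count_limit_approaches_log2_relative_rate(self):
        # scaled x100: shrinkage vanishes and E(IC) -> log2(10)
        ic, _ = pv.bcpnn_ic(pv.ContingencyTable(1000, 9000, 9000, 981000))
        assert ic == pytest.approx(np.log2(10), abs=0.15)


class TestMgps:
    def test_fixed_single_component_posterior_digamma_value(self):
        # prior Gamma(1,1) via two identical components; table (3,0,0,6) has
        # a=3, E=3*3/9=1 -> posterior Gamma(4,2), E[ln lambda] = psi(4) - ln 2
        prior = pv.MgpsPrior(1.0, 1.0, 1.0, 1.0, 0.5)
        (ebgm, ebgm05), = pv.mgps_ebgm([pv.ContingencyTable(3, 0, 0, 6)],
                                       prior=prior)
        elog = special.digamma(4) - np.log(2)
        assert elog == pytest.approx(0.5630, abs=1e-4)
        assert ebgm == pytest.approx(np.exp(elog), rel=1e-6)
        assert ebgm05 <= ebgm

    def test_null_simulation_median_near_one(self, rng):
        tables = []
        for _ in range(300):
            e = rng.uniform(20, 200)
            a = rng.poisson(e)
            row = int(np.ceil(e * 10))
            col = int(np.ceil(e * 10))
            n = row * col // max(int(e), 1)
            b, c = row - a, col - a
            d = max(n - a - b - c, 1)
            if min(a, b, c) < 0:
                continue
            tables.append(pv.ContingencyTable(int(a), int(b), int(c), int(d)))
        res = pv.mgps_ebgm(tables, seed=0)
        med = np.median([x[0] for x in res])
        assert 0.8 <= med <= 1.2
        assert all(e05 <= eb for eb, e05 in res)

    def test_prior_fit_requires_enough_pairs(self):
        with pytest.raises(ValueError):
            pv.fit_mgps_prior([pv.ContingencyTable(1, 1, 1, 1)] * 5)


def test_monotonicity_in_a_with_margins_fixed():
    """Shifting one report into the (drug, event) cell raises every statistic."""
    prior = pv.MgpsPrior()
    t1 = pv.ContingencyTable(20, 80, 180, 720)
    t2 = pv.ContingencyTable(21, 79, 179, 721)
    assert pv.ror(t2)[0] > pv.ror(t1)[0]
    assert pv.prr_chi2(t2)[0] > pv.prr_chi2(t1)[0]
    assert pv.bcpnn_ic(t2)[0] > pv.bcpnn_ic(t1)[0]
    e1 = pv.mgps_ebgm([t1], prior=prior)[0][0]
    e2 = pv.mgps_ebgm([t2], prior=prior)[0][0]
    assert e2 > e1


class TestDetectSignals:
    def test_minimum_count_rule_blocks_tiny_a(self):
        res = pd.DataFrame([dict(drug="X", a=2, b=1, c=1, d=10000,
                                 ror=1000.0, ror_lo=50.0, ror_hi=2e4,
                                 prr=900.0, chi2=500.0, ic=5.0, ic025=3.0,
                                 ebgm=50.0, ebgm05=10.0, corrected=False)])
        out = pv.detect_signals(res)
        assert not out["flag_ror"].item()
        assert not out["flag_prr"].item()
        assert not out["consensus"].item()

    def test_planted_signal_reaches_consensus(self, dedup_reports):
        tab = pv.detect_signals(
            pv.disproportionality_table(dedup_reports, TARGET_EVENT, seed=0))
        row = tab.set_index("drug").loc["D00"]
        assert row["consensus"]
        assert row[["flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps"]].all()


class TestSensitivityFilter:
    def test_identity_when_no_match_and_empty_list(self, dedup_reports):
        assert pv.sensitivity_filter(dedup_reports, []).equals(dedup_reports)
        out = pv.sensitivity_filter(dedup_reports, ["NOT A DRUG"])
        assert len(out) == len(dedup_reports)

    def test_comedicated_reports_removed(self, dedup_reports):
        before = pv.build_contingency(dedup_reports, "D00", TARGET_EVENT).a
        out = pv.sensitivity_filter(dedup_reports, ["METHOTREXATE"])
        after = pv.build_contingency(out, "D00", TARGET_EVENT).a
        # comed_fraction=0.2 of D00 reports carried the confounder
        assert after / before == pytest.approx(0.8, abs=0.06)

    def test_excluding_all_drugs_empties_table(self, dedup_reports):
        drugs = [f"D{i:02d}" for i in range(10)] + ["METHOTREXATE"]
        assert len(pv.sensitivity_filter(dedup_reports, drugs)) == 0


class TestDescriptiveSummary:
    def test_all_female_cohort(self):
        df = _mini_reports([("1", "2020-01-01", "D", "E"),
                            ("2", "2021-01-01", "D", "E")])
        df["SEX"] = "F"
        s = pv.descriptive_summary(df)
        assert s["sex"]["female_share"] == 1.0
        assert s["yearly_counts"] == {2020: 1, 2021: 1}

    def test_shares_match_generator_proportions(self, dedup_reports):
        s = pv.descriptive_summary(dedup_reports)
        assert s["sex"]["female_share"] == pytest.approx(0.64 / 0.90, abs=0.02)
        assert s["country"]["shares"]["CANADA"] == pytest.approx(0.35, abs=0.02)
        assert s["reporter"]["shares"]["MD"] == pytest.approx(0.37, abs=0.02)
        assert s["outcome"]["shares"]["HO"] == pytest.approx(0.236, abs=0.02)
        assert sum(s["age_groups"].values()) == s["n_reports"]
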