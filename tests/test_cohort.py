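import numpy as np
import pandas as pd
import pytest

import oncotriad as ot
from oncotriad import cohort as cm
from oncotriad.cohort import AssociationList
from oncotriad.synthetic_data import PatientCohort


def tiny_cohort(myc, tp53, kras, extra_genes=None):
    """Cohort from explicit per-patient values."""
    n = len(myc)
    idx = pd.Index([f"P{i}" for i in range(n)], name="patient_id")
    data = {"MYC": myc}
    for gene, values in (extra_genes or {}).items():
        data[gene] = values
    return PatientCohort(
        expression=pd.DataFrame(data, index=idx),
        tp53_status=pd.Series(tp53, index=idx),
        kras_status=pd.Series(kras, index=idx),
    )


def assoc_list(stratum, genes):
    records = pd.DataFrame(
        {"t": 5.0, "p": 1e-6, "q": 1e-5, "direction": 1},
        index=pd.Index(list(genes), name="gene"),
    )
    return AssociationList(stratum=stratum, fdr_threshold=0.001, records=records)


class TestStratify:
    def test_exclusive_definitions(self):
        cohort = tiny_cohort(
            myc=[10.0, 1.0, 10.0, 1.0, 1.0],
            tp53=["WT", "null", "missense", "missense", "WT"],
            kras=["WT", "WT", "point_mutant", "WT", "point_mutant"],
        )
        labels = cm.stratify(cohort)
        assert labels["P0"] == "MYC_high_only"  # high MYC, WT elsewhere
        assert labels["P1"] == "control"  # TP53 null is control-eligible
        assert labels["P2"] == "triple_active"
        assert labels["P3"] == "TP53_mut_only"
        assert labels["P4"] == "KRAS_mut_only"

    def test_missing_myc_column_rejected(self):
        cohort = tiny_cohort([1.0, 2.0], ["WT", "WT"], ["WT", "WT"])
        cohort.expression = cohort.expression.drop(columns="MYC")
        with pytest.raises(ValueError, match="MYC"):
            cm.stratify(cohort)


class TestSignatureScore:
    def test_mean_of_listed_genes(self):
        cohort = tiny_cohort(
            [1.0], ["WT"], ["WT"], extra_genes={"A": [2.0], "B": [4.0], "C": [6.0]}
        )
        assert cm.signature_score(cohort, ["A", "B", "C"]).iloc[0] == pytest.approx(4.0)
        assert cm.signature_score(cohort, ["A"]).iloc[0] == pytest.approx(2.0)
        permuted = cm.signature_score(cohort, ["C", "A", "B"])
        assert permuted.iloc[0] == pytest.approx(4.0)

    def test_missing_gene_named_in_error(self):
        cohort = tiny_cohort([1.0], ["WT"], ["WT"], extra_genes={"A": [1.0]})
        with pytest.raises(ValueError, match="XPO1"):
            cm.signature_score(cohort, ["A", "XPO1"])


class TestCompareGroups:
    def test_identical_distribution_gives_p_one(self):
        scores = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        strata = pd.Series(
            ["control"] * 3 + ["MYC_high_only"] * 3, index=list("abcdef")
        )
        out = cm.compare_signature_groups(scores, strata, groups=("MYC_high_only",))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_small_group_skipped_with_warning(self):
        scores = pd.Series([1.0, 2.0, 3.0, 9.0], index=list("abcd"))
        strata = pd.Series(["control"] * 3 + ["triple_active"], index=list("abcd"))
        with pytest.warns(UserWarning, match="triple_active"):
            out = cm.compare_signature_groups(scores, strata, groups=("triple_active",))
        assert out.empty


class TestAssociation:
    def test_null_cohort_controls_fdr(self):
        model = ot.cohort_association_model(400, 5, 3, seed=0)
        table = model.table.copy()
        table["mode"] = "null"
        table["effect_size"] = 0.0
        null_model = ot.RegulatoryModel(table)
        counts = 0
        for seed in range(5):
            cohort, _ = ot.simulate_cohort(200, null_model, seed=seed)
            assoc = cm.associate_transcriptome(cohort, "MYC_high_only")
            counts += len(assoc.genes)
        assert counts <= 5  # expected ~0.4 per cohort at FDR 0.001

    def test_planted_genes_recovered(self):
        model = ot.cohort_association_model(600, solo_per_oncogene=20, shared_per_pair=10, effect_size=2.0, seed=1)
        cohort, truth = ot.simulate_cohort(300, model, seed=1)
        assoc = cm.associate_transcriptome(cohort, "MYC_high_only", comparator="control")
        planted = set(truth.associated_genes["MYC"])
        sensitivity = len(planted & assoc.genes) / len(planted)
        assert sensitivity >= 0.9

    def test_degenerate_stratum_rejected(self):
        cohort = tiny_cohort(
            [1.0, 2.0, 3.0, 4.0], ["WT"] * 4, ["WT"] * 4, extra_genes={"A": [1, 2, 3, 4]}
        )
        strata = pd.Series(["MYC_high_only"] * 4, index=cohort.patients)
        with pytest.raises(ValueError, match="degenerate"):
            cm.associate_transcriptome(cohort, "MYC_high_only", strata=strata)


class TestLikelyRedundant:
    def test_set_arithmetic_example(self):
        lists = {
            "MYC": assoc_list("MYC_high_only", ["g1", "g2", "g3", "g4"]),
            "KRAS_mut": assoc_list("KRAS_mut_only", ["g3", "g5"]),
            "TP53_mut": assoc_list("TP53_mut_only", ["g4", "g6"]),
        }
        out = cm.likely_redundant(lists)
        assert out.at["MYC", "likely_pct"] == pytest.approx(50.0)
        assert out.at["MYC", "unlikely_pct"] == pytest.approx(50.0)

    def test_disjoint_and_identical_extremes(self):
        disjoint = {
            "MYC": assoc_list("s", ["a"]),
            "KRAS_mut": assoc_list("s", ["b"]),
            "TP53_mut": assoc_list("s", ["c"]),
        }
        assert cm.likely_redundant(disjoint)["likely_pct"].tolist() == [0.0, 0.0, 0.0]
        same = {o: assoc_list("s", ["a", "b"]) for o in disjoint}
        assert cm.likely_redundant(same)["likely_pct"].tolist() == [100.0, 100.0, 100.0]

    def test_multiple_datasets_averaged(self):
        ds1 = {o: assoc_list("s", ["a", "b"]) for o in ("MYC", "KRAS_mut", "TP53_mut")}
        ds2 = {
            "MYC": assoc_list("s", ["x"]),
            "KRAS_mut": assoc_list("s", ["y"]),
            "TP53_mut": assoc_list("s", ["z"]),
        }
        out = cm.likely_redundant([ds1, ds2])
        assert out["likely_pct"].tolist() == [50.0, 50.0, 50.0]

    def test_empty_list_warns_and_is_nan(self):
        lists = {
            "MYC": assoc_list("s", []),
            "KRAS_mut": assoc_list("s", ["a"]),
            "TP53_mut": assoc_list("s", ["a"]),
        }
        with pytest.warns(UserWarning, match="empty association list"):
            out = cm.likely_redundant(lists)
        assert np.isnan(out.at["MYC", "likely_pct"])


class TestKMLogrank:
    def test_hand_computed_toy_table(self):
        # A events at 1 and 2, B events at 3 and 4: O_A=2, E_A=5/6, V=17/36
        time = [1.0, 2.0, 3.0, 4.0]
        event = [True] * 4
        group = ["A", "A", "B", "B"]
        res = cm.km_logrank(time, event, group)
        assert res.observed[0] == pytest.approx(2.0)
        assert res.expected[0] == pytest.approx(0.833333, abs=1e-5)
        assert res.statistic == pytest.approx((2 - 5 / 6) ** 2 / (17 / 36), rel=1e-9)
        assert res.statistic == pytest.approx(2.882, abs=5e-3)

    def test_identical_groups_are_null(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        event = [True, True, False] * 2
        group = ["A"] * 3 + ["B"] * 3
        res = cm.km_logrank(time, event, group)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_relabeling_inverts_hazard_ratio(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(100, 60)
        event = rng.random(60) < 0.8
        group = np.array(["A"] * 30 + ["B"] * 30)
        fwd = cm.km_logrank(time, event, group)
        rev = cm.km_logrank(time, event, np.where(group == "A", "Z", "A"))
        assert fwd.statistic == pytest.approx(rev.statistic, rel=1e-9)
        assert fwd.hazard_ratio == pytest.approx(1.0 / rev.hazard_ratio, rel=1e-9)

    def test_matches_lifelines_on_random_data(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 40
            time = rng.exponential(50, n)
            event = rng.random(n) < 0.7
            group = rng.random(n) < 0.5
            if not (event[group].any() and event[~group].any()):
                continue
            mine = cm.km_logrank(time, event, np.where(group, "A", "B"))
            ref = lifelines_stats.logrank_test(
                time[group], time[~group], event[group], event[~group]
            )
            assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
            assert mine.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cm.km_logrank([1.0, 2.0], [False, False], ["A", "B"])
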