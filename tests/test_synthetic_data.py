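import numpy as np
import pandas as pd
import pytest

import oncotriad as ot
from oncotriad.containers import ONCOGENES, parse_oncogene_set
from oncotriad.synthetic_data import (
    DEFAULT_COMPETITIVE_FRACTION,
    derive_planted_classes,
    dominance_weighted_model,
)


def brute_force_classes(model):
    """Independent re-derivation of planted classes from the model table.

    Walks the table directly (no RegulatoryModel helpers) and applies the
    mode rules literally for the single-{X} and triple genotypes.
    """

    def contributes(row, onc, active):
        regs = set(str(row["regulators"]).split(";")) & active
        if row["mode"] == "null" or onc not in regs:
            return False
        if row["mode"] == "cooperative":
            return True
        dominant = next(o for o in row["dominance"].split(">") if o in regs)
        if row["mode"] == "redundant":
            return onc == dominant
        return True  # competitive: dominant drives, sub-dominant opposes

    out = {}
    triple = set(ONCOGENES)
    for gene, row in model.table.iterrows():
        for onc in ONCOGENES:
            if not contributes(row, onc, {onc}):
                out[(gene, onc)] = "null"
                continue
            a = contributes(row, onc, triple)
            b = any(contributes(row, o, triple) for o in ONCOGENES if o != onc)
            out[(gene, onc)] = (
                "non_redundant" if a and not b
                else "redundancy_possible" if a and b
                else "redundant" if b
                else "null"
            )
    return out


class TestRegulatoryModel:
    def test_null_model_plants_nothing(self):
        model = ot.null_model(20, seed=0)
        truth = derive_planted_classes(model)
        assert set(truth["planted_class"]) == {"null"}
        for gene in model.genes:
            for onc in ONCOGENES:
                assert model.expected_knockdown_lfc(gene, onc, frozenset(ONCOGENES)) == 0.0

    def test_redundant_gene_dominance_example(self):
        # one redundant gene, dominance MYC > KRAS > TP53: in the triple
        # line only the MYC knockdown moves it, so it is non-redundant for
        # MYC and redundant for the other two
        table = ot.null_model(10, seed=0).table.copy()
        gene = table.index[0]
        table.loc[gene, ["mode", "effect_size", "dominance"]] = [
            "redundant",
            2.0,
            "MYC>KRAS_mut>TP53_mut",
        ]
        truth = derive_planted_classes(ot.RegulatoryModel(table))
        by = truth.set_index(["gene", "oncogene"])["planted_class"]
        assert by[(gene, "MYC")] == "non_redundant"
        assert by[(gene, "KRAS_mut")] == "redundant"
        assert by[(gene, "TP53_mut")] == "redundant"

    def test_competitive_subdominant_shifts_opposite(self):
        table = ot.null_model(10, seed=0).table.copy()
        gene = table.index[0]
        table.loc[gene, ["mode", "effect_size", "dominance"]] = [
            "competitive",
            2.0,
            "MYC>KRAS_mut>TP53_mut",
        ]
        model = ot.RegulatoryModel(table)
        triple = frozenset(ONCOGENES)
        assert model.expected_knockdown_lfc(gene, "MYC", triple) == -2.0
        assert model.expected_knockdown_lfc(gene, "KRAS_mut", triple) == pytest.approx(
            DEFAULT_COMPETITIVE_FRACTION * 2.0
        )

    def test_planted_classes_match_brute_force(self):
        rng = np.random.default_rng(42)
        table = ot.null_model(200, seed=42).table.copy()
        modes = rng.choice(["null", "redundant", "cooperative", "competitive"], 200)
        for gene, mode in zip(table.index, modes):
            dom = list(ONCOGENES)
            rng.shuffle(dom)
            regs = sorted(
                rng.choice(ONCOGENES, size=rng.integers(1, 4), replace=False)
            )
            table.loc[gene, ["mode", "dominance", "regulators"]] = [
                mode,
                ">".join(dom),
                ";".join(regs),
            ]
            table.loc[gene, "effect_size"] = 0.0 if mode == "null" else 2.0
        model = ot.RegulatoryModel(table)
        truth = derive_planted_classes(model)
        oracle = brute_force_classes(model)
        for _, row in truth.iterrows():
            assert row["planted_class"] == oracle[(row["gene"], row["oncogene"])]

    def test_invalid_models_rejected(self):
        table = ot.null_model(10, seed=0).table.copy()
        bad = table.copy()
        bad.loc[bad.index[0], "effect_size"] = 1.0  # null mode, nonzero effect
        with pytest.raises(ValueError, match="effect_size"):
            ot.RegulatoryModel(bad)
        bad = table.copy()
        bad.loc[bad.index[0], "dominance"] = "MYC>KRAS_mut"
        with pytest.raises(ValueError, match="permutation"):
            ot.RegulatoryModel(bad)


class TestCellLineSimulation:
    def test_seed_determinism_is_byte_identical(self):
        model = ot.plant_class_fractions(100, pool_size=20, seed=3)
        panel = ot.standard_panel()
        out1 = ot.simulate_cellline_experiment(panel, model, 3, seed=5)
        out2 = ot.simulate_cellline_experiment(panel, model, 3, seed=5)
        assert out1[0].values.to_csv() == out2[0].values.to_csv()
        assert out1[1].values.to_csv() == out2[1].values.to_csv()
        out3 = ot.simulate_cellline_experiment(panel, model, 3, seed=6)
        assert out1[0].values.to_csv() != out3[0].values.to_csv()

    def test_rejects_degenerate_designs(self):
        model = ot.null_model(10, seed=0)
        with pytest.raises(ValueError, match="n_replicates"):
            ot.simulate_cellline_experiment([ot.triple_line()], model, 1, seed=0)
        with pytest.raises(ValueError, match="unknown oncogene"):
            ot.single_line("NRAS")

    def test_planted_mean_lfc_recovered(self):
        # 10% of genes planted at effect size 2: the empirical mean
        # control/knockdown log2 ratio of planted genes is ~2
        table = ot.null_model(2000, seed=1).table.copy()
        rng = np.random.default_rng(1)
        planted = rng.choice(table.index, 200, replace=False)
        table.loc[planted, ["mode", "effect_size"]] = ["redundant", 2.0]
        model = ot.RegulatoryModel(table)
        line = ot.single_line("MYC")
        mrna, _, _ = ot.simulate_cellline_experiment([line], model, 3, seed=1)
        ctrl_ids = mrna.samples.index[mrna.samples["perturbation"] == "control"]
        kd_ids = mrna.samples.index[mrna.samples["perturbation"] == "MYC"]
        ctrl = mrna.values[list(ctrl_ids)].mean(axis=1)
        kd = mrna.values[list(kd_ids)].mean(axis=1)
        ratio = np.log2(ctrl[planted] + 0.5) - np.log2(kd[planted] + 0.5)
        assert ratio.mean() == pytest.approx(2.0, abs=0.2)

    def test_counts_and_intensities_have_expected_types(self, small_panel):
        mrna, protein = small_panel["mrna"], small_panel["protein"]
        assert (mrna.values.to_numpy() == mrna.values.to_numpy().astype(int)).all()
        assert (protein.values.to_numpy() > 0).all()

    def test_partial_knockdown_scales_expected_lfc(self):
        model = ot.plant_class_fractions(60, pool_size=12, seed=2)
        line = ot.single_line("MYC")
        _, _, truth = ot.simulate_cellline_experiment(
            [line], model, 2, seed=2, knockdown_efficiency=0.5
        )
        assert truth.expected_lfc["expected_lfc"].abs().max() == pytest.approx(1.0)


class TestDominanceWeightedModel:
    def test_myc_heavy_weights_minimize_myc_redundancy(self):
        model = dominance_weighted_model(
            300, n_targets=150, top_weights={"MYC": 0.6, "KRAS_mut": 0.2, "TP53_mut": 0.2}, seed=0
        )
        truth = derive_planted_classes(model)
        redundant = (
            truth[truth["planted_class"] == "redundant"].groupby("oncogene").size()
        )
        assert redundant["MYC"] < redundant["KRAS_mut"]
        assert redundant["MYC"] < redundant["TP53_mut"]


class TestCohortSimulation:
    def test_rejects_degenerate_inputs(self):
        model = ot.cohort_association_model(200, 5, 3, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            ot.simulate_cohort(50, model, mutation_freqs={"KRAS_mut": 1.0}, seed=0)
        with pytest.raises(ValueError, match="n_patients"):
            ot.simulate_cohort(10, model, seed=0)

    def test_zero_effect_gives_equal_signature_means(self):
        from oncotriad import cohort as cm

        model = ot.cohort_association_model(200, 5, 3, effect_size=2.0, seed=0)
        cohort, _ = ot.simulate_cohort(
            2000, model, seed=0, signature_genes=("SIG1", "SIG2", "SIG3"),
            signature_effect=0.0,
        )
        strata = cm.stratify(cohort)
        scores = cm.signature_score(cohort, ["SIG1", "SIG2", "SIG3"])
        comparison = cm.compare_signature_groups(scores, strata)
        assert (comparison["mean"] - comparison["control_mean"]).abs().max() < 0.1

    def test_redundant_planting_is_not_additive(self):
        from oncotriad import cohort as cm

        model = ot.cohort_association_model(200, 5, 3, seed=1)
        cohort, _ = ot.simulate_cohort(
            1500, model, seed=1, signature_genes=("SIG1", "SIG2", "SIG3"),
            signature_effect=1.0,
        )
        strata = cm.stratify(cohort)
        scores = cm.signature_score(cohort, ["SIG1", "SIG2", "SIG3"])
        comparison = cm.compare_signature_groups(scores, strata).set_index("group")
        singles = comparison.loc[
            ["MYC_high_only", "KRAS_mut_only", "TP53_mut_only"], "mean"
        ]
        triple = comparison.at["triple_active", "mean"]
        # one active oncogene saturates the signature: triple is not higher
        assert triple <= singles.max() + 0.15

    def test_null_hazard_gives_null_logrank(self):
        from oncotriad import cohort as cm

        model = ot.cohort_association_model(200, 5, 3, seed=2)
        extreme = 0
        for seed in range(20):
            cohort, _ = ot.simulate_cohort(
                80, model, seed=seed, signature_genes=("SIG1",), hazard_factor=1.0
            )
            scores = cm.signature_score(cohort, ["SIG1"])
            groups = (scores > scores.median()).map({True: "high", False: "low"})
            res = cm.km_logrank(cohort.survival["time"], cohort.survival["event"], groups)
            extreme += res.p < 0.05
        assert extreme <= 4  # ~1 expected under the null

    def test_truth_lists_match_model_regulators(self):
        model = ot.cohort_association_model(300, solo_per_oncogene=10, shared_per_pair=5, seed=3)
        _, truth = ot.simulate_cohort(50, model, seed=3)
        for onc in ONCOGENES:
            expected = {
                g
                for g in model.genes
                if model.table.at[g, "mode"] != "null"
                and onc in parse_oncogene_set(model.table.at[g, "regulators"])
            }
            assert set(truth.associated_genes[onc]) == expected
            # 10 shared (2 pairs x 5) of 20 total genes per oncogene
            assert truth.likely_fractions[onc] == pytest.approx(50.0, abs=1e-9)
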