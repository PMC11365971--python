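"""End-to-end stage orchestration with run manifests.

Every stage reads declared inputs from (and writes outputs plus a
``manifest_<stage>.json`` into) a run directory; rerunning a stage with
the same configuration and seed is byte-identical.  Stages never mutate
their inputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import diffexpr, io, redundancy, signature
from .config import PipelineConfig
from .containers import ONCOGENES
from .synthetic_data import (
    add_universal_targets,
    cohort_association_model,
    plant_class_fractions,
    simulate_cellline_experiment,
    simulate_cohort,
    standard_panel,
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig, inputs: list[Path], outputs: list[Path]) -> None:
    io.write_json(
        {
            "stage": stage,
            "seed": config.seed,
            "parameters": config.model_dump(mode="json"),
            "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
            "outputs": sorted(p.name for p in outputs),
        },
        out_dir / f"manifest_{stage}.json",
    )


def make_synthetic_genesets(
    model_genes: list[str],
    universal_targets: tuple[str, ...],
    n_random_sets: int = 12,
    set_size: int = 25,
    seed: int = 0,
) -> dict[str, set[str]]:
    """GMT-ready synthetic pathway collection.

    One planted "common target" pathway contains the universal target
    genes padded with random members; the remaining sets are random draws
    from the quantified universe.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([g for g in model_genes if g not in set(universal_targets)])
    sets: dict[str, set[str]] = {}
    pad = rng.choice(genes, size=max(set_size - len(universal_targets), 0), replace=False)
    sets["COMMON_TARGET_PATHWAY"] = set(universal_targets) | set(pad)
    for i in range(n_random_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = set(members)
    return sets


def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    """Simulate the cell-line panel, gene sets, coding list and cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    model = plant_class_fractions(
        n_genes=sim.n_genes,
        pool_size=sim.pool_size,
        fractions=sim.class_fractions,
        effect_size=sim.effect_size,
        dispersion=sim.dispersion,
        seed=config.seed,
    )
    model = add_universal_targets(model, sim.universal_targets, sim.universal_effect)
    panel = standard_panel(tissue=sim.tissue)
    mrna, protein, truth = simulate_cellline_experiment(
        panel,
        model,
        n_replicates=sim.replicates,
        seed=config.seed,
        knockdown_efficiency=sim.knockdown_efficiency,
    )
    paths = config.paths
    io.write_matrix(mrna, out_dir / paths.mrna_matrix)
    io.write_matrix(protein, out_dir / paths.protein_matrix)
    io.write_annotations(mrna, out_dir / paths.annotations)
    io.write_gene_list(model.genes, out_dir / paths.coding_genes)
    io.write_gmt(
        make_synthetic_genesets(list(model.genes), sim.universal_targets, seed=config.seed),
        out_dir / paths.gene_sets,
    )
    (out_dir / "truth_celllines.json").write_text(truth.to_json() + "\n", encoding="utf-8")

    cm = sim.cohort
    cohort_model = cohort_association_model(
        n_genes=cm.n_genes,
        solo_per_oncogene=cm.solo_per_oncogene,
        shared_per_pair=cm.shared_per_pair,
        effect_size=cm.association_effect,
        seed=config.seed,
    )
    cohort, cohort_truth = simulate_cohort(
        n_patients=cm.n_patients,
        model=cohort_model,
        mutation_freqs={
            "MYC": cm.myc_high_freq,
            "KRAS_mut": cm.kras_mut_freq,
            "TP53_mut": cm.tp53_missense_freq,
        },
        seed=config.seed,
        signature_genes=sim.universal_targets,
        signature_effect=cm.signature_effect,
        noise_sigma=cm.noise_sigma,
        hazard_factor=cm.hazard_factor,
    )
    io.write_cohort(cohort, out_dir)
    (out_dir / "truth_cohort.json").write_text(cohort_truth.to_json() + "\n", encoding="utf-8")

    outputs = [
        out_dir / paths.mrna_matrix,
        out_dir / paths.protein_matrix,
        out_dir / paths.annotations,
        out_dir / paths.coding_genes,
        out_dir / paths.gene_sets,
        out_dir / "truth_celllines.json",
        out_dir / paths.cohort_expression,
        out_dir / paths.cohort_mutations,
        out_dir / paths.cohort_survival,
        out_dir / "truth_cohort.json",
    ]
    _write_manifest(out_dir, "simulate", config, [], outputs)


def stage_diffexp(config: PipelineConfig, out_dir: Path) -> None:
    """Differential analysis for every line/knockdown/layer."""
    out_dir = Path(out_dir)
    paths = config.paths
    mrna = io.read_matrix(out_dir / paths.mrna_matrix, out_dir / paths.annotations, "mRNA")
    protein = io.read_matrix(out_dir / paths.protein_matrix, out_dir / paths.annotations, "protein")
    tables = diffexpr.run_all_differential(
        [mrna, protein],
        mrna_q_threshold=config.thresholds.mrna_fdr,
        protein_p_threshold=config.thresholds.protein_p,
    )
    deg_dir = out_dir / "deg"
    deg_dir.mkdir(exist_ok=True)
    outputs = []
    for table in tables:
        path = deg_dir / io.deg_table_filename(table)
        io.write_deg_table(table, path)
        outputs.append(path)
    inputs = [out_dir / paths.mrna_matrix, out_dir / paths.protein_matrix, out_dir / paths.annotations]
    _write_manifest(out_dir, "diffexp", config, inputs, outputs)


def stage_signature(config: PipelineConfig, out_dir: Path) -> None:
    """Signatures, enrichment, pathway overlap, recurrence, target pick."""
    out_dir = Path(out_dir)
    tables = io.read_deg_dir(out_dir / "deg")
    gene_sets = io.read_gmt(out_dir / config.paths.gene_sets)
    background = set(tables[0].records.index)

    enriched_names: dict[str, list[str]] = {}
    enrich_rows = []
    for onc in ONCOGENES:
        sig = signature.fuse_signature([t for t in tables if t.oncogene == onc])
        results = signature.enrich(
            sig, gene_sets, background, p_threshold=config.thresholds.enrichment_p
        )
        enriched_names[onc] = [r.set_name for r in results if r.enriched]
        for r in results:
            enrich_rows.append(
                {
                    "oncogene": onc,
                    "set_name": r.set_name,
                    "overlap": r.overlap_count,
                    "set_size": r.set_size,
                    "p": r.p,
                    "enriched": r.enriched,
                    "signature_size": len(sig),
                }
            )
    pd.DataFrame(enrich_rows).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    regions = signature.overlap_pathways(enriched_names)
    common = regions[tuple(ONCOGENES)]
    io.write_json(
        {"+".join(k): sorted(v) for k, v in regions.items()}, out_dir / "pathway_overlap.json"
    )
    common_genes = set().union(*(gene_sets[name] for name in common)) & background if common else set()
    if not common_genes:
        # fall back to the full background so recurrence is still reportable
        common_genes = background
    scores = signature.score_recurrence(common_genes, tables)
    scores.to_csv(out_dir / "recurrence_scores.tsv", sep="\t")
    targets = signature.select_targets(scores, config.select_k)
    io.write_gene_list(targets, out_dir / "selected_targets.txt")
    lfc = signature.mean_group_lfc(tables, targets)
    lfc.to_csv(out_dir / "target_mean_lfc.tsv", sep="\t", index=False, float_format="%.6g")

    inputs = sorted((out_dir / "deg").glob("deg_*.tsv")) + [out_dir / config.paths.gene_sets]
    outputs = [
        out_dir / "enrichment.tsv",
        out_dir / "pathway_overlap.json",
        out_dir / "recurrence_scores.tsv",
        out_dir / "selected_targets.txt",
        out_dir / "target_mean_lfc.tsv",
    ]
    _write_manifest(out_dir, "signature", config, inputs, outputs)


def stage_redundancy(config: PipelineConfig, out_dir: Path) -> None:
    """Gene-pool construction, redundancy classification, ribbon export."""
    out_dir = Path(out_dir)
    tables = io.read_deg_dir(out_dir / "deg")
    ann = pd.read_csv(out_dir / config.paths.annotations, sep="\t", index_col=0)
    ann["active_oncogenes"] = ann["active_oncogenes"].fillna("")
    genotypes = io.genotypes_from_annotations(ann)
    coding = io.read_gene_list(out_dir / config.paths.coding_genes)
    pools = redundancy.build_pools(tables, genotypes, coding)
    classifications = redundancy.classify_all(pools)

    per_gene = []
    summary = {}
    outputs = []
    for onc, cls in classifications.items():
        for gene, label in cls.classes.items():
            per_gene.append({"oncogene": onc, "gene": gene, "class": label})
        summary[onc] = {
            "n_classified": cls.n_classified,
            "n_dropped": cls.n_dropped,
            "percentages": cls.percentages,
            "percentages_incl_dropped": cls.percentages_incl_dropped,
        }
        ribbon = redundancy.ribbon_export(cls)
        path = out_dir / f"ribbon_{onc}.tsv"
        ribbon.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    pd.DataFrame(per_gene, columns=["oncogene", "gene", "class"]).to_csv(
        out_dir / "redundancy_classes.tsv", sep="\t", index=False
    )
    io.write_json(summary, out_dir / "redundancy_summary.json")
    outputs += [out_dir / "redundancy_classes.tsv", out_dir / "redundancy_summary.json"]
    inputs = sorted((out_dir / "deg").glob("deg_*.tsv")) + [
        out_dir / config.paths.annotations,
        out_dir / config.paths.coding_genes,
    ]
    _write_manifest(out_dir, "redundancy", config, inputs, outputs)


def stage_cohort(config: PipelineConfig, out_dir: Path) -> None:
    """Stratification, signature comparison, associations, survival."""
    out_dir = Path(out_dir)
    paths = config.paths
    cohort = io.read_cohort(
        out_dir / paths.cohort_expression,
        out_dir / paths.cohort_mutations,
        out_dir / paths.cohort_survival,
    )
    targets_path = out_dir / "selected_targets.txt"
    if targets_path.exists():
        genes = sorted(io.read_gene_list(targets_path))
    else:
        genes = [g for g in config.simulate.universal_targets]
    genes = [g for g in genes if g in cohort.expression.columns]
    if not genes:
        raise ValueError("no signature genes available in the cohort expression matrix")

    strata = cohort_mod.stratify(cohort)
    scores = cohort_mod.signature_score(cohort, genes)
    comparison = cohort_mod.compare_signature_groups(scores, strata)
    comparison.to_csv(out_dir / "signature_groups.tsv", sep="\t", index=False, float_format="%.6g")
    long = pd.DataFrame({"patient_id": scores.index, "score": scores.values, "stratum": strata.values})
    long.to_csv(out_dir / "signature_scores.tsv", sep="\t", index=False, float_format="%.6g")

    lists = {}
    outputs = [out_dir / "signature_groups.tsv", out_dir / "signature_scores.tsv"]
    for onc, stratum in cohort_mod.STRATUM_OF_ONCOGENE.items():
        assoc = cohort_mod.associate_transcriptome(
            cohort,
            stratum,
            strata=strata,
            comparator=config.cohort_comparator,
            fdr_threshold=config.thresholds.association_fdr,
        )
        lists[onc] = assoc
        path = out_dir / f"association_{stratum}.tsv"
        rec = assoc.records.copy()
        rec.index.name = "gene"
        rec.to_csv(path, sep="\t", float_format="%.6g")
        outputs.append(path)
    likely = cohort_mod.likely_redundant(lists)
    likely.to_csv(out_dir / "likely_redundant.tsv", sep="\t", float_format="%.6g")
    outputs.append(out_dir / "likely_redundant.tsv")

    summary = {
        "signature_genes": genes,
        "strata_sizes": strata.value_counts().to_dict(),
        "group_vs_control": comparison.to_dict(orient="records"),
        "likely_redundant_pct": likely["likely_pct"].to_dict(),
    }
    if cohort.survival is not None:
        high = (scores > scores.median()).map({True: "high", False: "low"})
        surv = cohort_mod.km_logrank(cohort.survival["time"], cohort.survival["event"], high)
        summary["survival"] = {
            "logrank_statistic": surv.statistic,
            "p": surv.p,
            "hazard_ratio_high_vs_low": surv.hazard_ratio,
        }
    io.write_json(summary, out_dir / "cohort_summary.json")
    outputs.append(out_dir / "cohort_summary.json")
    inputs = [
        out_dir / paths.cohort_expression,
        out_dir / paths.cohort_mutations,
        out_dir / paths.cohort_survival,
        targets_path,
    ]
    _write_manifest(out_dir, "cohort", config, inputs, outputs)


def stage_report(config: PipelineConfig, out_dir: Path) -> dict:
    """Aggregate stage summaries into one JSON + human-readable text."""
    out_dir = Path(out_dir)
    report: dict = {"seed": config.seed}
    red_path = out_dir / "redundancy_summary.json"
    if red_path.exists():
        report["redundancy"] = io.read_json(red_path)
    cohort_path = out_dir / "cohort_summary.json"
    if cohort_path.exists():
        report["cohort"] = io.read_json(cohort_path)
    targets_path = out_dir / "selected_targets.txt"
    if targets_path.exists():
        report["selected_targets"] = sorted(io.read_gene_list(targets_path))
    io.write_json(report, out_dir / "report.json")

    lines = [f"oncotriad run report (seed {config.seed})", ""]
    if "selected_targets" in report:
        lines.append("Selected common-target genes: " + ", ".join(report["selected_targets"]))
    if "redundancy" in report:
        lines.append("Redundancy class percentages (context-dropped excluded):")
        for onc, entry in report["redundancy"].items():
            pct = entry["percentages"]
            lines.append(
                f"  {onc}: non-redundant {pct['non_redundant']:.1f}%, "
                f"possible {pct['redundancy_possible']:.1f}%, "
                f"redundant {pct['redundant']:.1f}% "
                f"(n={entry['n_classified']}, dropped {entry['n_dropped']})"
            )
    if "cohort" in report:
        lines.append("Cohort likely-redundant percentages:")
        for onc, pct in report["cohort"]["likely_redundant_pct"].items():
            lines.append(f"  {onc}: {pct:.1f}%")
        if "survival" in report["cohort"]:
            s = report["cohort"]["survival"]
            lines.append(
                f"Survival (high vs low signature): log-rank X2={s['logrank_statistic']:.2f}, "
                f"p={s['p']:.3g}, HR={s['hazard_ratio_high_vs_low']:.2f}"
            )
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    _write_manifest(
        out_dir,
        "report",
        config,
        [red_path, cohort_path, targets_path],
        [out_dir / "report.json", out_dir / "report.txt"],
    )
    return report


STAGES = {
    "simulate": stage_simulate,
    "diffexp": stage_diffexp,
    "signature": stage_signature,
    "redundancy": stage_redundancy,
    "cohort": stage_cohort,
    "report": stage_report,
}


def run_all(config: PipelineConfig, out_dir: Path) -> dict:
    """Run every stage in order; returns the final report dictionary."""
    for name in ("simulate", "diffexp", "signature", "redundancy", "cohort"):
        STAGES[name](config, out_dir)
    return stage_report(config, out_dir)
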