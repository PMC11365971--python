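"""Gene-pool redundancy classification between single- and triple-oncogene contexts.

For each oncogene X the classifier compares the pool of genes dependent
on X in cell lines where X is the only activated driver (the
single-context pool) against the pools measured in triple-oncogene lines:

* still dependent on X only            -> non_redundant
* dependent on X and on the others     -> redundancy_possible
* dependent only on the co-expressed
  oncogenes (control taken over)       -> redundant
* dependent on nothing in the triple
  context                              -> context_dropped

Percentages are reported over the first three classes (context-dropped
genes excluded from the denominator, and also reported with the
alternative all-inclusive denominator).  Membership ignores the sign of
regulation by default; a strict sign-concordant mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DEGTable, ONCOGENES, check_oncogene
from .synthetic_data import GenotypeConfig

CLASS_ORDER = ("non_redundant", "redundancy_possible", "redundant")


@dataclass
class GenePool:
    """Significant (FDR < 0.05, coding) genes for one oncogene/context."""

    oncogene: str
    context: str  # "single" | "triple"
    genes: set[str]
    source_cell_lines: tuple[str, ...] = ()
    #: optional gene -> sign of regulation (-1/+1), for the strict mode
    signs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_oncogene(self.oncogene)
        if self.context not in ("single", "triple"):
            raise ValueError("context must be 'single' or 'triple'")
        self.genes = {g.upper() for g in self.genes}
        self.signs = {g.upper(): int(s) for g, s in self.signs.items()}


@dataclass
class RedundancyClassification:
    oncogene: str
    classes: pd.Series  # gene -> class label (incl. context_dropped)
    n_classified: int
    n_dropped: int
    percentages: dict[str, float]  # over classified genes, sums to 100
    percentages_incl_dropped: dict[str, float] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        vc = self.classes.value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASS_ORDER + ("context_dropped",)}


def build_pools(
    tables: list[DEGTable],
    genotypes: list[GenotypeConfig],
    coding_filter: set[str] | None = None,
    tissue: str | None = None,
    combine: str = "union",
) -> dict[tuple[str, str], GenePool]:
    """Single- and triple-context pools per oncogene from mRNA DEG tables.

    The single-context pool for X unions (or intersects) the significant
    genes over cell lines whose genotype activates only X; the
    triple-context pool for X unions over triple-genotype lines'
    X-knockdown results.  Pools are intersected with the coding filter.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    genotype_by_line = {g.cell_line_id: g for g in genotypes}
    if tissue is not None:
        genotype_by_line = {
            k: v for k, v in genotype_by_line.items() if v.tissue == tissue
        }
    coding = {g.upper() for g in coding_filter} if coding_filter is not None else None

    pools: dict[tuple[str, str], GenePool] = {}
    for oncogene in ONCOGENES:
        for context in ("single", "triple"):
            if context == "single":
                lines = [
                    cid
                    for cid, g in genotype_by_line.items()
                    if g.active_oncogenes == frozenset({oncogene})
                ]
            else:
                lines = [
                    cid
                    for cid, g in genotype_by_line.items()
                    if g.active_oncogenes == frozenset(ONCOGENES)
                ]
            relevant = [
                t
                for t in tables
                if t.layer == "mRNA" and t.oncogene == oncogene and t.cell_line in lines
            ]
            if not relevant:
                where = f" in tissue {tissue!r}" if tissue else ""
                raise ValueError(
                    f"missing genotype coverage: no mRNA results for the "
                    f"{context}-context {oncogene} knockdown{where} "
                    f"(need a cell line with active_oncogenes="
                    f"{'{' + oncogene + '}' if context == 'single' else set(ONCOGENES)})"
                )
            gene_sets = [t.significant_features for t in relevant]
            genes = set.union(*gene_sets) if combine == "union" else set.intersection(*gene_sets)
            if coding is not None:
                genes &= coding
            signs: dict[str, int] = {}
            for t in relevant:  # last-writer ties are irrelevant: signs agree or gene is ambiguous
                sig = t.records.loc[t.records["significant"]]
                for gene, lfc in sig["lfc"].items():
                    if gene in genes:
                        signs[gene] = 1 if lfc >= 0 else -1
            pools[(oncogene, context)] = GenePool(
                oncogene, context, genes, tuple(sorted(t.cell_line for t in relevant)), signs
            )
    return pools


def classify_redundancy(
    single: GenePool,
    triple_same: GenePool | set[str],
    triple_others: GenePool | set[str],
    require_sign_concordance: bool = False,
) -> RedundancyClassification:
    """Classify every gene of the single-context pool.

    ``triple_others`` is the union pool of the other two oncogenes'
    triple-context results (a plain set is accepted).  With
    ``require_sign_concordance`` a gene only counts as retained in the
    triple context if its regulation sign matches the single context
    (needs pools built with sign information).
    """
    if single.context != "single":
        raise ValueError("first pool must be the single-context pool")
    if isinstance(triple_others, GenePool):
        others = triple_others.genes
    else:
        others = {g.upper() for g in triple_others}
    if isinstance(triple_same, GenePool):
        if triple_same.oncogene != single.oncogene:
            raise ValueError("single and triple pools must share the oncogene")
        same = triple_same.genes
    else:
        same = {g.upper() for g in triple_same}
    if require_sign_concordance:
        if not single.signs or not isinstance(triple_same, GenePool) or not triple_same.signs:
            raise ValueError("sign concordance requires pools built with sign information")
        same = {
            g
            for g in same
            if g not in single.signs
            or g not in triple_same.signs
            or single.signs[g] == triple_same.signs[g]
        }

    labels = {}
    for gene in sorted(single.genes):
        in_same = gene in same
        in_others = gene in others
        if in_same and not in_others:
            labels[gene] = "non_redundant"
        elif in_same and in_others:
            labels[gene] = "redundancy_possible"
        elif in_others:
            labels[gene] = "redundant"
        else:
            labels[gene] = "context_dropped"
    classes = pd.Series(labels, dtype=object, name="class")
    n_dropped = int((classes == "context_dropped").sum())
    n_classified = len(classes) - n_dropped
    pct = {
        c: (100.0 * (classes == c).sum() / n_classified) if n_classified else float("nan")
        for c in CLASS_ORDER
    }
    total = len(classes)
    pct_all = {
        c: (100.0 * (classes == c).sum() / total) if total else float("nan")
        for c in CLASS_ORDER + ("context_dropped",)
    }
    return RedundancyClassification(
        oncogene=single.oncogene,
        classes=classes,
        n_classified=n_classified,
        n_dropped=n_dropped,
        percentages=pct,
        percentages_incl_dropped=pct_all,
    )


def classify_all(pools: dict[tuple[str, str], GenePool]) -> dict[str, RedundancyClassification]:
    """Run the classifier for each oncogene from a pool dictionary."""
    out = {}
    for oncogene in ONCOGENES:
        others = set().union(
            *(pools[(o, "triple")].genes for o in ONCOGENES if o != oncogene)
        )
        out[oncogene] = classify_redundancy(
            pools[(oncogene, "single")], pools[(oncogene, "triple")], others
        )
    return out


def summarize_across(
    classifications: list[RedundancyClassification],
) -> dict[str, float]:
    """Unweighted mean of class percentages across tissue/cell-line groups."""
    if not classifications:
        raise ValueError("no classifications supplied")
    oncogenes = {c.oncogene for c in classifications}
    if len(oncogenes) != 1:
        raise ValueError(f"mixed oncogenes: {sorted(oncogenes)}")
    return {
        c: float(np.mean([cl.percentages[c] for cl in classifications]))
        for c in CLASS_ORDER
    }


def ribbon_export(classification: RedundancyClassification) -> pd.DataFrame:
    """Sankey/ribbon flow table conserving the single-pool size."""
    counts = classification.counts()
    onc = classification.oncogene
    rows = [
        {
            "left": f"single_{onc}",
            "right": f"retained_by_{onc}",
            "n_genes": counts["non_redundant"] + counts["redundancy_possible"],
        },
        {"left": f"single_{onc}", "right": "taken_over", "n_genes": counts["redundant"]},
        {"left": f"single_{onc}", "right": "dropped", "n_genes": counts["context_dropped"]},
    ]
    flows = pd.DataFrame(rows, columns=["left", "right", "n_genes"])
    if len(classification.classes) == 0:
        return flows.iloc[0:0]
    return flows
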