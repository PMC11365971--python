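"""Per-oncogene signatures, gene-set enrichment and recurrent-target scoring.

One oncogene's signature is the duplicate-filtered union of its
significant features across every cell line and both omics layers.  The
three signatures are tested for gene-set enrichment (hypergeometric
upper tail against a declared background universe), the enriched pathway
names are overlapped into a three-way Venn partition, and genes from the
common pathways are ranked by how often they recur as significant calls
across the whole experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

from .containers import DEGTable, ONCOGENES, check_oncogene

ENRICH_P_THRESHOLD = 0.05


@dataclass
class OncogeneSignature:
    """Duplicate-free union of one oncogene's significant features."""

    oncogene: str
    features: set[str]
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_oncogene(self.oncogene)

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    p: float
    enriched: bool


def fuse_signature(tables: list[DEGTable], oncogene: str | None = None) -> OncogeneSignature:
    """Union of significant features over all tables for one oncogene."""
    if not tables:
        raise ValueError("no DEG tables supplied")
    oncogenes = {t.oncogene for t in tables}
    if len(oncogenes) != 1:
        raise ValueError(f"mixed oncogene keys in tables: {sorted(oncogenes)}")
    (found,) = oncogenes
    if oncogene is not None and oncogene != found:
        raise ValueError(f"tables are for {found}, not {oncogene}")
    provenance: dict[str, list[tuple[str, str]]] = {}
    for table in tables:
        for gene in sorted(table.significant_features):
            provenance.setdefault(gene, []).append((table.cell_line, table.layer))
    signature = OncogeneSignature(found, set(provenance), provenance)
    if not signature.features:
        warnings.warn(f"empty signature for {found}: no significant features", stacklevel=2)
    return signature


def enrich(
    signature: OncogeneSignature | set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
    p_threshold: float = ENRICH_P_THRESHOLD,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of a signature in named sets.

    For each set: population ``|background|``, successes
    ``|set & background|``, draws ``|signature|``; p = P(X >= overlap).
    ``adjust=True`` applies BH across the sets and thresholds the q.
    """
    if not background:
        raise ValueError("background universe is empty")
    features = signature.features if isinstance(signature, OncogeneSignature) else set(signature)
    features = {g.upper() for g in features}
    background = {g.upper() for g in background}
    extra = features - background
    if extra:
        raise ValueError(f"signature not contained in background: {sorted(extra)[:5]}")
    results = []
    m = len(background)
    n_draws = len(features)
    for name in sorted(gene_sets):
        members = {g.upper() for g in gene_sets[name]} & background
        overlap = len(members & features)
        p = float(hypergeom.sf(overlap - 1, m, len(members), n_draws))
        p = min(p, 1.0)
        results.append(EnrichmentResult(name, overlap, len(members), p, False))
    if adjust:
        from .diffexpr import bh_adjust

        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.enriched = bool(q < p_threshold)
    else:
        for r in results:
            r.enriched = bool(r.p < p_threshold)
    return results


def overlap_pathways(enriched_names: dict[str, list[str] | set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Three-way Venn partition of per-oncogene enriched pathway names.

    Returns the 7 disjoint regions keyed by the sorted tuple of oncogenes
    whose lists (exactly) contain the member; the ``tuple(ONCOGENES)``
    key is the common region.
    """
    missing = set(ONCOGENES) - set(enriched_names)
    if missing:
        raise ValueError(f"need one list per oncogene; missing {sorted(missing)}")
    sets = {o: set(enriched_names[o]) for o in ONCOGENES}
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, 4):
        for combo in combinations(ONCOGENES, r):
            inside = set.intersection(*(sets[o] for o in combo))
            outside = set().union(*(sets[o] for o in ONCOGENES if o not in combo)) if r < 3 else set()
            regions[combo] = inside - outside
    return regions


def common_pathways(enriched_names: dict[str, list[str] | set[str]]) -> set[str]:
    return overlap_pathways(enriched_names)[tuple(ONCOGENES)]


def score_recurrence(genes: set[str], tables: list[DEGTable]) -> pd.DataFrame:
    """Count significant occurrences of each gene over all results.

    Returns a DataFrame (index = gene) with ``mrna_count``,
    ``protein_count`` and ``total``, ranked by total descending with
    deterministic ties (mrna_count descending, then gene id).
    """
    if not genes:
        raise ValueError("gene set is empty")
    genes = sorted({g.upper() for g in genes})
    rows = []
    for gene in genes:
        mrna = sum(
            1 for t in tables if t.layer == "mRNA" and gene in t.significant_features
        )
        prot = sum(
            1 for t in tables if t.layer == "protein" and gene in t.significant_features
        )
        rows.append({"gene": gene, "mrna_count": mrna, "protein_count": prot, "total": mrna + prot})
    scores = pd.DataFrame(rows).sort_values(
        by=["total", "mrna_count", "gene"], ascending=[False, False, True]
    )
    return scores.set_index("gene")


def select_targets(scores: pd.DataFrame, k: int) -> list[str]:
    """Top-k recurrence-ranked genes (prefix of the full ranking)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        warnings.warn(
            f"k={k} exceeds the {len(scores)} scored genes; truncating", stacklevel=2
        )
        k = len(scores)
    return list(scores.index[:k])


def mean_group_lfc(
    tables: list[DEGTable], genes: list[str]
) -> pd.DataFrame:
    """Average LFC per (gene, oncogene, layer) across contributing lines.

    Missing (gene, table) entries are skipped; genes found in no table are
    reported with NaN mean and n_lines = 0.
    """
    genes = [g.upper() for g in genes]
    rows = []
    for oncogene in ONCOGENES:
        for layer in ("mRNA", "protein"):
            group = [t for t in tables if t.oncogene == oncogene and t.layer == layer]
            for gene in genes:
                lfcs = [
                    float(t.records.at[gene, "lfc"]) for t in group if gene in t.records.index
                ]
                rows.append(
                    {
                        "gene": gene,
                        "oncogene": oncogene,
                        "layer": layer,
                        "mean_lfc": sum(lfcs) / len(lfcs) if lfcs else float("nan"),
                        "n_lines": len(lfcs),
                    }
                )
    return pd.DataFrame(rows)
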