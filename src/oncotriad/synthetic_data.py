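"""Synthetic perturbation experiments and patient cohorts with planted truth.

The generator emulates a CRISPR knockdown panel across cancer cell lines
carrying one or all three of the driver oncogenes (c-Myc, mutant KRAS,
mutant p53), plus TCGA-style patient cohorts.  Every target gene follows a
declared regulatory mode:

``redundant``
    Each regulating oncogene can drive the gene on its own; when several
    are co-active only the dominant one (per the gene's dominance order)
    actually does, so its loss is the only knockdown that moves the gene.
``cooperative``
    Every active regulator contributes additively; removing any one of
    them removes its contribution.
``competitive``
    The dominant active regulator drives the gene while co-active
    sub-dominant regulators suppress it; knocking down a sub-dominant
    regulator therefore *raises* expression by a stated fraction of the
    effect size.
``null``
    No oncogene control.

The planted redundancy class of every gene (the quantity the downstream
classifier must recover) is a deterministic function of the regulatory
model and the genotype panel, and is serialized alongside each dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    ONCOGENES,
    ExpressionMatrix,
    check_oncogene,
    format_oncogene_set,
    parse_oncogene_set,
)

MODES = ("cooperative", "redundant", "competitive", "null")
CLASSES = ("non_redundant", "redundancy_possible", "redundant", "null")

#: default negative-binomial dispersion (variance = mu + mu^2 * phi)
DEFAULT_DISPERSION = 0.1
#: default log2-scale sigma of protein intensities
DEFAULT_PROTEIN_SIGMA = 0.3
#: default natural-log sigma of per-sample library-size factors
DEFAULT_LIBSIZE_SIGMA = 0.15
#: default opposite-direction fraction for competitive knockdowns
DEFAULT_COMPETITIVE_FRACTION = 0.5


@dataclass(frozen=True)
class GenotypeConfig:
    """One cell line: identifier, tissue and the set of active oncogenes."""

    cell_line_id: str
    tissue: str
    active_oncogenes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "active_oncogenes", parse_oncogene_set(self.active_oncogenes)
        )

    @property
    def is_normal(self) -> bool:
        return len(self.active_oncogenes) == 0


def triple_line(cell_line_id: str = "TRIPLE1", tissue: str = "colon") -> GenotypeConfig:
    return GenotypeConfig(cell_line_id, tissue, frozenset(ONCOGENES))


def single_line(oncogene: str, cell_line_id: str | None = None, tissue: str = "colon") -> GenotypeConfig:
    check_oncogene(oncogene)
    return GenotypeConfig(cell_line_id or f"SINGLE_{oncogene}", tissue, frozenset({oncogene}))


def standard_panel(tissue: str = "colon") -> list[GenotypeConfig]:
    """Three single-oncogene lines plus one triple-oncogene line."""
    return [single_line(o, tissue=tissue) for o in ONCOGENES] + [triple_line(tissue=tissue)]


class RegulatoryModel:
    """Per-gene oncogene control model.

    Backed by a DataFrame (index = gene id) with columns ``mode``,
    ``dominance`` (">"-joined permutation of the three oncogenes),
    ``regulators`` (";"-joined subset), ``effect_size`` (log2 units),
    ``baseline_mean`` (counts / intensity units) and ``dispersion``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        competitive_fraction: float = DEFAULT_COMPETITIVE_FRACTION,
        cooperative_share: float | str = 1.0,
    ) -> None:
        required = {"mode", "dominance", "regulators", "effect_size", "baseline_mean", "dispersion"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"model table missing columns: {sorted(missing)}")
        table = table.copy()
        table.index = table.index.astype(str).str.upper()
        if table.index.duplicated().any():
            raise ValueError("duplicate gene ids in regulatory model")
        bad_mode = set(table["mode"]) - set(MODES)
        if bad_mode:
            raise ValueError(f"unknown modes: {sorted(bad_mode)}")
        for dom in table["dominance"].unique():
            order = tuple(dom.split(">"))
            if sorted(order) != sorted(ONCOGENES):
                raise ValueError(f"dominance {dom!r} is not a permutation of {ONCOGENES}")
        null_rows = table["mode"] == "null"
        if (table.loc[null_rows, "effect_size"] != 0).any():
            raise ValueError("effect_size must be 0 for null-mode genes")
        if (table.loc[~null_rows, "effect_size"] == 0).any():
            raise ValueError("effect_size must be non-zero for non-null genes")
        self.table = table
        self.competitive_fraction = float(competitive_fraction)
        self.cooperative_share = cooperative_share

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def regulators_of(self, gene: str) -> frozenset[str]:
        return parse_oncogene_set(self.table.at[gene, "regulators"])

    def dominance_of(self, gene: str) -> tuple[str, ...]:
        return tuple(self.table.at[gene, "dominance"].split(">"))

    # --- planted control logic -------------------------------------------

    def contribution(self, gene: str, oncogene: str, active: frozenset[str]) -> float:
        """Log2 contribution of `oncogene` to `gene` in a genotype `active`.

        Zero unless the oncogene is both active and a regulator of the
        gene.  The genotype's expected log2 abundance is baseline plus the
        sum of contributions; a (complete) knockdown removes exactly the
        knocked-down oncogene's contribution.
        """
        check_oncogene(oncogene)
        row = self.table.loc[gene]
        regs = parse_oncogene_set(row["regulators"])
        eligible = active & regs
        if oncogene not in eligible or row["mode"] == "null":
            return 0.0
        effect = float(row["effect_size"])
        mode = row["mode"]
        if mode == "cooperative":
            if self.cooperative_share == "split":
                return effect / len(eligible)
            return effect * float(self.cooperative_share)
        dominance = tuple(row["dominance"].split(">"))
        dominant = next(o for o in dominance if o in eligible)
        if mode == "redundant":
            return effect if oncogene == dominant else 0.0
        # competitive
        if oncogene == dominant:
            return effect
        return -self.competitive_fraction * effect

    def genotype_shift(self, gene: str, active: frozenset[str]) -> float:
        return sum(self.contribution(gene, o, active) for o in active)

    def expected_knockdown_lfc(
        self, gene: str, oncogene: str, active: frozenset[str], efficiency: float = 1.0
    ) -> float:
        """Expected log2 fold change, knockdown vs control, for one gene."""
        return -efficiency * self.contribution(gene, oncogene, active)


@dataclass
class SimulationTruth:
    """Ground truth serialized alongside every simulated dataset.

    ``planted_classes``: (gene, oncogene) -> redundancy class, derived for
    the canonical single-vs-triple contexts.  ``expected_lfc``: one row
    per (gene, cell_line, oncogene) with the planted knockdown log2 fold
    change.  ``signature_genes`` / ``associated_genes`` are populated by
    the builders that plant them.
    """

    planted_classes: pd.DataFrame
    expected_lfc: pd.DataFrame | None = None
    signature_genes: list[str] = field(default_factory=list)
    associated_genes: dict[str, list[str]] = field(default_factory=dict)
    likely_fractions: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_classes": {
                oncogene: dict(group["planted_class"])
                for oncogene, group in self.planted_classes.groupby("oncogene")
            },
            "signature_genes": self.signature_genes,
            "associated_genes": self.associated_genes,
            "likely_fractions": self.likely_fractions,
        }
        if self.expected_lfc is not None:
            payload["expected_lfc"] = self.expected_lfc.to_dict(orient="records")
        return json.dumps(payload, indent=1, sort_keys=True)


def derive_planted_classes(model: RegulatoryModel, efficiency: float = 1.0) -> pd.DataFrame:
    """Planted redundancy class per (gene, oncogene).

    Uses the canonical contexts: a single-oncogene genotype {X} and the
    triple genotype.  A gene enters X's single-context pool iff X shifts
    it there; the class then follows the triple-context memberships:
    in triple_X only -> non_redundant, in both -> redundancy_possible,
    only in the others' pools -> redundant.  Genes outside the single
    pool are class ``null``.
    """
    all3 = frozenset(ONCOGENES)
    rows = []
    for gene in model.genes:
        for onc in ONCOGENES:
            if model.expected_knockdown_lfc(gene, onc, frozenset({onc}), efficiency) == 0.0:
                cls = "null"
            else:
                in_triple_self = (
                    model.expected_knockdown_lfc(gene, onc, all3, efficiency) != 0.0
                )
                in_triple_others = any(
                    model.expected_knockdown_lfc(gene, other, all3, efficiency) != 0.0
                    for other in ONCOGENES
                    if other != onc
                )
                if in_triple_self and not in_triple_others:
                    cls = "non_redundant"
                elif in_triple_self and in_triple_others:
                    cls = "redundancy_possible"
                elif in_triple_others:
                    cls = "redundant"
                else:
                    cls = "null"  # unreachable with complete knockdown
            rows.append({"gene": gene, "oncogene": onc, "planted_class": cls})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model builders
# --------------------------------------------------------------------------

_DOM_DEFAULT = ">".join(ONCOGENES)


def _base_table(genes: list[str], baseline_means: np.ndarray, dispersion: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mode": "null",
            "dominance": _DOM_DEFAULT,
            "regulators": format_oncogene_set(frozenset(ONCOGENES)),
            "effect_size": 0.0,
            "baseline_mean": baseline_means,
            "dispersion": dispersion,
        },
        index=pd.Index(genes, name="gene"),
    )


def _gene_names(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _draw_baselines(n: int, rng: np.random.Generator, low: float = 50.0, high: float = 5000.0) -> np.ndarray:
    return np.exp(rng.uniform(np.log(low), np.log(high), size=n)).round(1)


def null_model(
    n_genes: int, dispersion: float = DEFAULT_DISPERSION, seed: int = 0
) -> RegulatoryModel:
    """All genes unregulated: the null-calibration condition."""
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)
    return RegulatoryModel(_base_table(_gene_names(n_genes), _draw_baselines(n_genes, rng), dispersion))


def plant_class_fractions(
    n_genes: int,
    pool_size: int = 400,
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    effect_size: float = 2.0,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
) -> RegulatoryModel:
    """Model whose planted per-oncogene class fractions equal `fractions`.

    Each oncogene's single-context pool has ``pool_size`` genes split
    into non_redundant / redundancy_possible / redundant per `fractions`.
    Construction (per oncogene X, with Y the next oncogene cyclically):

    * solo non-redundant genes: mode=redundant, regulators={X};
    * shared genes: mode=cooperative, regulators={X, Y} — class
      redundancy_possible for both X and Y;
    * taken-over genes: mode=redundant, regulators={X, Y} with Y
      dominant — class redundant for X and non_redundant for Y.

    Each taken-over gene planted *for* X also adds one non-redundant gene
    to Y's pool, so the solo allocation is reduced accordingly.
    """
    f_nr, f_po, f_re = fractions
    if not np.isclose(f_nr + f_po + f_re, 1.0):
        raise ValueError("class fractions must sum to 1")
    if f_nr < f_re:
        raise ValueError(
            "non_redundant fraction must be >= redundant fraction "
            "(each taken-over gene donates a non-redundant gene to its dominator)"
        )
    n_re = int(round(f_re * pool_size))
    n_po_pair = int(round(f_po * pool_size / 2.0))  # each shared gene covers 2 pools
    n_solo = int(round(f_nr * pool_size)) - n_re
    n_planted = 3 * (n_solo + n_re) + 3 * n_po_pair
    if n_planted > n_genes:
        raise ValueError(f"need {n_planted} planted genes but n_genes={n_genes}")

    rng = np.random.default_rng(seed)
    table = _base_table(_gene_names(n_genes), _draw_baselines(n_genes, rng), dispersion)
    order = rng.permutation(len(table))
    cursor = 0

    def take(k: int) -> pd.Index:
        nonlocal cursor
        idx = table.index[order[cursor : cursor + k]]
        cursor += k
        return idx

    pairs = [(ONCOGENES[i], ONCOGENES[(i + 1) % 3]) for i in range(3)]
    for onc in ONCOGENES:
        idx = take(n_solo)
        table.loc[idx, ["mode", "regulators", "effect_size"]] = ["redundant", onc, effect_size]
        table.loc[idx, "dominance"] = ">".join([onc] + [o for o in ONCOGENES if o != onc])
    for x, y in pairs:
        idx = take(n_po_pair)
        table.loc[idx, ["mode", "regulators", "effect_size"]] = [
            "cooperative",
            format_oncogene_set(frozenset({x, y})),
            effect_size,
        ]
    for x, y in pairs:  # genes of X taken over by dominant Y
        idx = take(n_re)
        table.loc[idx, ["mode", "regulators", "effect_size"]] = [
            "redundant",
            format_oncogene_set(frozenset({x, y})),
            effect_size,
        ]
        table.loc[idx, "dominance"] = ">".join([y, x] + [o for o in ONCOGENES if o not in (x, y)])
    return RegulatoryModel(table)


def dominance_weighted_model(
    n_genes: int,
    n_targets: int,
    top_weights: dict[str, float],
    effect_size: float = 2.0,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
) -> RegulatoryModel:
    """Redundant-mode targets with dominance orders drawn by weight.

    ``top_weights`` gives the probability that each oncogene heads a
    target's dominance order (e.g. MYC-heavy weights make the c-Myc
    program the least redundant one).  All targets are regulated by all
    three oncogenes.
    """
    rng = np.random.default_rng(seed)
    table = _base_table(_gene_names(n_genes), _draw_baselines(n_genes, rng), dispersion)
    w = np.array([top_weights.get(o, 0.0) for o in ONCOGENES], dtype=float)
    if w.sum() <= 0:
        raise ValueError("top_weights must contain a positive weight")
    w = w / w.sum()
    targets = table.index[rng.permutation(len(table))[:n_targets]]
    for gene in targets:
        top = ONCOGENES[rng.choice(3, p=w)]
        rest = [o for o in ONCOGENES if o != top]
        rng.shuffle(rest)
        table.loc[gene, ["mode", "effect_size", "dominance"]] = [
            "redundant",
            effect_size,
            ">".join([top] + rest),
        ]
    return RegulatoryModel(table)


def add_universal_targets(
    model: RegulatoryModel,
    target_genes: tuple[str, ...] = ("RUVBL1", "HSPA9", "XPO1"),
    effect_size: float = 3.0,
) -> RegulatoryModel:
    """Append universally controlled target genes (every oncogene drives
    them in every genotype) — planted analogues of a common druggable
    signature.  Appended, so existing gene plantings are untouched."""
    table = model.table.copy()
    baseline = float(np.median(table["baseline_mean"]))
    for gene in target_genes:
        gene = gene.upper()
        if gene in table.index:
            raise ValueError(f"gene {gene} already present in model")
        table.loc[gene] = {
            "mode": "cooperative",
            "dominance": _DOM_DEFAULT,
            "regulators": format_oncogene_set(frozenset(ONCOGENES)),
            "effect_size": effect_size,
            "baseline_mean": baseline,
            "dispersion": float(table["dispersion"].iloc[0]),
        }
    return RegulatoryModel(table, model.competitive_fraction, model.cooperative_share)


# --------------------------------------------------------------------------
# cell-line experiment simulation
# --------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + mu^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = dispersion <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        shape = 1.0 / dispersion[~pois]
        lam = rng.gamma(shape, mean[~pois] / shape)
        out[~pois] = rng.poisson(lam)
    return out


def simulate_cellline_experiment(
    configs: list[GenotypeConfig],
    model: RegulatoryModel,
    n_replicates: int = 3,
    seed: int = 0,
    knockdown_efficiency: float = 1.0,
    libsize_sigma: float = DEFAULT_LIBSIZE_SIGMA,
    protein_sigma: float = DEFAULT_PROTEIN_SIGMA,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimulationTruth]:
    """Simulate the control-vs-knockdown panel for every configured line.

    Each cell line contributes a control condition plus one knockdown per
    active oncogene, with ``n_replicates`` replicates each.  mRNA values
    are negative-binomial counts; protein values are log-normal
    intensities around the same planted means.  Identical seeds give
    bit-identical output.
    """
    if len(model) < 10:
        raise ValueError("n_genes must be >= 10")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (downstream variance undefined)")
    if not 0.0 < knockdown_efficiency <= 1.0:
        raise ValueError("knockdown_efficiency must be in (0, 1]")
    if len({c.cell_line_id for c in configs}) != len(configs):
        raise ValueError("duplicate cell_line_id in configs")

    rng = np.random.default_rng(seed)
    genes = model.genes
    baseline = model.table["baseline_mean"].to_numpy(dtype=float)
    dispersion = model.table["dispersion"].to_numpy(dtype=float)

    # per-(gene, oncogene, genotype) contributions, vectorized per config
    mrna_cols: dict[str, np.ndarray] = {}
    prot_cols: dict[str, np.ndarray] = {}
    annot_rows = []
    lfc_rows = []
    for config in configs:
        active = config.active_oncogenes
        contrib = {
            o: np.array([model.contribution(g, o, active) for g in genes])
            for o in ONCOGENES
        }
        base_shift = sum(contrib.values())
        conditions = [CONTROL] + [o for o in ONCOGENES if o in active]
        for condition in conditions:
            if condition == CONTROL:
                shift = base_shift
            else:
                shift = base_shift - knockdown_efficiency * contrib[condition]
                for g, lfc in zip(genes, -knockdown_efficiency * contrib[condition]):
                    if lfc != 0.0:
                        lfc_rows.append(
                            {
                                "gene": g,
                                "cell_line": config.cell_line_id,
                                "oncogene": condition,
                                "expected_lfc": lfc,
                            }
                        )
            mean = baseline * np.exp2(shift)
            for rep in range(1, n_replicates + 1):
                sample_id = f"{config.cell_line_id}_{condition}_r{rep}"
                lib = float(np.exp(rng.normal(0.0, libsize_sigma)))
                mrna_cols[sample_id] = _nb_draw(rng, mean * lib, dispersion)
                lib_p = float(np.exp(rng.normal(0.0, libsize_sigma)))
                prot_cols[sample_id] = (
                    mean * lib_p * np.exp2(rng.normal(0.0, protein_sigma, size=len(genes)))
                )
                annot_rows.append(
                    {
                        "sample_id": sample_id,
                        "cell_line": config.cell_line_id,
                        "tissue": config.tissue,
                        "active_oncogenes": format_oncogene_set(active),
                        "perturbation": condition,
                        "replicate": rep,
                    }
                )

    samples = pd.DataFrame(annot_rows).set_index("sample_id")
    mrna = ExpressionMatrix(pd.DataFrame(mrna_cols, index=genes), samples, "mRNA")
    protein = ExpressionMatrix(pd.DataFrame(prot_cols, index=genes), samples, "protein")
    truth = SimulationTruth(
        planted_classes=derive_planted_classes(model, knockdown_efficiency),
        expected_lfc=pd.DataFrame(
            lfc_rows, columns=["gene", "cell_line", "oncogene", "expected_lfc"]
        ),
    )
    return mrna, protein, truth


# --------------------------------------------------------------------------
# patient cohorts
# --------------------------------------------------------------------------

@dataclass
class PatientCohort:
    """Patient x gene expression with mutation statuses and survival.

    ``expression`` is on a log2-like normalized scale (platform units).
    ``tp53_status`` in {WT, null, missense}; ``kras_status`` in
    {WT, point_mutant}; ``survival`` has columns (time, event).
    """

    expression: pd.DataFrame
    tp53_status: pd.Series
    kras_status: pd.Series
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.expression = self.expression.copy()
        self.expression.columns = self.expression.columns.astype(str).str.upper()
        for name, series, allowed in (
            ("tp53_status", self.tp53_status, {"WT", "null", "missense"}),
            ("kras_status", self.kras_status, {"WT", "point_mutant"}),
        ):
            if not series.index.equals(self.expression.index):
                raise ValueError(f"{name} must be indexed by the expression patients")
            bad = set(series) - allowed
            if bad:
                raise ValueError(f"invalid {name} values: {sorted(bad)}")
        if self.survival is not None and not {"time", "event"} <= set(self.survival.columns):
            raise ValueError("survival needs 'time' and 'event' columns")

    @property
    def patients(self) -> pd.Index:
        return self.expression.index


def cohort_association_model(
    n_genes: int,
    solo_per_oncogene: int = 30,
    shared_per_pair: int = 15,
    effect_size: float = 2.0,
    seed: int = 0,
) -> RegulatoryModel:
    """Cohort model with planted per-oncogene association lists.

    Per oncogene X: ``solo_per_oncogene`` genes regulated by X alone
    (unlikely-redundant) and, per oncogene pair, ``shared_per_pair``
    redundant-mode genes regulated by both (likely-redundant for each).
    Planted likely fraction per oncogene = 2*shared / (solo + 2*shared).
    """
    rng = np.random.default_rng(seed)
    table = _base_table(_gene_names(n_genes), _draw_baselines(n_genes, rng), 0.0)
    n_needed = 3 * solo_per_oncogene + 3 * shared_per_pair + 3
    if n_needed > n_genes:
        raise ValueError(f"need {n_needed} genes, got {n_genes}")
    order = rng.permutation(len(table))
    cursor = 0

    def take(k: int) -> pd.Index:
        nonlocal cursor
        idx = table.index[order[cursor : cursor + k]]
        cursor += k
        return idx

    for onc in ONCOGENES:
        idx = take(solo_per_oncogene)
        table.loc[idx, ["mode", "regulators", "effect_size"]] = ["redundant", onc, effect_size]
    pairs = [(ONCOGENES[i], ONCOGENES[(i + 1) % 3]) for i in range(3)]
    for x, y in pairs:
        idx = take(shared_per_pair)
        table.loc[idx, ["mode", "regulators", "effect_size"]] = [
            "redundant",
            format_oncogene_set(frozenset({x, y})),
            effect_size,
        ]
    return RegulatoryModel(table)


def simulate_cohort(
    n_patients: int,
    model: RegulatoryModel,
    mutation_freqs: dict[str, float] | None = None,
    seed: int = 0,
    signature_genes: tuple[str, ...] = (),
    signature_effect: float = 1.0,
    noise_sigma: float = 0.5,
    hazard_factor: float = 1.5,
    baseline_hazard: float = 1.0 / 1000.0,
    censor_time: float = 2000.0,
    tp53_null_freq: float = 0.15,
) -> tuple[PatientCohort, SimulationTruth]:
    """Simulate a TCGA-style cohort with oncogene-dependent expression.

    Each patient draws an independent MYC activation state (reflected in
    a bimodal continuous MYC expression), a TP53 status (WT / null /
    missense) and a KRAS point-mutation status.  Planted genes follow the
    regulatory model given the patient's active-oncogene set; designated
    signature genes are elevated by ``signature_effect`` under redundant
    control (any active oncogene suffices, no additivity).  Survival is
    exponential with hazard multiplied by ``hazard_factor`` per unit of
    centered signature score, administratively censored.
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    freqs = {"MYC": 0.5, "KRAS_mut": 0.35, "TP53_mut": 0.35}
    if mutation_freqs:
        for k, v in mutation_freqs.items():
            check_oncogene(k)
            freqs[k] = float(v)
    for onc, f in freqs.items():
        if not 0.0 < f < 1.0:
            raise ValueError(f"degenerate mutation frequency for {onc}: {f}")

    rng = np.random.default_rng(seed)
    patients = pd.Index([f"P{i:04d}" for i in range(1, n_patients + 1)], name="patient_id")

    myc_active = rng.random(n_patients) < freqs["MYC"]
    kras_mut = rng.random(n_patients) < freqs["KRAS_mut"]
    u = rng.random(n_patients)
    tp53 = np.where(
        u < freqs["TP53_mut"], "missense", np.where(u < freqs["TP53_mut"] + tp53_null_freq, "null", "WT")
    )

    active_sets = [
        frozenset(
            (["MYC"] if m else [])
            + (["KRAS_mut"] if k else [])
            + (["TP53_mut"] if t == "missense" else [])
        )
        for m, k, t in zip(myc_active, kras_mut, tp53)
    ]
    if "MYC" in set(model.genes) | set(g.upper() for g in signature_genes):
        raise ValueError("'MYC' is reserved for the cohort MYC-expression column")

    model_table = model.table
    signature_genes = tuple(g.upper() for g in signature_genes)
    genes = list(model.genes) + [g for g in signature_genes if g not in set(model.genes)]
    base_level = pd.Series(rng.normal(6.0, 1.0, size=len(genes)), index=genes)

    # planted shift per (patient active-set, gene); cache by active set
    shift_cache: dict[frozenset[str], np.ndarray] = {}

    extra_signature = [g for g in signature_genes if g not in set(model.genes)]

    def shifts_for(active: frozenset[str]) -> np.ndarray:
        # extra signature genes are redundantly controlled: elevated by
        # signature_effect when any oncogene is active, with no additivity
        if active not in shift_cache:
            s = np.array([model.genotype_shift(g, active) for g in model.genes])
            sig = np.full(len(extra_signature), signature_effect if active else 0.0)
            shift_cache[active] = np.concatenate([s, sig])
        return shift_cache[active]

    expr = np.empty((n_patients, len(genes)))
    for i, active in enumerate(active_sets):
        expr[i] = base_level.to_numpy() + shifts_for(active) + rng.normal(0.0, noise_sigma, len(genes))
    expression = pd.DataFrame(expr, index=patients, columns=genes)

    # MYC expression column: bimodal by activation state so an above-mean
    # split recovers the planted state essentially always
    expression["MYC"] = 5.0 + 1.5 * myc_active.astype(float) + rng.normal(0.0, 0.3, n_patients)

    if signature_genes:
        score = expression[list(signature_genes)].mean(axis=1)
    else:
        score = pd.Series(0.0, index=patients)
    score_c = score - score.mean()
    hazard = baseline_hazard * np.power(hazard_factor, score_c.to_numpy())
    times = rng.exponential(1.0 / hazard)
    event = times <= censor_time
    survival = pd.DataFrame(
        {"time": np.minimum(times, censor_time), "event": event}, index=patients
    )

    cohort = PatientCohort(
        expression=expression,
        tp53_status=pd.Series(tp53, index=patients, name="tp53_status"),
        kras_status=pd.Series(
            np.where(kras_mut, "point_mutant", "WT"), index=patients, name="kras_status"
        ),
        survival=survival,
    )

    associated: dict[str, list[str]] = {o: [] for o in ONCOGENES}
    for gene in model.genes:
        if model_table.at[gene, "mode"] == "null":
            continue
        for onc in parse_oncogene_set(model_table.at[gene, "regulators"]):
            associated[onc].append(gene)
    # extra signature genes respond to any active oncogene, so they belong
    # to every oncogene's planted association list
    for gene in extra_signature:
        for onc in ONCOGENES:
            associated[onc].append(gene)
    likely = {}
    for onc in ONCOGENES:
        own = set(associated[onc])
        others = set().union(*(associated[o] for o in ONCOGENES if o != onc))
        likely[onc] = 100.0 * len(own & others) / len(own) if own else float("nan")

    truth = SimulationTruth(
        planted_classes=derive_planted_classes(model),
        signature_genes=list(signature_genes),
        associated_genes={k: sorted(v) for k, v in associated.items()},
        likely_fractions=likely,
    )
    return cohort, truth
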