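"""Stand-in differential analysis for mRNA counts and protein intensities.

The stage mirrors the normalization and significance conventions of a
typical knockdown screen: relative-log-expression (median-of-ratios) size
factors for counts, total-protein-approach proportions for intensities,
per-gene Student's t-tests on log2 values, and Benjamini-Hochberg
adjustment (a Welch variant of the row-wise test is available).
mRNA calls use the BH-adjusted q (q < 0.05); protein calls use the raw p
(p < 0.05).  It deliberately does not re-implement a negative-binomial
GLM: downstream consumers need only (gene, LFC, p, q) and also accept
externally produced tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL, DEGTable, ExpressionMatrix, check_oncogene

MRNA_Q_THRESHOLD = 0.05
PROTEIN_P_THRESHOLD = 0.05


def rle_size_factors(counts: pd.DataFrame | ExpressionMatrix) -> pd.Series:
    """Relative-log-expression (median-of-ratios) size factors.

    ``factor_j = median_g count[g, j] / geomean_j' count[g, j']`` over the
    genes with strictly positive counts in every sample.  Dividing each
    column by its factor equalizes expression against the pseudo-reference.
    """
    if isinstance(counts, ExpressionMatrix):
        counts = counts.values
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature is positive in all samples; add a pseudocount or "
            "filter samples before computing RLE size factors"
        )
    logs = np.log(arr[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpa_normalize(intensities: pd.DataFrame | ExpressionMatrix) -> pd.DataFrame:
    """Total-protein-approach normalization: within-sample proportions."""
    matrix = intensities.values if isinstance(intensities, ExpressionMatrix) else intensities
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with non-positive total intensity: {bad[:5]}")
    return matrix / totals


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Welch-Satterthwaite df, two-sided p).

    Degenerate conventions: zero variance in both groups with equal means
    gives (0, nan, 1); with unequal means the p -> 0 limit is returned
    with an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float("nan"), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float("nan"), 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_rows(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test for two (features x replicates) blocks.

    ``equal_var=True`` gives the pooled-variance Student's t (exact size
    at small n); the default is the Welch-Satterthwaite form.
    """
    res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0.0) & (b.var(axis=1, ddof=1) == 0.0)
    if degenerate.any():
        equal = degenerate & (a.mean(axis=1) == b.mean(axis=1))
        t[equal] = 0.0
        p[equal] = 1.0
        unequal = degenerate & ~equal
        t[unequal] = np.sign(a.mean(axis=1) - b.mean(axis=1))[unequal] * np.inf
        p[unequal] = 0.0
    return t, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-d sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_counts(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    factors = rle_size_factors(values)
    return np.log2(values / factors + pseudocount)


def _log2_proportions(values: pd.DataFrame) -> pd.DataFrame:
    props = tpa_normalize(values)
    arr = props.to_numpy()
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("no positive intensities")
    pseudo = 0.5 * positive.min()
    return np.log2(props + pseudo)


def differential_analysis(
    matrix: ExpressionMatrix,
    cell_line: str,
    oncogene: str,
    mrna_q_threshold: float = MRNA_Q_THRESHOLD,
    protein_p_threshold: float = PROTEIN_P_THRESHOLD,
) -> DEGTable:
    """Control vs one-oncogene-knockdown differential test in one line.

    mRNA: RLE-normalize, log2(x + 1), per-gene Welch t, BH; significant
    iff q < threshold.  Protein: TPA proportions, log2, Welch t;
    significant iff raw p < threshold.  LFC is the difference of log2
    means (knockdown minus control).
    """
    check_oncogene(oncogene)
    ann = matrix.samples
    in_line = ann["cell_line"] == cell_line
    if not in_line.any():
        raise ValueError(f"cell line {cell_line!r} not present")
    sub = matrix.subset_samples(in_line)
    ctrl_ids = sub.samples.index[sub.samples["perturbation"] == CONTROL]
    kd_ids = sub.samples.index[sub.samples["perturbation"] == oncogene]
    if len(ctrl_ids) < 2 or len(kd_ids) < 2:
        raise ValueError(
            f"need >=2 replicates per arm for {cell_line}/{oncogene}; "
            f"got {len(ctrl_ids)} control, {len(kd_ids)} knockdown"
        )
    arms = sub.values[list(ctrl_ids) + list(kd_ids)]
    if matrix.layer == "mRNA":
        log2v = _log2_counts(arms)
    else:
        log2v = _log2_proportions(arms)
    ctrl = log2v[list(ctrl_ids)].to_numpy()
    kd = log2v[list(kd_ids)].to_numpy()
    # pooled-variance Student's t: exact small-sample size, and arm
    # variances are exchangeable in this design
    t, p = welch_t_rows(kd, ctrl, equal_var=True)
    q = bh_adjust(p)
    lfc = kd.mean(axis=1) - ctrl.mean(axis=1)
    if matrix.layer == "mRNA":
        significant = q < mrna_q_threshold
    else:
        significant = p < protein_p_threshold
    records = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "q": q, "significant": significant},
        index=matrix.feature_ids,
    )
    return DEGTable(cell_line=cell_line, oncogene=oncogene, layer=matrix.layer, records=records)


def run_all_differential(
    matrices: list[ExpressionMatrix],
    mrna_q_threshold: float = MRNA_Q_THRESHOLD,
    protein_p_threshold: float = PROTEIN_P_THRESHOLD,
) -> list[DEGTable]:
    """Differential analysis for every (cell line, active oncogene, layer)."""
    tables = []
    for matrix in matrices:
        ann = matrix.samples
        for cell_line in dict.fromkeys(ann["cell_line"]):
            line_ann = ann[ann["cell_line"] == cell_line]
            kds = [p for p in dict.fromkeys(line_ann["perturbation"]) if p != CONTROL]
            for oncogene in kds:
                tables.append(
                    differential_analysis(
                        matrix, cell_line, oncogene, mrna_q_threshold, protein_p_threshold
                    )
                )
    return tables
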