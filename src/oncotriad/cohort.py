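"""Patient-cohort analyses: stratification, signature scoring, association
lists, likely-redundant overlaps and survival comparison.

Patients are stratified by MYC expression (strictly above the dataset
mean = "high") combined with TP53 and KRAS mutation status into mutually
exclusive groups; the control group is MYC-low / TP53 WT-or-null /
KRAS WT.  A signature score is the per-patient mean of the listed genes'
expression.  Transcriptome-wide association compares each stratum against
the rest of the cohort (or against the control group) by Student's t with
BH adjustment at a stringent FDR.  Survival is compared by a standard
two-group log-rank test with an observed/expected hazard-ratio estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ONCOGENES
from .diffexpr import bh_adjust
from .synthetic_data import PatientCohort

STRATA = ("MYC_high_only", "KRAS_mut_only", "TP53_mut_only", "triple_active", "control", "other")
ACTIVE_STRATA = ("MYC_high_only", "KRAS_mut_only", "TP53_mut_only", "triple_active")
#: maps single-oncogene stratum label -> oncogene identifier
STRATUM_OF_ONCOGENE = {
    "MYC": "MYC_high_only",
    "KRAS_mut": "KRAS_mut_only",
    "TP53_mut": "TP53_mut_only",
}

ASSOCIATION_FDR = 0.001


@dataclass
class AssociationList:
    """Genes significantly associated with one stratum at the stated FDR."""

    stratum: str
    fdr_threshold: float
    records: pd.DataFrame  # index=gene; columns t, p, q, direction

    @property
    def genes(self) -> set[str]:
        return set(self.records.index)

    def genes_with_direction(self, direction: int) -> set[str]:
        return set(self.records.index[self.records["direction"] == direction])


@dataclass
class SurvivalResult:
    statistic: float  # log-rank chi-squared, 1 df
    p: float
    hazard_ratio: float  # (O1/E1)/(O2/E2)
    observed: tuple[float, float]
    expected: tuple[float, float]


def stratify(cohort: PatientCohort) -> pd.Series:
    """Assign each patient to one exclusive oncogene-status stratum.

    MYC-high means MYC expression strictly above the cohort mean; the
    TP53 "mut" strata use missense mutations only, and TP53-null counts
    as eligible for the control group.
    """
    if "MYC" not in cohort.expression.columns:
        raise ValueError("cohort expression must contain a MYC column")
    myc_high = cohort.expression["MYC"] > cohort.expression["MYC"].mean()
    tp53_mis = cohort.tp53_status == "missense"
    tp53_wt_null = cohort.tp53_status.isin(["WT", "null"])
    kras_mut = cohort.kras_status == "point_mutant"
    kras_wt = ~kras_mut

    labels = pd.Series("other", index=cohort.patients, name="stratum", dtype=object)
    labels[myc_high & tp53_wt_null & kras_wt] = "MYC_high_only"
    labels[~myc_high & tp53_wt_null & kras_mut] = "KRAS_mut_only"
    labels[~myc_high & tp53_mis & kras_wt] = "TP53_mut_only"
    labels[myc_high & tp53_mis & kras_mut] = "triple_active"
    labels[~myc_high & tp53_wt_null & kras_wt] = "control"
    return labels


def signature_score(cohort: PatientCohort, genes: list[str], zscore: bool = False) -> pd.Series:
    """Per-patient mean expression of the listed genes.

    ``zscore=True`` standardizes each gene across patients first.
    """
    genes = [g.upper() for g in genes]
    missing = [g for g in genes if g not in cohort.expression.columns]
    if missing:
        raise ValueError(f"genes absent from cohort expression: {missing}")
    block = cohort.expression[genes]
    if zscore:
        block = (block - block.mean()) / block.std(ddof=1)
    return block.mean(axis=1).rename("signature_score")


def compare_signature_groups(
    scores: pd.Series, strata: pd.Series, groups: tuple[str, ...] = ACTIVE_STRATA
) -> pd.DataFrame:
    """Two-sided t-test of each named group's scores against control."""
    control = scores[strata == "control"]
    if len(control) == 0:
        raise ValueError("control group is empty")
    rows = []
    for group in groups:
        vals = scores[strata == group]
        if len(vals) < 2:
            warnings.warn(f"group {group} has <2 patients; skipped", stacklevel=2)
            continue
        res = scipy.stats.ttest_ind(vals, control, equal_var=True)
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "mean": float(vals.mean()),
                "control_mean": float(control.mean()),
                "t": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "mean", "control_mean", "t", "p"])


def associate_transcriptome(
    cohort: PatientCohort,
    stratum: str,
    strata: pd.Series | None = None,
    comparator: str = "rest",
    fdr_threshold: float = ASSOCIATION_FDR,
    exclude: tuple[str, ...] = ("MYC",),
) -> AssociationList:
    """Transcriptome-wide stratum association at a stringent FDR.

    Per gene, a two-sided Student's t-test of the stratum's patients
    against the comparator (``"rest"`` = all other patients, the default;
    ``"control"`` = the control stratum), BH-adjusted; genes kept at
    q < ``fdr_threshold`` with their direction of change.  The MYC
    expression column used for stratification is excluded by default.
    """
    if strata is None:
        strata = stratify(cohort)
    in_stratum = strata == stratum
    if comparator == "rest":
        in_comp = ~in_stratum
    elif comparator == "control":
        in_comp = strata == "control"
    else:
        raise ValueError("comparator must be 'rest' or 'control'")
    if in_stratum.sum() < 2 or in_comp.sum() < 2:
        raise ValueError(
            f"degenerate strata: {int(in_stratum.sum())} in {stratum}, "
            f"{int(in_comp.sum())} in comparator {comparator!r}"
        )
    genes = [g for g in cohort.expression.columns if g not in set(exclude)]
    a = cohort.expression.loc[in_stratum, genes].to_numpy().T
    b = cohort.expression.loc[in_comp, genes].to_numpy().T
    res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    t = np.asarray(res.statistic, dtype=float)
    q = bh_adjust(p)
    keep = q < fdr_threshold
    records = pd.DataFrame(
        {
            "t": t[keep],
            "p": p[keep],
            "q": q[keep],
            "direction": np.where(t[keep] >= 0, 1, -1),
        },
        index=pd.Index(np.asarray(genes)[keep], name="gene"),
    )
    return AssociationList(stratum=stratum, fdr_threshold=fdr_threshold, records=records)


def likely_redundant(
    lists: dict[str, AssociationList] | list[dict[str, AssociationList]],
) -> pd.DataFrame:
    """Likely/unlikely-redundant percentages per oncogene.

    For oncogene X with association list A_X: likely% = share of A_X also
    present in A_Y or A_Z.  A list of per-dataset dictionaries is averaged
    unweighted across datasets.  Keys are oncogene identifiers.
    """
    datasets = lists if isinstance(lists, list) else [lists]
    per_dataset = []
    for ds in datasets:
        missing = set(ONCOGENES) - set(ds)
        if missing:
            raise ValueError(f"need an association list per oncogene; missing {sorted(missing)}")
        row = {}
        for onc in ONCOGENES:
            own = ds[onc].genes
            if not own:
                warnings.warn(f"empty association list for {onc}; undefined", stacklevel=2)
                row[onc] = float("nan")
                continue
            others = set().union(*(ds[o].genes for o in ONCOGENES if o != onc))
            row[onc] = 100.0 * len(own & others) / len(own)
        per_dataset.append(row)
    likely = pd.DataFrame(per_dataset).mean()
    return pd.DataFrame(
        {"likely_pct": likely, "unlikely_pct": 100.0 - likely},
        index=pd.Index(ONCOGENES, name="oncogene"),
    )


def km_logrank(
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    group: pd.Series | np.ndarray,
) -> SurvivalResult:
    """Two-group log-rank test with an O/E hazard-ratio estimate.

    ``group`` holds exactly two labels; group 1 is the lexicographically
    smaller label.  The statistic is (O1-E1)^2/V with the standard
    hypergeometric variance over the shared risk-set table; the hazard
    ratio is (O1/E1)/(O2/E2).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    if not event.any():
        raise ValueError("no events observed in either group")
    g1 = group == labels[0]

    o1 = e1 = var = 0.0
    for tj in np.unique(time[event]):
        at_risk = time >= tj
        nj = float(at_risk.sum())
        n1j = float((at_risk & g1).sum())
        dj = float((event & (time == tj)).sum())
        d1j = float((event & (time == tj) & g1).sum())
        o1 += d1j
        e1 += dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1.0 - n1j / nj) * (nj - dj) / (nj - 1.0)
    o_total = float(event.sum())
    o2 = o_total - o1
    e2 = o_total - e1
    if var == 0.0:
        stat = 0.0
        p = 1.0
    else:
        stat = (o1 - e1) ** 2 / var
        p = float(scipy.stats.chi2.sf(stat, df=1))
    if e1 > 0 and e2 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
    else:
        hr = float("nan")
    return SurvivalResult(
        statistic=float(stat), p=max(p, np.finfo(float).tiny), hazard_ratio=float(hr),
        observed=(o1, o2), expected=(e1, e2),
    )
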