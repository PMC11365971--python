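"""Core in-memory containers shared across the analysis stages.

Expression data live in a feature x sample :class:`pandas.DataFrame` wrapped
by :class:`ExpressionMatrix`, which carries the per-sample annotations
(cell line, tissue, active oncogenes, perturbation, replicate) needed to
form control-vs-knockdown designs.  Differential results are wrapped by
:class:`DEGTable`, keyed by (cell_line, oncogene, layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical oncogene identifiers, in display order.
ONCOGENES: tuple[str, ...] = ("MYC", "KRAS_mut", "TP53_mut")

#: Valid expression layers.
LAYERS: tuple[str, ...] = ("mRNA", "protein")

CONTROL = "control"

REQUIRED_SAMPLE_COLUMNS = (
    "cell_line",
    "tissue",
    "active_oncogenes",
    "perturbation",
    "replicate",
)


def check_oncogene(name: str) -> str:
    if name not in ONCOGENES:
        raise ValueError(
            f"unknown oncogene {name!r}; expected one of {ONCOGENES}"
        )
    return name


def parse_oncogene_set(value: str | frozenset[str]) -> frozenset[str]:
    """Parse a semicolon-joined oncogene list (annotation-table format)."""
    if isinstance(value, frozenset):
        names = value
    else:
        names = frozenset(s for s in str(value).split(";") if s)
    for name in names:
        check_oncogene(name)
    return frozenset(names)


def format_oncogene_set(active: frozenset[str]) -> str:
    return ";".join(o for o in ONCOGENES if o in active)


@dataclass
class ExpressionMatrix:
    """Feature x sample omics matrix with sample annotations.

    Parameters
    ----------
    values
        Non-negative values; index = feature ids (uppercased, unique),
        columns = sample ids.  Counts for the mRNA layer, intensities
        for the protein layer.
    samples
        One row per sample (index = sample id) with columns
        ``cell_line, tissue, active_oncogenes, perturbation, replicate``.
    layer
        ``"mRNA"`` or ``"protein"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample annotations missing columns: {missing}")
        unannotated = [s for s in self.values.columns if s not in self.samples.index]
        if unannotated:
            raise ValueError(f"samples without annotation: {unannotated[:5]}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, mask: pd.Series) -> "ExpressionMatrix":
        keep = self.samples.index[mask.reindex(self.samples.index, fill_value=False)]
        keep = [s for s in self.values.columns if s in set(keep)]
        return ExpressionMatrix(
            self.values[keep], self.samples.loc[keep], self.layer
        )

    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["cell_line"]))


@dataclass
class DEGTable:
    """Differential results for one (cell line, oncogene knockdown, layer).

    ``records`` has one row per feature with columns
    ``lfc`` (log2 knockdown/control), ``p`` (raw two-sided), ``q``
    (Benjamini-Hochberg adjusted) and ``significant``.
    """

    cell_line: str
    oncogene: str
    layer: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        check_oncogene(self.oncogene)
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        required = {"lfc", "p", "q", "significant"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"DEG records missing columns: {sorted(missing)}")
        if self.records.index.duplicated().any():
            raise ValueError("duplicate feature ids in DEG table")
        p = self.records["p"].to_numpy()
        q = self.records["q"].to_numpy()
        ok = np.isfinite(p) & np.isfinite(q)
        if ((p[ok] < 0) | (p[ok] > 1) | (q[ok] < 0) | (q[ok] > 1)).any():
            raise ValueError("p and q must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cell_line, self.oncogene, self.layer)

    @property
    def significant_features(self) -> set[str]:
        return set(self.records.index[self.records["significant"]])
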