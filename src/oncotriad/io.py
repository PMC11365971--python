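"""Tab-separated / GMT / JSON input and output for all pipeline stages.

Conventions: UTF-8, header row required, no quoting; gene identifiers
uppercased at ingest; duplicate feature ids rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .containers import DEGTable, ExpressionMatrix, parse_oncogene_set
from .synthetic_data import GenotypeConfig, PatientCohort


def write_matrix(matrix: ExpressionMatrix, path: Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_annotations(matrix: ExpressionMatrix, path: Path) -> None:
    ann = matrix.samples.copy()
    ann.index.name = "sample_id"
    ann.to_csv(path, sep="\t")


def read_matrix(values_path: Path, annotations_path: Path, layer: str) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(annotations_path, sep="\t", index_col=0)
    samples["active_oncogenes"] = samples["active_oncogenes"].fillna("")
    return ExpressionMatrix(values, samples, layer)


def genotypes_from_annotations(samples: pd.DataFrame) -> list[GenotypeConfig]:
    configs = []
    for cell_line, group in samples.groupby("cell_line", sort=True):
        active = {parse_oncogene_set(a) for a in group["active_oncogenes"]}
        if len(active) != 1:
            raise ValueError(f"inconsistent active_oncogenes for cell line {cell_line}")
        configs.append(GenotypeConfig(str(cell_line), str(group["tissue"].iloc[0]), active.pop()))
    return configs


def deg_table_filename(table: DEGTable) -> str:
    return f"deg_{table.cell_line}_{table.oncogene}_{table.layer}.tsv"


def write_deg_table(table: DEGTable, path: Path) -> None:
    df = table.records.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_deg_table(path: Path, cell_line: str, oncogene: str, layer: str) -> DEGTable:
    records = pd.read_csv(path, sep="\t", index_col=0)
    records.index = records.index.astype(str).str.upper()
    records["significant"] = records["significant"].astype(bool)
    return DEGTable(cell_line=cell_line, oncogene=oncogene, layer=layer, records=records)


def read_deg_dir(directory: Path) -> list[DEGTable]:
    """Read every `deg_<cell_line>_<oncogene>_<layer>.tsv` in a directory."""
    tables = []
    for path in sorted(Path(directory).glob("deg_*.tsv")):
        stem = path.stem[len("deg_") :]
        # oncogene ids contain "_mut": split off the layer, then match a
        # known oncogene suffix
        parts = stem.rsplit("_", 1)
        layer = parts[1]
        body = parts[0]
        for onc in ("MYC", "KRAS_mut", "TP53_mut"):
            suffix = f"_{onc}"
            if body.endswith(suffix):
                cell_line = body[: -len(suffix)]
                oncogene = onc
                break
        else:
            raise ValueError(f"cannot parse DEG filename {path.name}")
        tables.append(read_deg_table(path, cell_line, oncogene, layer))
    return tables


def read_gmt(path: Path) -> dict[str, set[str]]:
    """Named gene sets from a GMT file (uppercased, validated non-empty)."""
    raw = _gseapy_read_gmt(str(path))
    if not raw:
        raise ValueError(f"no gene sets parsed from {path}")
    sets = {}
    for name, members in raw.items():
        members = {m.upper() for m in members if m}
        if not members:
            raise ValueError(f"empty gene set {name!r} in {path}")
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: Path, description: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gene_list(path: Path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def write_gene_list(genes, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(genes):
            fh.write(f"{gene}\n")


def write_cohort(cohort: PatientCohort, directory: Path, prefix: str = "cohort") -> dict[str, Path]:
    directory = Path(directory)
    paths = {
        "expression": directory / f"{prefix}_expression.tsv",
        "mutations": directory / f"{prefix}_mutations.tsv",
        "survival": directory / f"{prefix}_survival.tsv",
    }
    expr = cohort.expression.copy()
    expr.index.name = "patient_id"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    muts = pd.DataFrame(
        {"tp53_status": cohort.tp53_status, "kras_status": cohort.kras_status}
    )
    muts.index.name = "patient_id"
    muts.to_csv(paths["mutations"], sep="\t")
    if cohort.survival is not None:
        surv = cohort.survival.copy()
        surv.index.name = "patient_id"
        surv.to_csv(paths["survival"], sep="\t", float_format="%.6g")
    else:
        del paths["survival"]
    return paths


def read_cohort(
    expression_path: Path, mutations_path: Path, survival_path: Path | None = None
) -> PatientCohort:
    expression = pd.read_csv(expression_path, sep="\t", index_col=0)
    # keep_default_na: the TP53 status literal "null" must survive parsing
    muts = pd.read_csv(mutations_path, sep="\t", index_col=0, keep_default_na=False)
    survival = None
    if survival_path is not None and Path(survival_path).exists():
        survival = pd.read_csv(survival_path, sep="\t", index_col=0)
        survival["event"] = survival["event"].astype(bool)
    return PatientCohort(
        expression=expression,
        tp53_status=muts["tp53_status"],
        kras_status=muts["kras_status"],
        survival=survival,
    )


def write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
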