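import numpy as np
import pandas as pd
import pytest

from oncotriad.containers import CONTROL, DEGTable, ExpressionMatrix


def make_deg_table(
    cell_line: str,
    oncogene: str,
    layer: str,
    significant: dict[str, float],
    nonsignificant: dict[str, float] | None = None,
) -> DEGTable:
    """DEG table from gene -> LFC maps (significant / non-significant)."""
    rows = {}
    for gene, lfc in significant.items():
        rows[gene.upper()] = {"lfc": lfc, "p": 0.001, "q": 0.01, "significant": True}
    for gene, lfc in (nonsignificant or {}).items():
        rows[gene.upper()] = {"lfc": lfc, "p": 0.5, "q": 0.8, "significant": False}
    records = pd.DataFrame.from_dict(rows, orient="index")
    return DEGTable(cell_line=cell_line, oncogene=oncogene, layer=layer, records=records)


def make_two_arm_matrix(
    control: np.ndarray, knockdown: np.ndarray, layer: str = "mRNA",
    cell_line: str = "LINE1", oncogene: str = "MYC",
) -> ExpressionMatrix:
    """Expression matrix with one control and one knockdown arm."""
    n_genes, n_ctrl = control.shape
    n_kd = knockdown.shape[1]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    cols, ann = {}, []
    for i in range(n_ctrl):
        sid = f"{cell_line}_{CONTROL}_r{i + 1}"
        cols[sid] = control[:, i]
        ann.append((sid, CONTROL, i + 1))
    for i in range(n_kd):
        sid = f"{cell_line}_{oncogene}_r{i + 1}"
        cols[sid] = knockdown[:, i]
        ann.append((sid, oncogene, i + 1))
    samples = pd.DataFrame(
        {
            "sample_id": [a[0] for a in ann],
            "cell_line": cell_line,
            "tissue": "colon",
            "active_oncogenes": oncogene,
            "perturbation": [a[1] for a in ann],
            "replicate": [a[2] for a in ann],
        }
    ).set_index("sample_id")
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), samples, layer)


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated panel shared by read-only tests."""
    import oncotriad as ot

    model = ot.plant_class_fractions(600, pool_size=120, dispersion=0.02, seed=7)
    panel = ot.standard_panel()
    mrna, protein, truth = ot.simulate_cellline_experiment(
        panel, model, n_replicates=3, seed=7
    )
    return {"model": model, "panel": panel, "mrna": mrna, "protein": protein, "truth": truth}
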