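import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from ornstage import SyntheticConfig, simulate
from ornstage import qc


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Tiny two-stage dataset: fast enough for per-module unit tests."""
    return SyntheticConfig(
        n_types=5,
        stages=("24hAPF", "adult"),
        nucleus_stages=("adult",),
        cells_per_type_per_stage=12,
        n_genes=500,
        n_receptor_genes=10,
        n_de_genes_per_type=15,
        doublet_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def small_norm(small_data):
    adata, truth = small_data
    merged = qc.merge_layers(adata)
    filtered, _ = qc.filter_cells(merged)
    norm = qc.normalize(filtered)
    norm, _ = qc.remove_off_target_cells(norm)
    return norm, truth


def make_norm_adata(values: np.ndarray, genes: list[str], categories=None) -> AnnData:
    """Build a normalized-values AnnData directly from a matrix fixture."""
    n_cells = values.shape[0]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["category"] = categories if categories is not None else "other"
    var["family"] = ""
    var["co_receptor"] = False
    obs = pd.DataFrame(
        {"stage": "adult", "modality": "nucleus"},
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell"),
    )
    return AnnData(X=np.asarray(values, dtype=float), obs=obs, var=var)
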