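import numpy as np
import pandas as pd
import pytest

from ifnsig.dge import StimulationDataset
from ifnsig.netmeta import NODES, NetworkResult, TreatmentNetwork


def make_dataset(
    log2_values: np.ndarray,
    conditions: list[str],
    genes: list[str] | None = None,
    dataset_id: str = "toy",
    dose: list[float] | None = None,
    time: list[float] | None = None,
    is_raw_counts: bool = False,
) -> StimulationDataset:
    """Build a StimulationDataset from log2 values (stored as 2^x - offsetless)."""
    log2_values = np.asarray(log2_values, dtype=float)
    n_genes, n_samples = log2_values.shape
    genes = genes or [f"G{i}" for i in range(1, n_genes + 1)]
    samples = [f"s{i}" for i in range(1, n_samples + 1)]
    ann = pd.DataFrame({"condition": conditions}, index=pd.Index(samples, name="sample"))
    if dose is not None:
        ann["dose"] = dose
    if time is not None:
        ann["time"] = time
    # invert the log2(x+1) transform so fits see exactly log2_values
    expression = pd.DataFrame(2.0**log2_values - 1.0, index=genes, columns=samples)
    return StimulationDataset(
        expression=expression, annotations=ann, dataset_id=dataset_id,
        is_raw_counts=is_raw_counts,
    )


def make_network(rows, gene: str = "g") -> TreatmentNetwork:
    """TreatmentNetwork from (study, a, b, effect, se) tuples (independent edges)."""
    edges = pd.DataFrame(rows, columns=["study", "a", "b", "effect", "se"])
    nodes = tuple(dict.fromkeys(list(edges["a"]) + list(edges["b"])))
    return TreatmentNetwork(gene=gene, nodes=nodes, edges=edges)


def make_result(gene: str, effects: dict, qvals: dict | None = None) -> NetworkResult:
    """NetworkResult with given effects {(a, b): log2 effect} and q-values."""
    effect = pd.DataFrame(0.0, index=list(NODES), columns=list(NODES))
    fdr = pd.DataFrame(1.0, index=list(NODES), columns=list(NODES))
    for (a, b), value in effects.items():
        effect.loc[a, b] = value
        effect.loc[b, a] = -value
    for (a, b), value in (qvals or {}).items():
        fdr.loc[a, b] = value
        fdr.loc[b, a] = value
    se = pd.DataFrame(1.0, index=list(NODES), columns=list(NODES))
    p = fdr.copy()
    return NetworkResult(gene=gene, effect=effect, se=se, p=p, tau2=0.0,
                         model="fixed", fdr=fdr)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
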