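import numpy as np
import pandas as pd
import pytest

from ncrip.de import CountMatrix, DEResult, DEThresholds


def make_counts(wt: np.ndarray, mut: np.ndarray, molecule: str = "mRNA",
                gene_ids=None, lengths=None) -> CountMatrix:
    """Assemble a CountMatrix from WT and mutant replicate blocks."""
    wt = np.atleast_2d(wt)
    mut = np.atleast_2d(mut)
    n_genes = wt.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    cols, meta = [], []
    for strain, block in (("WT", wt), ("mutant", mut)):
        for rep in range(1, block.shape[1] + 1):
            name = f"{strain}_{rep}"
            cols.append(name)
            meta.append({"sample": name, "strain": strain,
                         "replicate": rep, "molecule": molecule})
    counts = pd.DataFrame(np.hstack([wt, mut]), index=gene_ids, columns=cols)
    samples = pd.DataFrame(meta).set_index("sample")
    if lengths is not None:
        lengths = pd.Series(lengths, index=gene_ids, dtype=float)
    return CountMatrix(counts, samples, lengths)


def make_de_result(calls: dict[str, str], lfc: dict[str, float] | None = None,
                   thresholds: DEThresholds | None = None) -> DEResult:
    """Minimal DEResult with given per-gene calls (and optional log2FCs)."""
    genes = list(calls)
    lfc = lfc or {}
    table = pd.DataFrame({
        "baseMean": 100.0,
        "log2FC": [lfc.get(g, {"up": 2.0, "down": -2.0, "ns": 0.0}[calls[g]])
                   for g in genes],
        "SE": 0.5,
        "stat": 0.0,
        "pvalue": [0.001 if calls[g] != "ns" else 0.9 for g in genes],
        "padj": [0.01 if calls[g] != "ns" else 0.95 for g in genes],
        "call": [calls[g] for g in genes],
    }, index=pd.Index(genes, name="gene_id"))
    return DEResult(table, thresholds or DEThresholds())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
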