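"""Negative-binomial differential expression for two-group count data.

Implements a compact DESeq-style pipeline — median-of-ratios size factors,
method-of-moments dispersion, a Wald test on log2 fold changes and
Benjamini–Hochberg correction — for comparing an RNAi mutant against the
wild type in either mRNA or small-RNA count tables.  The model is
NB(mean mu, dispersion alpha) with Var = mu + alpha * mu**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEThresholds",
    "DEResult",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "fpkm",
]

#: Dispersion values below this floor are clamped (effectively Poisson).
DISPERSION_FLOOR = 1e-8

#: Pseudo-count added to normalized group means before taking log2 ratios.
PSEUDOCOUNT = 0.5

WT = "WT"
MUTANT = "mutant"


class NormalizationError(ValueError):
    """No gene has positive counts in every sample."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample, non-negative
        integer counts.
    samples
        DataFrame indexed by sample id with columns ``strain`` (``WT`` or
        ``mutant``), ``replicate`` (int) and ``molecule`` (``mRNA`` or
        ``sRNA``).
    gene_lengths
        Optional per-gene transcript length in bp (for FPKM).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet rows disagree")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        missing = {"strain", "replicate", "molecule"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def strain_columns(self, strain: str) -> list[str]:
        return list(self.samples.index[self.samples["strain"] == strain])

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame | None = None,
                 gene_lengths: pd.Series | None = None) -> "CountMatrix":
        """Read a counts TSV (gene_id + one column per sample).

        Without an explicit sample sheet, sample columns must be named
        ``<strain>_<replicate>``; the molecule class defaults to mRNA.
        """
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("gene_id")
        if samples is None:
            rows = []
            for col in df.columns:
                strain, _, rep = col.rpartition("_")
                rows.append({"sample": col, "strain": strain,
                             "replicate": int(rep), "molecule": "mRNA"})
            samples = pd.DataFrame(rows).set_index("sample")
        return cls(df, samples, gene_lengths)


@dataclass(frozen=True)
class DEThresholds:
    """Significance cutoffs: FDR-adjusted p <= fdr and |log2FC| >= lfc_min."""

    fdr: float = 0.05
    lfc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


@dataclass
class DEResult:
    """Per-gene differential-expression table (mutant vs WT).

    ``table`` columns: baseMean, log2FC, SE, stat, pvalue, padj, call.
    Calls are ``up`` / ``down`` / ``ns``; genes with zero counts everywhere
    are excluded from testing and carry NaN p-values with call ``ns``.
    """

    table: pd.DataFrame
    thresholds: DEThresholds = field(default_factory=DEThresholds)

    def __post_init__(self) -> None:
        expected = {"baseMean", "log2FC", "SE", "stat", "pvalue", "padj", "call"}
        missing = expected - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["call"] != "ns"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, thresholds: DEThresholds | None = None) -> "DEResult":
        df = pd.read_csv(path, sep="\t").set_index("gene_id")
        return cls(df, thresholds or DEThresholds())


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    The pseudo-reference is the per-gene geometric mean across samples,
    restricted to genes positive in every sample; each sample's factor is
    the median of its count-to-reference ratios.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "size-factor estimation needs at least one gene with positive "
            "counts in every sample")
    sub = arr[positive]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def _group_moments(norm: np.ndarray, cols_by_strain: dict[str, np.ndarray]):
    """Within-strain means and pooled (df-weighted) variances."""
    means, variances, dfs = {}, {}, {}
    for strain, idx in cols_by_strain.items():
        block = norm[:, idx]
        means[strain] = block.mean(axis=1)
        variances[strain] = block.var(axis=1, ddof=1)
        dfs[strain] = block.shape[1] - 1
    return means, variances, dfs


def estimate_dispersion(counts: CountMatrix, factors: pd.Series) -> pd.Series:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    Variance is pooled within strain (so condition effects do not inflate
    it); alpha_hat = max(floor, (s2 - mean) / mean**2).  Genes with zero
    mean get the floor.
    """
    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()
    cols = {s: np.array([counts.counts.columns.get_loc(c)
                         for c in counts.strain_columns(s)])
            for s in counts.samples["strain"].unique()}
    means, variances, dfs = _group_moments(norm, cols)
    total_df = sum(dfs.values())
    pooled_var = sum(variances[s] * dfs[s] for s in cols) / total_df
    grand_mean = np.mean([means[s] for s in cols], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - grand_mean) / grand_mean**2
    alpha = np.where(grand_mean > 0, alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def nb_wald_test(counts: CountMatrix,
                 factors: pd.Series | None = None,
                 dispersion: pd.Series | None = None,
                 thresholds: DEThresholds | None = None,
                 moderate_dispersion: bool = True) -> DEResult:
    """Wald test of mutant-vs-WT log2 fold change under the NB model.

    log2FC = log2((mu_mut + pc) / (mu_WT + pc)) on size-factor-normalized
    group means; the SE comes from the delta method with NB variance
    mu + alpha * mu**2.  With ``moderate_dispersion`` each gene's alpha is
    floored at the across-gene median, guarding against the strong downward
    noise of the moments estimator at two or three replicates per group.
    Two-sided normal p-values are BH-adjusted over the tested genes
    (all-zero genes are excluded from testing).
    """
    thresholds = thresholds or DEThresholds()
    strains = set(counts.samples["strain"])
    if strains != {WT, MUTANT}:
        raise ValueError(f"expected strains {{'WT', 'mutant'}}, got {sorted(strains)}")
    for strain in (WT, MUTANT):
        if len(counts.strain_columns(strain)) < 2:
            raise ValueError(f"need >=2 replicates for strain {strain!r}")
    if factors is None:
        factors = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors)

    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()
    wt_idx = [counts.counts.columns.get_loc(c) for c in counts.strain_columns(WT)]
    mut_idx = [counts.counts.columns.get_loc(c) for c in counts.strain_columns(MUTANT)]
    mu_w = norm[:, wt_idx].mean(axis=1)
    mu_m = norm[:, mut_idx].mean(axis=1)
    n_w, n_m = len(wt_idx), len(mut_idx)

    alpha = dispersion.to_numpy(dtype=float)
    tested = counts.counts.to_numpy().sum(axis=1) > 0
    if moderate_dispersion and tested.any():
        alpha = np.maximum(alpha, np.median(alpha[tested]))

    pc = PSEUDOCOUNT
    lfc = np.log2((mu_m + pc) / (mu_w + pc))
    var_w = mu_w + alpha * mu_w**2
    var_m = mu_m + alpha * mu_m**2
    se = np.sqrt(var_w / (n_w * (mu_w + pc) ** 2)
                 + var_m / (n_m * (mu_m + pc) ** 2)) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(z))
    pvalue = np.where(tested, pvalue, np.nan)
    padj = bh_adjust(pvalue)

    call = np.full(len(lfc), "ns", dtype=object)
    sig = tested & (padj <= thresholds.fdr)
    call[sig & (lfc >= thresholds.lfc_min)] = "up"
    call[sig & (lfc <= -thresholds.lfc_min)] = "down"

    table = pd.DataFrame({
        "baseMean": (mu_w + mu_m) / 2,
        "log2FC": lfc,
        "SE": se,
        "stat": z,
        "pvalue": pvalue,
        "padj": padj,
        "call": call,
    }, index=counts.gene_ids)
    return DEResult(table, thresholds)


def fpkm(counts: CountMatrix, gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM[i, j] = count[i, j] * 1e9 / (length_bp[i] * column_total[j]).
    """
    lengths = gene_lengths if gene_lengths is not None else counts.gene_lengths
    if lengths is None:
        raise ValueError("gene lengths required for FPKM")
    lengths = lengths.reindex(counts.gene_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all gene lengths must be present and positive")
    totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = counts.counts.columns[totals == 0].tolist()
        raise ValueError(f"zero column total for samples: {bad}")
    values = (counts.counts.to_numpy(dtype=float) * 1e9
              / (lengths.to_numpy(dtype=float)[:, None] * totals[None, :]))
    return pd.DataFrame(values, index=counts.gene_ids, columns=counts.counts.columns)
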