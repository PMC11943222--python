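"""Luciferase reporter statistics and RT-qPCR relative quantification.

Light emission (RLU) from strains expressing polycistronic
luciferase-target mRNAs is normalized to calcofluor-stained biomass
fluorescence; degradation of a construct is detected as lower normalized
emission in the wild type than in the RNAi mutant, tested with an
unpaired t-test.  Relative transcript levels from qPCR use the
delta-delta Ct method against a reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReporterTable",
    "QPCRRecord",
    "normalize_rlu",
    "degradation_test",
    "construct_tests",
    "ddct",
]


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicates in a comparison group."""


@dataclass
class ReporterTable:
    """Rows of (construct, strain, replicate, rlu, fluor)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"construct", "strain", "replicate", "rlu", "fluor"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reporter table missing columns: {sorted(missing)}")
        bad = self.table.index[self.table["fluor"] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive fluorescence in rows {bad[:5]}")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReporterTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class QPCRRecord:
    """Cycle thresholds for a target and the reference gene in one condition."""

    gene: str
    condition: str
    ct_target: float
    ct_reference: float
    reference_gene: str = "ef"

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")


def normalize_rlu(table: ReporterTable) -> pd.Series:
    """Per-well biomass normalization: RLU / fluorescence."""
    return table.table["rlu"] / table.table["fluor"]


def degradation_test(wt, mut, welch: bool = False) -> tuple[float, float, float]:
    """Unpaired t-test of WT vs mutant normalized emission.

    Returns (ratio of means mut/WT, t statistic, two-sided p).  Pooled
    variance by default; Welch optional.  A mut/WT ratio above 1 with a
    significant p indicates degradation of the construct in the wild type.
    """
    wt = np.asarray(wt, dtype=float)
    mut = np.asarray(mut, dtype=float)
    if len(wt) < 2 or len(mut) < 2:
        raise InsufficientReplicatesError("need >=2 replicates per group")
    res = stats.ttest_ind(wt, mut, equal_var=not welch)
    mean_wt = wt.mean()
    ratio = np.inf if mean_wt == 0 else mut.mean() / mean_wt
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    return ratio, t, p


def construct_tests(table: ReporterTable, welch: bool = False) -> pd.DataFrame:
    """Normalize and test every construct: one row per construct."""
    norm = normalize_rlu(table)
    df = table.table.assign(norm=norm)
    rows = []
    for construct, grp in df.groupby("construct"):
        wt = grp.loc[grp["strain"] == "WT", "norm"].to_numpy()
        mut = grp.loc[grp["strain"] == "mutant", "norm"].to_numpy()
        ratio, t, p = degradation_test(wt, mut, welch=welch)
        rows.append({"construct": construct, "n_wt": len(wt), "n_mut": len(mut),
                     "mean_wt": wt.mean(), "mean_mut": mut.mean(),
                     "ratio_mut_over_wt": ratio, "t": t, "pvalue": p})
    return pd.DataFrame(rows).set_index("construct")


def ddct(mut: QPCRRecord, wt: QPCRRecord) -> float:
    """Delta-delta Ct fold change of the mutant relative to wild type.

    ddCt = (Ct_target - Ct_ref)_mut - (Ct_target - Ct_ref)_wt;
    fold = 2 ** (-ddCt).
    """
    if mut.gene != wt.gene:
        raise ValueError("records quantify different genes")
    if mut.reference_gene != wt.reference_gene:
        raise ValueError("records use different reference genes")
    delta_mut = mut.ct_target - mut.ct_reference
    delta_wt = wt.ct_target - wt.ct_reference
    return float(2.0 ** (-(delta_mut - delta_wt)))
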