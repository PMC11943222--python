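"""Integration of mRNA and sRNA differential results into target classes.

A gene whose mRNA rises while its sense-derived sRNAs fall in the mutant
(-sRNA, +mRNA) carries the operational signature of direct degradation by
the non-canonical RNAi pathway and is labelled ``direct_target``.  The
remaining sign patterns partition the gene universe into co-regulated,
single-axis and unchanged classes, and the summary reproduces the
marginal totals of the published contingency layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de import DEResult

__all__ = [
    "LABELS",
    "GeneClassification",
    "ClassificationSummary",
    "ConditionComparison",
    "classify",
    "summarize",
    "direct_targets",
    "compare_conditions",
]

LABELS = (
    "co_up",            # +sRNA, +mRNA
    "co_down",          # -sRNA, -mRNA
    "direct_target",    # -sRNA, +mRNA
    "anti_target",      # +sRNA, -mRNA
    "mrna_only_up",
    "mrna_only_down",
    "srna_only_up",
    "srna_only_down",
    "unchanged",
)

_PATTERN = {
    ("up", "up"): "co_up",
    ("up", "down"): "direct_target",
    ("down", "down"): "co_down",
    ("down", "up"): "anti_target",
    ("up", "ns"): "mrna_only_up",
    ("down", "ns"): "mrna_only_down",
    ("ns", "up"): "srna_only_up",
    ("ns", "down"): "srna_only_down",
    ("ns", "ns"): "unchanged",
}


@dataclass
class GeneClassification:
    """Per-gene sign-pattern labels over the union of both gene universes.

    ``table`` columns: label, mrna_call, srna_call, mrna_lfc, mrna_padj,
    srna_lfc, srna_padj, mrna_tested, srna_tested.  ``*_tested`` records
    whether the gene was present in that DE table at all (absence and
    non-significance collapse to the same label but stay distinguishable
    here).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids in classification")
        bad = set(self.table["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def to_tsv(self, path) -> None:
        cols = ["label", "mrna_lfc", "mrna_padj", "srna_lfc", "srna_padj"]
        out = self.table[cols].copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_labels(cls, labels: pd.Series) -> "GeneClassification":
        """Build a classification from bare labels (no DE statistics)."""
        call_of = {
            "co_up": ("up", "up"), "direct_target": ("up", "down"),
            "co_down": ("down", "down"), "anti_target": ("down", "up"),
            "mrna_only_up": ("up", "ns"), "mrna_only_down": ("down", "ns"),
            "srna_only_up": ("ns", "up"), "srna_only_down": ("ns", "down"),
            "unchanged": ("ns", "ns"),
        }
        table = pd.DataFrame({"label": labels})
        table["mrna_call"] = [call_of[l][0] for l in labels]
        table["srna_call"] = [call_of[l][1] for l in labels]
        for col in ("mrna_lfc", "mrna_padj", "srna_lfc", "srna_padj"):
            table[col] = float("nan")
        table["mrna_tested"] = True
        table["srna_tested"] = True
        return cls(table)


@dataclass
class ClassificationSummary:
    """Label counts plus the contingency-table marginals.

    The marginals satisfy, by construction:
    total_mrna_up = co_up + direct_target + mrna_only_up, etc.;
    dual_detected = the four cells significant on both axes;
    total_srna_genes = total_srna_up + total_srna_down.
    """

    counts: dict[str, int]

    @property
    def marginals(self) -> dict[str, int]:
        c = self.counts
        return {
            "total_mrna_up": c["co_up"] + c["direct_target"] + c["mrna_only_up"],
            "total_mrna_down": c["co_down"] + c["anti_target"] + c["mrna_only_down"],
            "total_srna_up": c["co_up"] + c["anti_target"] + c["srna_only_up"],
            "total_srna_down": c["direct_target"] + c["co_down"] + c["srna_only_down"],
            "dual_detected": (c["co_up"] + c["direct_target"]
                              + c["co_down"] + c["anti_target"]),
            "mrna_only": c["mrna_only_up"] + c["mrna_only_down"],
            "srna_only": c["srna_only_up"] + c["srna_only_down"],
            "total_mrna_genes": (c["co_up"] + c["direct_target"] + c["co_down"]
                                 + c["anti_target"] + c["mrna_only_up"]
                                 + c["mrna_only_down"]),
            "total_srna_genes": (c["co_up"] + c["direct_target"] + c["co_down"]
                                 + c["anti_target"] + c["srna_only_up"]
                                 + c["srna_only_down"]),
        }

    def to_dict(self) -> dict:
        return {"cells": dict(self.counts), "marginals": self.marginals}


@dataclass
class ConditionComparison:
    """DEG overlap between two growth conditions with direction concordance."""

    common: pd.DataFrame           # index gene_id; column concordance
    only_a: list[str]
    only_b: list[str]

    @property
    def n_common(self) -> int:
        return len(self.common)


def _calls_frame(de: DEResult, prefix: str) -> pd.DataFrame:
    df = de.table[["call", "log2FC", "padj"]].copy()
    df.columns = [f"{prefix}_call", f"{prefix}_lfc", f"{prefix}_padj"]
    return df


def classify(mrna_de: DEResult, srna_de: DEResult) -> GeneClassification:
    """Label every gene in the union of both DE tables by sign pattern.

    Genes absent from one table count as 'no match' on that axis, the same
    outcome as a tested-but-non-significant gene; presence is recorded in
    the ``*_tested`` columns.
    """
    for de, name in ((mrna_de, "mRNA"), (srna_de, "sRNA")):
        if de.table.index.duplicated().any():
            raise ValueError(f"duplicate gene ids in {name} DE table")
    m = _calls_frame(mrna_de, "mrna")
    s = _calls_frame(srna_de, "srna")
    merged = m.join(s, how="outer")
    merged["mrna_tested"] = merged.index.isin(m.index)
    merged["srna_tested"] = merged.index.isin(s.index)
    merged["mrna_call"] = merged["mrna_call"].fillna("ns")
    merged["srna_call"] = merged["srna_call"].fillna("ns")
    merged["label"] = [
        _PATTERN[(mc, sc)]
        for mc, sc in zip(merged["mrna_call"], merged["srna_call"])
    ]
    merged = merged.sort_index()
    return GeneClassification(merged)


def summarize(classification: GeneClassification) -> ClassificationSummary:
    """Count genes per label; marginal identities hold by construction."""
    counts = {label: 0 for label in LABELS}
    counts.update(classification.labels.value_counts().to_dict())
    return ClassificationSummary(counts)


def direct_targets(classification: GeneClassification) -> list[str]:
    """Gene ids labelled direct_target, sorted by id."""
    mask = classification.labels == "direct_target"
    return sorted(classification.table.index[mask])


def compare_conditions(degs_a: DEResult, degs_b: DEResult) -> ConditionComparison:
    """Intersect two significant-DEG sets and score direction concordance."""
    a = degs_a.significant()
    b = degs_b.significant()
    common_ids = sorted(set(a.index) & set(b.index))
    concordance = [
        "same_direction" if a.loc[g, "call"] == b.loc[g, "call"]
        else "opposite_direction"
        for g in common_ids
    ]
    common = pd.DataFrame({"concordance": concordance}, index=pd.Index(common_ids, name="gene_id"))
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    return ConditionComparison(common, only_a, only_b)
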