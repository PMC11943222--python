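"""Functional-class enrichment: delta-rank / Mann–Whitney and Fisher tests.

Genes are grouped into KOG-style functional classes.  Two complementary
statistics are computed per class: a signed delta-rank (mean rank of the
class members minus mean rank of all other genes, ranks ascending on the
per-gene score, typically log2FC) tested with a two-sided Mann–Whitney U,
and a one-sided Fisher's exact over-representation test of a gene set
against the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ClassMap", "delta_rank", "fisher_enrichment", "enrichment_table"]


@dataclass
class ClassMap:
    """gene id -> functional class label, over an explicit universe.

    Genes in the universe without an assignment fall into the class
    ``None`` (unannotated) and are never reported as a class of their own,
    but do count toward "all other genes".
    """

    assignments: pd.Series    # index gene_id, values class label
    universe: pd.Index

    def __post_init__(self) -> None:
        if self.assignments.index.duplicated().any():
            raise ValueError("a gene may map to at most one class")
        extra = set(self.assignments.index) - set(self.universe)
        if extra:
            raise ValueError(f"assigned genes outside universe: {sorted(extra)[:5]}")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.assignments))

    def members(self, cls: str) -> pd.Index:
        return self.assignments.index[self.assignments == cls]

    @classmethod
    def from_tsv(cls, path, universe=None) -> "ClassMap":
        df = pd.read_csv(path, sep="\t")
        ser = pd.Series(df["class"].to_numpy(), index=df["gene_id"])
        if universe is None:
            universe = pd.Index(ser.index)
        return cls(ser, pd.Index(universe))


def delta_rank(class_map: ClassMap, gene_scores: pd.Series) -> pd.DataFrame:
    """Delta-rank and Mann–Whitney U p-value per class.

    Scores are ranked ascending with average ranks on ties;
    delta_rank(c) = mean rank inside c - mean rank outside c.  The p-value
    uses the normal approximation with tie correction.  An empty class, or
    one covering the whole universe, degenerates to delta_rank 0 / p 1.
    """
    missing = set(class_map.universe) - set(gene_scores.index)
    if missing:
        raise ValueError(f"scores missing for universe genes: {sorted(missing)[:5]}")
    scores = gene_scores.reindex(class_map.universe)
    ranks = pd.Series(stats.rankdata(scores.to_numpy()), index=scores.index)
    rows = []
    n_total = len(ranks)
    for cls in class_map.classes:
        members = class_map.members(cls)
        in_mask = ranks.index.isin(members)
        k = int(in_mask.sum())
        if k == 0 or k == n_total:
            rows.append({"class": cls, "n_in_class": k,
                         "delta_rank": 0.0, "mwu_p": 1.0})
            continue
        dr = float(ranks[in_mask].mean() - ranks[~in_mask].mean())
        inside = scores[in_mask].to_numpy()
        outside = scores[~in_mask].to_numpy()
        if np.ptp(scores.to_numpy()) == 0:
            p = 1.0  # all scores tied: no ordering information
        else:
            p = float(stats.mannwhitneyu(inside, outside, alternative="two-sided",
                                         method="asymptotic").pvalue)
        rows.append({"class": cls, "n_in_class": k,
                     "delta_rank": dr, "mwu_p": min(p, 1.0)})
    return pd.DataFrame(rows).set_index("class")


def fisher_enrichment(gene_set, class_map: ClassMap,
                      alpha: float = 0.05) -> pd.DataFrame:
    """One-sided (greater) Fisher's exact over-representation per class.

    For each class the 2x2 table is (in set & in class, in set & out of
    class; out of set & in class, out of set & out of class) over the
    universe; p is the hypergeometric upper tail.
    """
    if len(class_map.universe) == 0:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    stray = gene_set - set(class_map.universe)
    if stray:
        raise ValueError(f"gene set outside universe: {sorted(stray)[:5]}")
    N = len(class_map.universe)
    n = len(gene_set)
    rows = []
    for cls in class_map.classes:
        members = set(class_map.members(cls))
        K = len(members)
        k = len(gene_set & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"class": cls, "n_in_class": K, "n_overlap": k,
                     "fisher_p": min(p, 1.0), "enriched": p <= alpha})
    return pd.DataFrame(rows).set_index("class")


def enrichment_table(class_map: ClassMap, gene_scores: pd.Series,
                     gene_set=None, alpha: float = 0.05,
                     bh_correct: bool = False) -> pd.DataFrame:
    """Combined per-class table: delta-rank/MWU plus Fisher enrichment.

    ``gene_set`` defaults to nothing (Fisher columns omitted).  Raw p <=
    alpha flags enrichment, matching common practice for KOG scans; BH
    correction across classes is available but off by default.
    """
    out = delta_rank(class_map, gene_scores)
    if gene_set is not None:
        fish = fisher_enrichment(gene_set, class_map, alpha=alpha)
        out = out.join(fish[["n_overlap", "fisher_p", "enriched"]])
    if bh_correct:
        from .de import bh_adjust
        out["mwu_p_adj"] = bh_adjust(out["mwu_p"].to_numpy())
        if "fisher_p" in out:
            out["fisher_p_adj"] = bh_adjust(out["fisher_p"].to_numpy())
    return out
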