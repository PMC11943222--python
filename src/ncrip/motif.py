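"""CAG tandem-repeat detection in transcript sequences.

Direct targets of the Mucor non-canonical RNAi pathway carry runs of the
CAG trinucleotide in their RNA, a repeat class known to fold into hairpins.
This module scans sense-strand transcript sequences for maximal runs of
consecutive CAG units (any phase, pure repeats only) and tests whether the
presence of such runs is enriched in a target set relative to a background
set of genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MotifHit", "find_cag_repeats", "motif_enrichment", "sample_background"]

_VALID = set("ACGUTN")
_UNIT = "CAG"


@dataclass(frozen=True)
class MotifHit:
    """A maximal run of consecutive CAG units (1-based inclusive coords)."""

    seq_id: str
    start: int
    end: int
    n_units: int

    def __post_init__(self) -> None:
        assert self.end - self.start + 1 == 3 * self.n_units


def find_cag_repeats(seq: str, min_units: int = 4,
                     seq_id: str = "") -> list[MotifHit]:
    """Find maximal non-overlapping CAG runs of at least ``min_units``.

    The scan is phase-agnostic (a run may start at any offset), operates on
    the sense strand only, and treats T and U as equivalent.  Runs are
    maximal: they cannot be extended by another CAG unit on either side.
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    upper = seq.upper()
    bad = [i + 1 for i, ch in enumerate(upper) if ch not in _VALID]
    if bad:
        raise ValueError(f"invalid characters at positions {bad[:10]}")
    s = upper.replace("U", "T")
    unit = _UNIT  # on the DNA alphabet
    hits: list[MotifHit] = []
    i, n = 0, len(s)
    while i + 3 <= n:
        if s[i:i + 3] == unit:
            j = i + 3
            while j + 3 <= n and s[j:j + 3] == unit:
                j += 3
            units = (j - i) // 3
            if units >= min_units:
                hits.append(MotifHit(seq_id, i + 1, j, units))
            i = j
        else:
            i += 1
    return hits


def sample_background(candidate_ids, size: int, seed: int) -> list[str]:
    """Uniform sample without replacement of background gene ids."""
    rng = np.random.default_rng(seed)
    ids = sorted(candidate_ids)
    if size > len(ids):
        raise ValueError("background size exceeds candidate pool")
    return sorted(rng.choice(ids, size=size, replace=False).tolist())


def motif_enrichment(target_seqs: dict[str, str], background_seqs: dict[str, str],
                     min_units: int = 4):
    """Fisher one-sided test of CAG-run presence in targets vs background.

    Each sequence contributes presence/absence of at least one qualifying
    run.  Returns (2x2 table as a dict, one-sided p for targets enriched).
    """
    if not target_seqs or not background_seqs:
        raise ValueError("both sequence sets must be non-empty")
    t_hit = sum(bool(find_cag_repeats(s, min_units, i))
                for i, s in target_seqs.items())
    b_hit = sum(bool(find_cag_repeats(s, min_units, i))
                for i, s in background_seqs.items())
    t_n, b_n = len(target_seqs), len(background_seqs)
    table = [[t_hit, t_n - t_hit], [b_hit, b_n - b_hit]]
    _, p = stats.fisher_exact(table, alternative="greater")
    counts = {"targets_with_motif": t_hit, "targets_total": t_n,
              "background_with_motif": b_hit, "background_total": b_n}
    return counts, float(p)
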