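"""Transposable-element annotation from coding potential and coverage.

Candidate TE loci are characterised by six-frame translation, ORF capture,
and a scan against a small bundled library of amino-acid consensus motifs
for the retroelement cassette (protease, reverse transcriptase RVT,
RNase H, integrase, plus a DDE transposase).  A locus carrying the full
protease–RVT–RNaseH–integrase cassette is classified ``LTR_complete``; one
carrying only RVT is ``RVT_only`` (truncated or LINE-like non-LTR
element).  Helpers check that genes adjacent to a TE are unchanged in both
mRNA and sRNA differential tables, and bin read coverage into fixed-width
bins-per-million (BPM) tracks.

The consensus strings are synthetic, fixed motifs designed for
deterministic offline matching against cassettes built by the simulator;
they are not Pfam profiles and carry no claim of sensitivity on real
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .de import DEResult

__all__ = [
    "DOMAIN_LIBRARY",
    "ORF",
    "DomainHit",
    "TEModel",
    "CoverageTrack",
    "six_frame_translate",
    "find_orfs",
    "scan_domains",
    "classify_te",
    "adjacent_gene_check",
    "bin_coverage",
]

_DNA = set("ACGTN")

# Synthetic amino-acid consensus motifs (>=12 aa each); order in a full
# LTR cassette is protease < RVT < RNaseH < integrase along the ORF.
DOMAIN_LIBRARY: dict[str, str] = {
    "protease": "LVDTGAQVSVIPESFWRK",
    "RVT": ("KRLVQDLRKINEAVLPTPYPLPNIQDILSQLGGAKYFSKLDLRSGYHQIRMAEGDEWKTAFR"),
    "RNaseH": "IAYADDILVFSKDWESHL",
    "integrase": "HLGVQKTYDRIREDYYWPGM",
    "transposase": "WGFRRVLCIDEKSVEHYL",
}

#: Default maximum mismatch fraction when matching a consensus.
MAX_MISMATCH_FRACTION = 0.25


@dataclass(frozen=True)
class ORF:
    """A stop-free peptide stretch in one of the six frames.

    ``frame`` is +1..+3 (given strand) or -1..-3 (reverse complement);
    ``aa_start``/``aa_end`` are 1-based inclusive positions in that
    frame's peptide; ``start_type`` is 'M' (begins at a methionine) or
    'edge' (begins at the peptide start or right after a stop).
    """

    frame: int
    aa_start: int
    aa_end: int
    peptide: str
    start_type: str

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class DomainHit:
    """Best placement of one consensus motif in one ORF."""

    domain: str
    orf_index: int
    aa_offset: int        # 1-based offset within the ORF peptide
    mismatches: int


@dataclass
class TEModel:
    """A candidate TE locus with its ORFs, domain hits and class."""

    locus_id: str
    contig: str
    start: int            # 1-based inclusive
    end: int
    strand: str = "+"
    orfs: list[ORF] = field(default_factory=list)
    hits: list[DomainHit] = field(default_factory=list)
    te_class: str = "none"
    partial: bool = False


@dataclass
class CoverageTrack:
    """BPM-normalized coverage in fixed-width bins along one contig."""

    contig: str
    bin_width: int
    values: np.ndarray
    total_reads: int


def six_frame_translate(seq: str) -> list[str]:
    """Translate all six reading frames with the standard genetic code.

    Returns peptides for frames +1, +2, +3 then -1, -2, -3 (reverse
    complement read 5'->3').  Stops are '*', codons containing N become
    'X', and trailing partial codons are dropped.
    """
    upper = seq.upper()
    bad = [i + 1 for i, ch in enumerate(upper) if ch not in _DNA]
    if bad:
        raise ValueError(f"invalid characters at positions {bad[:10]}")
    fwd = Seq(upper)
    rev = fwd.reverse_complement()
    peptides = []
    for strand_seq in (fwd, rev):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            peptides.append(str(sub.translate()))
    return peptides


def find_orfs(peptides: list[str], min_len_aa: int = 100) -> list[ORF]:
    """Capture stop-free stretches of length >= min_len_aa in each frame.

    Each maximal '*'-free stretch is reported from its first residue
    ('edge' start) and, if distinct, from its first internal methionine
    ('M' start).  A stretch that itself begins with M is reported once,
    as an 'M' start.
    """
    frames = [1, 2, 3, -1, -2, -3]
    orfs: list[ORF] = []
    for frame, pep in zip(frames, peptides):
        pos = 0
        for chunk in pep.split("*"):
            if chunk:
                start = pos
                m_rel = chunk.find("M")
                if m_rel == 0:
                    candidates = [(0, "M")]
                elif m_rel > 0:
                    candidates = [(0, "edge"), (m_rel, "M")]
                else:
                    candidates = [(0, "edge")]
                for rel, kind in candidates:
                    sub = chunk[rel:]
                    if len(sub) >= min_len_aa:
                        orfs.append(ORF(frame, start + rel + 1,
                                        start + len(chunk), sub, kind))
            pos += len(chunk) + 1
    return orfs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_domains(orfs: list[ORF],
                 domain_library: dict[str, str] | None = None,
                 max_mismatch: dict[str, int] | None = None) -> list[DomainHit]:
    """Best-scoring placement of each consensus in each ORF.

    A placement qualifies when its Hamming distance to the consensus is at
    most the domain's mismatch budget (default: 25% of the consensus
    length, rounded down).  Ties on distance break to the leftmost
    position; at most one hit per (ORF, domain) pair is returned.
    """
    if domain_library is None:
        domain_library = DOMAIN_LIBRARY
    if not domain_library:
        raise ValueError("domain library is empty")
    hits: list[DomainHit] = []
    for orf_idx, orf in enumerate(orfs):
        pep = orf.peptide
        for name, consensus in domain_library.items():
            L = len(consensus)
            budget = (max_mismatch or {}).get(
                name, int(MAX_MISMATCH_FRACTION * L))
            best: tuple[int, int] | None = None
            for off in range(len(pep) - L + 1):
                d = _hamming(pep[off:off + L], consensus)
                if d <= budget and (best is None or d < best[0]):
                    best = (d, off)
            if best is not None:
                hits.append(DomainHit(name, orf_idx, best[1] + 1, best[0]))
    return hits


_LTR_CASSETTE = frozenset({"protease", "RVT", "RNaseH", "integrase"})


def classify_te(hits: list[DomainHit]) -> tuple[str, bool]:
    """Classify a locus from its domain-hit names.

    Returns (te_class, partial): LTR_complete when all four cassette
    domains are present, RVT_only when RVT is the only hit, otherwise
    'none' — with partial=True when some but not the full cassette is
    there.
    """
    names = {h.domain for h in hits}
    if _LTR_CASSETTE <= names:
        return "LTR_complete", False
    if names == {"RVT"}:
        return "RVT_only", False
    return "none", bool(names)


def annotate_locus(locus_id: str, contig: str, start: int, end: int,
                   sequence: str, min_len_aa: int = 100,
                   domain_library: dict[str, str] | None = None) -> TEModel:
    """Full annotation of one locus: translate, find ORFs, scan, classify."""
    peptides = six_frame_translate(sequence)
    orfs = find_orfs(peptides, min_len_aa=min_len_aa)
    hits = scan_domains(orfs, domain_library)
    te_class, partial = classify_te(hits)
    return TEModel(locus_id, contig, start, end, "+", orfs, hits,
                   te_class, partial)


def adjacent_gene_check(te: TEModel, genes, mrna_de: DEResult,
                        srna_de: DEResult, window_genes: int = 1) -> dict[str, str]:
    """Verdict per neighbouring gene: unchanged unless significant anywhere.

    ``genes`` is a DataFrame with columns gene_id, contig, start, end
    (1-based inclusive), as produced by the GFF reader.  The nearest
    ``window_genes`` genes on each side of the locus (same contig,
    non-overlapping) are checked against both DE tables; a neighbour is
    'unchanged' iff its call is 'ns' or it is absent in both.
    """
    same = genes[genes["contig"] == te.contig]
    if same.empty:
        raise ValueError(f"no annotated genes on contig {te.contig!r}")
    left = same[same["end"] < te.start].sort_values("end")
    right = same[same["start"] > te.end].sort_values("start")
    neighbours = (list(left["gene_id"].iloc[-window_genes:])
                  + list(right["gene_id"].iloc[:window_genes]))
    if not neighbours:
        raise ValueError(f"locus {te.locus_id} has no resolvable neighbours")
    verdict = {}
    for gid in neighbours:
        calls = []
        for de in (mrna_de, srna_de):
            calls.append(de.table.loc[gid, "call"] if gid in de.table.index else "ns")
        verdict[gid] = "unchanged" if all(c == "ns" for c in calls) else "changed"
    return verdict


def bin_coverage(read_intervals, contig_length: int, contig: str = "",
                 bin_width: int = 25, total_reads: int | None = None) -> CoverageTrack:
    """Per-bin read counts normalized to bins per million mapped reads.

    ``read_intervals`` are 1-based inclusive (start, end) pairs.  Each bin
    counts reads overlapping it by at least one base; BPM = count * 1e6 /
    total_reads.  The last bin may be shorter than ``bin_width``.
    """
    intervals = list(read_intervals)
    if total_reads is None:
        total_reads = len(intervals)
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    n_bins = (contig_length + bin_width - 1) // bin_width
    counts = np.zeros(n_bins)
    for start, end in intervals:
        if start < 1 or end > contig_length or end < start:
            raise ValueError(f"interval ({start}, {end}) outside contig")
        first = (start - 1) // bin_width
        last = (end - 1) // bin_width
        counts[first:last + 1] += 1
    return CoverageTrack(contig, bin_width, counts * 1e6 / total_reads,
                         total_reads)


def refine_boundaries(te: TEModel, track: CoverageTrack,
                      theta: float = 1.0) -> tuple[int, int]:
    """Extend locus bounds over the contiguous run of bins with BPM >= theta.

    A read-evidence heuristic: starting from the bins overlapping the seed
    locus, extend left and right while bins stay at or above ``theta``.
    Returns new (start, end) in 1-based base coordinates.
    """
    bw = track.bin_width
    first = (te.start - 1) // bw
    last = (te.end - 1) // bw
    lo, hi = first, last
    while lo > 0 and track.values[lo - 1] >= theta:
        lo -= 1
    while hi + 1 < len(track.values) and track.values[hi + 1] >= theta:
        hi += 1
    return lo * bw + 1, min((hi + 1) * bw, (len(track.values) - 1) * bw
                            + bw)
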