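"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates the design of a paired mRNA/sRNA sequencing experiment comparing
an RNAi-pathway deletion mutant against the wild type: two strains with
three replicates each, negative-binomial counts with planted gene classes
(direct targets show mRNA up and sense-sRNA down in the mutant), a small
genome whose TE loci carry either a full LTR retroelement cassette
(protease-RVT-RNaseH-integrase) or an RVT-only fragment, CAG tandem
repeats inserted into direct-target transcripts, and luciferase reporter
tables with a strain effect for degraded constructs.

All randomness flows from one seed; sub-generators derive child seeds
deterministically, so every artifact is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import CountMatrix
from .reporter import ReporterTable
from .te import DOMAIN_LIBRARY

__all__ = [
    "SimConfig",
    "TruthLabels",
    "GenomeBundle",
    "generate_counts",
    "generate_genome",
    "generate_reporter",
    "generate_class_map",
]

PLANTED_LABELS = (
    "direct_target", "co_up", "co_down",
    "mrna_only_up", "mrna_only_down",
    "srna_only_up", "srna_only_down",
)

#: Planted class sizes sized after the published contingency table.
DEFAULT_PLANTED = {
    "direct_target": 35,
    "co_up": 239,
    "co_down": 173,
    "mrna_only_up": 373,
    "mrna_only_down": 169,
    "srna_only_up": 189,
    "srna_only_down": 962,
}

_KOG_CLASSES = list("CEGIJKLOPQT")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    n_genes
        Genes in the universe (default 10_000, roughly a compact fungal
        genome).
    n_replicates
        Biological replicates per strain (default 3, as in the study
        design).
    planted_counts
        Genes per non-null class; the remainder are null.
    effect_lfc
        Log2 fold-change magnitude of every planted effect (default 2).
    dispersion
        NB dispersion alpha with Var = mu + alpha*mu^2 (default 0.05,
        typical for biological replicates).
    mean_log_range
        Baseline log2 means drawn uniformly over this interval (default
        (3, 10): ~8 to ~1000 expected counts).
    library_size_sigma
        Lognormal sd of per-sample depth factors (default 0.1); not a
        study-reported quantity, chosen as mild realistic depth variation.
    n_te_loci
        (LTR-complete, RVT-only) locus counts (default (4, 5), the split
        reported for the nine TE targets).
    cag_units
        Consecutive CAG units inserted into each direct-target transcript
        (default 6).
    """

    n_genes: int = 10_000
    n_replicates: int = 3
    planted_counts: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    effect_lfc: float = 2.0
    dispersion: float = 0.05
    mean_log_range: tuple[float, float] = (3.0, 10.0)
    library_size_sigma: float = 0.1
    n_te_loci: tuple[int, int] = (4, 5)
    cag_units: int = 6
    gene_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.planted_counts) - set(PLANTED_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown planted labels: {sorted(unknown)}")
        if any(v < 0 for v in self.planted_counts.values()):
            raise ConfigurationError("planted counts must be non-negative")
        if sum(self.planted_counts.values()) > self.n_genes:
            raise ConfigurationError("planted counts exceed n_genes")
        if self.effect_lfc < 0:
            raise ConfigurationError("effect_lfc must be >= 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("need >=2 replicates per strain")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named sub-stream, derived from the seed."""
        key = zlib.crc32(stream.encode()) % 2**31
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class TruthLabels:
    """gene id -> planted label ('null' for unplanted genes)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate gene ids")

    def genes_with(self, label: str) -> list[str]:
        return sorted(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"gene_id": self.labels.index, "label": self.labels})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthLabels":
        df = pd.read_csv(path, sep="\t")
        return cls(pd.Series(df["label"].to_numpy(), index=df["gene_id"]))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               alpha: float) -> np.ndarray:
    """NB(mean, alpha) with Var = mu + alpha*mu^2; Poisson when alpha=0."""
    mean = np.maximum(mean, 1e-12)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def _assign_labels(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)
    labels = np.array(["null"] * config.n_genes, dtype=object)
    pos = 0
    for label in PLANTED_LABELS:
        k = config.planted_counts.get(label, 0)
        labels[order[pos:pos + k]] = label
        pos += k
    return pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"))


def _fold_vectors(labels: pd.Series, effect_lfc: float):
    """Per-gene mutant/WT fold change on the mRNA and sRNA axes."""
    eff = 2.0 ** effect_lfc
    fm = pd.Series(1.0, index=labels.index)
    fs = pd.Series(1.0, index=labels.index)
    fm[labels.isin(["direct_target", "co_up", "mrna_only_up"])] = eff
    fm[labels.isin(["co_down", "mrna_only_down"])] = 1 / eff
    fs[labels.isin(["co_up", "srna_only_up"])] = eff
    fs[labels.isin(["direct_target", "co_down", "srna_only_down"])] = 1 / eff
    return fm, fs


def generate_counts(config: SimConfig) -> tuple[CountMatrix, CountMatrix, TruthLabels]:
    """NB count matrices for mRNA and sense-strand sRNA libraries.

    For a direct-target gene the mutant mRNA mean is WT * 2**effect_lfc
    and the mutant sRNA mean is WT * 2**(-effect_lfc); the other planted
    classes follow their sign patterns; null genes have equal means.
    Per-sample depth factors are lognormal around 1.
    """
    rng = config.rng("counts")
    labels = _assign_labels(config, rng)
    lo, hi = config.mean_log_range
    mu_m = 2.0 ** rng.uniform(lo, hi, config.n_genes)
    mu_s = 2.0 ** rng.uniform(lo, hi, config.n_genes)
    fm, fs = _fold_vectors(labels, config.effect_lfc)

    def matrix(mu_base: np.ndarray, fold: pd.Series, molecule: str) -> CountMatrix:
        cols, data, meta = [], [], []
        for strain, f in (("WT", np.ones(config.n_genes)), ("mutant", fold.to_numpy())):
            for rep in range(1, config.n_replicates + 1):
                depth = rng.lognormal(0.0, config.library_size_sigma)
                data.append(_nb_sample(rng, mu_base * f * depth, config.dispersion))
                name = f"{strain}_{rep}"
                cols.append(name)
                meta.append({"sample": name, "strain": strain,
                             "replicate": rep, "molecule": molecule})
        counts = pd.DataFrame(np.stack(data, axis=1), index=labels.index,
                              columns=cols)
        samples = pd.DataFrame(meta).set_index("sample")
        lengths = pd.Series(float(config.gene_length), index=labels.index)
        return CountMatrix(counts, samples, lengths)

    mrna = matrix(mu_m, fm, "mRNA")
    srna = matrix(mu_s, fs, "sRNA")
    return mrna, srna, TruthLabels(labels)


# --- genome construction ---------------------------------------------------

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_LINKER = "GGSGS"
_AA20 = sorted(_CODON)

# Clade-defining substitution positions in the RVT consensus: LTR loci share
# one set, RVT-only (LINE-like) loci another, giving the phylogeny two
# well-separated clades.
_LTR_CLADE_POS = (5, 17, 29, 41)
_LINE_CLADE_POS = (11, 23, 35, 47)


def _reverse_translate(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


def _mutate(peptide: str, positions, replacement: str) -> str:
    chars = list(peptide)
    for pos in positions:
        chars[pos] = replacement if chars[pos] != replacement else "Y"
    return "".join(chars)


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """Stop-free random coding sequence (keeps ORF structure plausible)."""
    aa = rng.choice(_AA20, size=n_codons)
    return "".join(_CODON[a] for a in aa)


@dataclass
class GenomeBundle:
    """Contigs, gene annotation, transcript sequences and TE locus info."""

    contigs: dict[str, str]
    genes: pd.DataFrame            # gene_id, contig, start, end, strand
    transcripts: dict[str, str]
    te_loci: pd.DataFrame          # locus_id, contig, start, end, planted_class

    def features(self) -> pd.DataFrame:
        g = self.genes.rename(columns={"gene_id": "ID"}).copy()
        g["type"] = "gene"
        t = self.te_loci.rename(columns={"locus_id": "ID"}).copy()
        t["type"] = "mobile_genetic_element"
        cols = ["contig", "type", "start", "end", "strand", "ID"]
        t["strand"] = "+"
        return pd.concat([g[cols], t[cols]], ignore_index=True)


def _rvt_variant(rng: np.random.Generator, clade: str, index: int) -> str:
    base = DOMAIN_LIBRARY["RVT"]
    positions = _LTR_CLADE_POS if clade == "LTR" else _LINE_CLADE_POS
    pep = _mutate(base, positions, "W" if clade == "LTR" else "F")
    # two private substitutions per locus keep within-clade resolution
    forbidden = set(_LTR_CLADE_POS) | set(_LINE_CLADE_POS)
    free = [i for i in range(len(base)) if i not in forbidden]
    priv = rng.choice(free, size=2, replace=False)
    chars = list(pep)
    for pos in priv:
        choices = [a for a in _AA20 if a != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _te_peptide(rng: np.random.Generator, clade: str, index: int) -> str:
    rvt = _rvt_variant(rng, clade, index)
    if clade == "LTR":
        return ("M" + DOMAIN_LIBRARY["protease"] + _LINKER + rvt + _LINKER
                + DOMAIN_LIBRARY["RNaseH"] + _LINKER
                + DOMAIN_LIBRARY["integrase"])
    pad = _LINKER * 4
    return "M" + pad + rvt + pad


def generate_genome(config: SimConfig) -> GenomeBundle:
    """Small genome with genes, CAG-bearing targets and TE cassettes.

    Each LTR-complete locus encodes, in one forward-strand ORF, the four
    cassette domains in order protease < RVT < RNaseH < integrase; each
    RVT-only locus encodes only the (clade-mutated) RVT motif.  Every
    direct-target transcript contains at least ``cag_units`` consecutive
    CAG units.  GFF3-style coordinates are 1-based inclusive.
    """
    rng = config.rng("genome")
    # label assignment must match generate_counts: reuse that stream
    labels = _assign_labels(config, config.rng("counts"))

    spacer = "T" * 200
    parts: list[str] = []
    gene_rows: list[dict] = []
    te_rows: list[dict] = []
    transcripts: dict[str, str] = {}
    pos = 0

    def push(seq: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        parts.append(seq)
        pos += len(seq)
        return start, pos

    n_codons = config.gene_length // 3
    cag = "CAG" * config.cag_units
    n_ltr, n_line = config.n_te_loci
    te_specs = ([("LTR", i) for i in range(n_ltr)]
                + [("LINE", i) for i in range(n_line)])
    n_total_te = len(te_specs)
    te_every = max(1, config.n_genes // (n_total_te + 1)) if n_total_te else None

    te_index = 0
    pending_te = False
    label_arr = labels.to_numpy()
    for gi, (gene_id, label) in enumerate(labels.items()):
        push(spacer)
        seq = _random_coding(rng, n_codons)
        if label == "direct_target":
            mid = (len(seq) // 6) * 3
            seq = seq[:mid] + cag + seq[mid:]
        start, end = push(seq)
        gene_rows.append({"gene_id": gene_id, "contig": "contig_1",
                          "start": start, "end": end, "strand": "+"})
        transcripts[gene_id] = seq
        if te_every and te_index < n_total_te and (gi + 1) % te_every == 0:
            pending_te = True
        # TE loci sit between two null (non-DE) genes so that the
        # adjacent-gene silencing check is meaningful on synthetic data
        if (pending_te and label == "null"
                and gi + 1 < len(label_arr) and label_arr[gi + 1] == "null"):
            pending_te = False
            clade, idx = te_specs[te_index]
            pep = _te_peptide(rng, clade, idx)
            te_seq = _reverse_translate(pep) + "TAA"
            push(spacer)
            t_start, t_end = push(te_seq)
            te_rows.append({"locus_id": f"TE{te_index + 1:03d}",
                            "contig": "contig_1", "start": t_start,
                            "end": t_end,
                            "planted_class": ("LTR_complete" if clade == "LTR"
                                              else "RVT_only")})
            te_index += 1
    push(spacer)

    contigs = {"contig_1": "".join(parts)}
    return GenomeBundle(contigs, pd.DataFrame(gene_rows), transcripts,
                        pd.DataFrame(te_rows, columns=["locus_id", "contig",
                                                       "start", "end",
                                                       "planted_class"]))


def generate_class_map(config: SimConfig) -> pd.DataFrame:
    """Random KOG-style class assignment (gene_id, class) over all genes."""
    rng = config.rng("classes")
    labels = _assign_labels(config, config.rng("counts"))
    classes = rng.choice(_KOG_CLASSES, size=config.n_genes)
    return pd.DataFrame({"gene_id": labels.index, "class": classes})


def generate_reporter(config: SimConfig, degraded_fraction: float = 0.5,
                      ratio: float = 4.0, n_constructs: int = 4,
                      n_replicates: int | None = None,
                      noise_sigma: float = 0.2) -> tuple[ReporterTable, pd.Series]:
    """Reporter table with a strain effect for degraded constructs.

    For a degraded construct the WT mean normalized emission is lower than
    the mutant mean by ``ratio``; replicate noise is lognormal.  Returns
    the table and the per-construct truth (degraded yes/no).
    """
    if not (0 <= degraded_fraction <= 1):
        raise ConfigurationError("degraded_fraction must be in [0, 1]")
    rng = config.rng("reporter")
    n_rep = n_replicates if n_replicates is not None else config.n_replicates
    n_degraded = round(degraded_fraction * n_constructs)
    rows = []
    truth = {}
    base_rlu = 1000.0
    for ci in range(1, n_constructs + 1):
        construct = f"construct_{ci}"
        degraded = ci <= n_degraded
        truth[construct] = degraded
        for strain in ("WT", "mutant"):
            mean = base_rlu / ratio if (degraded and strain == "WT") else base_rlu
            for rep in range(1, n_rep + 1):
                fluor = rng.lognormal(np.log(100.0), noise_sigma)
                rlu = mean * fluor / 100.0 * rng.lognormal(0.0, noise_sigma)
                rows.append({"construct": construct, "strain": strain,
                             "replicate": rep, "rlu": rlu, "fluor": fluor})
    table = ReporterTable(pd.DataFrame(rows))
    return table, pd.Series(truth)
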