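"""End-to-end orchestration: simulate -> DE -> integrate -> downstream.

One entry point, :func:`run_pipeline`, wires the stages together on a run
directory: differential analysis of mRNA and sRNA counts, sign-pattern
classification with the contingency summary, functional-class enrichment,
CAG-motif enrichment of direct targets against a random background, TE
annotation with an adjacent-gene silencing check, and a bootstrapped NJ
phylogeny of the RVT domains extracted from the annotated TE loci.
Everything derives from one seed, so a rerun reproduces every output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, enrich, integrate, io, motif, phylo, simulate, te
from .de import DEThresholds

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ncrip")


@dataclass
class PipelineConfig:
    """Every tunable of the full run, with study defaults.

    The thresholds mirror the published analysis: FDR <= 0.05 and
    |log2FC| >= 1 for significance, CAG runs of >= 4 units, 25-bp
    coverage bins, 1000 bootstrap replicates.
    """

    out_dir: str = "ncrip_run"
    seed: int = 0
    sim: simulate.SimConfig | None = None
    fdr: float = 0.05
    lfc_min: float = 1.0
    motif_min_units: int = 4
    orf_min_len_aa: int = 100
    coverage_bin: int = 25
    phylo_model: str = "poisson"
    bootstrap_reps: int = 1000
    mrna_counts: str | None = None   # paths for user-supplied inputs
    srna_counts: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            cfg.sim = simulate.SimConfig(**sim_raw)
        return cfg


def _stage(name: str):
    log.info("stage %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages into ``config.out_dir``; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = DEThresholds(config.fdr, config.lfc_min)
    summary: dict = {"seed": config.seed}

    sim_cfg = config.sim or simulate.SimConfig(seed=config.seed)

    t0 = _stage("simulate")
    if config.mrna_counts and config.srna_counts:
        mrna = de.CountMatrix.from_tsv(config.mrna_counts)
        srna = de.CountMatrix.from_tsv(config.srna_counts)
        truth = None
        genome = None
    else:
        mrna, srna, truth = simulate.generate_counts(sim_cfg)
        genome = simulate.generate_genome(sim_cfg)
        mrna.to_tsv(out / "counts_mrna.tsv")
        srna.to_tsv(out / "counts_srna.tsv")
        truth.to_tsv(out / "truth_labels.tsv")
        io.write_fasta(genome.contigs, out / "genome.fa")
        io.write_fasta(genome.transcripts, out / "transcripts.fa")
        io.write_gff3(genome.features(), out / "genome.gff3")
    log.info("simulate done in %.1fs", time.time() - t0)

    t0 = _stage("de")
    mrna_de = de.nb_wald_test(mrna, thresholds=thresholds)
    srna_de = de.nb_wald_test(srna, thresholds=thresholds)
    mrna_de.to_tsv(out / "de_mrna.tsv")
    srna_de.to_tsv(out / "de_srna.tsv")
    log.info("de done in %.1fs", time.time() - t0)

    t0 = _stage("integrate")
    classification = integrate.classify(mrna_de, srna_de)
    classification.to_tsv(out / "classification.tsv")
    cls_summary = integrate.summarize(classification)
    targets = integrate.direct_targets(classification)
    summary["classification"] = cls_summary.to_dict()
    summary["n_direct_targets"] = len(targets)
    (out / "direct_targets.txt").write_text("\n".join(targets) + "\n")
    if truth is not None:
        planted = set(truth.genes_with("direct_target"))
        called = set(targets)
        tp = len(planted & called)
        summary["recovery"] = {
            "planted": len(planted), "called": len(called), "tp": tp,
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "precision": tp / len(called) if called else float("nan"),
        }
    log.info("integrate done in %.1fs", time.time() - t0)

    t0 = _stage("enrich")
    class_map_df = simulate.generate_class_map(sim_cfg) if truth is not None else None
    if class_map_df is not None:
        class_map_df.to_csv(out / "kog_classes.tsv", sep="\t", index=False)
        cmap = enrich.ClassMap(
            pd.Series(class_map_df["class"].to_numpy(),
                      index=class_map_df["gene_id"]),
            pd.Index(mrna_de.table.index))
        scores = mrna_de.table["log2FC"].fillna(0.0)
        table = enrich.enrichment_table(cmap, scores, gene_set=set(targets))
        table.to_csv(out / "enrichment.tsv", sep="\t")
    log.info("enrich done in %.1fs", time.time() - t0)

    t0 = _stage("motif")
    if genome is not None:
        target_seqs = {g: genome.transcripts[g] for g in targets
                       if g in genome.transcripts}
        pool = sorted(set(genome.transcripts) - set(targets))
        bg_ids = motif.sample_background(pool, min(len(target_seqs), len(pool)),
                                         seed=config.seed)
        bg_seqs = {g: genome.transcripts[g] for g in bg_ids}
        if target_seqs and bg_seqs:
            counts2x2, p = motif.motif_enrichment(target_seqs, bg_seqs,
                                                  config.motif_min_units)
            summary["motif"] = {**counts2x2, "fisher_p": p}
            hits = []
            for gid, seq in target_seqs.items():
                for h in motif.find_cag_repeats(seq, config.motif_min_units, gid):
                    hits.append({"seq_id": h.seq_id, "start": h.start,
                                 "end": h.end, "n_units": h.n_units})
            pd.DataFrame(hits, columns=["seq_id", "start", "end", "n_units"]
                         ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    log.info("motif done in %.1fs", time.time() - t0)

    t0 = _stage("te")
    rvt_rows: dict[str, str] = {}
    if genome is not None and not genome.te_loci.empty:
        te_reports = []
        for _, row in genome.te_loci.iterrows():
            seq = genome.contigs[row["contig"]][row["start"] - 1:row["end"]]
            model = te.annotate_locus(row["locus_id"], row["contig"],
                                      row["start"], row["end"], seq,
                                      min_len_aa=config.orf_min_len_aa)
            verdicts = te.adjacent_gene_check(model, genome.genes,
                                              mrna_de, srna_de)
            te_reports.append({
                "locus_id": model.locus_id, "te_class": model.te_class,
                "partial": model.partial,
                "domains": ",".join(sorted({h.domain for h in model.hits})),
                "neighbors_unchanged": all(v == "unchanged"
                                           for v in verdicts.values()),
            })
            for h in model.hits:
                if h.domain == "RVT":
                    pep = model.orfs[h.orf_index].peptide
                    L = len(te.DOMAIN_LIBRARY["RVT"])
                    rvt_rows[model.locus_id] = pep[h.aa_offset - 1:
                                                   h.aa_offset - 1 + L]
        te_df = pd.DataFrame(te_reports)
        te_df.to_csv(out / "te_report.tsv", sep="\t", index=False)
        summary["te"] = {
            "n_ltr_complete": int((te_df["te_class"] == "LTR_complete").sum()),
            "n_rvt_only": int((te_df["te_class"] == "RVT_only").sum()),
            "all_neighbors_unchanged": bool(te_df["neighbors_unchanged"].all()),
        }
    log.info("te done in %.1fs", time.time() - t0)

    t0 = _stage("phylo")
    if len(rvt_rows) >= 3:
        aln = phylo.Alignment(list(rvt_rows), list(rvt_rows.values()))
        aln.to_fasta(out / "rvt_alignment.fa")
        tree = phylo.bootstrap(aln, n_reps=config.bootstrap_reps,
                               model=config.phylo_model, seed=config.seed)
        newick = phylo.write_newick(tree)
        (out / "rvt_tree.nwk").write_text(newick + "\n")
        summary["phylo"] = {"n_taxa": aln.n_seqs,
                            "newick_len": len(newick)}
    log.info("phylo done in %.1fs", time.time() - t0)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
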