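# ncrip

Identification of direct targets of the **non-canonical RNAi pathway
(NCRIP)** of *Mucor lusitanicus* from paired mRNA and small-RNA sequencing
of an `r3b2`Δ mutant versus the wild type — as a tested, reusable Python
pipeline with a synthetic-data generator carrying known ground truth.

NCRIP degrades specific mRNAs through the atypical RNase III R3B2,
producing small RNAs *sense* to the transcript. Deleting `r3b2` therefore
leaves a characteristic footprint at a direct target: its **mRNA rises**
(no more degradation) while its **sense sRNAs fall** (no more degradation
products). The package implements that signature end to end:

1. **Differential expression** (`ncrip.de`) — a compact NB pipeline per
   molecule class: median-of-ratios size factors, method-of-moments
   dispersion `α̂ = max(floor, (s² − μ̄)/μ̄²)` with Var = μ + αμ², a Wald
   test on `log2FC = log2((μ̂_mut + ½)/(μ̂_WT + ½))`, BH correction, and the
   study thresholds (FDR ≤ 0.05, |log2FC| ≥ 1). FPKM normalization included.
2. **Integration** (`ncrip.integrate`) — the sign-pattern partition
   (+sRNA,+mRNA), (−sRNA,−mRNA), (−sRNA,+mRNA = **direct target**),
   (+sRNA,−mRNA), single-axis and unchanged classes, with the
   contingency-table marginal identities, plus cross-condition DEG
   comparison with direction concordance.
3. **Enrichment** (`ncrip.enrich`) — per KOG class, the signed
   **delta-rank** (mean rank inside the class minus mean rank outside,
   Mann–Whitney U) and one-sided Fisher over-representation.
4. **Motif** (`ncrip.motif`) — a deterministic scanner for maximal runs of
   ≥ 4 consecutive CAG units (any phase, sense strand) and a Fisher test of
   presence in direct targets versus a seeded random gene background.
5. **TE annotation** (`ncrip.te`) — six-frame translation, ORF capture,
   consensus-based domain scanning, and classification into
   `LTR_complete` (protease + RVT + RNase H + integrase) versus `RVT_only`
   (truncated / LINE-like), with an adjacent-gene silencing check and
   25-bp bins-per-million coverage tracks.
6. **Phylogeny** (`ncrip.phylo`) — neighbor joining on pairwise-deletion
   amino-acid distances (p, Poisson, or a JTT-motivated correction) of RVT
   domains, 1000-replicate column bootstrap, Newick output.
7. **Reporter assays** (`ncrip.reporter`) — calcofluor-normalized
   luciferase statistics (unpaired t-test per construct) and ΔΔCt qPCR
   fold changes.
8. **Simulator** (`ncrip.simulate`) — NB counts with planted gene classes,
   a small genome whose TE loci carry full or truncated retroelement
   cassettes, CAG repeats inserted into direct-target transcripts, and
   reporter tables; everything derived deterministically from one seed.

## Worked example

One command runs the whole pipeline on synthetic data (10 000 genes,
planted classes sized after the published study, 3 replicates per strain):

```bash
ncrip run --out demo --seed 7
```

prints the classification cells

```json
{
  "co_up": 234, "co_down": 149, "direct_target": 32, "anti_target": 1,
  "mrna_only_up": 379, "mrna_only_down": 164,
  "srna_only_up": 209, "srna_only_down": 900, "unchanged": 7932
}
```

and `demo/summary.json` holds the rest of the run, including

```json
"recovery": {"planted": 35, "called": 32, "tp": 32,
             "sensitivity": 0.914, "precision": 1.0},
"motif":    {"targets_with_motif": 32, "targets_total": 32,
             "background_with_motif": 0, "background_total": 32,
             "fisher_p": 5.5e-19},
"te":       {"n_ltr_complete": 4, "n_rvt_only": 5,
             "all_neighbors_unchanged": true}
```

Reading: of 35 planted direct targets, 32 were recovered with no false
positives; every recovered target's transcript carries the planted CAG
tandem repeat while none of 32 random background genes does; and the nine
TE loci split into four full LTR cassettes and five RVT-only elements, with
all TE-adjacent genes unchanged in both DE tables. Individual stages are
also available (`ncrip de`, `ncrip integrate`, `ncrip enrich`,
`ncrip motif`, `ncrip phylo`, `ncrip reporter`) and as library functions.

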