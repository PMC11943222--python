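# Methods

## The inference problem

A direct target of the R3B2-centred non-canonical RNAi pathway is defined
operationally: in the `r3b2`Δ mutant its mRNA accumulates (call `up` at
FDR ≤ 0.05 and log2FC ≥ 1) while its sense-derived small RNAs deplete
(call `down` under the same thresholds on the sRNA table). The pipeline
therefore runs the same two-group differential test twice — once per
molecule class — and intersects the sign patterns. All other pattern
combinations are retained as their own classes (co-regulated, single-axis,
unchanged), so the output is a partition of the union of both gene
universes and every marginal of the classification table is an arithmetic
identity over the cells.

## Count model and differential test

Counts are modelled as negative binomial with mean μ and dispersion α,
Var = μ + αμ². Per sample, a median-of-ratios size factor is estimated
against the geometric-mean pseudo-reference over genes positive in every
sample. Per gene, α is estimated by method of moments on normalized
counts, with the variance pooled *within* strain (degrees-of-freedom
weighted) so condition effects do not inflate it:
α̂ = max(10⁻⁸, (s² − μ̄)/μ̄²).

The Wald statistic is z = log2FC / SE with
log2FC = log2((μ̂_mut + ½)/(μ̂_WT + ½)) (the ½ pseudo-count stabilizes
zeros) and, by the delta method,
SE² = [v_WT/(n_WT(μ̂_WT+½)²) + v_mut/(n_mut(μ̂_mut+½)²)]/ln²2 with
v = μ̂ + αμ̂². Two-sided normal p-values are BH-adjusted over the tested
genes; genes with zero counts in every sample are excluded before
correction and reported with NaN p-values.

**Dispersion moderation.** At two or three replicates per group the raw
moments estimator of α has only ~4 degrees of freedom; plugging it into a
normal Wald test is anticonservative (empirically ≈ 0.10 rejection at
nominal 0.05). `nb_wald_test` therefore floors each gene's α̂ at the
median α̂ across tested genes — a trend-free, one-parameter analogue of
the empirical-Bayes moderation mature DE tools apply. This restores
calibration (≈ 0.05 empirically) without measurable power loss, because
only genes whose dispersion was *under*-estimated are affected. It can be
disabled (`moderate_dispersion=False`). No shrinkage toward a
mean–dispersion trend is performed; exact per-gene agreement with DESeq2
is explicitly not a contract of this module — the preserved semantics are
the thresholds (FDR ≤ 0.05, |log2FC| ≥ 1) and the NB Wald structure.

## Enrichment statistics

For each functional class, the delta-rank is the mean ascending rank
(average ranks on ties) of the class members' scores (log2FC by default;
the ranked quantity is configurable) minus the mean rank of all other
genes; positive values mean the class shifts upward. Significance uses
the Mann–Whitney U normal approximation with tie correction; an empty
class or one covering the universe degenerates to (0, p = 1).
Over-representation of a gene set in a class is the one-sided
hypergeometric upper tail of the 2×2 table over the universe. Raw p ≤
0.05 flags enrichment, matching common KOG-scan practice; BH across
classes is available but off by default.

## CAG repeat scanner

The scanner reports maximal runs of consecutive, uninterrupted CAG units
(T ≡ U; any phase; sense strand only; no reverse-complement scan) of at
least `min_units` (default 4 — multi-unit runs are the biologically
motivated signal, but no published length threshold exists, so the cutoff
is exposed). Interrupted repeats (CAA/CAG mixtures) are deliberately not
counted: pure tandem repeats are the simplest defensible definition.
Enrichment compares per-sequence presence between targets and an
equal-sized, seeded uniform sample of non-target genes with a one-sided
Fisher test.

## TE annotation

Loci are six-frame translated (standard code, stops as `*`, N-codons as
`X`, trailing partial codons dropped); maximal stop-free stretches ≥ 100
aa are captured both from their first residue and from their first
internal methionine. Domain detection slides five bundled amino-acid
consensus strings (protease, RVT, RNase H, integrase, transposase; 18–62
aa) over each ORF and accepts the best placement within a Hamming budget
of 25 % of the consensus length, ties to the leftmost position. The
consensus strings are fixed synthetic motifs: they make the annotation
deterministic and dependency-free and are guaranteed only against
cassettes built by the simulator — they are not Pfam/InterPro profiles
and make no sensitivity claim on real genomes. Classification is a
function of the hit-name set alone: all four cassette domains ⇒
`LTR_complete`; exactly {RVT} ⇒ `RVT_only`; anything else ⇒ `none`
(flagged partial when non-empty).

Coverage tracks count reads overlapping fixed 25-bp bins, normalized to
bins per million mapped reads (BPM). Boundary refinement extends a seed
locus over the contiguous run of bins with BPM ≥ θ (default 1.0); this is
a flagged heuristic, as no published algorithm exists for that step.
Neighbouring genes (nearest non-overlapping gene on each side, window
configurable) are "unchanged" iff non-significant (or absent) in both DE
tables.

## Phylogeny

Distances use pairwise deletion of gap columns. Available corrections:
`p` (mismatch fraction), `poisson` (−ln(1−p)), and `jtt_like`
(−ln(1 − p − 0.2p²)), a closed-form curvature correction standing in for
matrix-based ML distances; no Γ rate heterogeneity or extra scaling is
applied, and pairs beyond the correction's domain raise a saturation
error naming the pair. `poisson` is the default: distance-NJ workflows
described as "JTT" in tree viewers are not bit-reproducible anyway, and
the meaningful contract here is topology-level. Neighbor joining follows
the Saitou–Nei Q criterion with deterministic lexicographic tie-breaking;
negative branch lengths are clamped to zero with the deficit moved to the
sister branch, preserving path lengths. Bootstrap resamples columns with
replacement (default 1000 replicates, seeded); support is the percentage
of replicates containing each internal bipartition of the point-estimate
tree. Newick serialization writes branch lengths and integer supports as
internal labels and round-trips through the module's parser.

## Reporter statistics

Luminescence is normalized per well as RLU/fluorescence (calcofluor
biomass proxy); per-construct averaging is available as an option. The
degradation test is an unpaired two-sided t-test, pooled-variance by
default (a plain "unpaired t-test" is the reference analysis) with a
Welch flag, reporting the mutant/WT ratio of mean normalized emission —
a ratio > 1 with small p indicates the construct is degraded in the wild
type. ΔΔCt fold change is 2^(−ΔΔCt) against a shared reference gene,
assuming matched amplification efficiencies.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the analysis
assumes: two strains × 3 replicates; NB counts with Var = μ + αμ²
(α default 0.05) so the simulator and the test share one model and
recovery is well-posed; baseline log2 means uniform on [3, 10] (≈ 8–1000
counts, a realistic dynamic range without heavy tails); planted classes
sized after the published contingency table (35 direct targets, 239
co-up, 173 co-down, 373/169 mRNA-only, 189/962 sRNA-only, remainder
null); every planted effect a clean ±2 log2 units; mild lognormal
library-depth variation (σ = 0.1 — replicate depth variability is not
reported anywhere, so this default is documented rather than derived).
sRNA counts are generated sense-strand only, mirroring the degradation
products the pathway produces; antisense signal is not simulated.

The genome places one forward-strand gene per locus on a single contig,
inserts `cag_units` (default 6) consecutive CAG units into each
direct-target transcript, and drops nine TE loci (4 full-cassette, 5
RVT-only) at junctions between two *null* genes so the adjacent-gene
silencing check is meaningful. RVT domains carry four clade-defining
substitutions per TE family plus two private ones per locus, giving the
bootstrap a recoverable two-clade structure. Reporter tables draw
lognormal noise (σ = 0.2) around a 4-fold WT deficit for degraded
constructs.

Consequences for interpretation: passing recovery tests shows the
pipeline correctly inverts its own generative model at study scale — it
does not show robustness to features real data have and the simulator
lacks (outlier replicates, mean–dispersion trends, overlapping genes,
multi-mapping sRNA reads, interrupted repeats, real TE sequence
divergence).

## Numerical and design choices

- Size factors require at least one gene positive in all samples;
  otherwise a normalization error is raised rather than silently falling
  back.
- BH is delegated to `statsmodels.multipletests` behind `bh_adjust`; the
  step-up arithmetic is verified against a brute-force oracle in tests.
- All-tied score vectors short-circuit the MWU to p = 1 (the tie-corrected
  normal approximation is undefined there).
- Coordinates are 1-based inclusive throughout (GFF3 convention),
  including motif hits.
- NJ tie-breaks and the domain scanner's leftmost rule make every output
  deterministic; the pipeline derives all stage seeds from one global
  seed.
- Problem sizes in tests and the acceptance script (10⁴ genes for
  recovery and calibration, 100 × 10-kb sequences for the scanner oracle,
  ≤ 30-gene universes for exact enumeration, ≤ 10-taxon additive
  matrices) are the package's chosen verification scale: large enough for
  stable Monte-Carlo bands, small enough to run on a laptop in seconds.

## Known limitations

- The DE module supports exactly two groups; no covariates, interaction
  designs, outlier replacement, or dispersion–mean trends.
- Sensitivity of direct-target recovery at n = 3 is power-limited for
  genes at the bottom of the expression range (observed ≈ 0.86–0.94
  across seeds at effect 2 log2 units); precision is consistently high
  because a false direct call needs coincident false positives on both
  axes.
- The domain library and the `jtt_like` correction are simplified,
  deterministic stand-ins; real-genome TE annotation should use profile
  HMMs and proper substitution models.
- De novo motif discovery is out of scope: the CAG scanner tests a
  pre-specified repeat class, it does not rediscover it.
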