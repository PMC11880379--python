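# Methods

`skelconv` quantifies how three embryonic lineages — cranial neural crest
(NC), somitic sclerotome (SOM) and lateral-plate mesoderm (LPM) — converge
on a shared early-chondrogenic transcriptome while retaining
lineage-specific trans- and cis-regulatory inputs. This note documents the
models, the synthetic cohort the package tests itself against, and the
numerical choices a user should know about.

## The analysis model

**Normalization and pseudobulks.** UMI and fragment counts are
depth-normalized per cell, `ln(1 + 10^4 · x / total)`; the scale factor and
natural log are conventions (the choice is irrelevant to every rank-based
statistic downstream). Pseudobulks are arithmetic means of normalized
values over labeled cell groups. Cross-group agreement is Spearman's rho on
a restricted feature set, co-clustered by average-linkage agglomeration on
the distance 1 − rho. A "verdict" (e.g., the three early-chondrogenic
pseudobulks forming an exclusive clade) is a statement about the dendrogram
topology: the designated groups are exactly the leaf set of some internal
node.

**Variable features.** Per-feature variance is standardized by a
trend-predicted standard deviation (lowess of log10 variance on log10 mean
across features, values clipped at √n_cells); features above the median
plus the unscaled median absolute deviation (MAD) of the standardized
variances are called highly variable. With few features the local trend can
absorb an isolated outlier, so planted-variance checks keep the outlier's
mean inside the feature cloud.

**Quality control.** RNA cells are dropped when total UMI > 4× the sample
mean or < 0.2× the sample median; when the mitochondrial fraction exceeds
median + 3×MAD *and* 0.1 (cells above the median depth are spared); or when
genes-per-UMI < 0.15 (cells detecting ≥ 2/3 of the sample maximum gene
count are spared — the printed exception clause is ambiguous, and the
opposite reading is selectable via `RnaQcThresholds.spare_low_genes`).
Sample statistics are computed once; re-filtering with the recorded
`frozen_stats` is idempotent. ATAC barcodes pass when fragments-in-peaks
lies in the closed range [1000, 100000], FRiP > 0.15, nucleosome signal
(mono-nucleosome/nucleosome-free length-count ratio) < 4 and TSS enrichment
> 2. TSS enrichment is the mean insertion rate within ±50 bp of TSSs over
the rate in the ±(1901–2000) bp flanks; the pseudocount of 0.1 added to
both rates is expressed in units of the barcode's genome-wide mean
insertion rate, which makes the score invariant to sequencing depth and
genome size (an absolute per-base pseudocount would dominate single-cell
coverage and pin the score at 1).

**Marker testing.** One logistic regression per feature: group membership ~
feature value + latent covariates, versus covariates alone, scored by a
1-df likelihood-ratio chi-square. Newton iterations are vectorized across
features (the covariate block is shared); `statsmodels.Logit` serves as the
independent oracle in the tests. Perfect separation is detected by
non-convergence or runaway coefficients and re-fit with a small L2 ridge
(flagged `separation_penalized`). Adjustment is Bonferroni by default, BH
selectable. Features enter only when detected in ≥ 10% of either group;
log-fold-change is `ln((mean(expm1 x)_in + 1)/(mean(expm1 x)_out + 1))`, and a
marker passes at adjusted p < 0.05 with log-FC above 0.25 (fine) / 0.5
(broad).

**Peaks.** Summits are extended to fixed width (501 bp, odd so the summit
is the exact center); windows spilling past a chromosome end are dropped
rather than truncated, preserving width homogeneity. Overlaps are resolved
by significance-greedy "iterative overlap": keep the most significant peak,
discard everything overlapping it, repeat (ties by chromosome, then start).
Consensus sets merge per-lineage peaks with the same rule, recording
contributing origins. Categories: *promoter* when overlapping the
strand-aware window (−2000, +100) around any TSS, else *intronic* when
inside a gene body, else *intergenic*; the three-way reporting folds exonic
into intronic. Category enrichment of differential peaks against the
consensus uses a two-sided binomial test. Promoter-vs-distal similarity
compares, per lineage pair, Spearman's rho of pseudobulk accessibility over
promoter-proximal differential peaks against a distribution of equal-size
random distal draws (n_resamples, default 80), summarized by a two-sided
Mann–Whitney test.

**Trajectories.** Pseudotime is an input (planted truth, or user-provided
from any trajectory-inference tool). Cells are binned into equal-width
pseudotime intervals (right-closed, lowest edge included); empty bins are
dropped. For cross-lineage alignment, each feature's bin-mean profile is
linearly interpolated at 40 equidistant points between the outermost bin
centers; the point-pair dissimilarity is 1 − Spearman rho across shared
features; dynamic time warping (steps diagonal/up/left) runs from every
admissible boundary start to every boundary end, and the cut pair
minimizing the mean path cost wins (ties go to the fewest unmatched
terminals). Cuts are capped at 50% of either trajectory (`max_cut`):
without the cap, the minimum-mean-cost criterion collapses onto one cheap
corner cell. Cut-off terminal indices are reported as unmatched, mirroring
trajectory sections that fail to align between lineages. Pseudotime
transfer to ATAC cells is a Spearman-correlation kNN on jointly z-scored
shared features of the RNA matrix and the ATAC gene-activity matrix (sum of
peak counts over gene body plus 2 kb upstream of the TSS), with
similarity-weighted averaging of the k = 10 nearest RNA cells'
pseudotimes.

**Motifs.** PWMs are 4×L column-stochastic matrices. Per-column information
content is `2 + Σ p log2 p` bits; trimming strips terminal runs below 0.25
bits from both ends (never below length 4) and is idempotent. Similarity is
the maximum, over all ungapped offsets with overlap ≥ max(5, ⌈0.75·min(L_a,
L_b)⌉) and over the reverse complement, of the mean column-wise Pearson
correlation; uniform column pairs correlate 1 when identical, else 0.
Redundancy removal links motifs with similarity > 0.8 and keeps the lowest
discovery p per connected component. Per-cell deviations follow the
chromVAR construction: expected counts from the motif set's share of total
accessibility times cell depth; raw deviation (obs − exp)/exp; z-scored
against 50 background sets built by resampling each member peak's nearest
neighbors in z-scored (GC, log mean accessibility) space. De-novo motif
annotation gates reference candidates at similarity ≥ 0.6 and ≥ 5%
expressing cells, then ranks by the Spearman correlation between aggregate
mean motif deviation and aggregate mean TF expression (400 aggregates of
50 cells, with replacement; 200×20 for populations under 500 cells — the
aggregate-count/cell-count reading of "k, n" is a documented choice).

**Links and conservation.** Peak-to-gene links are Pearson correlations of
depth-normalized accessibility and (pseudo)expression over cell aggregates.
Aggregates pool *neighboring* cells (kNN in a pseudotime embedding, 500
aggregates × 100 cells): uniform random pooling would average trajectory
variation out of both modalities and erase every dynamics-driven link.
Candidate pairs are peaks whose center is within ±250 kb of a TSS; p-values
come from the t distribution with n_aggregates − 2 df, BH-adjusted per
lineage; retention requires r ≥ 0.45 and FDR < 1e-4 (all configurable —
these defaults are this package's, not published values). Because
aggregates overlap heavily when the population is small, the nominal df
overstate independence; precision against planted truth improves with
population size, which is why recovery claims are made at the default
cohort scale. `hkmeans` clusters z-scored link activity by Ward
initialization plus k-means refinement and is deterministic. Conservation
is the arithmetic per-base mean of a bedGraph track over each element
(uncovered bases score 0 and lower the recorded covered fraction), grouped
by cross-lineage sharing.

## The synthetic cohort

The generator plants, with one RNG seeded per subsystem, exactly the
structure the analysis claims to detect:

- **Cells.** Three lineages × 1500 cells by default, pseudotime t ~ U(0,1),
  clusters PC/other/EC by pseudotime terciles. Embryonic stage follows
  pseudotime only loosely (30% weight) — each stage sample spans the whole
  differentiation spectrum, as in real embryos — so stage can serve as a
  latent covariate without absorbing the signal.
- **RNA.** Negative binomial (dispersion r = 5) around
  `exp(baseline + effects) × depth`, depth lognormal. The chondrogenic
  module (17 + 41 genes) rises along a sigmoid in *every* lineage with
  per-gene baselines, amplitudes and staggered switch-points shared across
  lineages — staggering is what lets chromatin state encode position along
  the whole trajectory, and gene-specific magnitudes are what make
  cross-lineage profiles rankable. Each lineage's TFs carry a constant
  own-lineage offset plus a Gaussian pseudotime bump centered *before* the
  module's rise. A declining "early precursor" program mirrors each module
  gene with exactly complementary dynamics, keeping the expected library
  size pseudotime-free; without it, depth normalization converts the
  module's rise into a spurious anti-correlation of every flat gene with
  pseudotime and manufactures false peak-gene links at desk scale (58
  module genes among 400 are a far larger share of the library than in a
  real transcriptome).
- **ATAC.** Poisson counts; promoter peaks of module genes open along the
  gene's own sigmoid in all lineages, early-program promoters close
  complementarily, lineage DAP blocks (one desert per lineage chromosome)
  open only in their lineage with staggered midpoints, and planted CRE
  peaks share a per-cell latent factor with their target gene (common CREs
  in all lineages; lineage-specific CREs converge on shared target genes).
  All planted amplitudes scale with `effect_size_logfc`, so an effect-0
  cohort is fully dynamics-free. Fragments are expanded lazily from counts
  with a bimodal nucleosome-free/mono-nucleosome length mixture plus ~30%
  genome-wide background.
- **Motifs.** Reference PWMs (one per TF plus decoys) and noisy
  de-novo-like copies with near-uniform flanks; occurrence is a planted hit
  matrix concentrated in the source TF's lineage DAPs. Context-comparison
  motifs model the same TF recovered in each lineage: mesenchymal variants
  carry lineage-specific heterodimeric 5′ extensions, non-mesenchymal ones
  are exact copies.
- **Conservation.** Per-base Beta scores over peaks, mean 0.8 on shared
  elements versus 0.35 on lineage-specific ones (sd 0.1).
- **Null.** `null_cohort` permutes cell labels within lineage ×
  depth-quartile strata, leaving all marginals intact.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: doublets and ambient RNA, batch effects
beyond depth, sequence-level motif occurrences (hits are planted, not
scanned from DNA, except in toy-sequence tests), realistic genome geometry
(genes sit on a regular 600 kb grid so link windows never overlap
neighboring genes), per-peak copy number or mappability artifacts, and the
near-binary sparsity of real scATAC (per-peak rates are set so QC
thresholds designed for real depths remain applicable).

## Problem sizes

Default verification conditions are 3 × 1500 cells, 400 genes, 600 peaks;
structural verdicts (co-clading, promoter-vs-distal, conservation
ordering) are checked across 10 generator seeds. Marker-test calibration
uses ~2100 features at 700 cells/lineage; power uses 300 vs 300 cells with
a planted two-fold effect, scored over genes whose planted fold between
the sampled groups reaches two-fold under the model. Unit tests run the
same code on 300-cell lineages.

## Known limitations

- The likelihood-ratio logistic test treats cells as independent; it does
  not model the pseudo-replication of real multi-embryo designs (the
  pseudobulk route in the source workflow exists for that reason and is
  approximated here only by treating pseudobulk replicates as
  observations).
- Aggregate-based link p-values ignore aggregate overlap; the FDR bound is
  honest only marginally, and precision depends on population size.
- Open-ended DTW optimizes mean path cost over boundary cuts; within flat
  profile stretches the alignment is inherently ambiguous and the reported
  cut location there is arbitrary to within the dissimilarity noise.
- The deviation-score background matches GC and mean accessibility but not
  temporal dynamics; with strong planted dynamics, null motif sets keep a
  set-level variance component (the calibration claim therefore refers to
  the exchangeable, effect-free regime).
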